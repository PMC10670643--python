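# Methods

`ctcpanel` implements a transcript-based pipeline for detecting circulating
tumor cells (CTCs) in liquid biopsies of esophageal squamous cell carcinoma
(ESCC) style cohorts, together with a synthetic-study generator that provides
ground truth for every stage. This note documents the models, the numerical
choices, and what the synthetic data do and do not establish.

## Relative quantification (2^−ΔΔCt)

RT-qPCR quantification cycles are normalized in two steps:
ΔCt(g, s) = Ct(g, s) − Ct(ref, s) against a housekeeping reference gene
(default *GAPDH*), and fold change fc(g, s) = 2^−(ΔCt(g, s) − ΔCt_cal(g))
against a calibrator. The calibrator is the per-gene **mean ΔCt across all
healthy-donor (HD) control samples**; HDs are treated as one pooled control
group rather than batch-matched calibrators, because nothing in the data
model distinguishes batches. Assumptions: amplification efficiency is exactly
2 (no efficiency correction) and a single reference gene suffices (no
multi-gene geometric averaging).

Two deliberate conventions:

* An *Undetermined* well (no amplification within 40 cycles) maps to fold
  change 0, i.e. "not detected" — **not** to Ct = 40. Imputing the clip value
  would manufacture small nonzero fold changes for absent transcripts.
* A sample whose reference gene fails is excluded with a warning instead of
  aborting the run; losing one sample should not lose the cohort.

Fold changes are discretized into three levels: negative (fc < 2), positive
(fc ≥ 2), high (fc ≥ 5). Both bounds are closed from below (a fold change of
exactly 2.0 is positive), matching the clinical reporting convention of
"fold change ≥ 2.0"; the thresholds are parameters (`pos_fc`, `high_fc`)
everywhere.

## Panel-derivation cascade

Candidate markers must be expressed in tumor cells and silent in the
peripheral-blood mononuclear cell (PBMC) background. Four filters run in
fixed order; each consumes its own assay:

1. **Single-cell screen** — keep genes with mean raw count < 0.10 in PBMCs
   *and* > 1.0 in the tumor population (both strict, on unnormalized counts).
2. **Pure-population qPCR** — exclude genes with PBMC Ct < 30 (leukocyte
   expression) or tumor Ct > 30 (weak tumor expression); an undetermined
   tumor well counts as not expressed. The Ct vectors are replicate means.
3. **Spike-in sensitivity** — keep genes called positive (fold change ≥ 2
   versus a PBMC-only control) at the 500-cell spike level in *every* tested
   cell line. "Detected" reuses the quantification module's call so the
   pipeline has exactly one detection definition.
4. **Pilot positivity** — keep genes detected in ≥ 30% of pilot blood
   samples (exactly 30% is kept).

Stages 1–2 are per-gene predicates and provably commute; the fixed order is
kept for the audit trail. Every candidate receives a terminal record: the
per-stage statistics, pass flags, and the stage of elimination. The cascade
refuses to return an empty panel and names the stage at which the last gene
was lost.

## CTC classification

A sample's detected-marker count n is the number of panel genes called
positive or high. Thresholds: **CTC-positive** at n ≥ 2, **CTC-high** at
n ≥ 5 (both configurable). A sample co-expressing the epithelial marker
*EpCAM* and the mesenchymal marker *TWIST1* is **hybrid-EMT**, an
intermediate epithelial/mesenchymal phenotype. By construction CTC-high ⊆
CTC-positive and hybrid-EMT ⊆ CTC-positive (two detected genes imply n ≥ 2).

The CTC-high count threshold can be re-derived by ROC analysis of n against
a binary survival outcome. The outcome is coded as event occurrence
(progression for PFS, death for OS) by end of follow-up — a documented
configuration choice, since a fixed-horizon coding would be equally
defensible. Sensitivity/specificity are evaluated at every integer threshold
k (predicted positive when n ≥ k); the chosen k is the smallest maximizing
Youden's J (ties resolved in favor of sensitivity); AUC is the trapezoidal
area of the step curve, identical to the tie-corrected Mann–Whitney
statistic. Patient-level status uses the baseline sample only; follow-up
samples feed the trajectory analysis (direction of change in n per patient,
summarized per treatment arm).

## Association statistics

Marker/status indicators are tested against clinical dichotomies (age ≤68 vs
>68, TNM 0–II vs III–IV, T0–T2 vs T3–T4, N0–N1 vs N2–N3, M0 vs M1, lower vs
upper/middle location, treatment arm) in 2×2 tables. The primary test is the
**exact two-sided Fisher test**, computed by enumerating all tables with the
observed margins and summing hypergeometric probabilities not exceeding the
observed table's point probability (the "sum of small p" rule). A relative
tie tolerance of 1e−7 prevents floating-point exclusion of exactly tied
tables. A zero margin carries no information and returns p = 1 with a
warning, because simulated cohorts can produce saturated columns. Pearson's
chi-square (optional Yates correction) and the asymptotic two-sample
Kolmogorov–Smirnov test are available behind the same interface. No
multiplicity correction is applied by default, matching the
single-comparison reporting convention; Benjamini–Hochberg adjustment is an
explicit opt-in.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test, and Cox proportional
hazards are provided through lifelines with validated interfaces. Times are
positive days; events precede censorings at ties; the median is the smallest
time with S(t) ≤ 0.5 (NaN if never reached). Cox models use **Efron tie
handling** — day-resolution times make ties common and Efron is less biased
than Breslow — with lifelines' Newton–Raphson and step-halving. Covariate
coding: age continuous in years, gender binary, TNM dichotomized at stage
III (matching the contingency dichotomy), treatment arm binary. Constant
covariates are dropped with a warning (an all-constant model reduces to the
null model); non-convergence and monotone-likelihood separation are flagged
rather than silently reported. No stratified Cox, time-varying covariates,
or competing risks.

## Synthetic-study generator

The generator emulates the data *structure* of a two-arm liquid-biopsy
study; all randomness flows from one seed through named, order-independent
substreams.

**Single-cell screen.** 224 candidate genes (40 true markers) over 1000
PBMCs and 200 tumor cells. Counts are negative binomial parameterized by
mean and dispersion k (variance μ + μ²/k, k = 0.5), the standard
overdispersed model for single-cell counts. Markers: mean 0.02 in PBMCs, 5.0
in tumor cells; background genes: mean 3.0 in both. No batch effects,
ambient RNA, or library-size variation are modeled.

**qPCR measurement model.** Ct = 38 − log2(relative abundance) + N(0, 0.25),
clipped to [10, 40]; a noiseless Ct past 40 cycles is reported Undetermined.
The spike-in layout spans 5–5000 tumor cells in 50,000 PBMCs (the 1:10,000
to 1:100 ratio series) for two cell lines plus a PBMC-only control. No
amplification-efficiency drift or PCR inhibition is modeled.

**Cohort.** 55 patients split 24/31 into palliative/curative arms. A latent
binary CTC-burden state (prevalence 28/55) drives everything: per-gene log2
fold changes over the HD level are N(1.55, 1) for high-burden and
N(0.20, 1) for low-burden patients. The means were calibrated analytically —
integrating the detection probability over the shared reference-gene noise
within a sample (a one-factor Gauss–Hermite quadrature; the shared noise
correlates detections with ρ ≈ 0.05 and an independence calibration misses
the target by ~2 points) — so that the expected patient-level CTC-positive
and CTC-high rates equal 46/55 (83.6%) and 28/55 (50.9%). Monte Carlo over
100 seeds confirms pooled rates of 83.3%/50.6%. Stage variables are drawn
with burden-dependent probabilities so marker–stage associations exist;
age, gender, and location are burden-independent.

**Survival.** Exponential proportional hazards with the burden state
(log HR = log 2.5) and treatment arm (log HR = log 119/299) in the linear
predictor; stage has no direct hazard effect, so a Cox fit of the burden
indicator is unconfounded. PFS is the composite of a progression draw and
the OS time (minimum), which preserves proportionality in the burden
effect. The baseline death hazard (0.003537/day) and the
progression-to-death hazard ratio (e^−0.875) were solved from the target
per-arm medians of the emulated cohort (palliative PFS/OS 84/119 days,
curative 243/299 days) under the burden mixture: the implied asymptotic medians
are 84/122 days (palliative PFS/OS) and 205/293 days (curative) — a single
arm-multiplier cannot match both arms'
PFS/OS ratios exactly. Administrative censoring at 1095 days.

**What passing tests do not show.** The generator reproduces marginal
positivity rates, hazard directions, and the study's data layout — not
per-gene fold-change distributions (no reference distributions exist to
calibrate against), inter-gene
expression correlation beyond the shared-reference factor, batch effects,
or informative censoring. Parameter-recovery results on these data
demonstrate correctness of the estimators, not clinical validity of the
panel on real cohorts.

## Reproducibility and problem sizes

Fixed seeds make every generated dataset byte-identical when serialized.
The test suite and acceptance script use 20 replicate cohorts of 55 patients
for calibration checks and 20 cohorts of 2000 patients for Cox parameter
recovery (SE(β̂) ≈ 0.046 for a binary covariate at that size, so recovered
hazard ratios scatter roughly ±0.12 around 2.5). The exhaustive Fisher
validation sweeps every 2×2 table with N ≤ 30 (46,375 tables) against an
exact-rational oracle.

## Known limitations

* Calibrator choice (pooled HD mean) and ROC outcome coding are conventions;
  alternatives (batch-matched calibrators, fixed-horizon outcomes) would
  change numeric results on real data.
* The latent burden is binary; the analysis only consumes dichotomies, but a
  continuous burden would induce gradual dose–response patterns the
  generator cannot produce.
* The exact Fisher enumeration uses floating-point hypergeometric
  probabilities with a tie tolerance rather than exact rationals; the test
  suite verifies equality with a rational oracle over all N ≤ 30 and spot
  checks beyond.
* Proportional-hazards diagnostics are out of scope; the Cox interface flags
  only non-convergence and separation.
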