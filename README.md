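# ctcpanel

Transcript-based detection of circulating tumor cells (CTCs) from
liquid-biopsy RT-qPCR panels, with the downstream prognostic statistics and a
fully specified synthetic-study generator.

## The problem

CTCs shed by a primary tumor into peripheral blood are rare and fragile, and
after size-based enrichment the captured fraction is still dominated by
peripheral-blood mononuclear cells (PBMCs). A practical molecular alternative
to imaging-based enumeration is to profile a small panel of tumor-enriched,
leukocyte-silent gene transcripts by RT-qPCR and call a sample CTC-positive
when enough panel genes are detected. This package implements that entire
workflow for cohorts of the kind studied in esophageal squamous cell
carcinoma (ESCC):

* **Panel derivation** — a four-stage filter cascade reducing a candidate
  gene list to the final CTC panel: single-cell screen
  (mean reads < 0.10 in PBMCs, > 1.0 in tumor cells), pure-population qPCR
  (exclude PBMC Ct < 30 or tumor Ct > 30), spike-in sensitivity (detected at
  500 tumor cells in every cell line), and pilot positivity (≥ 30% of pilot
  samples), with a per-gene audit trail.
* **Relative quantification** — the 2^−ΔΔCt method: ΔCt against a reference
  gene (*GAPDH*), ΔΔCt against healthy-donor calibrators, and three-level
  marker calls: negative (fc < 2), positive (fc ≥ 2), high (fc ≥ 5).
* **Classification** — per-sample detected-marker counts n; CTC-positive
  (n ≥ 2), CTC-high (n ≥ 5, threshold selectable by ROC/Youden analysis
  against a survival outcome), and the hybrid-EMT phenotype (*EpCAM* and
  *TWIST1* co-expression); longitudinal marker trajectories across paired
  time points.
* **Association statistics** — exact two-sided Fisher tests (hypergeometric
  enumeration, sum-of-small-p rule), Pearson chi-square, and two-sample
  Kolmogorov–Smirnov, over the standard clinicopathological dichotomies.
* **Survival** — Kaplan–Meier curves, log-rank tests, and Cox proportional
  hazards (Efron ties) for PFS/OS stratified by marker and CTC status.
* **Simulation** — negative-binomial single-cell screens, a log2-linear Ct
  measurement model, spike-in series, and a 55-patient two-arm cohort whose
  latent CTC burden drives marker fold changes and survival, calibrated so
  the expected CTC-positive/CTC-high patient rates are 83.6%/50.9%.

The scientific reasoning behind every model and threshold is in
[docs/methods.md](docs/methods.md).

## Worked example

Exact Fisher test on a published-style 2×2 table (rows: N0–N1 vs N2–N3
node stage; columns: marker positive vs negative):

```python
>>> from ctcpanel import fisher_exact_two_sided
>>> res = fisher_exact_two_sided([[11, 16], [22, 6]])
>>> round(res.p_value, 3), round(res.statistic, 5)
(0.006, 0.00378)
```

The p-value (0.006) is the exact probability, under fixed margins, of a
table at most as likely as the observed one; the statistic is the observed
table's hypergeometric point probability.

A full synthetic study from the command line:

```bash
ctcpanel simulate --out study --seed 7
ctcpanel run --input study --out results --seed 7
ctcpanel report --summary results/summary.json
```

which prints, for this seed:

```
patient-level rates: {"n": 55, "ctc_positive_rate": 0.855, "ctc_high_rate": 0.455, "hybrid_emt_rate": 0.291}
sample-level rates:  {"n": 77, "ctc_positive_rate": 0.818, "ctc_high_rate": 0.377, "hybrid_emt_rate": 0.247}
7 association(s) with p < 0.05
ctc_positive (os): logrank_p=0.154 hr=1.6
ctc_high (os): logrank_p=0.015 hr=3.4
hybrid_emt (os): logrank_p=0.289 hr=2.58
```

Reading this: 85% of the 55 simulated patients are CTC-positive at baseline
and 45% CTC-high; CTC-high patients die faster (adjusted hazard ratio 3.4,
log-rank p = 0.015), reflecting the latent burden state the simulator
planted (true HR 2.5) plus the sampling noise of a 55-patient cohort. The
`results/` directory also contains the per-gene calls (`calls.tsv`), sample
statuses (`ctc_status.tsv`), ROC table, association grid, Kaplan–Meier
curves, Cox summaries, and a schema-validated `summary.json`.

Panel derivation on the built-in constructed dataset (true markers plus
decoys that each violate exactly one stage):

```bash
$ ctcpanel derive-panel --out panel.json
panel of 10 gene(s): CCND1, ECT2, EpCAM, FSCN1, KRT5, KRT18, MET, TFRC, TWIST1, VEGFC
```

## Layout

```
src/ctcpanel/
  config.py     SimConfig / RunConfig (all thresholds live here)
  simulate.py   synthetic-study generators + ground truth
  quantify.py   ddCt transformer, fold changes, three-level calls
  panel.py      four-stage cascade (PanelSelector) + audit trail
  classify.py   CtcClassifier, ROC thresholding, trajectories
  stats.py      exact Fisher, chi-square, KS, contingency grids
  survival.py   KM / log-rank / Cox interfaces
  readwrite.py  TSV/MTX/CSV/JSON readers and writers, summary schema
  pipeline.py   quantify -> classify -> associate -> survive
  cli.py        `ctcpanel` command-line interface
```

Estimator classes follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, trailing-underscore fitted attributes) and compose
with sklearn tooling.
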