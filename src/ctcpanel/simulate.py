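"""Synthetic-data generators for every input the pipeline consumes.

The simulator emulates the structure of a molecular CTC study: a 10x-style
single-cell screen of candidate marker genes against a PBMC background,
RT-qPCR Ct tables for pure populations, tumor-cell spike-in series and
patient blood samples, and a survival-annotated two-arm patient cohort.
Every dataset carries a :class:`GroundTruth` record of the latent state
used to generate it, so downstream stages can be tested for recovery.

The qPCR measurement model is

    Ct = ct_intercept - log2(relative abundance) + N(0, ct_noise_sd),

clipped to the instrument range; templates whose noiseless Ct would exceed
``ct_max`` are reported as missing (an "Undetermined" well).  Patient
marker abundance is driven by a latent binary CTC-burden state: high-burden
patients draw per-gene log2 fold changes around ``fc_mu_pos``, low-burden
patients around ``fc_mu_neg``.  Survival times follow an exponential
proportional-hazards model whose linear predictor contains the burden
state and the treatment arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .config import SimConfig

Design = Literal["pure", "spike_in", "cohort"]

PBMC_LABEL = "PBMC"
TUMOR_LABEL = "tumor"


@dataclass
class GroundTruth:
    """Latent state of a generated dataset; never fed to the pipeline."""

    marker_genes: list[str] = field(default_factory=list)
    burden: dict[str, int] = field(default_factory=dict)   # patient -> 0/1
    log_hazard: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"marker_genes": self.marker_genes, "burden": self.burden,
                 "log_hazard": self.log_hazard},
                fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(marker_genes=list(raw["marker_genes"]),
                   burden=dict(raw["burden"]),
                   log_hazard=dict(raw["log_hazard"]))


@dataclass
class CohortData:
    """Bundle returned by :func:`gen_cohort`."""

    patients: pd.DataFrame
    samples: pd.DataFrame
    ct: pd.DataFrame
    ground_truth: GroundTruth


def _nb_draws(rng: np.random.Generator, mean: float, k: float, size) -> np.ndarray:
    """Negative binomial with variance mu + mu^2/k; mean 0 degenerates to zeros."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int64)


def gen_single_cell_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate the single-cell candidate screen.

    Returns a dense cell x gene count DataFrame, a population label per
    cell (``PBMC`` or ``tumor``), and the ground-truth marker gene list.
    Marker genes draw counts with mean ``nb_mean_pbmc`` in PBMCs and
    ``nb_mean_tumor`` in tumor cells; background genes draw with mean
    ``nb_mean_background`` in both populations, so the true markers are
    separated from the background on both stage-1 filter axes by
    construction.
    """
    if config.n_pbmc_cells <= 0 or config.n_tumor_cells <= 0:
        raise ValueError("cell counts must be positive")
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive")

    rng = config.rng("single_cell")
    n_marker = config.n_marker_genes
    markers = [f"MK{i + 1:03d}" for i in range(n_marker)]
    background = [f"BG{i + 1:03d}" for i in range(config.n_genes - n_marker)]
    genes = markers + background

    n_p, n_t = config.n_pbmc_cells, config.n_tumor_cells
    counts = np.zeros((n_p + n_t, len(genes)), dtype=np.int64)
    k = config.nb_dispersion
    for j, gene in enumerate(genes):
        if gene in markers:
            counts[:n_p, j] = _nb_draws(rng, config.nb_mean_pbmc, k, n_p)
            counts[n_p:, j] = _nb_draws(rng, config.nb_mean_tumor, k, n_t)
        else:
            counts[:n_p, j] = _nb_draws(rng, config.nb_mean_background, k, n_p)
            counts[n_p:, j] = _nb_draws(rng, config.nb_mean_background, k, n_t)

    cells = [f"PBMC_{i + 1:04d}" for i in range(n_p)] + \
            [f"TUM_{i + 1:04d}" for i in range(n_t)]
    populations = pd.Series(
        [PBMC_LABEL] * n_p + [TUMOR_LABEL] * n_t, index=cells, name="population")
    df = pd.DataFrame(counts, index=cells, columns=genes)
    gt = GroundTruth(marker_genes=markers)
    return df, populations, gt


def _ct_from_abundance(
    rng: np.random.Generator, abundance: np.ndarray, config: SimConfig,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Apply the Ct measurement model; zero abundance reads as missing (NaN)."""
    noise_sd = config.ct_noise_sd if noise_sd is None else noise_sd
    abundance = np.asarray(abundance, dtype=float)
    ct = np.full(abundance.shape, np.nan)
    detected = abundance > 0
    with np.errstate(divide="ignore"):
        ideal = config.ct_intercept - np.log2(np.where(detected, abundance, 1.0))
    noise = rng.normal(0.0, noise_sd, size=abundance.shape) if noise_sd > 0 else 0.0
    ct = np.where(detected, ideal + noise, np.nan)
    ct = np.where(ct > config.ct_max, np.nan, ct)      # past 40 cycles: Undetermined
    ct = np.clip(ct, config.ct_min, config.ct_max)
    ct[~detected] = np.nan
    return ct


def gen_ct_tables(
    config: SimConfig, design: Design,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a Ct table (genes x samples) and its sample manifest.

    ``pure``     -- replicate PBMC and tumor-cell RNA preparations, used by
                    the Ct-based panel filter.
    ``spike_in`` -- tumor cells spiked into a fixed PBMC background over the
                    configured ratio series (including the 500-cell level),
                    for both cell lines, plus a PBMC-only control.
    ``cohort``   -- patient blood samples; shorthand for
                    :func:`gen_cohort`, returning only its Ct table and
                    manifest.

    The reference gene is present in every sample.
    """
    if design == "cohort":
        data = gen_cohort(config)
        return data.ct, data.samples
    if design == "pure":
        return _gen_pure(config)
    if design == "spike_in":
        return _gen_spikein(config)
    raise ValueError(f"unknown design {design!r}")


# relative-abundance constants (log2 units above 1) shared by the layouts
_REF_LOG2 = 18.0          # reference gene: Ct ~ intercept - 18
_TUMOR_MARKER_LOG2 = 16.0  # markers in pure tumor RNA: strongly expressed
_BACKGROUND_LOG2 = 12.0    # PBMC-expressed background genes
_PER_CELL_LOG2 = 4.0       # marker abundance contributed per spiked tumor cell
_LEAK_LOG2 = 1.0           # trace marker signal in pure PBMC preparations
_COHORT_BASE_LOG2 = 8.0    # healthy-donor marker abundance (dCt = 10)


def _gen_pure(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = config.rng("ct_pure")
    n_marker = config.n_marker_genes
    markers = [f"MK{i + 1:03d}" for i in range(n_marker)]
    background = [f"BG{i + 1:03d}" for i in range(config.n_genes - n_marker)]
    genes = [config.reference_gene] + markers + background
    reps = 3
    samples = [f"PBMC_R{i + 1}" for i in range(reps)] + \
              [f"TUMOR_R{i + 1}" for i in range(reps)]
    abund = np.zeros((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        if gene == config.reference_gene:
            abund[i, :] = 2.0 ** _REF_LOG2
        elif gene in markers:
            abund[i, :reps] = 0.0                       # absent in PBMCs
            abund[i, reps:] = 2.0 ** _TUMOR_MARKER_LOG2
        else:
            abund[i, :reps] = 2.0 ** _BACKGROUND_LOG2   # Ct ~ 26 < 30 in PBMCs
            abund[i, reps:] = 2.0 ** _BACKGROUND_LOG2
    ct = pd.DataFrame(_ct_from_abundance(rng, abund, config),
                      index=pd.Index(genes, name="gene"), columns=samples)
    ct.loc[config.reference_gene] = ct.loc[config.reference_gene].fillna(
        config.ct_intercept - _REF_LOG2)
    manifest = pd.DataFrame({
        "sample_id": samples,
        "population": [PBMC_LABEL] * reps + [TUMOR_LABEL] * reps,
        "replicate": list(range(1, reps + 1)) * 2,
    })
    return ct, manifest


def _gen_spikein(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = config.rng("ct_spikein")
    genes = [config.reference_gene] + list(config.panel_genes)
    rows = [{"sample_id": "PBMC_CONTROL", "cell_line": "none", "spike_cells": 0}]
    for line in config.spike_cell_lines:
        for level in config.spike_levels:
            rows.append({"sample_id": f"{line}_S{level}",
                         "cell_line": line, "spike_cells": level})
    manifest = pd.DataFrame(rows)
    abund = np.zeros((len(genes), len(manifest)))
    for j, row in manifest.iterrows():
        for i, gene in enumerate(genes):
            if gene == config.reference_gene:
                abund[i, j] = 2.0 ** _REF_LOG2
            else:
                # trace leakage in the PBMC background plus the spiked signal
                abund[i, j] = 2.0 ** _LEAK_LOG2 + \
                    row["spike_cells"] * 2.0 ** _PER_CELL_LOG2
    ct = pd.DataFrame(_ct_from_abundance(rng, abund, config),
                      index=pd.Index(genes, name="gene"),
                      columns=list(manifest["sample_id"]))
    ct.loc[config.reference_gene] = ct.loc[config.reference_gene].fillna(
        config.ct_intercept - _REF_LOG2)
    return ct, manifest


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

_T_LOW = ("T1", "T2")
_T_HIGH = ("T3", "T4")
_N_LOW = ("N0", "N1")
_N_HIGH = ("N2", "N3")


def gen_cohort(config: SimConfig) -> CohortData:
    """Simulate the patient cohort, its blood samples, and their Ct table.

    Every patient contributes a baseline sample; a ``paired_fraction``
    subset contributes a follow-up sample (pre-cycle-III in the palliative
    arm, one-month post-op in the curative arm).  Healthy-donor control
    samples provide the fold-change calibrator.  Clinical stage variables
    are drawn with burden-dependent probabilities so that marker status
    and stage are positively associated; survival times come from an
    exponential proportional-hazards model with the burden state and
    treatment arm in the linear predictor (stage has no direct effect on
    hazard).
    """
    if config.n_patients < 2:
        raise ValueError("need at least 2 patients")
    if config.censor_time <= 0:
        raise ValueError("censor_time must be positive")

    rng_pat = config.rng("cohort.patients")
    rng_fc = config.rng("cohort.foldchange")
    rng_ct = config.rng("cohort.ct")
    rng_surv = config.rng("cohort.survival")

    n = config.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    burden = (rng_pat.random(n) < config.burden_prevalence).astype(int)
    arm = np.where(rng_pat.random(n) < config.arm_fractions[0],
                   "palliative", "curative")
    age = np.clip(np.round(rng_pat.normal(66, 9, n)), 33, 82).astype(int)
    gender = np.where(rng_pat.random(n) < 49 / 55, "M", "F")
    location = np.where(rng_pat.random(n) < 25 / 55, "lower", "upper/middle")

    # stage probabilities conditional on burden, set so the marginal rates
    # match the cohort composition (T3-T4 ~ 0.82, N2-N3 ~ 0.51, M1 ~ 0.25,
    # TNM III-IV ~ 0.60)
    p_t = np.where(burden == 1, 0.92, 0.72)
    p_n = np.where(burden == 1, 0.65, 0.37)
    p_m = np.where(burden == 1, 0.38, 0.13)
    p_tnm = np.where(burden == 1, 0.78, 0.42)
    t_hi = rng_pat.random(n) < p_t
    n_hi = rng_pat.random(n) < p_n
    m1 = rng_pat.random(n) < p_m
    tnm_hi = (rng_pat.random(n) < p_tnm) | m1
    t_stage = np.where(t_hi, rng_pat.choice(_T_HIGH, n), rng_pat.choice(_T_LOW, n))
    n_stage = np.where(n_hi, rng_pat.choice(_N_HIGH, n), rng_pat.choice(_N_LOW, n))
    m_stage = np.where(m1, "M1", "M0")
    tnm = np.where(m1, "IV",
                   np.where(tnm_hi, "III", rng_pat.choice(["I", "II"], n)))

    # survival: exponential PH; PFS is the composite of progression and
    # death, taken as the minimum of the progression draw and the OS time
    lin = config.log_hr_ctc_high * burden + \
        config.log_hr_curative * (arm == "curative")
    rate_os = config.hazard_baseline * np.exp(lin)
    rate_prog = config.hazard_baseline * np.exp(lin + config.log_hr_progression)
    os_raw = rng_surv.exponential(1.0 / rate_os)
    pfs_raw = np.minimum(rng_surv.exponential(1.0 / rate_prog), os_raw)
    os_days = np.ceil(np.minimum(os_raw, config.censor_time)).astype(int)
    pfs_days = np.ceil(np.minimum(pfs_raw, config.censor_time)).astype(int)
    os_event = (os_raw <= config.censor_time).astype(int)
    pfs_event = (pfs_raw <= config.censor_time).astype(int)

    patients = pd.DataFrame({
        "patient_id": patient_ids, "age": age, "gender": gender,
        "location": location, "t_stage": t_stage, "n_stage": n_stage,
        "m_stage": m_stage, "tnm_stage": tnm, "treatment_arm": arm,
        "pfs_days": pfs_days, "pfs_event": pfs_event,
        "os_days": os_days, "os_event": os_event,
    })

    # samples: one baseline each, paired follow-up for a stratified subset
    rows = []
    for pid in patient_ids:
        rows.append({"sample_id": f"S{len(rows) + 1:03d}", "patient_id": pid,
                     "timepoint": "baseline", "role": "case"})
    n_paired = round(config.paired_fraction * n)
    paired_idx = rng_pat.choice(n, size=n_paired, replace=False) if n_paired else []
    followup_burden = burden.copy()
    for i in sorted(paired_idx):
        pid = patient_ids[i]
        tp = "preIII" if arm[i] == "palliative" else "postop"
        rows.append({"sample_id": f"S{len(rows) + 1:03d}", "patient_id": pid,
                     "timepoint": tp, "role": "case"})
        if burden[i] and rng_pat.random() < config.followup_response_rate:
            followup_burden[i] = 0
    for h in range(config.n_hd):
        rows.append({"sample_id": f"HD{h + 1:02d}", "patient_id": f"HD{h + 1:02d}",
                     "timepoint": "baseline", "role": "healthy_control"})
    samples = pd.DataFrame(rows)

    # per-sample per-gene log2 fold change over the healthy-donor level
    genes = [config.reference_gene] + list(config.panel_genes)
    idx = {pid: i for i, pid in enumerate(patient_ids)}
    n_panel = len(config.panel_genes)
    log2fc = np.zeros((n_panel, len(samples)))
    for j, row in samples.iterrows():
        if row["role"] == "healthy_control":
            continue  # HDs sit at the calibrator level by definition
        i = idx[row["patient_id"]]
        b = burden[i] if row["timepoint"] == "baseline" else followup_burden[i]
        mu = config.fc_mu_pos if b else config.fc_mu_neg
        log2fc[:, j] = rng_fc.normal(mu, config.fc_sd, n_panel)

    abund = np.zeros((len(genes), len(samples)))
    abund[0, :] = 2.0 ** _REF_LOG2
    abund[1:, :] = 2.0 ** (_COHORT_BASE_LOG2 + log2fc)
    ct = pd.DataFrame(_ct_from_abundance(rng_ct, abund, config),
                      index=pd.Index(genes, name="gene"),
                      columns=list(samples["sample_id"]))
    ct.loc[config.reference_gene] = ct.loc[config.reference_gene].fillna(
        config.ct_intercept - _REF_LOG2)

    gt = GroundTruth(
        marker_genes=list(config.panel_genes),
        burden={pid: int(b) for pid, b in zip(patient_ids, burden)},
        log_hazard={"ctc_high_burden": config.log_hr_ctc_high,
                    "curative_arm": config.log_hr_curative,
                    "progression_vs_death": config.log_hr_progression,
                    "baseline": config.hazard_baseline},
    )
    return CohortData(patients=patients, samples=samples, ct=ct, ground_truth=gt)


# --------------------------------------------------------------------------
# constructed cascade fixture
# --------------------------------------------------------------------------

@dataclass
class CascadeDataset:
    """All four stage inputs of the panel cascade with known truth.

    True marker genes satisfy every stage threshold; each decoy gene is
    built to violate exactly one stage while passing the other three.
    """

    counts: pd.DataFrame
    populations: pd.Series
    ct_pure: pd.DataFrame          # per-gene PBMC / tumor Ct columns
    ct_spike: pd.DataFrame
    spike_manifest: pd.DataFrame
    ct_pilot: pd.DataFrame
    pilot_manifest: pd.DataFrame
    ground_truth: GroundTruth


def gen_panel_cascade_dataset(config: SimConfig, n_decoys_per_stage: int = 3,
                              ) -> CascadeDataset:
    """Build a dataset on which the four-stage cascade has a known answer.

    The candidate list is the configured panel plus ``n_decoys_per_stage``
    decoys per stage, named ``D<stage><k>``.  Deterministic abundances are
    used (measurement noise only), with margins several noise SDs wide of
    every threshold, so recovery is exact.
    """
    markers = list(config.panel_genes)
    ref = config.reference_gene
    decoys = {s: [f"D{s}{k + 1}" for k in range(n_decoys_per_stage)]
              for s in (1, 2, 3, 4)}
    all_decoys = [g for gs in decoys.values() for g in gs]
    genes = markers + all_decoys

    # stage 1: single-cell counts.  Stage-1 decoys have a PBMC mean of ~0.5;
    # everything else behaves like a true marker (PBMC ~0.02, tumor ~5).
    rng = config.rng("cascade.counts")
    n_p, n_t = 400, 200
    counts = np.zeros((n_p + n_t, len(genes)), dtype=np.int64)
    for j, gene in enumerate(genes):
        pbmc_mean = 0.5 if gene in decoys[1] else config.nb_mean_pbmc
        counts[:n_p, j] = _nb_draws(rng, pbmc_mean, config.nb_dispersion, n_p)
        counts[n_p:, j] = _nb_draws(rng, config.nb_mean_tumor,
                                    config.nb_dispersion, n_t)
    cells = [f"PBMC_{i + 1:04d}" for i in range(n_p)] + \
            [f"TUM_{i + 1:04d}" for i in range(n_t)]
    populations = pd.Series([PBMC_LABEL] * n_p + [TUMOR_LABEL] * n_t,
                            index=cells, name="population")
    counts_df = pd.DataFrame(counts, index=cells, columns=genes)

    # stage 2: pure-population Ct.  Stage-2 decoys read hot in PBMCs (Ct 25).
    rng2 = config.rng("cascade.ct_pure")
    rows = []
    for gene in genes:
        pbmc_log2 = 13.5 if gene in decoys[2] else _LEAK_LOG2   # Ct 24.5 vs 37
        tumor_log2 = _TUMOR_MARKER_LOG2                          # Ct 22
        rows.append((2.0 ** pbmc_log2, 2.0 ** tumor_log2))
    abund = np.array(rows).T  # 2 x genes
    ct_vals = _ct_from_abundance(rng2, abund, config, noise_sd=0.1)
    ct_pure = pd.DataFrame(
        {"PBMC": ct_vals[0], "tumor": ct_vals[1]},
        index=pd.Index(genes, name="gene"))

    # stage 3: spike-in series.  Stage-3 decoys carry no per-cell signal in
    # the second cell line until the top spike level.
    rng3 = config.rng("cascade.ct_spike")
    srows = [{"sample_id": "PBMC_CONTROL", "cell_line": "none", "spike_cells": 0}]
    for line in config.spike_cell_lines:
        for level in config.spike_levels:
            srows.append({"sample_id": f"{line}_S{level}",
                          "cell_line": line, "spike_cells": level})
    spike_manifest = pd.DataFrame(srows)
    sgenes = [ref] + genes
    abund = np.zeros((len(sgenes), len(spike_manifest)))
    weak_line = config.spike_cell_lines[-1]
    for j, row in spike_manifest.iterrows():
        for i, gene in enumerate(sgenes):
            if gene == ref:
                abund[i, j] = 2.0 ** _REF_LOG2
                continue
            per_cell = 2.0 ** _PER_CELL_LOG2
            if gene in decoys[3] and row["cell_line"] == weak_line \
                    and row["spike_cells"] <= 500:
                per_cell = 0.0   # undetectable at the required level
            abund[i, j] = 2.0 ** _LEAK_LOG2 + row["spike_cells"] * per_cell
    ct_spike = pd.DataFrame(_ct_from_abundance(rng3, abund, config, noise_sd=0.1),
                            index=pd.Index(sgenes, name="gene"),
                            columns=list(spike_manifest["sample_id"]))
    ct_spike.loc[ref] = ct_spike.loc[ref].fillna(config.ct_intercept - _REF_LOG2)

    # stage 4: pilot blood samples.  Stage-4 decoys are positive in only 2 of
    # the pilot samples (rate < 0.30); all other genes in ~60%.
    rng4 = config.rng("cascade.ct_pilot")
    n_pilot = config.n_pilot
    pilot_samples = [f"PL{i + 1:02d}" for i in range(n_pilot)]
    n_pos_common = max(int(np.ceil(0.6 * n_pilot)), 1)
    pgenes = [ref] + genes
    abund = np.zeros((len(pgenes), n_pilot + 1))   # last column: HD control
    for i, gene in enumerate(pgenes):
        if gene == ref:
            abund[i, :] = 2.0 ** _REF_LOG2
            continue
        n_pos = 2 if gene in decoys[4] else n_pos_common
        which = rng4.choice(n_pilot, size=n_pos, replace=False)
        base = 2.0 ** _COHORT_BASE_LOG2
        abund[i, :n_pilot] = base
        abund[i, which] = base * 2.0 ** 4.0        # fold change 16 in positives
        abund[i, n_pilot] = base                   # HD calibrator level
    cols = pilot_samples + ["HD01"]
    ct_pilot = pd.DataFrame(_ct_from_abundance(rng4, abund, config, noise_sd=0.1),
                            index=pd.Index(pgenes, name="gene"), columns=cols)
    ct_pilot.loc[ref] = ct_pilot.loc[ref].fillna(config.ct_intercept - _REF_LOG2)
    pilot_manifest = pd.DataFrame({
        "sample_id": cols,
        "role": ["pilot"] * n_pilot + ["healthy_control"],
    })

    gt = GroundTruth(marker_genes=markers)
    return CascadeDataset(
        counts=counts_df, populations=populations, ct_pure=ct_pure,
        ct_spike=ct_spike, spike_manifest=spike_manifest,
        ct_pilot=ct_pilot, pilot_manifest=pilot_manifest, ground_truth=gt)
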