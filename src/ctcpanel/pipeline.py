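"""End-to-end orchestration: quantify -> classify -> associate -> survive.

:func:`run_pipeline` consumes a directory produced by the ``simulate``
CLI command (or equivalently structured real data), runs each stage in
order, writes the per-stage tabular outputs, and emits a machine-readable
``summary.json`` (validated against the shipped schema) plus a run log
carrying versions, the configuration hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import CtcClassifier, marker_trajectory, roc_threshold, summarize_cohort
from .config import RunConfig
from .panel import PanelDefinition, default_annotation
from .quantify import DeltaDeltaCtQuantifier
from .readwrite import (
    AssociationRecord, ClassificationBlock, ConfigBlock, PipelineSummary,
    QuantificationBlock, StageRates, SurvivalStratum, read_cohort,
    read_ct_table, write_calls_long, write_summary,
)
from .stats import association_grid
from .survival import cox_ph, km_by_group, logrank_test

log = logging.getLogger("ctcpanel")


def _settings(config: RunConfig) -> dict:
    """Analysis parameters only; paths are excluded so runs of the same
    analysis hash identically regardless of where they read and write."""
    return {k: v for k, v in config.to_dict().items()
            if k not in ("input_dir", "out_dir")}


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_settings(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> PipelineSummary:
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_log(outdir, config)

    ct = _load(indir, config)
    patients, samples = read_cohort(indir / "patients.csv", indir / "samples.csv")

    fc, calls, quant_block = _quantify(ct, samples, config, outdir)
    status, cls_block = _classify(calls, patients, samples, config, outdir)
    assoc = _associate(status, calls, patients, samples, config, outdir)
    surv = _survive(status, patients, samples, config, outdir)

    summary = PipelineSummary(
        config=ConfigBlock(seed=config.seed, config_hash=_config_hash(config),
                           settings=_settings(config)),
        quantification=quant_block, classification=cls_block,
        associations=assoc, survival=surv)
    write_summary(summary, outdir / "summary.json")
    log.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary


def _setup_log(outdir: Path, config: RunConfig) -> None:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers = [handler]
    log.setLevel(logging.INFO)
    log.info("ctcpanel %s | seed=%d | config=%s",
             __version__, config.seed, _config_hash(config))


@_stage("load")
def _load(indir: Path, config: RunConfig) -> pd.DataFrame:
    return read_ct_table(indir / "ct_cohort.tsv", config.reference_gene)


@_stage("quantify")
def _quantify(ct, samples, config, outdir):
    controls = list(
        samples.loc[samples["role"] == "healthy_control", "sample_id"])
    if not controls:
        raise ValueError("no healthy_control samples to calibrate against")
    quant = DeltaDeltaCtQuantifier(
        reference_gene=config.reference_gene,
        pos_fc=config.pos_fc, high_fc=config.high_fc)
    quant.fit(ct[controls])
    fc = quant.transform(ct)
    calls = quant.call(ct)
    write_calls_long(fc, calls, outdir / "calls.tsv")
    block = QuantificationBlock(
        n_genes=int(fc.shape[0]), n_samples=int(fc.shape[1]),
        n_control_samples=len(controls), reference_gene=config.reference_gene)
    return fc, calls, block


def _resolve_panel(calls, config) -> PanelDefinition:
    if config.panel_path:
        return PanelDefinition.from_json(config.panel_path)
    genes = [g for g in config.panel_genes if g in calls.index]
    if not genes:
        genes = list(calls.index)
    return PanelDefinition(
        genes=genes,
        provenance=pd.DataFrame(index=pd.Index(genes, name="gene")),
        annotation=default_annotation(genes))


@_stage("classify")
def _classify(calls, patients, samples, config, outdir):
    panel = _resolve_panel(calls, config)
    clf = CtcClassifier(panel=panel, k_pos=config.k_pos, k_high=config.k_high)
    status = clf.predict(calls)
    # ROC re-derivation of the CTC-high threshold from the chosen endpoint
    roc_k, roc_auc = None, None
    base = samples[(samples["role"] == "case")
                   & (samples["timepoint"] == "baseline")]
    merged = base.merge(patients, on="patient_id")
    n_det = status.loc[merged["sample_id"], "n_detected"].to_numpy()
    outcome = merged[f"{config.endpoint}_event"].to_numpy()
    if 0 < outcome.sum() < len(outcome):
        roc = roc_threshold(n_det, outcome, panel_size=len(panel.genes))
        roc_k, roc_auc = roc.chosen_k, roc.auc
        roc.as_frame().to_csv(outdir / "roc.tsv", sep="\t", index=False,
                              float_format="%.6g")
    status.reset_index().to_csv(outdir / "ctc_status.tsv", sep="\t", index=False)
    traj, traj_summary = marker_trajectory(status, samples, patients)
    traj.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    rates = summarize_cohort(status, samples)
    block = ClassificationBlock(
        sample_level=StageRates(**rates["sample_level"]),
        patient_level=StageRates(**rates["patient_level"]),
        k_pos=config.k_pos, k_high=config.k_high,
        roc_chosen_k=roc_k, roc_auc=roc_auc)
    return status, block


def _baseline_status(status, patients, samples) -> pd.DataFrame:
    base = samples[(samples["role"] == "case")
                   & (samples["timepoint"] == "baseline")]
    s = status.loc[base["sample_id"]]
    s.index = pd.Index(base["patient_id"], name="patient_id")
    return s.reindex(patients["patient_id"])


@_stage("associate")
def _associate(status, calls, patients, samples, config, outdir):
    base = _baseline_status(status, patients, samples)
    statuses = base[["ctc_positive", "ctc_high", "hybrid_emt"]].copy()
    # per-gene positivity at baseline
    base_samples = samples[(samples["role"] == "case")
                           & (samples["timepoint"] == "baseline")]
    det = calls.isin(["positive", "high"])
    for gene in calls.index:
        col = det.loc[gene, base_samples["sample_id"]]
        col.index = statuses.index
        statuses[gene] = col
    grid = association_grid(patients, statuses, method="fisher")
    grid.to_csv(outdir / "associations.tsv", sep="\t", index=False,
                float_format="%.6g")
    return [AssociationRecord(**row) for row in grid.to_dict(orient="records")]


@_stage("survive")
def _survive(status, patients, samples, config, outdir):
    base = _baseline_status(status, patients, samples)
    df = patients.copy()
    for col in ("ctc_positive", "ctc_high", "hybrid_emt"):
        df[col] = base[col].to_numpy().astype(bool)
    dur, ev = f"{config.endpoint}_days", f"{config.endpoint}_event"
    # covariate coding: age continuous, gender binary, TNM dichotomized at
    # stage III (matching the clinical dichotomy), arm binary
    df["male"] = (df["gender"] == "M").astype(int)
    df["advanced_stage"] = df["tnm_stage"].isin(["III", "IV"]).astype(int)
    df["curative"] = (df["treatment_arm"] == "curative").astype(int)
    out = []
    km_rows = []
    for stratum in ("ctc_positive", "ctc_high", "hybrid_emt"):
        hi = df[df[stratum]]
        lo = df[~df[stratum]]
        entry = SurvivalStratum(stratum=stratum, endpoint=config.endpoint)
        if len(hi) and len(lo) and df[ev].sum() > 0:
            try:
                lr = logrank_test(lo[dur], lo[ev], hi[dur], hi[ev])
                entry.logrank_p = lr.p_value
            except ValueError:
                pass
            curves = km_by_group(df, dur, ev, stratum)
            entry.median_low = _nan_none(curves["False"].median)
            entry.median_high = _nan_none(curves["True"].median)
            for name, curve in curves.items():
                frame = curve.as_frame()
                frame.insert(0, "group", name)
                frame.insert(0, "stratum", stratum)
                km_rows.append(frame)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = cox_ph(df.assign(**{stratum: df[stratum].astype(int)}),
                                 dur, ev,
                                 [stratum, "age", "male", "advanced_stage",
                                  "curative"])
                    if stratum in fit.summary.index:
                        entry.hr = fit.hazard_ratio(stratum)
                        entry.cox_p = float(fit.summary.loc[stratum, "p"])
                except ValueError:
                    pass
        out.append(entry)
    if km_rows:
        pd.concat(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    pd.DataFrame([e.model_dump() for e in out]).to_csv(
        outdir / "cox.tsv", sep="\t", index=False, float_format="%.6g")
    return out


def _nan_none(x: float):
    return None if x != x else float(x)
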