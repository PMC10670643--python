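"""Readers and writers for every on-disk format the pipeline touches.

Conventions: matrices are tab-separated (first column ``gene``, remaining
columns sample IDs, values numeric / ``NA`` / ``Undetermined``); count
matrices are Matrix Market triplets with ``genes.tsv``, ``cells.tsv`` and
``populations.tsv`` sidecars; cohort metadata are CSV (``patients.csv``,
``samples.csv``); the panel is JSON.  Every writer's output round-trips
through its paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import io as spio
from scipy import sparse

MISSING_TOKENS = {"NA", "Undetermined", "undetermined", ""}

PATIENT_COLUMNS = [
    "patient_id", "age", "gender", "location", "t_stage", "n_stage",
    "m_stage", "tnm_stage", "treatment_arm", "pfs_days", "pfs_event",
    "os_days", "os_event",
]
SAMPLE_COLUMNS = ["sample_id", "patient_id", "timepoint", "role"]
VALID_TIMEPOINTS = {"baseline", "preIII", "postop"}
VALID_ROLES = {"case", "healthy_control", "pilot", "spikein"}


# --------------------------------------------------------------------------
# Ct tables
# --------------------------------------------------------------------------

def write_ct_table(ct: pd.DataFrame, path) -> None:
    out = ct.copy()
    out.index.name = "gene"
    out = out.round(4)
    out.to_csv(path, sep="\t", na_rep="Undetermined", float_format="%.4f")


def read_ct_table(path, reference_gene: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene row(s): {sorted(set(dup))}")
    df = df.set_index("gene")

    def parse(v):
        if pd.isna(v) or str(v).strip() in MISSING_TOKENS:
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise ValueError(f"{path}: non-numeric Ct value {v!r}") from None

    ct = df.map(parse).astype(float)
    bad = ct[(ct < 0) | (ct > 45)].stack()
    if len(bad):
        raise ValueError(f"{path}: Ct values outside [0, 45]: {bad.index.tolist()}")
    if reference_gene is not None and reference_gene not in ct.index:
        raise ValueError(f"{path}: reference gene {reference_gene!r} absent")
    return ct


# --------------------------------------------------------------------------
# single-cell counts
# --------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, populations: pd.Series, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.columns).to_csv(outdir / "genes.tsv", sep="\t",
                                     index=False, header=False)
    pd.Series(counts.index).to_csv(outdir / "cells.tsv", sep="\t",
                                   index=False, header=False)
    populations.reindex(counts.index).to_csv(
        outdir / "populations.tsv", sep="\t", header=False)


def read_counts(matrix_dir) -> tuple[pd.DataFrame, pd.Series]:
    d = Path(matrix_dir)
    mat = spio.mmread(d / "matrix.mtx").toarray()
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(d / "cells.tsv", sep="\t", header=None)[0].tolist()
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"{d}: matrix is {mat.shape} but sidecars describe "
            f"{len(cells)} cells x {len(genes)} genes")
    pops = pd.read_csv(d / "populations.tsv", sep="\t", header=None,
                       index_col=0)[1]
    pops.index.name = None
    missing = set(cells) - set(pops.index)
    if missing:
        raise ValueError(f"{d}: populations.tsv missing cell(s): {sorted(missing)[:5]}")
    counts = pd.DataFrame(mat.astype(np.int64), index=cells, columns=genes)
    return counts, pops.reindex(cells).rename("population")


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def write_cohort(patients: pd.DataFrame, samples: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients[PATIENT_COLUMNS].to_csv(outdir / "patients.csv", index=False)
    samples[SAMPLE_COLUMNS].to_csv(outdir / "samples.csv", index=False)


def read_cohort(patients_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    patients = pd.read_csv(patients_path)
    samples = pd.read_csv(samples_path)
    missing = set(PATIENT_COLUMNS) - set(patients.columns)
    if missing:
        raise ValueError(f"{patients_path}: missing column(s) {sorted(missing)}")
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"{samples_path}: missing column(s) {sorted(missing)}")
    dup = patients["patient_id"][patients["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dup))}")
    for col in ("pfs_event", "os_event"):
        bad = ~patients[col].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"{col} outside {{0,1}} for {patients.loc[bad, 'patient_id'].tolist()}")
    for col in ("pfs_days", "os_days"):
        if (patients[col] <= 0).any():
            raise ValueError(f"{col} must be positive")
    bad_tp = ~samples["timepoint"].isin(VALID_TIMEPOINTS)
    if bad_tp.any():
        raise ValueError(
            f"invalid timepoint(s): {sorted(set(samples.loc[bad_tp, 'timepoint']))}")
    bad_role = ~samples["role"].isin(VALID_ROLES)
    if bad_role.any():
        raise ValueError(
            f"invalid role(s): {sorted(set(samples.loc[bad_role, 'role']))}")
    case = samples[samples["role"] == "case"]
    orphans = set(case["patient_id"]) - set(patients["patient_id"])
    if orphans:
        raise ValueError(f"case sample(s) reference unknown patient(s): "
                         f"{sorted(orphans)}")
    base_counts = case[case["timepoint"] == "baseline"]["patient_id"].value_counts()
    multi = base_counts[base_counts > 1]
    if len(multi):
        raise ValueError(f"multiple baseline samples for patient(s): "
                         f"{multi.index.tolist()}")
    return patients, samples


# --------------------------------------------------------------------------
# long-format exports
# --------------------------------------------------------------------------

def write_calls_long(fc: pd.DataFrame, calls: pd.DataFrame, path) -> None:
    long = (fc.stack().rename("fc").to_frame()
            .join(calls.stack().rename("call")))
    long.index.names = ["gene", "sample"]
    long.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_long(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    long = pd.read_csv(path, sep="\t")
    fc = long.pivot(index="gene", columns="sample", values="fc")
    calls = long.pivot(index="gene", columns="sample", values="call")
    fc.columns.name = calls.columns.name = None
    return fc, calls


# --------------------------------------------------------------------------
# pipeline summary schema
# --------------------------------------------------------------------------

class StageRates(BaseModel):
    n: int
    ctc_positive_rate: float
    ctc_high_rate: float
    hybrid_emt_rate: float


class ClassificationBlock(BaseModel):
    sample_level: StageRates
    patient_level: StageRates
    k_pos: int
    k_high: int
    roc_chosen_k: int | None = None
    roc_auc: float | None = None


class QuantificationBlock(BaseModel):
    n_genes: int
    n_samples: int
    n_control_samples: int
    reference_gene: str


class AssociationRecord(BaseModel):
    marker: str
    variable: str
    a: int
    b: int
    c: int
    d: int
    method: str
    statistic: float
    p: float


class SurvivalStratum(BaseModel):
    stratum: str
    endpoint: str
    logrank_p: float | None = None
    hr: float | None = None
    cox_p: float | None = None
    median_low: float | None = None
    median_high: float | None = None


class ConfigBlock(BaseModel):
    seed: int
    config_hash: str
    settings: dict


class PipelineSummary(BaseModel):
    """Machine-readable end-of-run summary; schema shipped with the package."""

    config: ConfigBlock
    quantification: QuantificationBlock
    classification: ClassificationBlock
    associations: list[AssociationRecord]
    survival: list[SurvivalStratum]


def summary_schema() -> dict:
    return PipelineSummary.model_json_schema()


def shipped_schema_path() -> Path:
    return Path(__file__).parent / "schemas" / "summary.schema.json"


def validate_summary(payload: dict) -> PipelineSummary:
    """Parse and validate a summary JSON payload against the schema."""
    return PipelineSummary.model_validate(payload)


def write_summary(summary: PipelineSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(summary.model_dump_json(indent=1))
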