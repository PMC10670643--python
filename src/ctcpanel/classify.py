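"""Sample-level CTC classification from panel marker calls.

A sample's detected-marker count ``n_detected`` is the number of panel
genes called positive or high (fold change >= 2).  Samples with at least
``k_pos`` (default 2) detected markers are CTC-positive, with at least
``k_high`` (default 5) CTC-high, and samples co-expressing the epithelial
marker EpCAM and the mesenchymal marker TWIST1 carry a hybrid-EMT
phenotype.  The CTC-high count threshold can be chosen by ROC analysis
against a survival-derived binary outcome (Youden's J, smallest
maximizing k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import EPITHELIAL_GENE, MESENCHYMAL_GENE
from .panel import PanelDefinition
from .quantify import is_detected


def classify_samples(
    calls: pd.DataFrame, panel, k_pos: int = 2, k_high: int = 5,
    epithelial_gene: str = EPITHELIAL_GENE,
    mesenchymal_gene: str = MESENCHYMAL_GENE,
) -> pd.DataFrame:
    """Per-sample CTC status from a gene x sample marker-call matrix.

    ``panel`` is a :class:`~ctcpanel.panel.PanelDefinition` or a plain gene
    list; genes outside the panel are ignored, and every panel gene must be
    present in ``calls``.  Returns a DataFrame indexed by sample with
    columns ``n_detected, ctc_positive, ctc_high, hybrid_emt``.
    """
    genes = list(panel.genes) if isinstance(panel, PanelDefinition) else list(panel)
    missing = [g for g in genes if g not in calls.index]
    if missing:
        raise ValueError(f"panel gene(s) missing from calls: {missing}")
    if not (0 <= k_pos <= k_high):
        raise ValueError("need 0 <= k_pos <= k_high")
    det = is_detected(calls.loc[genes])
    n_detected = det.sum(axis=0)
    status = pd.DataFrame({
        "n_detected": n_detected.astype(int),
        "ctc_positive": n_detected >= k_pos,
        "ctc_high": n_detected >= k_high,
    })
    if epithelial_gene in genes and mesenchymal_gene in genes:
        status["hybrid_emt"] = det.loc[epithelial_gene] & det.loc[mesenchymal_gene]
    else:
        warnings.warn(
            f"panel lacks {epithelial_gene}/{mesenchymal_gene}; "
            "hybrid-EMT set to False", stacklevel=2)
        status["hybrid_emt"] = False
    status.index.name = "sample_id"
    return status


@dataclass
class RocResult:
    """ROC over integer detected-marker thresholds.

    ``thresholds[i]`` classifies a sample as predicted-positive when
    ``n_detected >= thresholds[i]``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_j: np.ndarray
    auc: float
    chosen_k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.thresholds, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "youden_j": self.youden_j,
        })


def roc_threshold(n_detected, outcome, panel_size: int | None = None) -> RocResult:
    """ROC analysis of the detected-marker count against a binary outcome.

    Sensitivity and specificity are evaluated at every integer threshold
    k in 0..panel_size (plus the all-negative endpoint for the curve);
    ``chosen_k`` is the smallest k maximizing Youden's J, favoring
    sensitivity among ties.  AUC is the trapezoidal area of the resulting
    step curve, which equals the Mann-Whitney statistic scaled by the
    number of case-control pairs.
    """
    x = np.asarray(n_detected, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("n_detected and outcome must be 1-D of equal length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both outcome classes must be present")
    if panel_size is None:
        panel_size = int(x.max())

    ks = np.arange(0, panel_size + 2)  # last threshold classifies none positive
    sens = np.array([(x[y == 1] >= k).mean() for k in ks])
    spec = np.array([(x[y == 0] < k).mean() for k in ks])
    j = sens + spec - 1.0

    # traverse the staircase from the strictest threshold (0,0) to the most
    # permissive (1,1); both FPR and TPR are non-increasing in k
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    inner = ks <= panel_size
    chosen = int(ks[inner][np.argmax(j[inner])])
    return RocResult(thresholds=ks[inner], sensitivity=sens[inner],
                     specificity=spec[inner], youden_j=j[inner],
                     auc=auc, chosen_k=chosen)


class CtcClassifier(BaseEstimator):
    """CTC-status classifier over marker-call matrices.

    The classifier is usable unfitted with the default count thresholds;
    ``fit(calls, y)`` re-selects ``k_high`` by ROC analysis of the
    detected-marker count against the binary outcome ``y`` (one label per
    sample, aligned with the columns of ``calls``).
    """

    def __init__(self, panel=None, k_pos: int = 2, k_high: int = 5,
                 epithelial_gene: str = EPITHELIAL_GENE,
                 mesenchymal_gene: str = MESENCHYMAL_GENE):
        self.panel = panel
        self.k_pos = k_pos
        self.k_high = k_high
        self.epithelial_gene = epithelial_gene
        self.mesenchymal_gene = mesenchymal_gene

    def _genes(self, calls):
        if self.panel is None:
            return list(calls.index)
        return list(self.panel.genes) if isinstance(self.panel, PanelDefinition) \
            else list(self.panel)

    def fit(self, calls: pd.DataFrame, y):
        genes = self._genes(calls)
        n_det = is_detected(calls.loc[genes]).sum(axis=0).to_numpy()
        self.roc_result_ = roc_threshold(n_det, np.asarray(y), len(genes))
        self.k_high_ = max(self.roc_result_.chosen_k, self.k_pos)
        return self

    def predict(self, calls: pd.DataFrame) -> pd.DataFrame:
        k_high = getattr(self, "k_high_", self.k_high)
        return classify_samples(
            calls, self._genes(calls), self.k_pos, k_high,
            self.epithelial_gene, self.mesenchymal_gene)

    transform = predict


def marker_trajectory(
    status: pd.DataFrame, manifest: pd.DataFrame,
    patients: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Baseline-to-follow-up change in detected-marker counts per patient.

    Patients lacking either time point are skipped with a warning.  The
    summary reports the fraction of patients whose count decreased, per
    treatment arm when patient metadata are given.
    """
    case = manifest[manifest["role"] == "case"]
    base = case[case["timepoint"] == "baseline"].set_index("patient_id")["sample_id"]
    follow = case[case["timepoint"] != "baseline"].set_index("patient_id")["sample_id"]
    rows = []
    for pid in case["patient_id"].unique():
        if pid not in base.index or pid not in follow.index:
            continue
        b, f = base[pid], follow[pid]
        if b not in status.index or f not in status.index:
            warnings.warn(f"patient {pid}: missing classified sample", stacklevel=2)
            continue
        nb = int(status.loc[b, "n_detected"])
        nf = int(status.loc[f, "n_detected"])
        direction = ("decrease" if nf < nb else
                     "increase" if nf > nb else "unchanged")
        rows.append({"patient_id": pid, "baseline_n": nb, "followup_n": nf,
                     "direction": direction})
    unpaired = set(base.index) ^ set(follow.index)
    if unpaired & set(follow.index):
        warnings.warn(
            f"unpaired follow-up sample(s) for {sorted(unpaired & set(follow.index))}",
            stacklevel=2)
    traj = pd.DataFrame(rows, columns=["patient_id", "baseline_n",
                                       "followup_n", "direction"])
    summary: dict = {"n_pairs": len(traj)}
    if len(traj):
        summary["fraction_decreasing"] = float((traj["direction"] == "decrease").mean())
    if patients is not None and len(traj):
        merged = traj.merge(patients[["patient_id", "treatment_arm"]], on="patient_id")
        for armname, sub in merged.groupby("treatment_arm"):
            summary[f"fraction_decreasing_{armname}"] = float(
                (sub["direction"] == "decrease").mean())
            summary[f"n_pairs_{armname}"] = int(len(sub))
    return traj, summary


def summarize_cohort(status: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Sample-level and patient-level (baseline) CTC rates."""
    if status.empty:
        raise ValueError("empty status set")
    case = manifest[manifest["role"] == "case"]
    case_samples = [s for s in case["sample_id"] if s in status.index]
    sample_status = status.loc[case_samples]
    base_ids = case.loc[case["timepoint"] == "baseline", "sample_id"]
    baseline_status = status.loc[[s for s in base_ids if s in status.index]]

    def rates(df):
        return {
            "n": int(len(df)),
            "ctc_positive_rate": float(df["ctc_positive"].mean()),
            "ctc_high_rate": float(df["ctc_high"].mean()),
            "hybrid_emt_rate": float(df["hybrid_emt"].mean()),
        }

    return {"sample_level": rates(sample_status),
            "patient_level": rates(baseline_status)}
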