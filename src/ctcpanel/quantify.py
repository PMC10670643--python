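"""Relative quantification of RT-qPCR Ct tables by the 2^-ddCt method.

A Ct table is a genes x samples DataFrame of quantification cycles with a
designated reference gene (default GAPDH) and NaN for undetermined wells.
Normalization proceeds in two steps:

    dCt(g, s)  = Ct(g, s) - Ct(ref, s)
    fc(g, s)   = 2 ** -(dCt(g, s) - dCt_calibrator(g))

where the calibrator is the per-gene mean dCt over healthy-donor control
samples.  A missing Ct propagates to fold change 0 ("not detected"); it is
deliberately not imputed at the instrument limit, which would manufacture
small nonzero fold changes.  Fold changes are then discretized into the
three-level call used throughout the pipeline: negative (fc < 2),
positive (fc >= 2), high (fc >= 5), with both bounds closed from below.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import DEFAULT_REFERENCE_GENE

CALL_LEVELS = ("negative", "positive", "high")


def compute_delta_ct(
    ct_table: pd.DataFrame, reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> pd.DataFrame:
    """Subtract the reference gene's Ct from every gene, per sample.

    Samples in which the reference gene itself failed to amplify cannot be
    normalized; they are dropped with a warning rather than aborting the
    run.  The reference row is removed from the result.
    """
    if reference_gene not in ct_table.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from table")
    ref = ct_table.loc[reference_gene]
    bad = ref.isna()
    if bad.any():
        warnings.warn(
            "reference gene undetermined in sample(s) "
            f"{list(ct_table.columns[bad])}; excluding them", stacklevel=2)
    kept = ct_table.loc[:, ~bad]
    delta = kept.drop(index=reference_gene).sub(kept.loc[reference_gene], axis=1)
    return delta


def hd_calibrator(delta_ct: pd.DataFrame, control_samples) -> pd.Series:
    """Per-gene mean dCt over the healthy-donor control samples."""
    controls = [s for s in control_samples if s in delta_ct.columns]
    missing = set(control_samples) - set(controls)
    if missing:
        raise ValueError(f"control samples absent from table: {sorted(missing)}")
    if not controls:
        raise ValueError("no control samples supplied")
    cal = delta_ct[controls].mean(axis=1, skipna=True)
    return cal


def compute_fold_change(
    delta_ct: pd.DataFrame, calibrator: pd.Series,
) -> pd.DataFrame:
    """2^-ddCt fold change relative to the calibrator dCt.

    Undetected genes (missing dCt) map to fold change 0.  Every gene in
    the table must have a finite calibrator value.
    """
    cal = calibrator.reindex(delta_ct.index)
    bad = cal.index[cal.isna()]
    if len(bad):
        raise ValueError(f"no calibrator dCt for gene(s): {list(bad)}")
    fc = np.power(2.0, -(delta_ct.sub(cal, axis=0)))
    return fc.fillna(0.0)


def call_markers(
    fc: pd.DataFrame, pos_fc: float = 2.0, high_fc: float = 5.0,
) -> pd.DataFrame:
    """Three-level call per (gene, sample): negative / positive / high.

    ``fc < pos_fc`` is negative, ``pos_fc <= fc < high_fc`` positive,
    ``fc >= high_fc`` high.  Both thresholds are closed from below.
    """
    if not 0 < pos_fc <= high_fc:
        raise ValueError("need 0 < pos_fc <= high_fc")
    arr = fc.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("fold changes must be non-negative")
    out = np.full(arr.shape, "negative", dtype=object)
    out[arr >= pos_fc] = "positive"
    out[arr >= high_fc] = "high"
    return pd.DataFrame(out, index=fc.index, columns=fc.columns)


def is_detected(calls: pd.DataFrame) -> pd.DataFrame:
    """Boolean detection matrix: call is positive or high."""
    return calls.isin(["positive", "high"])


class DeltaDeltaCtQuantifier(BaseEstimator, TransformerMixin):
    """Fold-change transformer learned from healthy-donor controls.

    ``fit`` consumes a Ct table restricted to (or containing) the control
    samples and stores the per-gene calibrator dCt; ``transform`` maps any
    Ct table over the same genes to 2^-ddCt fold changes.

    Parameters
    ----------
    reference_gene : housekeeping gene used for the first normalization.
    pos_fc, high_fc : thresholds for :meth:`call`, the three-level
        discretization of the transformed fold changes.
    """

    def __init__(self, reference_gene: str = DEFAULT_REFERENCE_GENE,
                 pos_fc: float = 2.0, high_fc: float = 5.0):
        self.reference_gene = reference_gene
        self.pos_fc = pos_fc
        self.high_fc = high_fc

    def fit(self, X: pd.DataFrame, y=None, control_samples=None):
        """Learn the calibrator from control columns of the Ct table ``X``.

        When ``control_samples`` is None every column of ``X`` is a control.
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a genes x samples DataFrame")
        controls = list(X.columns) if control_samples is None else list(control_samples)
        delta = compute_delta_ct(X, self.reference_gene)
        self.calibrator_ = hd_calibrator(delta, [c for c in controls])
        self.n_features_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "calibrator_"):
            raise AttributeError("quantifier is not fitted")
        delta = compute_delta_ct(X, self.reference_gene)
        return compute_fold_change(delta, self.calibrator_)

    def call(self, X: pd.DataFrame) -> pd.DataFrame:
        """Ct table -> three-level marker-call matrix."""
        return call_markers(self.transform(X), self.pos_fc, self.high_fc)


class MarkerCaller(BaseEstimator, TransformerMixin):
    """Stateless transformer discretizing fold changes into call levels."""

    def __init__(self, pos_fc: float = 2.0, high_fc: float = 5.0):
        self.pos_fc = pos_fc
        self.high_fc = high_fc

    def fit(self, X, y=None):
        if not 0 < self.pos_fc <= self.high_fc:
            raise ValueError("need 0 < pos_fc <= high_fc")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return call_markers(X, self.pos_fc, self.high_fc)
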