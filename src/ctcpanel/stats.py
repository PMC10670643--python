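"""Association tests linking marker/CTC status to clinical dichotomies.

The workhorse is the exact two-sided Fisher test, computed from first
principles by enumerating every 2x2 table compatible with the observed
margins and summing the hypergeometric probabilities of tables no more
likely than the observed one (the "sum of small p" two-sided rule, the
convention used by the common statistical packages for 2x2 tables).
A relative tolerance guards against floating-point exclusion of exactly
tied tables.

Pearson's chi-square and the two-sample Kolmogorov-Smirnov test are
provided through SciPy behind the same result interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return arr.astype(np.int64)


def fisher_exact_two_sided(table, tie_tol: float = 1e-7) -> TestResult:
    """Exact two-sided Fisher test by hypergeometric enumeration.

    The p-value is the sum, over all tables with the observed margins, of
    hypergeometric point probabilities that do not exceed the observed
    table's point probability (within relative tolerance ``tie_tol``).
    The reported statistic is the observed point probability.  A table
    with a zero margin carries no information; it yields p = 1 with a
    warning.
    """
    a, b, c, d = _as_table(table).ravel()
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; returning p = 1",
                      stacklevel=2)
        return TestResult(statistic=1.0, p_value=1.0, method="fisher_exact")
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + tie_tol)].sum())
    return TestResult(statistic=float(p_obs), p_value=min(p, 1.0),
                      method="fisher_exact")


def chi_square_test(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (1 df)."""
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires all margins > 0")
    res = sps.chi2_contingency(arr, correction=continuity_correction)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="chi_square" + ("_yates" if continuity_correction else ""))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs; the
    p-value comes from the asymptotic Kolmogorov distribution at the
    effective sample size n_x n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="ks_two_sample")


# --------------------------------------------------------------------------
# clinical dichotomies and contingency construction
# --------------------------------------------------------------------------

def _age_rule(cut: float) -> Callable[[pd.Series], pd.Series]:
    return lambda df: df["age"] > cut


DEFAULT_RULES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    # True = the "advanced"/second row of the printed dichotomy
    "age": _age_rule(68),
    "gender": lambda df: df["gender"] == "M",
    "location": lambda df: df["location"] == "upper/middle",
    "tnm_stage": lambda df: df["tnm_stage"].isin(["III", "IV"]),
    "tumor_size": lambda df: df["t_stage"].isin(["T3", "T4"]),
    "node_stage": lambda df: df["n_stage"].isin(["N2", "N3"]),
    "distant_metastasis": lambda df: df["m_stage"] == "M1",
    "treatment_arm": lambda df: df["treatment_arm"] == "curative",
}


@dataclass
class Dichotomizer:
    """Maps cohort records to the binary clinical splits used in testing.

    Default rules: age <=68 vs >68, TNM 0-II vs III-IV, tumor size T0-T2
    vs T3-T4, node N0-N1 vs N2-N3, distant metastasis M0 vs M1, tumor
    location lower vs upper/middle.
    """

    rules: dict[str, Callable[[pd.DataFrame], pd.Series]] = field(
        default_factory=lambda: dict(DEFAULT_RULES))

    def dichotomize(self, patients: pd.DataFrame, variable: str) -> pd.Series:
        if variable not in self.rules:
            raise KeyError(f"no dichotomy rule for variable {variable!r}")
        out = self.rules[variable](patients)
        if out.isna().any():
            bad = patients.loc[out.isna(), "patient_id"].tolist() \
                if "patient_id" in patients else list(patients.index[out.isna()])
            raise ValueError(f"unmapped records for {variable!r}: {bad}")
        return out.astype(bool)

    def variables(self) -> list[str]:
        return list(self.rules)


def build_contingency(
    patients: pd.DataFrame, marker_positive: pd.Series, variable: str,
    dichotomizer: Dichotomizer | None = None,
) -> np.ndarray:
    """2x2 table: rows = clinical dichotomy (low, high), columns =
    (marker positive, marker negative).

    ``marker_positive`` is a boolean per patient, aligned with
    ``patients["patient_id"]`` (or the frame's index).
    """
    dicho = dichotomizer or Dichotomizer()
    group_hi = dicho.dichotomize(patients, variable).to_numpy()
    key = patients["patient_id"] if "patient_id" in patients else patients.index
    pos = marker_positive.reindex(key)
    if pos.isna().any():
        missing = list(pd.Index(key)[pos.isna()])
        raise ValueError(f"no marker status for patient(s): {missing}")
    pos = pos.to_numpy(dtype=bool)
    return np.array([
        [int((pos & ~group_hi).sum()), int((~pos & ~group_hi).sum())],
        [int((pos & group_hi).sum()), int((~pos & group_hi).sum())],
    ])


def association_grid(
    patients: pd.DataFrame, statuses: pd.DataFrame, variables=None,
    method: str = "fisher", adjust: bool = False,
) -> pd.DataFrame:
    """Test every status column against every clinical dichotomy.

    ``statuses`` is a boolean DataFrame indexed by patient_id, one column
    per marker or CTC status.  Returns long-format results
    (marker, variable, a, b, c, d, method, statistic, p).  No multiplicity
    correction is applied by default, matching the single-comparison
    reporting convention; ``adjust=True`` adds Benjamini-Hochberg adjusted
    p-values as an extension.
    """
    dicho = Dichotomizer()
    variables = list(variables) if variables is not None else dicho.variables()
    test = {"fisher": fisher_exact_two_sided, "chisq": chi_square_test}[method]
    rows = []
    for marker in statuses.columns:
        for var in variables:
            t = build_contingency(patients, statuses[marker].astype(bool), var, dicho)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = test(t)
                except ValueError:
                    continue
            rows.append({"marker": marker, "variable": var,
                         "a": t[0, 0], "b": t[0, 1], "c": t[1, 0], "d": t[1, 1],
                         "method": res.method, "statistic": res.statistic,
                         "p": res.p_value})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
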