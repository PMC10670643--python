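"""CTC-status classification, ROC thresholding, trajectories, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ctcpanel import CtcClassifier, classify_samples, roc_threshold
from ctcpanel.classify import marker_trajectory, summarize_cohort

PANEL = ["CCND1", "ECT2", "EpCAM", "FSCN1", "KRT5",
         "KRT18", "MET", "TFRC", "TWIST1", "VEGFC"]


def calls_for(sample_levels: dict) -> pd.DataFrame:
    """Build a call matrix from {sample: {gene: level}} (default negative)."""
    data = {}
    for sample, levels in sample_levels.items():
        data[sample] = [levels.get(g, "negative") for g in PANEL]
    return pd.DataFrame(data, index=PANEL)


class TestClassifySamples:
    def test_two_detected_markers_is_positive_not_high(self):
        calls = calls_for({"S": {"MET": "positive", "KRT5": "high"}})
        st = classify_samples(calls, PANEL)
        assert st.loc["S", "n_detected"] == 2
        assert bool(st.loc["S", "ctc_positive"])
        assert not st.loc["S", "ctc_high"]

    def test_no_detection_leaves_all_flags_false(self):
        st = classify_samples(calls_for({"S": {}}), PANEL)
        assert st.loc["S", "n_detected"] == 0
        assert not st.loc["S", ["ctc_positive", "ctc_high", "hybrid_emt"]].any()

    def test_epcam_twist1_coexpression_is_hybrid(self):
        calls = calls_for({"S": {"EpCAM": "high", "TWIST1": "positive"}})
        st = classify_samples(calls, PANEL)
        assert st.loc["S", "n_detected"] == 2
        assert bool(st.loc["S", "ctc_positive"])
        assert bool(st.loc["S", "hybrid_emt"])

    def test_five_detected_is_high(self):
        calls = calls_for({"S": {g: "positive" for g in PANEL[:5]}})
        st = classify_samples(calls, PANEL)
        assert bool(st.loc["S", "ctc_high"])

    def test_missing_panel_gene_errors(self):
        calls = calls_for({"S": {}}).drop(index="MET")
        with pytest.raises(ValueError, match="MET"):
            classify_samples(calls, PANEL)

    def test_genes_outside_panel_ignored(self):
        calls = calls_for({"S": {g: "high" for g in PANEL}})
        calls.loc["EXTRA"] = "high"
        st = classify_samples(calls, PANEL)
        assert st.loc["S", "n_detected"] == 10


class TestStatusInvariants:
    def test_high_subset_positive_and_hybrid_subset_positive(self, cohort_status):
        assert (~cohort_status.ctc_high | cohort_status.ctc_positive).all()
        assert (~cohort_status.hybrid_emt | cohort_status.ctc_positive).all()

    def test_raising_k_high_never_adds_high_samples(self, cohort_calls):
        previous = None
        for k in range(2, 11):
            st = classify_samples(cohort_calls.loc[PANEL], PANEL, k_high=k)
            n_high = int(st.ctc_high.sum())
            if previous is not None:
                assert n_high <= previous
            previous = n_high


class TestRoc:
    def test_perfect_separation(self):
        res = roc_threshold([5, 6, 7, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(1.0)
        assert res.youden_j.max() == pytest.approx(1.0)
        assert res.chosen_k == 3  # smallest perfect separator

    def test_uninformative_predictor(self):
        res = roc_threshold([4, 4, 4, 4], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.5)
        assert res.youden_j.max() == pytest.approx(0.0)

    def test_matches_confusion_matrix_enumeration(self, rng):
        x = rng.integers(0, 11, 20)
        y = rng.integers(0, 2, 20)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        res = roc_threshold(x, y, panel_size=10)
        for i, k in enumerate(res.thresholds):
            pred = x >= k
            tp = int((pred & (y == 1)).sum())
            fn = int((~pred & (y == 1)).sum())
            tn = int((~pred & (y == 0)).sum())
            fp = int((pred & (y == 0)).sum())
            assert res.sensitivity[i] == pytest.approx(tp / (tp + fn))
            assert res.specificity[i] == pytest.approx(tn / (tn + fp))

    def test_auc_equals_mann_whitney(self, rng):
        x = rng.integers(0, 11, 40)
        y = np.array([0] * 25 + [1] * 15)
        res = roc_threshold(x, y, panel_size=10)
        u = mannwhitneyu(x[y == 1], x[y == 0]).statistic
        assert res.auc == pytest.approx(u / (25 * 15))

    def test_monotone_sensitivity_specificity(self, rng):
        x = rng.integers(0, 11, 30)
        y = (x + rng.integers(-3, 4, 30) > 5).astype(int)
        if 0 < y.sum() < 30:
            res = roc_threshold(x, y, panel_size=10)
            assert (np.diff(res.sensitivity) <= 1e-12).all()
            assert (np.diff(res.specificity) >= -1e-12).all()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_threshold([1, 2, 3], [1, 1, 1])

    def test_classifier_fit_sets_threshold(self, cohort_calls, cohort,
                                           default_config):
        base = cohort.samples[(cohort.samples.role == "case")
                              & (cohort.samples.timepoint == "baseline")]
        clf = CtcClassifier(panel=list(default_config.panel_genes))
        calls = cohort_calls[base["sample_id"]]
        outcome = np.arange(len(base)) % 2  # any valid binary endpoint coding
        clf.fit(calls, outcome)
        assert hasattr(clf, "roc_result_")
        assert 0 <= clf.k_high_ <= 10
        status = clf.predict(cohort_calls)
        assert (status.ctc_high == (status.n_detected >= clf.k_high_)).all()


class TestTrajectory:
    def build(self, pairs):
        """pairs: {patient: (baseline_n, followup_n or None)}"""
        manifest_rows, status_rows = [], []
        i = 0
        for pid, (nb, nf) in pairs.items():
            manifest_rows.append({"sample_id": f"S{i}", "patient_id": pid,
                                  "timepoint": "baseline", "role": "case"})
            status_rows.append({"sample_id": f"S{i}", "n_detected": nb})
            i += 1
            if nf is not None:
                manifest_rows.append({"sample_id": f"S{i}", "patient_id": pid,
                                      "timepoint": "preIII", "role": "case"})
                status_rows.append({"sample_id": f"S{i}", "n_detected": nf})
                i += 1
        status = pd.DataFrame(status_rows).set_index("sample_id")
        for col in ("ctc_positive", "ctc_high", "hybrid_emt"):
            status[col] = status["n_detected"] >= 2
        return status, pd.DataFrame(manifest_rows)

    def test_direction_sign_rule(self):
        status, manifest = self.build({"P1": (6, 2), "P2": (1, 4), "P3": (3, 3)})
        traj, _ = marker_trajectory(status, manifest)
        d = traj.set_index("patient_id")["direction"]
        assert d["P1"] == "decrease"
        assert d["P2"] == "increase"
        assert d["P3"] == "unchanged"

    def test_reported_palliative_fraction_five_of_nine(self):
        """9 palliative pairs with 5 decreasing reproduces the 56% figure."""
        pairs = {f"P{i}": (6, 2) for i in range(5)}
        pairs.update({f"P{i}": (2, 6) for i in range(5, 9)})
        status, manifest = self.build(pairs)
        patients = pd.DataFrame({
            "patient_id": list(pairs), "treatment_arm": "palliative"})
        _, summary = marker_trajectory(status, manifest, patients)
        assert summary["n_pairs_palliative"] == 9
        assert summary["fraction_decreasing_palliative"] == pytest.approx(5 / 9)
        assert round(summary["fraction_decreasing_palliative"], 2) == 0.56

    def test_baseline_only_patient_skipped(self):
        status, manifest = self.build({"P1": (6, 2), "P2": (3, None)})
        traj, summary = marker_trajectory(status, manifest)
        assert list(traj["patient_id"]) == ["P1"]
        assert summary["n_pairs"] == 1

    def test_followup_without_baseline_warns(self):
        status, manifest = self.build({"P1": (6, 2), "P2": (3, 1)})
        manifest = manifest[~((manifest.patient_id == "P2")
                              & (manifest.timepoint == "baseline"))]
        with pytest.warns(UserWarning, match="unpaired"):
            traj, _ = marker_trajectory(status, manifest)
        assert list(traj["patient_id"]) == ["P1"]


class TestCohortSummary:
    def test_saturated_and_empty_rates(self):
        manifest = pd.DataFrame({
            "sample_id": ["S1", "S2"], "patient_id": ["P1", "P2"],
            "timepoint": ["baseline", "baseline"], "role": ["case", "case"]})
        full = pd.DataFrame({"n_detected": [10, 10], "ctc_positive": True,
                             "ctc_high": True, "hybrid_emt": True},
                            index=["S1", "S2"])
        rates = summarize_cohort(full, manifest)
        assert rates["patient_level"]["ctc_positive_rate"] == 1.0
        assert rates["sample_level"]["ctc_high_rate"] == 1.0
        empty = full.assign(n_detected=0, ctc_positive=False, ctc_high=False,
                            hybrid_emt=False)
        rates = summarize_cohort(empty, manifest)
        assert rates["patient_level"]["ctc_positive_rate"] == 0.0

    def test_empty_status_errors(self):
        with pytest.raises(ValueError):
            summarize_cohort(pd.DataFrame(), pd.DataFrame())
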