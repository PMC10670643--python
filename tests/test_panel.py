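"""Four-stage panel-derivation cascade and its audit trail."""

import numpy as np
import pandas as pd
import pytest

from ctcpanel import derive_panel
from ctcpanel.panel import (
    PanelDefinition, filter_by_ct, filter_by_pilot_positivity,
    filter_by_singlecell, filter_by_spikein,
)


def counts_frame(gene_means_pbmc, gene_means_tumor, n_pbmc=200, n_tumor=100,
                 seed=0):
    """Counts with the requested per-gene means, exact by construction."""
    genes = list(gene_means_pbmc)
    rows = {}
    for g in genes:
        pb = np.full(n_pbmc, gene_means_pbmc[g])
        tm = np.full(n_tumor, gene_means_tumor[g])
        rows[g] = np.concatenate([pb, tm])
    cells = [f"P{i}" for i in range(n_pbmc)] + [f"T{i}" for i in range(n_tumor)]
    pops = pd.Series(["PBMC"] * n_pbmc + ["tumor"] * n_tumor, index=cells)
    return pd.DataFrame(rows, index=cells), pops


class TestSingleCellFilter:
    def test_keeps_separated_gene(self):
        counts, pops = counts_frame({"G": 0.05}, {"G": 2.0})
        kept, report = filter_by_singlecell(counts, pops)
        assert kept == ["G"]
        assert report.loc["G", "passed"]

    @pytest.mark.parametrize("pbmc_mean, tumor_mean", [
        (0.10, 2.0),   # boundary: strict < on the PBMC side
        (0.05, 1.0),   # boundary: strict > on the tumor side
        (0.5, 2.0),    # PBMC-expressed
        (0.05, 0.5),   # tumor-silent
    ])
    def test_boundary_and_violations_excluded(self, pbmc_mean, tumor_mean):
        counts, pops = counts_frame({"G": pbmc_mean}, {"G": tumor_mean})
        kept, _ = filter_by_singlecell(counts, pops)
        assert kept == []

    def test_empty_population_errors(self):
        counts, pops = counts_frame({"G": 0.0}, {"G": 2.0})
        with pytest.raises(ValueError, match="no cells"):
            filter_by_singlecell(counts, pops.replace("tumor", "PBMC"))

    def test_recovers_ground_truth_markers(self, default_config):
        from ctcpanel import gen_single_cell_counts
        counts, pops, gt = gen_single_cell_counts(default_config)
        kept, _ = filter_by_singlecell(counts, pops)
        assert set(kept) == set(gt.marker_genes)


class TestCtFilter:
    @pytest.mark.parametrize("pbmc, tumor, kept", [
        (28.0, 25.0, False),   # PBMC-enriched
        (35.0, 32.0, False),   # lowly expressed in tumor cells
        (35.0, 22.0, True),
        (np.nan, 22.0, True),  # undetected in PBMCs is fine
        (35.0, np.nan, False),  # undetected in tumor counts as not expressed
        (30.0, 30.0, True),    # both boundaries are non-strict exclusions
    ])
    def test_rule(self, pbmc, tumor, kept):
        out, _ = filter_by_ct(pd.Series({"G": pbmc}), pd.Series({"G": tumor}))
        assert (out == ["G"]) is kept

    def test_gene_absent_from_both_errors(self):
        with pytest.raises(ValueError, match="G2"):
            filter_by_ct(pd.Series({"G1": 35.0}), pd.Series({"G1": 22.0}),
                         genes=["G1", "G2"])

    def test_commutes_with_singlecell_filter(self, rng):
        """Stages 1 and 2 are per-gene predicates: order must not matter."""
        genes = [f"G{i}" for i in range(30)]
        pbmc_means = dict(zip(genes, rng.uniform(0, 0.3, 30)))
        tumor_means = dict(zip(genes, rng.uniform(0, 3, 30)))
        counts, pops = counts_frame(pbmc_means, tumor_means)
        ct_p = pd.Series(rng.uniform(20, 40, 30), index=genes)
        ct_t = pd.Series(rng.uniform(20, 40, 30), index=genes)

        s1_first, _ = filter_by_singlecell(counts, pops)
        both_a, _ = filter_by_ct(ct_p[s1_first], ct_t[s1_first])
        s2_first, _ = filter_by_ct(ct_p, ct_t)
        both_b, _ = filter_by_singlecell(counts[s2_first], pops)
        assert sorted(both_a) == sorted(both_b)


def calls_frame(values: dict, samples) -> pd.DataFrame:
    return pd.DataFrame(values, index=samples).T


class TestSpikeInFilter:
    manifest = pd.DataFrame({
        "sample_id": ["A500", "B500", "A5000", "B5000"],
        "cell_line": ["A", "B", "A", "B"],
        "spike_cells": [500, 500, 5000, 5000],
    })

    def test_positive_in_both_lines_kept(self):
        calls = calls_frame({"G": ["positive", "high", "high", "high"]},
                            ["A500", "B500", "A5000", "B5000"])
        kept, _ = filter_by_spikein(calls, self.manifest)
        assert kept == ["G"]

    def test_positive_in_one_line_excluded(self):
        calls = calls_frame({"G": ["positive", "negative", "high", "high"]},
                            ["A500", "B500", "A5000", "B5000"])
        kept, _ = filter_by_spikein(calls, self.manifest)
        assert kept == []

    def test_detected_only_at_higher_level_excluded(self):
        calls = calls_frame({"G": ["negative", "negative", "high", "high"]},
                            ["A500", "B500", "A5000", "B5000"])
        kept, _ = filter_by_spikein(calls, self.manifest)
        assert kept == []

    def test_missing_required_level_errors(self):
        calls = calls_frame({"G": ["high", "high"]}, ["A5000", "B5000"])
        with pytest.raises(ValueError, match="500"):
            filter_by_spikein(calls, self.manifest[self.manifest.spike_cells != 500])


class TestPilotFilter:
    @pytest.mark.parametrize("n_pos, n_total, kept", [
        (4, 14, False),   # 28.6% is below 30%
        (5, 14, True),    # 35.7%
        (3, 10, True),    # exactly 30% is kept
        (2, 10, False),
    ])
    def test_rate_threshold(self, n_pos, n_total, kept):
        row = ["positive"] * n_pos + ["negative"] * (n_total - n_pos)
        calls = calls_frame({"G": row}, [f"S{i}" for i in range(n_total)])
        out, report = filter_by_pilot_positivity(calls)
        assert (out == ["G"]) is kept
        assert report.loc["G", "pilot_positivity"] == pytest.approx(n_pos / n_total)

    def test_no_pilot_samples_errors(self):
        with pytest.raises(ValueError):
            filter_by_pilot_positivity(pd.DataFrame(index=["G"]))


class TestCascade:
    def test_recovers_ground_truth_panel(self, cascade_selector, cascade_data):
        assert cascade_selector.panel_.genes == \
            cascade_data.ground_truth.marker_genes

    def test_audit_records_correct_elimination_stage(self, cascade_selector):
        sel = cascade_selector
        audit = sel.audit_
        stage_of = {1: "single_cell", 2: "ct_filter", 3: "spike_in",
                    4: "pilot_positivity"}
        for gene in audit.index:
            if gene.startswith("D"):
                expected = stage_of[int(gene[1])]
                assert audit.loc[gene, "eliminated_at"] == expected, gene
            else:
                assert pd.isna(audit.loc[gene, "eliminated_at"])

    def test_audit_covers_every_candidate_once(self, cascade_selector,
                                               cascade_data):
        sel = cascade_selector
        assert sorted(sel.audit_.index) == sorted(cascade_data.counts.columns)
        assert not sel.audit_.index.duplicated().any()

    def test_panel_genes_pass_all_four_stages(self, cascade_selector):
        sel = cascade_selector
        flags = sel.audit_.loc[sel.panel_.genes,
                               [f"passed_{s}" for s in
                                ("single_cell", "ct_filter", "spike_in",
                                 "pilot_positivity")]]
        assert flags.all().all()

    def test_each_stage_shrinks_or_keeps_gene_set(self, cascade_selector):
        sel = cascade_selector
        audit = sel.audit_
        n_in = len(audit)
        for stage in ("single_cell", "ct_filter", "spike_in",
                      "pilot_positivity"):
            n_out = n_in - int((audit["eliminated_at"] == stage).sum())
            assert n_out <= n_in
            n_in = n_out
        assert n_in == len(sel.panel_.genes)

    def test_empty_panel_raises_naming_final_stage(self):
        counts, pops = counts_frame({"G": 0.5}, {"G": 2.0})  # fails stage 1
        with pytest.raises(ValueError, match="single_cell"):
            derive_panel(counts, pops,
                         pd.Series({"G": 35.0}), pd.Series({"G": 22.0}),
                         calls_frame({"G": ["positive"] * 2}, ["A500", "B500"]),
                         pd.DataFrame({"sample_id": ["A500", "B500"],
                                       "cell_line": ["A", "B"],
                                       "spike_cells": [500, 500]}),
                         calls_frame({"G": ["positive"] * 4},
                                     [f"S{i}" for i in range(4)]))


class TestPanelDefinition:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            PanelDefinition(genes=["A", "A"], provenance=pd.DataFrame())

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            PanelDefinition(genes=[], provenance=pd.DataFrame())

    def test_json_roundtrip(self, cascade_selector, tmp_path):
        sel = cascade_selector
        path = tmp_path / "panel.json"
        sel.panel_.to_json(path)
        back = PanelDefinition.from_json(path)
        assert back.genes == sel.panel_.genes
        assert back.annotation == sel.panel_.annotation
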