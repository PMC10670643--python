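"""Four-stage marker-derivation cascade for the CTC panel.

Candidate genes are filtered in a fixed order:

1. single-cell screen -- keep genes with mean count < 0.10 in PBMCs and
   mean count > 1.0 in the tumor population (both strict);
2. pure-population qPCR -- exclude genes amplifying early in PBMCs
   (Ct < 30) or late in tumor cells (Ct > 30; an undetermined tumor well
   counts as not expressed);
3. spike-in sensitivity -- keep genes called positive at the required
   spike level (default 500 tumor cells) in every tested cell line;
4. pilot positivity -- keep genes detected in at least 30% of pilot blood
   samples (a rate of exactly 30% is kept).

Stages 1-2 are per-gene predicates and commute; stages 3-4 consume marker
calls produced by the quantification module so the pipeline has a single
definition of "detected".  Every candidate receives a full audit trail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import EPITHELIAL_GENE, MESENCHYMAL_GENE
from .quantify import is_detected
from .simulate import PBMC_LABEL, TUMOR_LABEL

STAGES = ("single_cell", "ct_filter", "spike_in", "pilot_positivity")


@dataclass
class PanelDefinition:
    """Final panel: ordered genes plus a per-gene audit of stage decisions."""

    genes: list[str]
    provenance: pd.DataFrame  # audit trail, one row per candidate gene
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel contains duplicate genes")

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "annotation": self.annotation,
            "provenance": self.provenance.reset_index().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "PanelDefinition":
        with open(path) as fh:
            raw = json.load(fh)
        prov = pd.DataFrame(raw.get("provenance", []))
        if "gene" in prov.columns:
            prov = prov.set_index("gene")
        return cls(genes=list(raw["genes"]), provenance=prov,
                   annotation=dict(raw.get("annotation", {})))


def default_annotation(genes) -> dict[str, str]:
    """Epithelial/mesenchymal tags for the hybrid-EMT call."""
    ann = {}
    for g in genes:
        if g == MESENCHYMAL_GENE:
            ann[g] = "mesenchymal"
        elif g == EPITHELIAL_GENE:
            ann[g] = "epithelial"
    return ann


def filter_by_singlecell(
    counts: pd.DataFrame, populations: pd.Series,
    pbmc_max: float = 0.10, tumor_min: float = 1.0,
    pbmc_label: str = PBMC_LABEL, tumor_label: str = TUMOR_LABEL,
) -> tuple[list[str], pd.DataFrame]:
    """Stage 1: strict mean-count bounds in the two single-cell populations.

    Returns surviving genes and a per-gene report (means and pass flag).
    Means are taken on raw counts, without normalization.
    """
    populations = populations.reindex(counts.index)
    for label in (pbmc_label, tumor_label):
        if (populations == label).sum() == 0:
            raise ValueError(f"population {label!r} has no cells")
    mean_pbmc = counts.loc[populations == pbmc_label].mean(axis=0)
    mean_tumor = counts.loc[populations == tumor_label].mean(axis=0)
    keep = (mean_pbmc < pbmc_max) & (mean_tumor > tumor_min)
    report = pd.DataFrame({
        "mean_reads_pbmc": mean_pbmc, "mean_reads_tumor": mean_tumor,
        "passed": keep,
    })
    report.index.name = "gene"
    return list(report.index[keep]), report


def filter_by_ct(
    ct_pbmc: pd.Series, ct_tumor: pd.Series, cutoff: float = 30.0, genes=None,
) -> tuple[list[str], pd.DataFrame]:
    """Stage 2: exclude PBMC-enriched (Ct < cutoff) or tumor-silent
    (Ct > cutoff, or undetermined) genes.

    ``genes`` restricts the candidate list; every candidate must appear in
    at least one of the two Ct vectors.
    """
    if genes is None:
        genes = ct_pbmc.index.union(ct_tumor.index, sort=False)
    else:
        genes = pd.Index(genes)
    both_missing = [g for g in genes
                    if g not in ct_pbmc.index and g not in ct_tumor.index]
    if both_missing:
        raise ValueError(f"genes missing from both Ct vectors: {both_missing}")
    pbmc = ct_pbmc.reindex(genes)
    tumor = ct_tumor.reindex(genes)
    pbmc_hot = pbmc.notna() & (pbmc < cutoff)
    tumor_cold = tumor.isna() | (tumor > cutoff)
    keep = ~(pbmc_hot | tumor_cold)
    report = pd.DataFrame({
        "ct_pbmc": pbmc, "ct_tumor": tumor, "passed": keep,
    })
    report.index.name = "gene"
    return list(report.index[keep]), report


def filter_by_spikein(
    calls: pd.DataFrame, manifest: pd.DataFrame,
    required_level: int = 500, cell_lines=None,
) -> tuple[list[str], pd.DataFrame]:
    """Stage 3: detection at the required spike level in every cell line.

    ``calls`` is the marker-call matrix over the spike-in samples;
    ``manifest`` maps sample_id to (cell_line, spike_cells).
    """
    lines = list(cell_lines) if cell_lines is not None else sorted(
        set(manifest.loc[manifest["spike_cells"] > 0, "cell_line"]))
    det = is_detected(calls)
    per_line = {}
    for line in lines:
        sel = manifest[(manifest["cell_line"] == line)
                       & (manifest["spike_cells"] == required_level)]
        if sel.empty:
            raise ValueError(
                f"spike level {required_level} absent for cell line {line!r}")
        cols = [s for s in sel["sample_id"] if s in det.columns]
        if not cols:
            raise ValueError(f"no call columns for cell line {line!r}")
        per_line[f"detected_{line}"] = det[cols].all(axis=1)
    report = pd.DataFrame(per_line)
    report["passed"] = report.all(axis=1)
    report.index.name = "gene"
    return list(report.index[report["passed"]]), report


def filter_by_pilot_positivity(
    calls: pd.DataFrame, min_rate: float = 0.30,
) -> tuple[list[str], pd.DataFrame]:
    """Stage 4: overall positivity rate across pilot samples >= min_rate."""
    if calls.shape[1] == 0:
        raise ValueError("no pilot samples")
    rate = is_detected(calls).mean(axis=1)
    keep = rate >= min_rate
    report = pd.DataFrame({"pilot_positivity": rate, "passed": keep})
    report.index.name = "gene"
    return list(report.index[keep]), report


class PanelSelector(BaseEstimator):
    """Feature selector running the four-stage cascade in order.

    Fitted attributes
    -----------------
    panel_ : :class:`PanelDefinition` of the surviving genes.
    audit_ : DataFrame, one row per candidate, with per-stage statistics,
        pass flags (NA where the gene was already out), and the stage at
        which the gene was eliminated (NA if it survived).
    """

    def __init__(self, pbmc_max: float = 0.10, tumor_min: float = 1.0,
                 ct_cutoff: float = 30.0, required_spike_level: int = 500,
                 min_pilot_rate: float = 0.30,
                 pbmc_label: str = PBMC_LABEL, tumor_label: str = TUMOR_LABEL):
        self.pbmc_max = pbmc_max
        self.tumor_min = tumor_min
        self.ct_cutoff = ct_cutoff
        self.required_spike_level = required_spike_level
        self.min_pilot_rate = min_pilot_rate
        self.pbmc_label = pbmc_label
        self.tumor_label = tumor_label

    def fit(self, counts: pd.DataFrame, populations: pd.Series,
            ct_pbmc: pd.Series, ct_tumor: pd.Series,
            spike_calls: pd.DataFrame, spike_manifest: pd.DataFrame,
            pilot_calls: pd.DataFrame):
        candidates = list(counts.columns)
        audit = pd.DataFrame(index=pd.Index(candidates, name="gene"))
        audit["eliminated_at"] = pd.NA

        surviving = candidates
        stage_runs = [
            ("single_cell", lambda genes: filter_by_singlecell(
                counts[genes], populations, self.pbmc_max, self.tumor_min,
                self.pbmc_label, self.tumor_label)),
            ("ct_filter", lambda genes: filter_by_ct(
                ct_pbmc, ct_tumor, self.ct_cutoff, genes=genes)),
            ("spike_in", lambda genes: filter_by_spikein(
                spike_calls.loc[[g for g in genes if g in spike_calls.index]],
                spike_manifest, self.required_spike_level)),
            ("pilot_positivity", lambda genes: filter_by_pilot_positivity(
                pilot_calls.loc[[g for g in genes if g in pilot_calls.index]],
                self.min_pilot_rate)),
        ]
        for stage, run in stage_runs:
            kept, report = run(surviving)
            for col in report.columns:
                name = col if col != "passed" else f"passed_{stage}"
                audit.loc[report.index, name] = report[col]
            lost = [g for g in surviving if g not in kept]
            audit.loc[lost, "eliminated_at"] = stage
            surviving = kept
            if not surviving:
                raise ValueError(
                    "cascade eliminated every candidate; the last gene(s) "
                    f"were lost at stage {stage!r}")

        self.audit_ = audit
        self.panel_ = PanelDefinition(
            genes=surviving, provenance=audit,
            annotation=default_annotation(surviving))
        return self

    def get_support(self) -> list[str]:
        return list(self.panel_.genes)


def derive_panel(
    counts: pd.DataFrame, populations: pd.Series,
    ct_pbmc: pd.Series, ct_tumor: pd.Series,
    spike_calls: pd.DataFrame, spike_manifest: pd.DataFrame,
    pilot_calls: pd.DataFrame, **thresholds,
) -> PanelDefinition:
    """Run the full cascade and return the surviving panel with provenance."""
    sel = PanelSelector(**thresholds)
    sel.fit(counts, populations, ct_pbmc, ct_tumor,
            spike_calls, spike_manifest, pilot_calls)
    return sel.panel_


def pure_ct_vectors(ct_pure: pd.DataFrame, manifest: pd.DataFrame,
                    pbmc_label: str = PBMC_LABEL, tumor_label: str = TUMOR_LABEL,
                    ) -> tuple[pd.Series, pd.Series]:
    """Average replicate pure-population Ct columns into per-gene vectors."""
    def mean_for(label):
        cols = list(manifest.loc[manifest["population"] == label, "sample_id"])
        if not cols:
            raise ValueError(f"no samples labeled {label!r} in manifest")
        return ct_pure[cols].mean(axis=1, skipna=False)
    return mean_for(pbmc_label), mean_for(tumor_label)
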