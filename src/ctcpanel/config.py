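"""Configuration objects for simulation and pipeline runs.

All thresholds used anywhere in the pipeline live here as defaults so a
run can be reproduced from its serialized configuration alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from math import log
from typing import Sequence

import numpy as np
import yaml

#: The 10-gene CTC panel used as ground-truth marker set by the simulator.
DEFAULT_PANEL_GENES: tuple[str, ...] = (
    "CCND1", "ECT2", "EpCAM", "FSCN1", "KRT5",
    "KRT18", "MET", "TFRC", "TWIST1", "VEGFC",
)

DEFAULT_REFERENCE_GENE = "GAPDH"
EPITHELIAL_GENE = "EpCAM"
MESENCHYMAL_GENE = "TWIST1"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic liquid-biopsy study.

    The defaults describe a 55-patient esophageal-carcinoma-style cohort
    with a palliative/curative treatment split, a latent binary CTC-burden
    state driving marker fold changes, and exponential proportional-hazards
    survival.  Fold-change means are calibrated so that the expected
    patient-level CTC-positive and CTC-high rates equal 46/55 (83.6%) and
    28/55 (50.9%) when classified with the default thresholds.

    Single-cell parameters describe the marker screen: negative-binomial
    counts with tumor-enriched marker genes and PBMC-expressed background
    genes.
    """

    seed: int = 0

    # --- single-cell screen ---
    n_pbmc_cells: int = 1000
    n_tumor_cells: int = 200
    n_genes: int = 224
    marker_fraction: float = 40 / 224
    nb_mean_pbmc: float = 0.02       # marker-gene mean count in PBMCs
    nb_mean_tumor: float = 5.0       # marker-gene mean count in tumor cells
    nb_mean_background: float = 3.0  # non-marker mean count, both populations
    nb_dispersion: float = 0.5       # NB size k: var = mu + mu^2/k

    # --- qPCR model ---
    ct_intercept: float = 38.0       # cycles at unit relative abundance
    ct_noise_sd: float = 0.25        # cycles
    ct_min: float = 10.0
    ct_max: float = 40.0             # beyond this the well reads Undetermined

    # --- cohort ---
    n_patients: int = 55
    arm_fractions: tuple[float, float] = (24 / 55, 31 / 55)  # palliative, curative
    burden_prevalence: float = 28 / 55
    fc_mu_pos: float = 1.55          # mean log2 fold change, high-burden patients
    fc_mu_neg: float = 0.20          # mean log2 fold change, low-burden patients
    fc_sd: float = 1.0               # per-gene log2 fold-change SD
    n_hd: int = 5                    # healthy-donor calibrator samples
    paired_fraction: float = 22 / 55
    followup_response_rate: float = 0.6  # P(high burden resolves by follow-up)

    # --- survival ---
    # Baseline death hazard (low-burden palliative patients), set so the
    # burden-mixture OS median in the palliative arm is 119 days under the
    # default burden HR and prevalence; the progression-specific hazard is
    # expressed relative to it so the composite PFS median is 84 days.
    hazard_baseline: float = 0.00353708      # events/day
    log_hr_ctc_high: float = log(2.5)
    log_hr_curative: float = log(119 / 299)  # arm effect on both hazards
    log_hr_progression: float = -0.87547     # progression vs death hazard
    censor_time: float = 1095.0      # days

    # --- spike-in layout ---
    spike_levels: tuple[int, ...] = (5, 50, 500, 5000)
    spike_cell_lines: tuple[str, ...] = ("KYSE30", "KYSE270")
    n_pbmc_spike: int = 50000

    # --- pilot layout ---
    n_pilot: int = 14

    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self) -> None:
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for name in ("n_pbmc_cells", "n_tumor_cells", "n_genes", "n_patients",
                     "n_hd", "n_pilot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("marker_fraction", "burden_prevalence", "paired_fraction",
                     "followup_response_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("nb_mean_tumor", "nb_mean_background", "nb_dispersion",
                     "hazard_baseline", "fc_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_mean_pbmc < 0:
            raise ValueError("nb_mean_pbmc must be non-negative")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if abs(sum(self.arm_fractions) - 1.0) > 1e-9:
            raise ValueError("arm_fractions must sum to 1")

    @property
    def n_marker_genes(self) -> int:
        return round(self.n_genes * self.marker_fraction)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the global seed.

        Streams are independent and stable: adding a new generator does not
        shift draws of existing ones.
        """
        return np.random.default_rng([int(self.seed), zlib.crc32(stream.encode())])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("arm_fractions", "spike_levels", "spike_cell_lines", "panel_genes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunConfig:
    """End-to-end pipeline run settings, serialized alongside every output."""

    input_dir: str = "."
    out_dir: str = "out"
    pos_fc: float = 2.0
    high_fc: float = 5.0
    k_pos: int = 2
    k_high: int = 5
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator: str = "hd_mean"      # per-gene mean dCt over healthy-donor controls
    panel_path: str | None = None    # None: use panel genes found in the Ct table
    endpoint: str = "os"             # roc / survival endpoint: "pfs" or "os"
    seed: int = 0
    panel_genes: Sequence[str] = field(default_factory=lambda: list(DEFAULT_PANEL_GENES))

    def __post_init__(self) -> None:
        if self.pos_fc <= 0 or self.high_fc < self.pos_fc:
            raise ValueError("need 0 < pos_fc <= high_fc")
        if self.k_pos < 0 or self.k_high < self.k_pos:
            raise ValueError("need 0 <= k_pos <= k_high")
        if self.endpoint not in ("pfs", "os"):
            raise ValueError("endpoint must be 'pfs' or 'os'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel_genes"] = list(d["panel_genes"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
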