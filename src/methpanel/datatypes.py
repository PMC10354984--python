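"""Shared containers and record types for the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

GENE_SECTIONS = ("Promoter", "5'UTR", "1stExon", "Body", "3'UTR")
CONTROL_CATEGORIES = (
    "negative",
    "bisulphite_conversion",
    "staining",
    "extension",
    "hybridization",
    "specificity",
    "other",
    "none",
)

#: Sample-sheet columns that only exist for the patient group.
PICU_ONLY_FIELDS = (
    "pim3",
    "pelod",
    "strongkids",
    "randomisation_arm",
    "diagnosis",
    "gc_treatment",
    "picu_los",
)


@dataclass
class MethylationDataset:
    """Beta matrix with companion QC matrices, sample sheet and manifest.

    ``beta`` and ``detection_p`` are samples x signal-probes frames;
    ``control_intensities`` is samples x control-probes; the sample
    sheet is indexed by sample id and the manifest by probe id.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    control_intensities: pd.DataFrame
    sample_sheet: pd.DataFrame
    manifest: pd.DataFrame
    qc_state: str = "raw"

    def __post_init__(self):
        n = self.beta.shape[0]
        if self.detection_p.shape != self.beta.shape:
            raise ValueError("detection_p shape does not match beta")
        if self.control_intensities.shape[0] != n:
            raise ValueError("control_intensities rows do not match beta")
        if self.sample_sheet.shape[0] != n:
            raise ValueError("sample_sheet rows do not match beta")
        signal = self.manifest[self.manifest["probe_class"] == "signal"]
        if not self.beta.columns.equals(signal.index):
            raise ValueError("beta columns do not match manifest signal probes")
        b = self.beta.to_numpy()
        if ((b < 0) | (b > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]


@dataclass
class QCReport:
    excluded_samples: list = field(default_factory=list)  # (sample_id, reason)
    excluded_probes: list = field(default_factory=list)  # (probe_id, reason)
    thresholds: dict = field(default_factory=dict)

    SAMPLE_REASONS = ("low_yield", "non_bimodal")
    PROBE_REASONS = ("background", "snp")


@dataclass
class ControlPCs:
    """Principal-component scores of the (log2) control-probe intensities."""

    scores: pd.DataFrame  # samples x k, columns PC1..PCk
    explained_variance: list
    excluded_control_categories: list

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class DMPRecord:
    probe_id: str
    gene: str
    gene_section: str
    direction: str  # "hypomethylated" | "hypermethylated"
    logFC_M: float
    ci95: tuple
    abs_mean_beta_diff: float
    p_raw: float
    q_bh: float


@dataclass
class DMRRecord:
    gene: str
    chromosome: str
    start: int
    end: int
    width: int
    n_cpgs: int
    member_probe_ids: list
    mean_logFC_M: float
    min_q: float
    direction: str


@dataclass
class InteractionResult:
    probe_id: str
    factor: str  # "sex" | "age_ge6"
    interaction_p: float
    stratum_effects: dict  # stratum label -> group logFC_M


@dataclass
class GCEffectResult:
    probe_id: str
    gc_logFC_M: float
    p: float
    direction: str  # "aggravated" | "attenuated"


@dataclass
class RobustnessRecord:
    probe_id: str
    gene: str
    pct_significant_iterations: float
    fisher_p_median: float
    fisher_p_iqr: tuple
    robust: bool
    mean_coefficient: float
    direction_label: str = "none"  # "Harm" | "Benefit" | "none"
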