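"""Pipeline configuration and quality-control profiles.

All thresholds of the analysis live here: the allelic-ratio silencing
cut-off, the biallelic windows used at the gene and cell level, detection
support, normalisation scale, and the per-dataset single-cell QC gates.
Boundary strictness follows the wording each rule was defined with:
"more than" / "less than" are strict, "a minimum of" / "at least" /
"between" are inclusive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ParameterError

#: Core pluripotency network genes used for the per-cell pluripotency score.
PLURIPOTENCY_GENES: tuple[str, ...] = (
    "Pou5f1", "Sox2", "Nanog", "Klf2", "Esrrb", "Dppa3", "Tfcp2l1", "Prdm14",
)

#: Chromosome labels accepted without a warning by the annotation reader.
KNOWN_CHROMOSOMES = frozenset(
    {f"chr{i}" for i in range(1, 20)} | {"chrX", "chrY", "chrM"}
)


@dataclass(frozen=True)
class QCProfile:
    """Single-cell QC gates for one dataset type.

    ``min_allelic_reads`` is a strict lower bound ("more than");
    ``min_allelic_genes`` is inclusive ("a minimum of"); the minor-genotype
    gate is inclusive and absent (``None``) for profiles without it.
    ``min_detected_cell_fraction`` is the inclusive fraction of cells a gene
    must be detected in to count as informative.
    """

    name: str
    min_genes: int
    min_molecules: int
    max_mito_fraction: float
    min_allelic_reads: int
    min_allelic_genes: int
    min_minor_genotype_fraction: Optional[float]
    min_detected_cell_fraction: float


QC_PROFILES: dict[str, QCProfile] = {
    # In vitro SMART-seq germ cells.
    "invitro_sc": QCProfile(
        name="invitro_sc",
        min_genes=4000,
        min_molecules=10000,
        max_mito_fraction=0.05,
        min_allelic_reads=3500,
        min_allelic_genes=25,
        min_minor_genotype_fraction=0.03,
        min_detected_cell_fraction=0.25,
    ),
    # E6.5 embryo cells (CAST x C57 cross): shallower allelic coverage, no
    # minor-genotype gate, informative genes need 20% detection.
    "e65_sc": QCProfile(
        name="e65_sc",
        min_genes=4000,
        min_molecules=10000,
        max_mito_fraction=0.05,
        min_allelic_reads=400,
        min_allelic_genes=25,
        min_minor_genotype_fraction=None,
        min_detected_cell_fraction=0.20,
    ),
    # In vivo fetal germ cells (shallow droplet-style libraries).
    "invivo_germ": QCProfile(
        name="invivo_germ",
        min_genes=2000,
        min_molecules=2000,
        max_mito_fraction=0.05,
        min_allelic_reads=3500,
        min_allelic_genes=25,
        min_minor_genotype_fraction=0.03,
        min_detected_cell_fraction=0.25,
    ),
}


@dataclass
class PipelineConfig:
    """All tunable analysis parameters with their published defaults.

    Attributes
    ----------
    xci_threshold:
        Allelic ratio at or below which a gene is called X-inactive.
    biallelic_window:
        Open interval of reference-stage (ESC) ratios a gene must fall in
        to enter silencing-kinetics classification.
    cell_biallelic_window:
        Closed interval of per-cell average ratios called XaXa.
    min_allelic_total_per_gene_group:
        Pooled allelic reads a (gene, group) needs to yield a ratio.
    qc_profile:
        Name of the single-cell QC profile (key of :data:`QC_PROFILES`).
    bulk_mean_cutoff:
        Bulk genes are kept when their mean total count is strictly above
        this value.
    norm_scale:
        Counts-per-``norm_scale`` scaling of the log normalisation.
    """

    xci_threshold: float = 0.135
    biallelic_window: tuple[float, float] = (0.3, 0.7)
    cell_biallelic_window: tuple[float, float] = (0.4, 0.6)
    min_allelic_total_per_gene_group: int = 10
    qc_profile: str = "invitro_sc"
    bulk_mean_cutoff: float = 10.0
    norm_scale: float = 10_000.0
    pluripotency_genes: tuple[str, ...] = PLURIPOTENCY_GENES
    xist_gene: str = "Xist"
    kde_bandwidth: str | float = "silverman"
    kde_grid_step: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.xci_threshold < self.cell_biallelic_window[0]:
            raise ParameterError(
                "xci_threshold must lie in (0, lower cell-window bound); got "
                f"{self.xci_threshold} vs window {self.cell_biallelic_window}"
            )
        for name, window in (
            ("biallelic_window", self.biallelic_window),
            ("cell_biallelic_window", self.cell_biallelic_window),
        ):
            lo, hi = window
            if not (0.0 <= lo < hi <= 1.0):
                raise ParameterError(f"{name} must satisfy 0 <= lo < hi <= 1, got {window}")
        if self.qc_profile not in QC_PROFILES:
            raise ParameterError(
                f"unknown qc_profile {self.qc_profile!r}; known: {sorted(QC_PROFILES)}"
            )
        if self.min_allelic_total_per_gene_group < 1:
            raise ParameterError("min_allelic_total_per_gene_group must be >= 1")
        if self.norm_scale <= 0:
            raise ParameterError("norm_scale must be positive")

    @property
    def profile(self) -> QCProfile:
        return QC_PROFILES[self.qc_profile]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["biallelic_window"] = list(self.biallelic_window)
        d["cell_biallelic_window"] = list(self.cell_biallelic_window)
        d["pluripotency_genes"] = list(self.pluripotency_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("biallelic_window", "cell_biallelic_window", "pluripotency_genes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
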