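"""In-memory containers: allelic count matrices, annotation, ratio tables.

The central object is :class:`AllelicCountMatrix`: a gene x unit pair of
integer layers, one per parental allele (e.g. X^mus vs X^cas for the in
vitro hybrid line, C57 vs CAST for the E6.5 cross), optionally accompanied
by a non-allelic totals layer used for expression-level QC/normalisation
and by per-unit metadata (stage or cluster labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError


def _check_integer_nonnegative(df: pd.DataFrame, layer: str) -> pd.DataFrame:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.isfinite(values)) or not np.array_equal(values, np.floor(values)):
            raise ValidationError(f"layer {layer!r} contains non-integer entries")
        df = df.astype(np.int64)
        values = df.to_numpy()
    if (values < 0).any():
        raise ValidationError(f"layer {layer!r} contains negative entries")
    return df


@dataclass
class AllelicCountMatrix:
    """Gene x unit allele-resolved counts in two layers plus optional totals.

    Rows are genes, columns are units (bulk samples or single cells). The
    allele-1 layer defines the canonical gene/unit order; allele 2 must be
    index-aligned. ``counts_total`` may carry extra genes (e.g. autosomal
    background used only for QC/normalisation) but must dominate the allelic
    sum on every shared gene.
    """

    counts_a1: pd.DataFrame
    counts_a2: pd.DataFrame
    counts_total: Optional[pd.DataFrame] = None
    unit_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        a1, a2 = self.counts_a1, self.counts_a2
        if a1.shape != a2.shape:
            raise ValidationError(
                f"allele layers differ in shape: {a1.shape} vs {a2.shape}"
            )
        if not a1.index.equals(a2.index):
            raise ValidationError("allele layers differ on the gene axis")
        if not a1.columns.equals(a2.columns):
            raise ValidationError("allele layers differ on the unit axis")
        if not a1.index.is_unique:
            raise ValidationError("gene ids are not unique")
        if not a1.columns.is_unique:
            raise ValidationError("unit ids are not unique")
        self.counts_a1 = _check_integer_nonnegative(a1, "counts_a1")
        self.counts_a2 = _check_integer_nonnegative(a2, "counts_a2")
        if self.counts_total is not None:
            tot = self.counts_total
            if not tot.columns.equals(a1.columns):
                raise ValidationError("counts_total differs on the unit axis")
            if not tot.index.is_unique:
                raise ValidationError("counts_total gene ids are not unique")
            self.counts_total = tot = _check_integer_nonnegative(tot, "counts_total")
            shared = a1.index.intersection(tot.index)
            if len(shared):
                allelic = (
                    self.counts_a1.loc[shared].to_numpy()
                    + self.counts_a2.loc[shared].to_numpy()
                )
                if (tot.loc[shared].to_numpy() < allelic).any():
                    raise ValidationError(
                        "counts_total < counts_a1 + counts_a2 for some entries"
                    )
        if self.unit_meta is not None:
            missing = a1.columns.difference(self.unit_meta.index)
            if len(missing):
                raise ValidationError(
                    f"unit_meta is missing units: {list(missing[:5])}"
                )

    # ------------------------------------------------------------------ #
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts_a1.index

    @property
    def unit_ids(self) -> pd.Index:
        return self.counts_a1.columns

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def allelic_total(self) -> pd.DataFrame:
        """Per-entry sum of the two allele layers."""
        return self.counts_a1 + self.counts_a2

    def swap_alleles(self) -> "AllelicCountMatrix":
        """Return a copy with the two allele layers exchanged (r -> 1 - r)."""
        return AllelicCountMatrix(
            counts_a1=self.counts_a2.copy(),
            counts_a2=self.counts_a1.copy(),
            counts_total=None if self.counts_total is None else self.counts_total.copy(),
            unit_meta=None if self.unit_meta is None else self.unit_meta.copy(),
        )

    def subset_units(self, units: Iterable[str]) -> "AllelicCountMatrix":
        units = pd.Index(units, name=self.counts_a1.columns.name)
        return AllelicCountMatrix(
            counts_a1=self.counts_a1.loc[:, units],
            counts_a2=self.counts_a2.loc[:, units],
            counts_total=None if self.counts_total is None else self.counts_total.loc[:, units],
            unit_meta=None if self.unit_meta is None else self.unit_meta.loc[units],
        )

    def subset_genes(self, genes: Iterable[str]) -> "AllelicCountMatrix":
        genes = pd.Index(genes, name=self.counts_a1.index.name)
        total = self.counts_total
        if total is not None:
            total = total.loc[total.index.intersection(genes)]
        return AllelicCountMatrix(
            counts_a1=self.counts_a1.loc[genes],
            counts_a2=self.counts_a2.loc[genes],
            counts_total=total,
            unit_meta=self.unit_meta,
        )


@dataclass
class GeneAnnotation:
    """Gene -> (chromosome, start, end, is_patch) lookup.

    Coordinates are 0-based half-open (BED convention). ``is_patch`` flags
    genes on poorly annotated scaffolds/patches, which the bulk expression
    filter removes.
    """

    table: pd.DataFrame

    REQUIRED = ("chromosome", "start", "end", "is_patch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids in annotation: {list(dupes[:5])}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValidationError("annotation has start > end")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_on(self, chromosome: str) -> pd.Index:
        return self.table.index[self.table["chromosome"] == chromosome]

    def is_patch(self) -> pd.Series:
        return self.table["is_patch"].astype(bool)

    def position_of(self, genes: Iterable[str]) -> pd.DataFrame:
        """Chromosome/start for the given genes (for genomic-position sort)."""
        return self.table.loc[pd.Index(genes), ["chromosome", "start"]]


@dataclass
class AllelicRatioTable:
    """Per (gene, group) allelic ratios with their read support.

    ``ratio`` holds a1 / (a1 + a2) where the pooled support reaches
    ``min_support`` and NaN otherwise; ``support`` holds a1 + a2.
    Swapping allele layers maps every defined ratio r to 1 - r.
    """

    ratio: pd.DataFrame
    support: pd.DataFrame
    min_support: int

    def __post_init__(self) -> None:
        if self.ratio.shape != self.support.shape:
            raise ValidationError("ratio and support differ in shape")
        vals = self.ratio.to_numpy()
        finite = np.isfinite(vals)
        if ((vals[finite] < 0) | (vals[finite] > 1)).any():
            raise ValidationError("ratios outside [0, 1]")

    @property
    def detected(self) -> pd.DataFrame:
        return self.support >= self.min_support

    def mirrored(self) -> "AllelicRatioTable":
        return AllelicRatioTable(
            ratio=1.0 - self.ratio, support=self.support, min_support=self.min_support
        )
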