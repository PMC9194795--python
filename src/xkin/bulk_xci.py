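"""Bulk RNA-seq stage of the pipeline.

Takes stage-labelled bulk samples of a hybrid cross through: expression
filtering on non-allelic totals, median-of-ratios library size factors,
stage-pooled allelic ratios on chromosome X, silencing-kinetics
classification against the X-inactivation cut-off, an autosomal control
chromosome classified the same way, escapee-set overlap against an external
reference list, and category-wise expression comparisons.

Allelic ratios are computed from raw pooled counts: library-size
normalisation cancels within a sample, so size factors only enter the
expression-level comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .allelic_core import (
    classify_xci_frame,
    estimate_xci_threshold,
    pool_groups,
)
from .config import PipelineConfig
from .containers import AllelicCountMatrix, AllelicRatioTable, GeneAnnotation
from .exceptions import InsufficientDataError, ValidationError

REQUIRED_STAGES = ("ESC", "EpiLC", "PGCLC_neg")


# --------------------------------------------------------------------- #
def filter_expressed_genes(
    counts_total: pd.DataFrame,
    annotation: GeneAnnotation,
    mean_cutoff: float = 10.0,
) -> pd.Index:
    """Keep genes whose mean total count is strictly above the cutoff.

    Genes flagged as lying on annotation patches are removed regardless of
    expression; genes absent from the annotation are treated as non-patch.
    """
    if counts_total.shape[1] == 0:
        raise ValidationError("no samples in totals layer")
    means = counts_total.mean(axis=1)
    keep = means > mean_cutoff
    patch = annotation.is_patch().reindex(counts_total.index).fillna(False).astype(bool)
    return counts_total.index[keep & ~patch]


def size_factors_median_of_ratios(counts_total: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Per gene, the geometric mean across samples is taken over genes with
    nonzero counts in every sample; each sample's factor is the median of
    its count / geometric-mean ratios. Factors are returned unscaled.
    """
    if counts_total.shape[1] < 2:
        raise ValidationError("size factors need >= 2 samples")
    values = counts_total.to_numpy(dtype=float)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise InsufficientDataError(
            "no gene has nonzero counts in all samples; cannot form the "
            "geometric-mean reference"
        )
    log_values = np.log(values[all_nonzero])
    log_geomean = log_values.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_values - log_geomean, axis=0))
    return pd.Series(factors, index=counts_total.columns, name="size_factor")


def lognorm_expression(
    counts_total: pd.DataFrame, size_factors: pd.Series, base: float = 2.0
) -> pd.DataFrame:
    """log(1 + count / size_factor): expression values for between-category tests."""
    normed = counts_total.div(size_factors, axis=1)
    return np.log1p(normed) / np.log(base)


# --------------------------------------------------------------------- #
def compare_category_expression(
    expression: pd.Series,
    classification: pd.Series,
    min_genes: int = 3,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between gene categories.

    ``expression`` holds one normalised value per gene (one stage);
    categories with fewer than ``min_genes`` members are skipped with a
    warning. The exact null enumeration is used when both groups have at
    most ``exact_max_n`` genes, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    shared = expression.index.intersection(classification.index)
    expr = expression.loc[shared]
    cats = classification.loc[shared]
    groups: dict[str, np.ndarray] = {}
    for cat in pd.unique(cats):
        vals = expr[cats == cat].dropna().to_numpy()
        if len(vals) < min_genes:
            warnings.warn(
                f"category {cat!r} has {len(vals)} genes (< {min_genes}); skipped",
                stacklevel=2,
            )
            continue
        groups[cat] = vals
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 categories with enough genes")
    rows = []
    names = sorted(groups)
    for i, cat_a in enumerate(names):
        for cat_b in names[i + 1 :]:
            a, b = groups[cat_a], groups[cat_b]
            method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymptotic"
            result = mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                {
                    "category_a": cat_a,
                    "category_b": cat_b,
                    "n_a": len(a),
                    "n_b": len(b),
                    "method": method,
                    "p_value": min(1.0, float(result.pvalue)),
                }
            )
    return pd.DataFrame(rows)


def escapee_share_percent(n_early: int, n_late: int, n_escapee: int) -> int:
    """Escapee share of classified X-linked genes, as a round-half-up integer percent."""
    total = n_early + n_late + n_escapee
    if total == 0:
        raise ValidationError("no classified genes")
    pct = Decimal(100 * n_escapee) / Decimal(total)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------- #
@dataclass
class BulkRunResult:
    """Everything the bulk stage produces."""

    threshold: float
    size_factors: Optional[pd.Series]
    kept_genes: pd.Index
    ratio_table: AllelicRatioTable
    classification: pd.Series
    summary: dict[str, int]
    control_classification: Optional[pd.Series] = None
    control_summary: Optional[dict[str, int]] = None
    escapee_overlap: Optional[tuple[int, int, int]] = None

    @property
    def escapees(self) -> pd.Index:
        return self.classification.index[self.classification == "escapee"]


def _summary_counts(classification: pd.Series, categories: Iterable[str]) -> dict[str, int]:
    counts = classification.value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in categories}


def run_bulk_xci(
    matrix: AllelicCountMatrix,
    annotation: GeneAnnotation,
    config: PipelineConfig,
    stage_map: Mapping[str, str] | pd.Series,
    npc_reference_ratios: Optional[Iterable[float]] = None,
    external_escapee_set: Optional[Iterable[str]] = None,
    x_chromosome: str = "chrX",
    control_chromosome: str = "chr13",
) -> BulkRunResult:
    """Run the full bulk silencing-kinetics pipeline.

    ``stage_map`` assigns every sample to a stage; ESC, EpiLC and PGCLC_neg
    are required (additional stages such as PGCLC_pos or NPC are pooled and
    reported in the ratio table but do not enter classification). When
    ``npc_reference_ratios`` is given the silencing cut-off is re-estimated
    from that distribution, otherwise the configured value is used.
    """
    stages = pd.Series(dict(stage_map) if not isinstance(stage_map, pd.Series) else stage_map)
    missing_units = matrix.unit_ids.difference(stages.index)
    if len(missing_units):
        raise ValidationError(f"samples missing from stage_map: {list(missing_units)}")
    stages = stages.loc[matrix.unit_ids]
    missing_stages = [s for s in REQUIRED_STAGES if s not in set(stages)]
    if missing_stages:
        raise ValidationError(f"required stages missing: {missing_stages}")

    size_factors = None
    if matrix.counts_total is not None:
        size_factors = size_factors_median_of_ratios(matrix.counts_total)
        kept = filter_expressed_genes(
            matrix.counts_total, annotation, mean_cutoff=config.bulk_mean_cutoff
        )
    else:
        patch = annotation.is_patch().reindex(matrix.gene_ids).fillna(False).astype(bool)
        kept = matrix.gene_ids[~patch.to_numpy()]

    ratio_table = pool_groups(
        matrix, stages, min_support=config.min_allelic_total_per_gene_group
    )

    if npc_reference_ratios is not None:
        threshold = estimate_xci_threshold(
            npc_reference_ratios,
            bandwidth=config.kde_bandwidth,
            grid_step=config.kde_grid_step,
            default=config.xci_threshold,
        )
    else:
        threshold = config.xci_threshold

    def _classify(chromosome: str) -> pd.Series:
        genes = annotation.genes_on(chromosome).intersection(kept)
        genes = matrix.gene_ids.intersection(genes)
        return classify_xci_frame(
            ratio_table.ratio.loc[genes],
            stages=list(REQUIRED_STAGES),
            threshold=threshold,
            biallelic_window=config.biallelic_window,
        )

    classification = _classify(x_chromosome)
    summary = _summary_counts(
        classification,
        ("earlyXCI", "lateXCI", "escapee", "excluded_nonbiallelic", "undetected"),
    )

    control_classification = None
    control_summary = None
    if len(annotation.genes_on(control_chromosome)):
        control_classification = _classify(control_chromosome)
        control_summary = _summary_counts(
            control_classification,
            ("earlyXCI", "lateXCI", "escapee", "excluded_nonbiallelic", "undetected"),
        )

    escapee_overlap = None
    if external_escapee_set is not None:
        ours = set(classification.index[classification == "escapee"]) - {config.xist_gene}
        theirs = set(external_escapee_set) - {config.xist_gene}
        escapee_overlap = (
            len(ours - theirs),
            len(theirs - ours),
            len(ours & theirs),
        )

    return BulkRunResult(
        threshold=threshold,
        size_factors=size_factors,
        kept_genes=kept,
        ratio_table=ratio_table,
        classification=classification,
        summary=summary,
        control_classification=control_classification,
        control_summary=control_summary,
        escapee_overlap=escapee_overlap,
    )
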