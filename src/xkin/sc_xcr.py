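"""Single-cell stage of the pipeline: QC, profiling, X-status, reactivation.

The chain mirrors a germ-cell allelome analysis: non-allelic QC on totals
(genes/molecules/mitochondrial fraction), log normalisation to counts per
10,000, germ-cell marker subsetting (e.g. Dazl), allelic cell QC (total
allelic reads, allelically expressed genes, minor-genotype fraction),
informative-gene selection, per-cell average allelic ratio and X-status
calls, cluster-pooled gene ratios, reactivation-kinetics classification
against a bulk PGCLC reference, and a pluripotency score. An E6.5 in vivo
mode reuses the same gates under the ``e65_sc`` profile without the
marker/totals steps when no totals layer exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .allelic_core import classify_xcr_frame, pool_groups
from .config import PipelineConfig, QCProfile, QC_PROFILES
from .containers import AllelicCountMatrix, AllelicRatioTable, GeneAnnotation
from .exceptions import ParameterError, ValidationError

MACRO_GROUPS = ("premeiotic", "meiotic", "mitotic")
DEFAULT_MACRO_GROUPS = {
    "Mitotic1": "mitotic",
    "Mitotic2": "mitotic",
    "PreMeiotic1": "premeiotic",
    "PreMeiotic2": "premeiotic",
    "Meiotic": "meiotic",
}
QC_BINS = ("nonallelic_qc_fail", "marker_fail", "allelic_qc_fail", "profiled")


def _resolve_profile(profile: str | QCProfile) -> QCProfile:
    if isinstance(profile, QCProfile):
        return profile
    try:
        return QC_PROFILES[profile]
    except KeyError:
        raise ParameterError(
            f"unknown QC profile {profile!r}; known: {sorted(QC_PROFILES)}"
        ) from None


# --------------------------------------------------------------------- #
# non-allelic QC and normalisation
# --------------------------------------------------------------------- #
def cell_nonallelic_stats(
    counts_total: pd.DataFrame, mito_prefix: str = "mt-"
) -> pd.DataFrame:
    """Per-cell detected genes, molecules and mitochondrial read fraction."""
    if counts_total is None:
        raise ValidationError("non-allelic QC needs a totals layer")
    molecules = counts_total.sum(axis=0)
    n_genes = (counts_total > 0).sum(axis=0)
    mito_genes = counts_total.index[counts_total.index.str.startswith(mito_prefix)]
    mito = counts_total.loc[mito_genes].sum(axis=0) if len(mito_genes) else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(molecules > 0, mito / molecules, np.nan)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes,
            "n_molecules": molecules,
            "mito_fraction": mito_fraction,
        }
    )


def nonallelic_cell_qc(stats: pd.DataFrame, profile: str | QCProfile) -> pd.Series:
    """Keep cells with enough genes/molecules and low mitochondrial load.

    A cell is dropped iff genes < min, molecules < min, or mito fraction
    strictly above the cap — boundaries are kept, matching the "less than"
    / "more than" wording of the gates.
    """
    prof = _resolve_profile(profile)
    keep = (
        (stats["n_genes_detected"] >= prof.min_genes)
        & (stats["n_molecules"] >= prof.min_molecules)
        & ~(stats["mito_fraction"] > prof.max_mito_fraction)
    )
    return keep.rename("qc_pass")


def lognormalize(
    counts_total: pd.DataFrame, scale: float = 10_000.0, base: float = 2.0
) -> pd.DataFrame:
    """log_base(1 + scale * count / cell_total), i.e. log counts per ``scale``."""
    totals = counts_total.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0][:5])
        raise ValidationError(f"cells with zero total counts: {empty}")
    scaled = counts_total.div(totals, axis=1) * scale
    return np.log1p(scaled) / np.log(base)


def subset_by_markers(
    norm_expr: pd.DataFrame,
    include: Optional[Mapping[str, float]] = None,
    exclude: Optional[Mapping[str, float]] = None,
) -> pd.Index:
    """Keep cells strictly above every include and strictly below every exclude cut."""
    keep = pd.Series(True, index=norm_expr.columns)
    for gene, cutoff in (include or {}).items():
        if gene not in norm_expr.index:
            raise ValidationError(f"marker gene {gene!r} absent from matrix")
        keep &= norm_expr.loc[gene] > cutoff
    for gene, cutoff in (exclude or {}).items():
        if gene not in norm_expr.index:
            raise ValidationError(f"marker gene {gene!r} absent from matrix")
        keep &= norm_expr.loc[gene] < cutoff
    return norm_expr.columns[keep]


# --------------------------------------------------------------------- #
# allelic QC and profiling
# --------------------------------------------------------------------- #
def cell_allelic_stats(a1: pd.DataFrame, a2: pd.DataFrame) -> pd.DataFrame:
    """Per-cell total allelic reads, allelically expressed genes, minor fraction."""
    reads_a1 = a1.sum(axis=0)
    reads_a2 = a2.sum(axis=0)
    total = reads_a1 + reads_a2
    with np.errstate(invalid="ignore", divide="ignore"):
        minor = np.where(total > 0, np.minimum(reads_a1, reads_a2) / total, np.nan)
    return pd.DataFrame(
        {
            "total_allelic_reads": total,
            "n_allelic_genes": ((a1 + a2) > 0).sum(axis=0),
            "minor_genotype_fraction": minor,
        }
    )


def allelic_cell_qc(stats: pd.DataFrame, profile: str | QCProfile) -> pd.Series:
    """Allelic coverage gate: strict on reads, inclusive on genes and minor fraction."""
    prof = _resolve_profile(profile)
    keep = (stats["total_allelic_reads"] > prof.min_allelic_reads) & (
        stats["n_allelic_genes"] >= prof.min_allelic_genes
    )
    if prof.min_minor_genotype_fraction is not None:
        keep &= stats["minor_genotype_fraction"] >= prof.min_minor_genotype_fraction
    return keep.rename("qc_pass")


def informative_genes(
    a1: pd.DataFrame, a2: pd.DataFrame, profile: str | QCProfile
) -> pd.Index:
    """Genes with > 10 summed allelic reads, detected in enough cells.

    Detection means any allelic read in a cell; the required cell fraction
    comes from the profile (inclusive).
    """
    if a1.shape[1] == 0:
        raise ValidationError("informative-gene filter needs >= 1 QC-passed cell")
    prof = _resolve_profile(profile)
    allelic = a1 + a2
    enough_reads = allelic.sum(axis=1) > 10
    detected_fraction = (allelic > 0).mean(axis=1)
    return a1.index[enough_reads & (detected_fraction >= prof.min_detected_cell_fraction)]


def per_cell_avg_ratio(
    a1: pd.DataFrame,
    a2: pd.DataFrame,
    genes: Iterable[str],
    weighted: bool = False,
) -> pd.Series:
    """Per-cell average allelic ratio over the given (informative) genes.

    The default is the unweighted mean of per-gene ratios over genes with at
    least one allelic read in the cell, so each gene contributes equally
    regardless of depth. ``weighted=True`` instead pools counts across genes
    before dividing (read-weighted), provided for sensitivity analysis.
    Cells without any detected gene get NaN.
    """
    genes = pd.Index(genes).intersection(a1.index)
    x1 = a1.loc[genes].to_numpy(dtype=float)
    x2 = a2.loc[genes].to_numpy(dtype=float)
    total = x1 + x2
    if weighted:
        num = x1.sum(axis=0)
        den = total.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(total > 0, x1 / np.where(total > 0, total, 1.0), np.nan)
        detected = total > 0
        counts = detected.sum(axis=0)
        sums = np.nansum(np.where(detected, ratios, 0.0), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return pd.Series(avg, index=a1.columns, name="avg_allelic_ratio")


def classify_cell_xstatus(
    ratio: float | pd.Series, window: tuple[float, float] = (0.4, 0.6)
) -> str | pd.Series:
    """Call per-cell X status from the average allelic ratio.

    The biallelic window is closed: ratios inside [lo, hi] are XaXa; strictly
    below → XaXi (allele 1 inactive under the low-inactive orientation);
    strictly above → XiXa. NaN propagates as 'NA'.
    """
    lo, hi = window

    def _one(r: float) -> str:
        if r is None or not np.isfinite(r):
            return "NA"
        if lo <= r <= hi:
            return "XaXa"
        return "XaXi" if r < lo else "XiXa"

    if isinstance(ratio, pd.Series):
        return ratio.map(_one).rename("x_status")
    return _one(float(ratio))


def pluripotency_score(
    norm_expr: pd.DataFrame, gene_set: Iterable[str] = None
) -> pd.Series:
    """Per-cell mean of z-scored log-normalised pluripotency gene expression.

    Genes are z-scored across cells with the population SD; a gene constant
    across cells contributes 0. Absent genes are skipped with a warning; if
    none of the set is present an error is raised.
    """
    from .config import PLURIPOTENCY_GENES

    gene_set = tuple(gene_set) if gene_set is not None else PLURIPOTENCY_GENES
    present = [g for g in gene_set if g in norm_expr.index]
    absent = sorted(set(gene_set) - set(present))
    if not present:
        raise ValidationError(f"none of the pluripotency genes present: {absent}")
    if absent:
        warnings.warn(f"pluripotency genes absent and skipped: {absent}", stacklevel=2)
    values = norm_expr.loc[present].to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=0), index=norm_expr.columns, name="pluripotency_score")


# --------------------------------------------------------------------- #
# cluster summaries
# --------------------------------------------------------------------- #
def cluster_summaries(
    profiles: pd.DataFrame,
    clusters: pd.Series,
    matrix: AllelicCountMatrix,
    config: PipelineConfig,
    x_genes: Iterable[str],
    pluripotency: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, AllelicRatioTable]:
    """Per-cluster X-status fractions, escapee fraction and pooled gene ratios.

    The escapee fraction is computed over cells with an inactive X (XaXi or
    XiXa): each such cell's counts are oriented so its inactive allele is the
    numerator (random XCI makes a fixed orientation wrong), counts are pooled
    across cells, and the fraction of detected X-linked genes whose
    inactive-allele ratio exceeds the silencing cut-off is reported.
    """
    unlabeled = profiles.index.difference(clusters.index)
    if len(unlabeled):
        raise ValidationError(f"cells missing cluster labels: {list(unlabeled[:5])}")
    clusters = clusters.loc[profiles.index]
    x_genes = pd.Index(x_genes).intersection(matrix.gene_ids)
    min_support = config.min_allelic_total_per_gene_group

    pooled = pool_groups(
        matrix.subset_units(profiles.index), clusters, min_support=min_support
    )

    rows = []
    for cluster in pd.unique(clusters):
        cells = profiles.index[clusters == cluster]
        status = profiles.loc[cells, "x_status"]
        called = status[status != "NA"]
        n_called = len(called)
        frac = lambda s: (called == s).sum() / n_called if n_called else np.nan

        silenced = called.index[(called == "XaXi") | (called == "XiXa")]
        escapee_fraction = np.nan
        if len(silenced):
            num = np.zeros(len(x_genes))
            den = np.zeros(len(x_genes))
            a1 = matrix.counts_a1.loc[x_genes, silenced]
            a2 = matrix.counts_a2.loc[x_genes, silenced]
            xaxi = called.loc[silenced] == "XaXi"
            # XaXi: allele 1 inactive -> numerator a1; XiXa: allele 2 inactive.
            inactive = np.where(
                xaxi.to_numpy()[None, :], a1.to_numpy(), a2.to_numpy()
            )
            num = inactive.sum(axis=1).astype(float)
            den = (a1.to_numpy() + a2.to_numpy()).sum(axis=1).astype(float)
            detected = den >= min_support
            if detected.any():
                with np.errstate(invalid="ignore", divide="ignore"):
                    inactive_ratio = num[detected] / den[detected]
                escapee_fraction = float(
                    (inactive_ratio > config.xci_threshold).mean()
                )
        row = {
            "cluster": cluster,
            "n_cells": len(cells),
            "xaxa_fraction": frac("XaXa"),
            "xaxi_fraction": frac("XaXi"),
            "xixa_fraction": frac("XiXa"),
            "escapee_fraction_xaxi": escapee_fraction,
        }
        if pluripotency is not None:
            row["mean_pluripotency_score"] = float(
                pluripotency.reindex(cells).mean()
            )
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("cluster")
    return summary, pooled


# --------------------------------------------------------------------- #
# full runs
# --------------------------------------------------------------------- #
@dataclass
class ScRunResult:
    """Everything the single-cell stage produces."""

    qc_bin: pd.Series
    cell_profiles: pd.DataFrame
    informative_genes: pd.Index
    classification: pd.Series
    summary: dict[str, int]
    cluster_summary: pd.DataFrame
    cluster_ratios: AllelicRatioTable
    threshold: float
    pluripotency: Optional[pd.Series] = None


@dataclass
class E65RunResult:
    """E6.5 in vivo mode outputs (no reactivation classification)."""

    qc_bin: pd.Series
    cell_profiles: pd.DataFrame
    informative_genes: pd.Index
    cluster_summary: pd.DataFrame
    cluster_ratios: AllelicRatioTable


def _profile_cells(
    matrix: AllelicCountMatrix,
    annotation: GeneAnnotation,
    config: PipelineConfig,
    profile: QCProfile,
    candidate_cells: pd.Index,
    qc_bin: pd.Series,
    x_chromosome: str,
    weighted_avg: bool,
) -> tuple[pd.DataFrame, pd.Index]:
    """Allelic QC -> informative genes -> per-cell profiles for candidates."""
    a1 = matrix.counts_a1.loc[:, candidate_cells]
    a2 = matrix.counts_a2.loc[:, candidate_cells]
    stats = cell_allelic_stats(a1, a2)
    allelic_pass = allelic_cell_qc(stats, profile)
    qc_bin.loc[stats.index[~allelic_pass]] = "allelic_qc_fail"
    kept = stats.index[allelic_pass]
    qc_bin.loc[kept] = "profiled"

    info = informative_genes(a1.loc[:, kept], a2.loc[:, kept], profile)
    x_info = pd.Index(annotation.genes_on(x_chromosome)).intersection(info)

    avg = per_cell_avg_ratio(
        a1.loc[:, kept], a2.loc[:, kept], x_info, weighted=weighted_avg
    )
    profiles = stats.loc[kept].copy()
    profiles["avg_allelic_ratio"] = avg
    profiles["x_status"] = classify_cell_xstatus(
        avg, window=config.cell_biallelic_window
    )
    profiles["qc_pass"] = True
    return profiles, info


def run_sc_xcr(
    matrix: AllelicCountMatrix,
    annotation: GeneAnnotation,
    config: PipelineConfig,
    clusters: Mapping[str, str] | pd.Series,
    bulk_pgclc_ratios: pd.Series,
    macro_groups: Optional[Mapping[str, str]] = None,
    marker_include: Optional[Mapping[str, float]] = None,
    marker_exclude: Optional[Mapping[str, float]] = None,
    mito_prefix: str = "mt-",
    x_chromosome: str = "chrX",
    weighted_avg: bool = False,
) -> ScRunResult:
    """Run the full single-cell reactivation pipeline.

    ``clusters`` labels every cell; ``macro_groups`` maps cluster labels onto
    the ordered macro-groups premeiotic/meiotic/mitotic (a default mapping
    for the five germ-cell maturation clusters is used when omitted).
    ``bulk_pgclc_ratios`` supplies the silenced starting point (bulk XGFP-
    PGCLC pooled ratios) of each gene's reactivation trajectory. Marker
    subsetting defaults to Dazl > 1 when a totals layer is present.
    """
    profile = _resolve_profile(config.qc_profile)
    clusters = pd.Series(dict(clusters) if not isinstance(clusters, pd.Series) else clusters)
    macro = dict(DEFAULT_MACRO_GROUPS if macro_groups is None else macro_groups)
    if marker_include is None:
        marker_include = {"Dazl": 1.0}

    qc_bin = pd.Series("profiled", index=matrix.unit_ids, name="qc_bin")
    candidates = matrix.unit_ids
    norm = None
    if matrix.counts_total is not None:
        stats = cell_nonallelic_stats(matrix.counts_total, mito_prefix=mito_prefix)
        keep = nonallelic_cell_qc(stats, profile)
        qc_bin.loc[stats.index[~keep]] = "nonallelic_qc_fail"
        candidates = stats.index[keep]
        norm = lognormalize(
            matrix.counts_total.loc[:, candidates], scale=config.norm_scale
        )
        marked = subset_by_markers(norm, include=marker_include, exclude=marker_exclude)
        qc_bin.loc[candidates.difference(marked)] = "marker_fail"
        candidates = marked

    profiles, info = _profile_cells(
        matrix, annotation, config, profile, candidates, qc_bin,
        x_chromosome, weighted_avg,
    )

    missing_labels = profiles.index.difference(clusters.index)
    if len(missing_labels):
        raise ValidationError(f"cells missing cluster labels: {list(missing_labels[:5])}")

    pluri = None
    if norm is not None:
        if any(g in norm.index for g in config.pluripotency_genes):
            pluri = pluripotency_score(
                norm.loc[:, profiles.index], config.pluripotency_genes
            )
        else:
            warnings.warn("no pluripotency genes in matrix; score skipped", stacklevel=2)

    cluster_summary, cluster_ratios = cluster_summaries(
        profiles, clusters, matrix, config,
        x_genes=annotation.genes_on(x_chromosome),
        pluripotency=pluri,
    )

    # macro-group pooling for reactivation kinetics
    cell_macro = clusters.loc[profiles.index].map(macro)
    unmapped = profiles.index[cell_macro.isna()]
    if len(unmapped):
        raise ValidationError(
            f"clusters without a macro-group mapping: "
            f"{sorted(set(clusters.loc[unmapped]))}"
        )
    present = set(cell_macro)
    needed = {"premeiotic", "meiotic"}
    if not needed <= present:
        raise ValidationError(f"macro-groups missing: {sorted(needed - present)}")
    macro_pooled = pool_groups(
        matrix.subset_units(profiles.index),
        cell_macro,
        min_support=config.min_allelic_total_per_gene_group,
    )

    x_info = pd.Index(annotation.genes_on(x_chromosome)).intersection(info)
    trajectories = pd.DataFrame(
        {
            "PGCLC_neg": bulk_pgclc_ratios.reindex(x_info),
            "premeiotic": macro_pooled.ratio["premeiotic"].reindex(x_info),
            "meiotic": macro_pooled.ratio["meiotic"].reindex(x_info),
        }
    )
    classification = classify_xcr_frame(
        trajectories,
        groups=("PGCLC_neg", "premeiotic", "meiotic"),
        threshold=config.xci_threshold,
    )
    counts = classification.value_counts()
    summary = {
        cat: int(counts.get(cat, 0))
        for cat in ("escapee", "earlyXCR", "lateXCR", "noXCR", "unclassified")
    }

    return ScRunResult(
        qc_bin=qc_bin,
        cell_profiles=profiles,
        informative_genes=info,
        classification=classification,
        summary=summary,
        cluster_summary=cluster_summary,
        cluster_ratios=cluster_ratios,
        threshold=config.xci_threshold,
        pluripotency=pluri,
    )


def run_e65(
    matrix: AllelicCountMatrix,
    annotation: GeneAnnotation,
    config: PipelineConfig,
    clusters: Mapping[str, str] | pd.Series,
    marker_include: Optional[Mapping[str, float]] = None,
    marker_exclude: Optional[Mapping[str, float]] = None,
    mito_prefix: str = "mt-",
    x_chromosome: str = "chrX",
    weighted_avg: bool = False,
) -> E65RunResult:
    """E6.5 in vivo mode: per-cell X status and cluster summaries.

    Uses the configured QC profile (typically ``e65_sc``). Non-allelic QC
    and marker subsetting run only when the matrix carries a totals layer;
    the deposited E6.5 allelic tables often do not, in which case the chain
    starts at the allelic gates.
    """
    profile = _resolve_profile(config.qc_profile)
    clusters = pd.Series(dict(clusters) if not isinstance(clusters, pd.Series) else clusters)

    qc_bin = pd.Series("profiled", index=matrix.unit_ids, name="qc_bin")
    candidates = matrix.unit_ids
    if matrix.counts_total is not None:
        stats = cell_nonallelic_stats(matrix.counts_total, mito_prefix=mito_prefix)
        keep = nonallelic_cell_qc(stats, profile)
        qc_bin.loc[stats.index[~keep]] = "nonallelic_qc_fail"
        candidates = stats.index[keep]
        if marker_include or marker_exclude:
            norm = lognormalize(
                matrix.counts_total.loc[:, candidates], scale=config.norm_scale
            )
            marked = subset_by_markers(
                norm, include=marker_include, exclude=marker_exclude
            )
            qc_bin.loc[candidates.difference(marked)] = "marker_fail"
            candidates = marked

    profiles, info = _profile_cells(
        matrix, annotation, config, profile, candidates, qc_bin,
        x_chromosome, weighted_avg,
    )
    cluster_summary, cluster_ratios = cluster_summaries(
        profiles, clusters, matrix, config,
        x_genes=annotation.genes_on(x_chromosome),
    )
    return E65RunResult(
        qc_bin=qc_bin,
        cell_profiles=profiles,
        informative_genes=info,
        cluster_summary=cluster_summary,
        cluster_ratios=cluster_ratios,
    )
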