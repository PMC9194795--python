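"""Synthetic allelic count matrices with planted silencing/reactivation truth.

The generators emulate the statistical structure of hybrid-cross allelic
expression data at desk scale so that every pipeline stage can be tested
against a known ground truth:

* library depth per gene (bulk) or per cell (single cell) is negative
  binomial; dropout emerges from sampling, with no separate zero inflation;
* the allele-1 read count given a depth is beta-binomial with mean equal to
  the planted allelic ratio and overdispersion rho = 1 / (alpha + beta + 1),
  so rho = 0 degenerates to a pure binomial split;
* per-gene ratio trajectories are planted by category — escapees stay
  biallelic, early/late silencing drops below the cut-off at successive
  stages, and reactivation mirrors silencing in reverse across germ-cell
  maturation clusters;
* decoy genes non-biallelic in the reference stage, autosomal control genes,
  QC-violating cells and marker-negative somatic contaminants exercise every
  filter.

Planted composition is exact, not sampled: requested category counts, the
number of QC-failing cells and per-cluster XaXa counts are hit exactly so
recovery tests measure the pipeline rather than planting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import QC_PROFILES, QCProfile
from .containers import AllelicCountMatrix, GeneAnnotation
from .exceptions import ParameterError

BULK_STAGES = ("ESC", "EpiLC", "PGCLC_neg")
DEFAULT_BULK_CATEGORIES = {"earlyXCI": 62, "lateXCI": 138, "escapee": 93}

SC_CLUSTERS = ("Mitotic1", "Mitotic2", "PreMeiotic1", "PreMeiotic2", "Meiotic")
CLUSTER_MACRO = {
    "Mitotic1": "mitotic",
    "Mitotic2": "mitotic",
    "PreMeiotic1": "premeiotic",
    "PreMeiotic2": "premeiotic",
    "Meiotic": "meiotic",
}
DEFAULT_SC_CELLS = {
    "Mitotic1": 76, "Mitotic2": 76, "PreMeiotic1": 76, "PreMeiotic2": 76, "Meiotic": 75,
}
DEFAULT_XCR_CATEGORIES = {"escapee": 78, "earlyXCR": 58, "lateXCR": 17, "noXCR": 8}

E65_CLUSTERS = ("aVE", "pVE", "parietalE", "proxEpi", "transEpi", "postEpi")
DEFAULT_E65_CELLS = {
    "aVE": 40, "pVE": 53, "parietalE": 17, "proxEpi": 39, "transEpi": 21, "postEpi": 69,
}
E65_EXTRAEMBRYONIC = ("aVE", "pVE", "parietalE")
DEFAULT_E65_XAXA = {"proxEpi": 0.25, "transEpi": 0.08, "postEpi": 0.08}
DEFAULT_E65_ESCAPE = {
    "proxEpi": 0.56, "transEpi": 0.07, "postEpi": 0.07,
    "aVE": 0.07, "pVE": 0.07, "parietalE": 0.07,
}


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene categories/trajectories, per-cell states, params."""

    gene_truth: pd.DataFrame
    cell_truth: Optional[pd.DataFrame]
    params: dict

    def category_counts(self) -> dict[str, int]:
        return self.gene_truth["category"].value_counts().to_dict()

    @property
    def bulk_reference_ratios(self) -> pd.Series:
        """Planted PGCLC-stage ratios (reactivation-trajectory starting point)."""
        if "ratio_PGCLC_neg" not in self.gene_truth.columns:
            raise ParameterError("this truth table has no PGCLC-stage ratios")
        return self.gene_truth["ratio_PGCLC_neg"]


# --------------------------------------------------------------------- #
# sampling primitives
# --------------------------------------------------------------------- #
def _check_rho(rho: float) -> None:
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"beta-binomial overdispersion must be in [0, 1), got {rho}")


def _check_depth(depth: float) -> None:
    if depth <= 0:
        raise ParameterError(f"depth_mean must be positive, got {depth}")


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float, size):
    """Negative-binomial depth; dispersion 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _truncated_depth(rng: np.random.Generator, mean: float, dispersion: float,
                     minimum: int) -> int:
    """One depth draw conditioned on exceeding ``minimum`` (rejection sampling)."""
    for _ in range(10_000):
        n = int(_draw_depth(rng, mean, dispersion, None))
        if n > minimum:
            return n
    raise ParameterError(
        f"depth_mean {mean} cannot exceed the floor {minimum}; increase depth"
    )


def beta_binomial(rng: np.random.Generator, n, ratio, rho: float):
    """Beta-binomial draws parameterised by (mean ratio, overdispersion rho).

    rho = 1 / (alpha + beta + 1); rho = 0 is an exact binomial. Degenerate
    ratios 0 and 1 short-circuit to all-or-nothing splits.
    """
    _check_rho(rho)
    n = np.asarray(n)
    ratio = np.broadcast_to(np.asarray(ratio, dtype=float), n.shape)
    if rho == 0.0:
        return rng.binomial(n, ratio)
    k = 1.0 / rho - 1.0
    interior = (ratio > 0.0) & (ratio < 1.0)
    alpha = np.where(interior, ratio * k, 1.0)
    beta = np.where(interior, (1.0 - ratio) * k, 1.0)
    p = np.where(interior, rng.beta(alpha, beta), ratio)
    return rng.binomial(n, p)


def _spread_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Gene start coordinates: evenly spaced, order fixed (categories get shuffled)."""
    return (np.arange(n) + 1) * 10_000


# --------------------------------------------------------------------- #
# bulk generator
# --------------------------------------------------------------------- #
def generate_bulk(
    n_per_category: Optional[Mapping[str, int]] = None,
    stages: Sequence[str] = BULK_STAGES,
    replicates_per_stage: int = 3,
    depth_mean: float = 2000.0,
    nb_dispersion: float = 0.05,
    bb_overdispersion: float = 0.01,
    seed: int = 0,
    n_decoys: int = 41,
    n_autosomal_controls: int = 294,
    biallelic_stages: Sequence[str] = ("PGCLC_pos",),
    x_chromosome: str = "chrX",
    control_chromosome: str = "chr13",
) -> tuple[AllelicCountMatrix, GeneAnnotation, SyntheticTruth]:
    """Bulk stage-course counts with planted silencing kinetics.

    The first three stages are the (reference, intermediate, final) triple;
    extra stages take the final trajectory value unless listed in
    ``biallelic_stages`` (e.g. an XGFP+ PGCLC stage that never silences), in
    which case they take the reference value. Besides the requested X-linked
    categories, ``n_decoys`` genes non-biallelic in the reference stage and
    ``n_autosomal_controls`` biallelic control genes are emitted.
    """
    _check_rho(bb_overdispersion)
    _check_depth(depth_mean)
    if replicates_per_stage < 1:
        raise ParameterError("replicates_per_stage must be >= 1")
    if len(stages) < 3:
        raise ParameterError("need at least (reference, intermediate, final) stages")
    cats = dict(DEFAULT_BULK_CATEGORIES if n_per_category is None else n_per_category)
    unknown = set(cats) - set(DEFAULT_BULK_CATEGORIES)
    if unknown:
        raise ParameterError(f"unknown bulk categories: {sorted(unknown)}")
    if any(v < 0 for v in cats.values()) or n_decoys < 0 or n_autosomal_controls < 0:
        raise ParameterError("category counts must be >= 0")

    rng = np.random.default_rng(seed)
    labels = (
        ["earlyXCI"] * cats.get("earlyXCI", 0)
        + ["lateXCI"] * cats.get("lateXCI", 0)
        + ["escapee"] * cats.get("escapee", 0)
        + ["decoy_nonbiallelic"] * n_decoys
    )
    labels = list(rng.permutation(labels))  # interleave along genomic position
    n_x = len(labels)
    x_genes = [f"xg{i + 1:04d}" for i in range(n_x)]
    a_genes = [f"ag{i + 1:04d}" for i in range(n_autosomal_controls)]

    # planted trajectories (reference, intermediate, final)
    triples = np.empty((n_x, 3))
    for i, label in enumerate(labels):
        if label == "escapee":
            base = rng.uniform(0.45, 0.50)
            triples[i] = (base, base, base)
        elif label == "earlyXCI":
            triples[i] = (0.50, 0.05, 0.05)
        elif label == "lateXCI":
            triples[i] = (0.50, 0.25, 0.05)
        else:  # decoy: skewed already in the reference stage
            low = rng.random() < 0.5
            value = rng.uniform(0.05, 0.22) if low else rng.uniform(0.78, 0.95)
            triples[i] = (value, value, value)

    stage_ratio = np.empty((n_x, len(stages)))
    for j, stage in enumerate(stages):
        if j < 3:
            stage_ratio[:, j] = triples[:, j]
        elif stage in set(biallelic_stages):
            stage_ratio[:, j] = triples[:, 0]
        else:
            stage_ratio[:, j] = triples[:, 2]

    units = [f"{stage}_rep{k + 1}" for stage in stages for k in range(replicates_per_stage)]
    unit_stage = np.repeat(np.arange(len(stages)), replicates_per_stage)

    genes = x_genes + a_genes
    n_genes = len(genes)
    ratio_matrix = np.full((n_genes, len(units)), 0.5)
    ratio_matrix[:n_x] = stage_ratio[:, unit_stage]

    depth = _draw_depth(rng, depth_mean, nb_dispersion, (n_genes, len(units)))
    a1 = beta_binomial(rng, depth, ratio_matrix, bb_overdispersion)
    a2 = depth - a1
    totals = depth + rng.poisson(depth)  # non-allelic reads on top of SNP-covered ones

    gene_index = pd.Index(genes, name="gene_id")
    unit_index = pd.Index(units, name="unit_id")
    matrix = AllelicCountMatrix(
        counts_a1=pd.DataFrame(a1, index=gene_index, columns=unit_index),
        counts_a2=pd.DataFrame(a2, index=gene_index, columns=unit_index),
        counts_total=pd.DataFrame(totals, index=gene_index, columns=unit_index),
        unit_meta=pd.DataFrame(
            {"stage": [stages[s] for s in unit_stage]}, index=unit_index
        ),
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": [x_chromosome] * n_x + [control_chromosome] * len(a_genes),
                "start": np.concatenate(
                    [_spread_positions(rng, n_x), _spread_positions(rng, len(a_genes))]
                ),
                "end": np.concatenate(
                    [_spread_positions(rng, n_x) + 1000,
                     _spread_positions(rng, len(a_genes)) + 1000]
                ),
                "is_patch": False,
            },
            index=gene_index,
        )
    )
    gene_truth = pd.DataFrame(
        {"category": labels + ["autosomal_control"] * len(a_genes)}, index=gene_index
    )
    for j, stage in enumerate(stages):
        col = np.full(n_genes, 0.5)
        col[:n_x] = stage_ratio[:, j]
        gene_truth[f"ratio_{stage}"] = col
    truth = SyntheticTruth(
        gene_truth=gene_truth,
        cell_truth=None,
        params={
            "mode": "bulk",
            "n_per_category": cats,
            "n_decoys": n_decoys,
            "n_autosomal_controls": n_autosomal_controls,
            "stages": list(stages),
            "replicates_per_stage": replicates_per_stage,
            "depth_mean": depth_mean,
            "nb_dispersion": nb_dispersion,
            "bb_overdispersion": bb_overdispersion,
            "seed": seed,
        },
    )
    return matrix, annotation, truth


# --------------------------------------------------------------------- #
# in vitro single-cell generator
# --------------------------------------------------------------------- #
def _xcr_trajectory(rng: np.random.Generator, category: str) -> dict[str, float]:
    """Planted ratios: bulk PGCLC starting point plus per-macro-group values."""
    if category == "escapee":
        base = rng.uniform(0.45, 0.50)
        return {"PGCLC_neg": base, "premeiotic": base, "meiotic": base, "mitotic": base}
    if category == "earlyXCR":
        return {"PGCLC_neg": 0.05, "premeiotic": 0.45, "meiotic": 0.48, "mitotic": 0.50}
    if category == "lateXCR":
        return {"PGCLC_neg": 0.05, "premeiotic": 0.08, "meiotic": 0.45, "mitotic": 0.50}
    if category == "noXCR":
        return {"PGCLC_neg": 0.05, "premeiotic": 0.05, "meiotic": 0.05, "mitotic": 0.05}
    raise ParameterError(f"unknown reactivation category {category!r}")


def generate_sc(
    n_cells_per_cluster: Optional[Mapping[str, int]] = None,
    n_per_xcr_category: Optional[Mapping[str, int]] = None,
    depth_mean: float = 5000.0,
    nb_dispersion: float = 0.01,
    bb_overdispersion: float = 0.01,
    frac_qc_fail: float = 0.0,
    n_somatic: int = 0,
    seed: int = 0,
    qc_profile: str = "invitro_sc",
    n_background_genes: int = 6000,
    cell_molecules_mean: float = 30_000.0,
    marker_gene: str = "Dazl",
    x_chromosome: str = "chrX",
) -> tuple[AllelicCountMatrix, GeneAnnotation, SyntheticTruth]:
    """Single germ cells across maturation clusters with planted reactivation.

    Allelic layers cover the X-linked genes; the totals layer additionally
    carries autosomal background genes, a mitochondrial block and a germ-cell
    marker so that the non-allelic QC, normalisation and marker-subsetting
    steps are exercised. ``frac_qc_fail`` of the germ cells (rounded, chosen
    deterministically from the seed) are constructed to violate the allelic
    QC gates, cycling through three failure modes: too few allelic reads,
    fewer than the minimum allelically expressed genes, and a near-complete
    single-genotype skew (skipped for profiles without a genotype gate).
    ``n_somatic`` marker-negative contaminant cells are appended.
    """
    _check_rho(bb_overdispersion)
    _check_depth(depth_mean)
    if not 0.0 <= frac_qc_fail <= 1.0:
        raise ParameterError("frac_qc_fail must be in [0, 1]")
    profile = QC_PROFILES[qc_profile]
    cells_per_cluster = dict(
        DEFAULT_SC_CELLS if n_cells_per_cluster is None else n_cells_per_cluster
    )
    unmappable = [c for c in cells_per_cluster if c not in CLUSTER_MACRO]
    if unmappable:
        raise ParameterError(
            f"clusters without reactivation trajectories: {unmappable}; "
            f"known clusters: {list(SC_CLUSTERS)}"
        )
    cats = dict(
        DEFAULT_XCR_CATEGORIES if n_per_xcr_category is None else n_per_xcr_category
    )
    unknown = set(cats) - set(DEFAULT_XCR_CATEGORIES)
    if unknown:
        raise ParameterError(f"unknown reactivation categories: {sorted(unknown)}")
    if any(v < 0 for v in cats.values()):
        raise ParameterError("category counts must be >= 0")

    rng = np.random.default_rng(seed)

    n_x_total = sum(cats.values())
    if 0 < n_x_total < profile.min_allelic_genes:
        import warnings

        warnings.warn(
            f"only {n_x_total} X-linked genes requested but the "
            f"{profile.name} profile requires >= {profile.min_allelic_genes} "
            "allelically expressed genes per cell; every cell will fail QC",
            stacklevel=2,
        )

    # ---- genes and planted trajectories
    labels = [cat for cat in DEFAULT_XCR_CATEGORIES for _ in range(cats.get(cat, 0))]
    labels = list(rng.permutation(labels))
    n_x = len(labels)
    x_genes = [f"xg{i + 1:04d}" for i in range(n_x)]
    traj = pd.DataFrame([_xcr_trajectory(rng, lab) for lab in labels],
                        index=pd.Index(x_genes, name="gene_id"))
    gene_weights = rng.gamma(2.0, 1.0, n_x)
    gene_weights /= gene_weights.sum()

    # ---- cells
    cell_rows = []
    for cluster in cells_per_cluster:
        for k in range(cells_per_cluster[cluster]):
            cell_rows.append((f"{cluster}_c{k + 1:03d}", cluster))
    n_germ = len(cell_rows)
    n_fail = int(round(frac_qc_fail * n_germ))
    fail_idx = set(rng.choice(n_germ, size=n_fail, replace=False).tolist())
    fail_modes = ["low_reads", "few_genes"]
    if profile.min_minor_genotype_fraction is not None:
        fail_modes.append("genotype_skew")
    for j in range(n_somatic):
        cell_rows.append((f"Somatic_c{j + 1:03d}", "Somatic"))

    n_cells = len(cell_rows)
    a1 = np.zeros((n_x, n_cells), dtype=np.int64)
    a2 = np.zeros((n_x, n_cells), dtype=np.int64)
    cell_meta = []
    few_gene_weights = np.zeros(n_x)
    k_few = min(10, n_x)
    few_gene_weights[:k_few] = gene_weights[:k_few]
    few_gene_weights /= few_gene_weights.sum()

    fail_counter = 0
    for idx, (cell_id, cluster) in enumerate(cell_rows):
        somatic = cluster == "Somatic"
        mode = None
        if idx in fail_idx:
            mode = fail_modes[fail_counter % len(fail_modes)]
            fail_counter += 1
        if somatic:
            ratios = np.full(n_x, 0.5)
        else:
            ratios = traj[CLUSTER_MACRO[cluster]].to_numpy()
        if mode == "low_reads":
            depth = int(rng.integers(50, min(1500, profile.min_allelic_reads)))
            weights = gene_weights
        elif mode == "few_genes":
            depth = _truncated_depth(rng, depth_mean, nb_dispersion,
                                     profile.min_allelic_reads)
            weights = few_gene_weights
        else:
            depth = _truncated_depth(rng, depth_mean, nb_dispersion,
                                     profile.min_allelic_reads)
            weights = gene_weights
        per_gene = rng.multinomial(depth, weights)
        if mode == "genotype_skew":
            gene_a1 = per_gene  # essentially all reads from one genotype
        else:
            gene_a1 = beta_binomial(rng, per_gene, ratios, bb_overdispersion)
        a1[:, idx] = gene_a1
        a2[:, idx] = per_gene - gene_a1
        expected_avg = float(ratios.mean()) if not somatic else 0.5
        cell_meta.append(
            {
                "cell_id": cell_id,
                "cluster": cluster,
                "qc_should_fail": mode is not None,
                "fail_mode": mode or "",
                "is_somatic": somatic,
                "expected_avg_ratio": expected_avg,
            }
        )

    # ---- totals layer: background + mito + marker + X genes
    from .config import PLURIPOTENCY_GENES

    bg_genes = [f"bg{i + 1:05d}" for i in range(n_background_genes)]
    mito_genes = [f"mt-Gene{i + 1}" for i in range(10)]
    pluri_genes = list(PLURIPOTENCY_GENES)
    bg_w = rng.gamma(2.0, 1.0, n_background_genes)
    bg_w = bg_w / bg_w.sum() * 0.965
    mito_w = np.full(10, 0.022 / 10)
    pluri_w = np.full(len(pluri_genes), 0.008 / len(pluri_genes))
    marker_w = 0.005
    nonallelic_genes = bg_genes + mito_genes + pluri_genes + [marker_gene]
    germ_weights = np.concatenate([bg_w, mito_w, pluri_w, [marker_w]])
    somatic_weights = np.concatenate([bg_w, mito_w, pluri_w, [0.0]])
    somatic_weights /= somatic_weights.sum()

    totals_nonallelic = np.zeros((len(nonallelic_genes), n_cells), dtype=np.int64)
    for idx, (cell_id, cluster) in enumerate(cell_rows):
        molecules = _truncated_depth(rng, cell_molecules_mean, 0.05,
                                     profile.min_molecules)
        weights = somatic_weights if cluster == "Somatic" else germ_weights
        totals_nonallelic[:, idx] = rng.multinomial(molecules, weights)
    allelic_totals = a1 + a2
    totals_x = allelic_totals + rng.poisson(allelic_totals)

    cell_index = pd.Index([c for c, _ in cell_rows], name="cell_id")
    gene_index = pd.Index(x_genes, name="gene_id")
    totals = pd.DataFrame(
        np.vstack([totals_x, totals_nonallelic]),
        index=pd.Index(x_genes + nonallelic_genes, name="gene_id"),
        columns=cell_index,
    )
    matrix = AllelicCountMatrix(
        counts_a1=pd.DataFrame(a1, index=gene_index, columns=cell_index),
        counts_a2=pd.DataFrame(a2, index=gene_index, columns=cell_index),
        counts_total=totals,
        unit_meta=pd.DataFrame(
            {"cluster": [cl for _, cl in cell_rows]}, index=cell_index
        ),
    )
    ann_index = pd.Index(x_genes + nonallelic_genes, name="gene_id")
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": [x_chromosome] * n_x
                + ["chr1"] * n_background_genes
                + ["chrM"] * 10
                + ["chr3"] * len(pluri_genes)
                + ["chr17"],
                "start": np.concatenate(
                    [
                        _spread_positions(rng, n_x),
                        _spread_positions(rng, n_background_genes),
                        _spread_positions(rng, 10),
                        _spread_positions(rng, len(pluri_genes)),
                        [10_000],
                    ]
                ),
                "end": np.concatenate(
                    [
                        _spread_positions(rng, n_x) + 1000,
                        _spread_positions(rng, n_background_genes) + 1000,
                        _spread_positions(rng, 10) + 1000,
                        _spread_positions(rng, len(pluri_genes)) + 1000,
                        [11_000],
                    ]
                ),
                "is_patch": False,
            },
            index=ann_index,
        )
    )
    gene_truth = pd.DataFrame({"category": labels}, index=gene_index)
    for col in ("PGCLC_neg", "premeiotic", "meiotic", "mitotic"):
        gene_truth[f"ratio_{col}"] = traj[col].to_numpy()
    cell_truth = pd.DataFrame(cell_meta).set_index("cell_id")
    truth = SyntheticTruth(
        gene_truth=gene_truth,
        cell_truth=cell_truth,
        params={
            "mode": "sc",
            "n_cells_per_cluster": cells_per_cluster,
            "n_per_xcr_category": cats,
            "depth_mean": depth_mean,
            "nb_dispersion": nb_dispersion,
            "bb_overdispersion": bb_overdispersion,
            "frac_qc_fail": frac_qc_fail,
            "n_somatic": n_somatic,
            "qc_profile": qc_profile,
            "seed": seed,
        },
    )
    return matrix, annotation, truth


# --------------------------------------------------------------------- #
# E6.5 in vivo generator
# --------------------------------------------------------------------- #
def _per_cluster(value, clusters: Sequence[str], default_map: Mapping[str, float],
                 name: str) -> dict[str, float]:
    if value is None:
        out = {c: default_map.get(c, 0.0) for c in clusters}
    elif isinstance(value, Mapping):
        out = {c: float(value.get(c, default_map.get(c, 0.0))) for c in clusters}
    else:
        out = {c: float(value) for c in clusters}
    bad = {c: v for c, v in out.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ParameterError(f"{name} fractions outside [0, 1]: {bad}")
    return out


def generate_e65(
    n_cells_per_cluster: Optional[Mapping[str, int]] = None,
    epiblast_xaxa_fraction=None,
    escapee_fraction_xaxi=None,
    depth_mean: float = 5000.0,
    nb_dispersion: float = 0.01,
    bb_overdispersion: float = 0.01,
    n_x_genes: int = 120,
    seed: int = 0,
    extraembryonic_clusters: Sequence[str] = E65_EXTRAEMBRYONIC,
    x_chromosome: str = "chrX",
) -> tuple[AllelicCountMatrix, GeneAnnotation, SyntheticTruth]:
    """E6.5 embryo cells with imprinted vs random X inactivation.

    Allele 1 plays the paternal (C57-like) allele: extraembryonic clusters
    silence it in every cell (imprinted XCI); epiblast clusters plant
    round(f * n) XaXa cells per cluster and split the remainder evenly
    between the two silencing orientations (random XCI). Within silenced
    cells a per-cluster planted fraction of genes escapes, expressing the
    inactive allele above the silencing cut-off. No totals layer is emitted;
    the analysis starts at the allelic QC gates.
    """
    _check_rho(bb_overdispersion)
    _check_depth(depth_mean)
    cells_per_cluster = dict(
        DEFAULT_E65_CELLS if n_cells_per_cluster is None else n_cells_per_cluster
    )
    clusters = list(cells_per_cluster)
    xaxa_frac = _per_cluster(
        epiblast_xaxa_fraction, clusters, DEFAULT_E65_XAXA, "epiblast_xaxa_fraction"
    )
    escape_frac = _per_cluster(
        escapee_fraction_xaxi, clusters, DEFAULT_E65_ESCAPE, "escapee_fraction_xaxi"
    )
    profile = QC_PROFILES["e65_sc"]
    rng = np.random.default_rng(seed)

    x_genes = [f"xg{i + 1:04d}" for i in range(n_x_genes)]
    gene_weights = rng.gamma(2.0, 1.0, n_x_genes)
    gene_weights /= gene_weights.sum()

    escapee_sets: dict[str, list[str]] = {}
    for cluster in clusters:
        k = int(round(escape_frac[cluster] * n_x_genes))
        chosen = rng.choice(n_x_genes, size=k, replace=False)
        escapee_sets[cluster] = sorted(x_genes[i] for i in chosen)

    cell_rows: list[dict] = []
    for cluster in clusters:
        n = cells_per_cluster[cluster]
        if cluster in set(extraembryonic_clusters):
            statuses = ["XaXi"] * n  # paternal allele 1 always silenced
        else:
            n_xaxa = int(round(xaxa_frac[cluster] * n))
            n_sil = n - n_xaxa
            n_a1 = n_sil // 2 + int(n_sil % 2 and rng.random() < 0.5)
            statuses = ["XaXa"] * n_xaxa + ["XaXi"] * n_a1 + ["XiXa"] * (n_sil - n_a1)
            rng.shuffle(statuses)
        for k, status in enumerate(statuses):
            cell_rows.append(
                {"cell_id": f"{cluster}_c{k + 1:03d}", "cluster": cluster,
                 "x_status": status}
            )

    n_cells = len(cell_rows)
    a1 = np.zeros((n_x_genes, n_cells), dtype=np.int64)
    a2 = np.zeros((n_x_genes, n_cells), dtype=np.int64)
    escape_mask = {
        cluster: np.isin(np.array(x_genes), escapee_sets[cluster])
        for cluster in clusters
    }
    for idx, row in enumerate(cell_rows):
        cluster, status = row["cluster"], row["x_status"]
        if status == "XaXa":
            ratios = np.full(n_x_genes, 0.5)
        elif status == "XaXi":  # allele 1 inactive
            ratios = np.where(escape_mask[cluster], 0.30, 0.02)
        else:  # XiXa: allele 2 inactive
            ratios = np.where(escape_mask[cluster], 0.70, 0.98)
        depth = _truncated_depth(rng, depth_mean, nb_dispersion,
                                 profile.min_allelic_reads)
        per_gene = rng.multinomial(depth, gene_weights)
        gene_a1 = beta_binomial(rng, per_gene, ratios, bb_overdispersion)
        a1[:, idx] = gene_a1
        a2[:, idx] = per_gene - gene_a1

    cell_index = pd.Index([r["cell_id"] for r in cell_rows], name="cell_id")
    gene_index = pd.Index(x_genes, name="gene_id")
    matrix = AllelicCountMatrix(
        counts_a1=pd.DataFrame(a1, index=gene_index, columns=cell_index),
        counts_a2=pd.DataFrame(a2, index=gene_index, columns=cell_index),
        counts_total=None,
        unit_meta=pd.DataFrame(
            {"cluster": [r["cluster"] for r in cell_rows]}, index=cell_index
        ),
    )
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": x_chromosome,
                "start": _spread_positions(rng, n_x_genes),
                "end": _spread_positions(rng, n_x_genes) + 1000,
                "is_patch": False,
            },
            index=gene_index,
        )
    )
    gene_truth = pd.DataFrame({"category": "x_linked"}, index=gene_index)
    for cluster in clusters:
        gene_truth[f"escapee_in_{cluster}"] = escape_mask[cluster]
    cell_truth = pd.DataFrame(cell_rows).set_index("cell_id")
    cell_truth["qc_should_fail"] = False
    truth = SyntheticTruth(
        gene_truth=gene_truth,
        cell_truth=cell_truth,
        params={
            "mode": "e65",
            "n_cells_per_cluster": cells_per_cluster,
            "epiblast_xaxa_fraction": xaxa_frac,
            "escapee_fraction_xaxi": escape_frac,
            "extraembryonic_clusters": list(extraembryonic_clusters),
            "escapee_genes": escapee_sets,
            "depth_mean": depth_mean,
            "nb_dispersion": nb_dispersion,
            "bb_overdispersion": bb_overdispersion,
            "n_x_genes": n_x_genes,
            "seed": seed,
        },
    )
    return matrix, annotation, truth
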