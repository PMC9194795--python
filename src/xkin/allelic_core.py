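"""Core allelic statistic and classifiers.

The pipeline's central quantity is the allelic ratio r = a1 / (a1 + a2),
the fraction of allele-resolved reads assigned to allele 1 — by convention
the allele subject to (forced or imprinted) inactivation, so silencing
drives r towards 0 and the X-inactivation cut-off (default 0.135) is a
lower bound. A gene is classified by where its ratio trajectory crosses
that cut-off:

* bulk silencing (XCI): reference -> intermediate -> final stage, with
  genes outside the open biallelic reference window excluded first;
* single-cell reactivation (XCR): PGCLC-like -> pre-meiotic -> meiotic
  pooled groups.

The cut-off itself can be re-estimated from a reference ratio distribution
(e.g. fully inactivated neural progenitors) as the lowest-density local
minimum of a Gaussian KDE between its two dominant modes.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .containers import AllelicCountMatrix, AllelicRatioTable
from .exceptions import InsufficientDataError, ValidationError

XCI_CATEGORIES = ("earlyXCI", "lateXCI", "escapee", "excluded_nonbiallelic", "undetected")
XCR_CATEGORIES = ("escapee", "earlyXCR", "lateXCR", "noXCR", "unclassified")


# --------------------------------------------------------------------- #
def allelic_ratio(a1, a2, min_support: int = 10):
    """Allelic ratio a1 / (a1 + a2), NaN below the support threshold.

    Accepts scalars or arrays; negative counts raise a validation error.
    """
    a1_arr = np.asarray(a1, dtype=float)
    a2_arr = np.asarray(a2, dtype=float)
    if (a1_arr < 0).any() or (a2_arr < 0).any():
        raise ValidationError("allelic counts must be non-negative")
    total = a1_arr + a2_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total >= min_support, a1_arr / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(a1) and np.isscalar(a2):
        return float(ratio)
    return ratio


def pool_groups(
    matrix: AllelicCountMatrix,
    grouping: Mapping[str, str] | pd.Series,
    min_support: int = 10,
) -> AllelicRatioTable:
    """Sum allelic counts within unit groups, then compute per-gene ratios.

    Pooling sums raw counts before dividing (not an average of per-unit
    ratios), so low-coverage units contribute proportionally to their reads.
    Every unit must be mapped to exactly one group.
    """
    groups = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    missing = matrix.unit_ids.difference(groups.index)
    if len(missing):
        raise ValidationError(f"units missing from grouping: {list(missing)}")
    groups = groups.loc[matrix.unit_ids]
    # deterministic group order: first appearance in unit order
    order = groups.drop_duplicates().tolist()
    a1 = matrix.counts_a1.T.groupby(groups).sum().T[order]
    a2 = matrix.counts_a2.T.groupby(groups).sum().T[order]
    support = a1 + a2
    ratio = pd.DataFrame(
        allelic_ratio(a1.to_numpy(), a2.to_numpy(), min_support=min_support),
        index=a1.index,
        columns=a1.columns,
    )
    return AllelicRatioTable(ratio=ratio, support=support, min_support=min_support)


# --------------------------------------------------------------------- #
def estimate_xci_threshold(
    reference_ratios: Iterable[float],
    bandwidth: str | float = "silverman",
    grid_step: float = 0.001,
    default: float = 0.135,
    min_valley_depth: float = 0.1,
) -> float:
    """Estimate the silencing cut-off from a reference ratio distribution.

    Fits a Gaussian KDE on [0, 1] and returns the grid location of the
    lowest-density local minimum strictly between the two largest density
    modes. The valley must be prominent — its density at most
    ``1 - min_valley_depth`` times the lower of the two mode densities —
    otherwise the sample is treated as effectively unimodal (finite-sample
    KDEs of unimodal data carry shallow noise wiggles) and the configured
    ``default`` is returned with a warning.

    Requires at least 30 finite ratios in [0, 1].
    """
    ratios = np.asarray(list(reference_ratios), dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ((ratios < 0) | (ratios > 1)).any():
        raise ValidationError("reference ratios must lie in [0, 1]")
    if ratios.size < 30:
        raise InsufficientDataError(
            f"need >= 30 finite reference ratios, got {ratios.size}"
        )
    kde = gaussian_kde(ratios, bw_method=bandwidth)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    density = kde(grid)
    interior = np.arange(1, len(grid) - 1)
    maxima = interior[
        (density[interior] > density[interior - 1])
        & (density[interior] >= density[interior + 1])
    ].tolist()
    # edges can host a mode when density falls away from them
    if density[0] > density[1]:
        maxima.insert(0, 0)
    if density[-1] > density[-2]:
        maxima.append(len(grid) - 1)
    minima = interior[
        (density[interior] < density[interior - 1])
        & (density[interior] <= density[interior + 1])
    ]
    if len(maxima) < 2:
        warnings.warn(
            "reference distribution is unimodal; falling back to the default "
            f"threshold {default}",
            stacklevel=2,
        )
        return default
    top_two = sorted(sorted(maxima, key=lambda i: density[i], reverse=True)[:2])
    lo, hi = top_two
    between = minima[(minima > lo) & (minima < hi)]
    if len(between) == 0:
        warnings.warn(
            "no interior density minimum between the two dominant modes "
            f"(effectively unimodal); falling back to the default {default}",
            stacklevel=2,
        )
        return default
    best = between[np.argmin(density[between])]
    if density[best] > (1.0 - min_valley_depth) * min(density[lo], density[hi]):
        warnings.warn(
            "density valley between the two modes is too shallow (effectively "
            f"unimodal); falling back to the default threshold {default}",
            stacklevel=2,
        )
        return default
    return float(grid[best])


# --------------------------------------------------------------------- #
def _is_inactive(ratio: float, threshold: float, inactive_side: str) -> bool:
    # ties at the threshold count as inactive (ratio <= threshold is silent)
    if inactive_side == "low":
        return ratio <= threshold
    return ratio >= 1.0 - threshold


def classify_xci(
    reference: float,
    intermediate: float,
    final: float,
    threshold: float = 0.135,
    biallelic_window: tuple[float, float] = (0.3, 0.7),
    inactive_side: str = "low",
) -> str:
    """Classify one gene's silencing trajectory.

    Stages are ordered (reference/ESC-like, intermediate/EpiLC-like,
    final/PGCLC-like). Genes whose reference ratio falls outside the *open*
    biallelic window are excluded before kinetics are considered; any
    required stage without a ratio yields ``undetected``.

    ``inactive_side="high"`` mirrors the logic onto 1 - r for swapped
    allele orientations.
    """
    if inactive_side not in ("low", "high"):
        raise ValidationError(f"inactive_side must be 'low' or 'high', got {inactive_side!r}")
    if reference is None or not np.isfinite(reference):
        return "undetected"
    lo, hi = biallelic_window
    if not (lo < reference < hi):
        return "excluded_nonbiallelic"
    if (
        intermediate is None
        or final is None
        or not np.isfinite(intermediate)
        or not np.isfinite(final)
    ):
        return "undetected"
    if _is_inactive(intermediate, threshold, inactive_side):
        return "earlyXCI"
    if _is_inactive(final, threshold, inactive_side):
        return "lateXCI"
    return "escapee"


def classify_xcr(
    pgclc: float,
    premeiotic: float,
    meiotic: float,
    threshold: float = 0.135,
    inactive_side: str = "low",
) -> str:
    """Classify one gene's reactivation trajectory.

    Groups are ordered (PGCLC-like, pre-meiotic, meiotic). A gene active at
    every group is an escapee; one silent in PGCLCs that turns active in
    pre-meiotic cells reactivates early; one that turns active only in
    meiotic cells reactivates late; one still silent in meiosis has not
    reactivated. Non-monotone trajectories that none of these rules cover,
    or any undetected group, yield ``unclassified``.
    """
    if inactive_side not in ("low", "high"):
        raise ValidationError(f"inactive_side must be 'low' or 'high', got {inactive_side!r}")
    values = (pgclc, premeiotic, meiotic)
    if any(v is None or not np.isfinite(v) for v in values):
        return "unclassified"
    silent = [_is_inactive(v, threshold, inactive_side) for v in values]
    if not any(silent):
        return "escapee"
    if silent[0] and not silent[1]:
        return "earlyXCR"
    if silent[0] and silent[1] and not silent[2]:
        return "lateXCR"
    if silent[2]:
        return "noXCR"
    return "unclassified"


def classify_xci_frame(
    trajectories: pd.DataFrame,
    stages: Sequence[str],
    threshold: float = 0.135,
    biallelic_window: tuple[float, float] = (0.3, 0.7),
    inactive_side: str = "low",
) -> pd.Series:
    """Apply :func:`classify_xci` to each row of a gene x stage ratio frame."""
    if len(stages) != 3:
        raise ValidationError("classify_xci_frame needs exactly three ordered stages")
    missing = [s for s in stages if s not in trajectories.columns]
    if missing:
        raise ValidationError(f"missing stages in ratio table: {missing}")
    ref, mid, fin = (trajectories[s] for s in stages)
    return pd.Series(
        [
            classify_xci(r, m, f, threshold, biallelic_window, inactive_side)
            for r, m, f in zip(ref, mid, fin)
        ],
        index=trajectories.index,
        name="category",
    )


def classify_xcr_frame(
    trajectories: pd.DataFrame,
    groups: Sequence[str],
    threshold: float = 0.135,
    inactive_side: str = "low",
) -> pd.Series:
    """Apply :func:`classify_xcr` to each row of a gene x group ratio frame."""
    if len(groups) != 3:
        raise ValidationError("classify_xcr_frame needs exactly three ordered groups")
    missing = [g for g in groups if g not in trajectories.columns]
    if missing:
        raise ValidationError(f"missing groups in ratio table: {missing}")
    cols = [trajectories[g] for g in groups]
    return pd.Series(
        [
            classify_xcr(p, pre, mei, threshold, inactive_side)
            for p, pre, mei in zip(*cols)
        ],
        index=trajectories.index,
        name="category",
    )
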