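"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def grid_minimum_oracle(sample, grid_step=0.001, bandwidth="silverman", default=0.135):
    """Loop-based search for the KDE density minimum between the two top modes."""
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(np.asarray(sample, dtype=float), bw_method=bandwidth)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    d = kde(grid)
    maxima = []
    for i in range(1, len(grid) - 1):
        if d[i] > d[i - 1] and d[i] >= d[i + 1]:
            maxima.append(i)
    if d[0] > d[1]:
        maxima.insert(0, 0)
    if d[-1] > d[-2]:
        maxima.append(len(grid) - 1)
    if len(maxima) < 2:
        return default
    maxima.sort(key=lambda i: d[i], reverse=True)
    lo, hi = sorted(maxima[:2])
    best, best_density = None, np.inf
    for i in range(lo + 1, hi):
        if d[i] < d[i - 1] and d[i] <= d[i + 1] and d[i] < best_density:
            best, best_density = i, d[i]
    if best is None:
        return default
    if best_density > 0.9 * min(d[lo], d[hi]):  # shallow valley: unimodal
        return default
    return float(grid[best])
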