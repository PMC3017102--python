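"""Independent from-scratch reference implementations used as test oracles.

Everything here is deliberately naive: explicit loops, scipy.stats.pearsonr,
full recomputation at every step. These functions share no code path with
the package's incremental engines.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def naive_pairwise_correlation(
    values: np.ndarray, min_overlap: int = 3
) -> np.ndarray:
    """Pairwise-complete Pearson correlation between columns, loop by loop."""
    n_series, n_regions = values.shape
    out = np.full((n_regions, n_regions), np.nan)
    for i in range(n_regions):
        out[i, i] = 1.0
        for j in range(i + 1, n_regions):
            ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            if ok.sum() < min_overlap:
                continue
            a, b = values[ok, i], values[ok, j]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            out[i, j] = out[j, i] = stats.pearsonr(a, b)[0]
    return out


def naive_mantel_r(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of upper triangles, masking missing pairs."""
    n = A.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(A[i, j]) and np.isfinite(B[i, j]):
                xs.append(A[i, j])
                ys.append(B[i, j])
    return stats.pearsonr(xs, ys)[0]


def pandas_backward_eliminate(
    values: np.ndarray,
    series_ids: list[str],
    target: np.ndarray,
    k_min: int = 3,
    min_overlap: int = 3,
):
    """From-scratch greedy elimination using pandas' pairwise-complete corr.

    Same contract as :func:`naive_backward_eliminate` but fast enough for
    larger instances; still fully independent of the package's incremental
    engine (pandas .corr + scipy pearsonr).
    """
    import pandas as pd

    n_regions = target.shape[0]
    iu, ju = np.triu_indices(n_regions, k=1)
    tvec = target[iu, ju]

    def mantel_r_of(idx: list[int]) -> float:
        corr = pd.DataFrame(values[idx]).corr(min_periods=min_overlap).to_numpy()
        a = corr[iu, ju]
        ok = np.isfinite(a) & np.isfinite(tvec)
        return stats.pearsonr(a[ok], tvec[ok])[0]

    active = list(range(len(series_ids)))
    trajectory = [mantel_r_of(active)]
    removal_order: list[str] = []
    while len(active) > k_min:
        best_id, best_r, best_pos = None, -np.inf, None
        for pos in sorted(active, key=lambda k: series_ids[k]):
            rest = [k for k in active if k != pos]
            r = mantel_r_of(rest)
            if np.isfinite(r) and r > best_r:
                best_id, best_r, best_pos = series_ids[pos], r, pos
        active.remove(best_pos)
        removal_order.append(best_id)
        trajectory.append(best_r)
    return removal_order, np.asarray(trajectory)


def naive_backward_eliminate(
    values: np.ndarray,
    series_ids: list[str],
    target: np.ndarray,
    k_min: int = 3,
    min_overlap: int = 3,
):
    """Full-recomputation greedy backward elimination.

    Returns (removal_order, trajectory) with trajectory[0] the initial Mantel
    r. At every iteration each candidate's post-removal r is recomputed from
    scratch; the candidate with the highest r is removed, ties broken by
    lexicographically smallest series id.
    """

    def mantel_r_of(idx: list[int]) -> float:
        corr = naive_pairwise_correlation(values[idx], min_overlap)
        return naive_mantel_r(corr, target)

    active = list(range(len(series_ids)))
    trajectory = [mantel_r_of(active)]
    removal_order: list[str] = []
    while len(active) > k_min:
        best_id, best_r, best_pos = None, -np.inf, None
        for pos in sorted(active, key=lambda k: series_ids[k]):
            rest = [k for k in active if k != pos]
            r = mantel_r_of(rest)
            if np.isfinite(r) and r > best_r:
                best_id, best_r, best_pos = series_ids[pos], r, pos
        active.remove(best_pos)
        removal_order.append(best_id)
        trajectory.append(best_r)
    return removal_order, np.asarray(trajectory)
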