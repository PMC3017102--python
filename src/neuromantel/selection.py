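"""Greedy backward elimination of image series against a Mantel objective.

The optimizer looks for the subset of image series (gene measurements) whose
region-pair expression correlations best match a fixed target matrix —
typically the proximity-controlled (residualized) connectivity-profile
correlation. Exhaustive subset search is infeasible, so each iteration ranks
every active series by its leave-one-out contribution to the Mantel r and
removes the least informative one (the series whose removal *increases* the
correlation the most), repeating until only ``k_min`` series remain. The
series still active when the trajectory peaks form the optimized ("peak")
set.

Recomputing a pairwise-complete correlation matrix from scratch for every
leave-one-out candidate would be quadratic in the number of series per
iteration; instead the engine maintains per-region-pair sufficient
statistics (complete-pair counts, sums, sums of squares and cross-products)
over the active series and *downdates* them for each candidate. Missing
cells are respected: a series contributes to a pair's statistics only where
both regions are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, StatisticError
from .harmonize import ExpressionMatrix
from .similarity import SimilarityMatrix, upper_triangle

__all__ = [
    "EliminationState",
    "EliminationTrace",
    "backward_eliminate",
    "contribution_ranking",
    "rank_series",
    "high_confidence_genes",
    "ranking_auroc",
    "shuffled_optimization_control",
    "ShuffledControlResult",
]


class EliminationState:
    """Sufficient statistics of the active series set, pair by region pair.

    For every region pair (i, j) the state tracks, over active series where
    both regions are observed: the count, the two value sums, the two sums of
    squares, and the cross-product sum. These six arrays suffice to rebuild
    every pairwise Pearson correlation, and removing a series is a vectorized
    subtraction.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        target: SimilarityMatrix,
        min_overlap: int = 3,
        resync_every: int = 32,
    ):
        if min_overlap < 3:
            raise ConfigurationError("min_overlap below 3 makes pair correlations degenerate")
        missing = [r for r in target.regions if r not in expr.regions]
        if missing:
            raise ConfigurationError(f"target regions missing from expression: {missing[:5]}")
        expr = expr.subset_regions(list(target.regions))
        self.series = list(expr.series)
        self.gene_of_series = dict(expr.gene_of_series)
        self.regions = list(target.regions)
        self.min_overlap = min_overlap
        self.resync_every = resync_every

        values = expr.values
        obs = np.isfinite(values)
        n_regions = len(self.regions)
        self._iu, self._ju = np.triu_indices(n_regions, k=1)
        tvec = upper_triangle(target).values
        self._tmask = np.isfinite(tvec)
        if self._tmask.sum() < 3:
            raise StatisticError("target has fewer than 3 defined pairs")
        self._t = np.where(self._tmask, tvec, 0.0)

        # per-series, per-pair contributions (y x P); zero where incomplete
        pair_obs = obs[:, self._iu] & obs[:, self._ju]
        zi = np.where(pair_obs, values[:, self._iu], 0.0)
        zj = np.where(pair_obs, values[:, self._ju], 0.0)
        self._c_n = pair_obs.astype(float)
        self._c_sx = zi
        self._c_sy = zj
        self._c_sxx = zi * zi
        self._c_syy = zj * zj
        self._c_sxy = zi * zj

        self.active = np.ones(len(self.series), dtype=bool)
        self._since_resync = 0
        self._recompute_totals()

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_series(self) -> list[str]:
        return [s for s, a in zip(self.series, self.active) if a]

    def _recompute_totals(self) -> None:
        act = self.active
        self._n = self._c_n[act].sum(axis=0)
        self._sx = self._c_sx[act].sum(axis=0)
        self._sy = self._c_sy[act].sum(axis=0)
        self._sxx = self._c_sxx[act].sum(axis=0)
        self._syy = self._c_syy[act].sum(axis=0)
        self._sxy = self._c_sxy[act].sum(axis=0)
        self._since_resync = 0

    def remove(self, idx: int) -> None:
        if not self.active[idx]:
            raise ConfigurationError(f"series {self.series[idx]!r} already removed")
        self.active[idx] = False
        self._n -= self._c_n[idx]
        self._sx -= self._c_sx[idx]
        self._sy -= self._c_sy[idx]
        self._sxx -= self._c_sxx[idx]
        self._syy -= self._c_syy[idx]
        self._sxy -= self._c_sxy[idx]
        self._since_resync += 1
        if self._since_resync >= self.resync_every:
            self._recompute_totals()  # bound floating-point drift

    # -- statistics --------------------------------------------------------
    def _pair_correlations(self, n, sx, sy, sxx, syy, sxy) -> np.ndarray:
        """Pairwise Pearson r from sufficient statistics; NaN where degenerate."""
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / n
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            r = cov / np.sqrt(vx * vy)
        bad = (n < self.min_overlap) | (vx <= 0) | (vy <= 0)
        return np.where(bad, np.nan, r)

    def _mantel_r(self, pair_r: np.ndarray) -> np.ndarray:
        """Pearson of pair correlations against the fixed target vector.

        Accepts a (P,) vector or a (k, P) matrix of candidate rows; invalid
        pairs (NaN correlation or undefined target) are excluded row-wise.
        Rows where the statistic is undefined come back NaN.
        """
        single = pair_r.ndim == 1
        R = np.atleast_2d(pair_r)
        valid = np.isfinite(R) & self._tmask
        n = valid.sum(axis=1)
        Rv = np.where(valid, R, 0.0)
        Tv = np.where(valid, self._t, 0.0)
        sr = Rv.sum(axis=1)
        st = Tv.sum(axis=1)
        srr = (Rv * Rv).sum(axis=1)
        stt = (Tv * Tv).sum(axis=1)
        srt = (Rv * Tv).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = srt - sr * st / n
            vr = srr - sr * sr / n
            vt = stt - st * st / n
            out = cov / np.sqrt(vr * vt)
        out = np.where((n < 3) | (vr <= 0) | (vt <= 0), np.nan, out)
        return out[0] if single else out

    def current_r(self) -> float:
        r = self._mantel_r(
            self._pair_correlations(self._n, self._sx, self._sy, self._sxx, self._syy, self._sxy)
        )
        if not np.isfinite(r):
            raise StatisticError("Mantel statistic undefined on the active set")
        return float(r)

    def leave_one_out_r(self) -> tuple[np.ndarray, np.ndarray]:
        """Mantel r after removing each active series in turn.

        Returns ``(candidate_indices, r_values)`` with candidates ordered by
        series id (the tie-break order). Undefined statistics come back NaN.
        """
        cand = np.flatnonzero(self.active)
        cand = cand[np.argsort(np.asarray(self.series, dtype=object)[cand])]
        n = self._n[None, :] - self._c_n[cand]
        sx = self._sx[None, :] - self._c_sx[cand]
        sy = self._sy[None, :] - self._c_sy[cand]
        sxx = self._sxx[None, :] - self._c_sxx[cand]
        syy = self._syy[None, :] - self._c_syy[cand]
        sxy = self._sxy[None, :] - self._c_sxy[cand]
        pair_r = self._pair_correlations(n, sx, sy, sxx, syy, sxy)
        return cand, self._mantel_r(pair_r)


@dataclass
class EliminationTrace:
    """Full record of one backward-elimination run.

    ``r_trajectory[0]`` is the Mantel r of the complete series set;
    ``r_trajectory[k]`` the value after the k-th removal. The peak set is the
    series still active at the global maximum of the trajectory (first
    occurrence on ties), and the terminal set the series never removed.
    """

    series_initial: list[str]
    removal_order: list[str]
    r_trajectory: np.ndarray
    gene_of_series: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.r_trajectory = np.asarray(self.r_trajectory, dtype=float)
        if self.r_trajectory.size != len(self.removal_order) + 1:
            raise ConfigurationError("trajectory length must be removals + 1")

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(self.r_trajectory))

    @property
    def peak_r(self) -> float:
        return float(self.r_trajectory[self.peak_index])

    @property
    def peak_set(self) -> list[str]:
        removed = set(self.removal_order[: self.peak_index])
        return [s for s in self.series_initial if s not in removed]

    @property
    def terminal_set(self) -> list[str]:
        removed = set(self.removal_order)
        return [s for s in self.series_initial if s not in removed]


def backward_eliminate(
    expr: ExpressionMatrix,
    target: SimilarityMatrix,
    k_min: int = 3,
    seed: int | None = None,
    min_overlap: int = 3,
    resync_every: int = 32,
) -> EliminationTrace:
    """Greedy backward elimination maximizing the Mantel r against ``target``.

    The target (typically a residual-kind connectivity correlation matrix) is
    fixed once, up front; expression correlations are recomputed for the
    shrinking active set each iteration. At every step the series whose
    removal yields the highest Mantel r is removed (ties broken by
    lexicographically smallest series id); elimination runs down to ``k_min``
    series. ``k_min`` must be at least 3 because pairwise Pearson
    correlations over fewer series are degenerate. The procedure is
    deterministic; ``seed`` is only recorded for provenance.
    """
    if k_min < 3:
        raise ConfigurationError("k_min must be at least 3")
    if expr.n_series <= k_min:
        raise ConfigurationError("need more than k_min series to eliminate")
    state = EliminationState(expr, target, min_overlap=min_overlap, resync_every=resync_every)
    trajectory = [state.current_r()]
    removal_order: list[str] = []
    while state.n_active > k_min:
        cand, r_loo = state.leave_one_out_r()
        scores = np.where(np.isfinite(r_loo), r_loo, -np.inf)
        best = int(np.argmax(scores))  # first max -> lexicographic tie-break
        if not np.isfinite(r_loo[best]):
            raise StatisticError("every leave-one-out statistic undefined")
        state.remove(int(cand[best]))
        removal_order.append(state.series[int(cand[best])])
        trajectory.append(float(r_loo[best]))
    return EliminationTrace(
        list(state.series), removal_order, np.asarray(trajectory),
        dict(state.gene_of_series), seed,
    )


def contribution_ranking(state: EliminationState) -> dict[str, float]:
    """Leave-one-out Mantel r for every active series (id -> r-without-it)."""
    cand, r_loo = state.leave_one_out_r()
    return {state.series[int(i)]: float(r) for i, r in zip(cand, r_loo)}


def rank_series(trace: EliminationTrace) -> list[tuple[str, int]]:
    """Rank all series by contribution: terminal survivors tie at rank 1,
    then removed series in reverse removal order."""
    out = [(s, 1) for s in sorted(trace.terminal_set)]
    rank = len(trace.terminal_set) + 1
    for s in reversed(trace.removal_order):
        out.append((s, rank))
        rank += 1
    return out


def high_confidence_genes(peak_set: list[str], gene_of_series: dict[str, str]) -> set[str]:
    """Genes with two or more independent image series inside the peak set.

    Concordance across independent probes/section planes makes an expression
    artifact an unlikely explanation for a gene's high rank.
    """
    counts: dict[str, int] = {}
    for s in peak_set:
        g = gene_of_series[s]
        counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= 2}


def ranking_auroc(ranking: list[tuple[str, int]], positives: set[str]) -> float:
    """AUROC that ``positives`` receive better (smaller) ranks than the rest.

    Tied ranks (the terminal set) are handled with mid-ranks, so this equals
    the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    ids = [s for s, _ in ranking]
    scores = -np.asarray([r for _, r in ranking], dtype=float)  # higher = better
    is_pos = np.asarray([s in positives for s in ids])
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticError("AUROC needs both positive and negative series")
    ranks = rankdata(scores)  # ascending mid-ranks
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class ShuffledControlResult:
    """Peak correlations from elimination runs on label-shuffled expression."""

    peaks: list[float]
    seed: int | None

    @property
    def max_peak(self) -> float:
        return float(max(self.peaks))


def shuffled_optimization_control(
    expr: ExpressionMatrix,
    target: SimilarityMatrix,
    k_runs: int = 10,
    seed: int | None = None,
    permutations: list[np.ndarray] | None = None,
    **eliminate_kwargs,
) -> ShuffledControlResult:
    """Null reference for optimized Mantel correlations.

    Runs backward elimination ``k_runs`` times on copies of the expression
    matrix whose region labels have been shuffled (columns permuted while the
    target stays fixed) and records the peak correlation of each run. The
    maximum peak indicates how high the optimizer can push the statistic on
    signal-free data. Explicit ``permutations`` (one per run) can be supplied
    for reproducibility tests, e.g. the identity permutation.
    """
    rng = np.random.default_rng(seed)
    n_regions = expr.n_regions
    peaks: list[float] = []
    for run in range(k_runs):
        if permutations is not None:
            perm = np.asarray(permutations[run])
        else:
            perm = rng.permutation(n_regions)
        shuffled = ExpressionMatrix(
            list(expr.series), dict(expr.gene_of_series), list(expr.regions),
            expr.values[:, perm],
        )
        trace = backward_eliminate(shuffled, target, seed=seed, **eliminate_kwargs)
        peaks.append(trace.peak_r)
    return ShuffledControlResult(peaks, seed)
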