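"""Mantel test, partial Mantel test and Mantel correlogram.

The Mantel statistic is the Pearson correlation between the upper triangles
of two square region-pair matrices — a "correlation of correlations" when
both inputs are themselves profile-correlation matrices. Significance comes
from an empirical null built by shuffling region labels: one matrix has its
rows and columns jointly permuted, which preserves the value distribution
while breaking the pairing. The partial Mantel test first residualizes both
matrices on a covariate (here, spatial proximity) and runs the same test on
the residual matrices. The correlogram resolves an association into distance
classes, testing each class's indicator matrix against the data matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .errors import ConfigurationError, StatisticError
from .similarity import SimilarityMatrix, residualize

__all__ = [
    "MantelResult",
    "CorrelogramResult",
    "mantel_test",
    "partial_mantel",
    "mantel_correlogram",
    "shuffled_optimization_control",
]


def __getattr__(name):
    # the shuffled-expression optimization control lives beside the optimizer
    if name == "shuffled_optimization_control":
        from .selection import shuffled_optimization_control

        return shuffled_optimization_control
    raise AttributeError(name)


@dataclass
class MantelResult:
    """Outcome of a (partial) Mantel test."""

    r: float
    p: float
    n_perm: int
    n_regions: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise StatisticError(f"Mantel r out of range: {self.r}")
        if not 0.0 < self.p <= 1.0:
            raise StatisticError(f"invalid p-value: {self.p}")

    def summary(self) -> str:
        mode = "exhaustive" if self.exhaustive else f"{self.n_perm} permutations"
        return (
            f"Mantel r = {self.r:.4f}, p = {self.p:.4g} "
            f"({self.n_regions} regions, {mode})"
        )


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel statistics."""

    classes: list[tuple[float, float, int]]  # (lower, upper, pair count)
    r_per_class: np.ndarray
    p_per_class: np.ndarray
    p_corrected: np.ndarray
    n_perm: int
    correction: str
    dropped_classes: list[tuple[float, float]] = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_corrected <= alpha


def _pair_values(values: np.ndarray, perm: np.ndarray, iu: np.ndarray,
                 ju: np.ndarray) -> np.ndarray:
    return values[perm[iu], perm[ju]]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    denom = math.sqrt(float(xm @ xm) * float(ym @ ym))
    if denom == 0:
        raise StatisticError("zero-variance pair vector: Mantel statistic undefined")
    return float(xm @ ym) / denom


def mantel_test(
    A: SimilarityMatrix,
    B: SimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """One-sided (greater) Mantel test between two region-pair matrices.

    Each permutation applies one random region-label permutation jointly to
    B's rows and columns; ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``.
    Pairs with a missing value in either matrix are excluded (the missingness
    mask of A follows A's fixed labels; B's moves with the permutation).

    With ``exhaustive=True`` all n! label permutations are enumerated
    (including the identity) and the p-value is the exact tail fraction; only
    sensible for small n.
    """
    if A.regions != B.regions:
        raise ConfigurationError("matrices must share the same region order")
    n = A.n
    if n < 3:
        raise StatisticError("Mantel test needs at least 3 regions")
    if not exhaustive and n_perm < 99:
        raise ConfigurationError("n_perm must be at least 99")
    iu, ju = np.triu_indices(n, k=1)
    a = A.values[iu, ju]
    b_full = B.values

    def stat(perm: np.ndarray) -> float:
        b = _pair_values(b_full, perm, iu, ju)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            raise StatisticError("fewer than 3 complete pairs")
        return _pearson(a[ok], b[ok])

    identity = np.arange(n)
    r_obs = stat(identity)

    if exhaustive:
        r_all = np.array([stat(np.array(p)) for p in permutations(range(n))])
        p_val = float(np.mean(r_all >= r_obs - 1e-12))
        return MantelResult(r_obs, p_val, len(r_all), n, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_perm = stat(rng.permutation(n))
        if r_perm >= r_obs:
            hits += 1
    p_val = (hits + 1) / (n_perm + 1)
    return MantelResult(r_obs, p_val, n_perm, n, seed)


def partial_mantel(
    A: SimilarityMatrix,
    B: SimilarityMatrix,
    C: SimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for covariate C.

    Both A and B are residualized on C by simple OLS over region pairs, then
    a plain Mantel test is run on the residual matrices, permuting the
    residualized B's labels (method of residuals).
    """
    A_res = residualize(A, C)
    B_res = residualize(B, C)
    return mantel_test(A_res, B_res, n_perm=n_perm, seed=seed, exhaustive=exhaustive)


def _progressive_correction(p: np.ndarray, method: str) -> np.ndarray:
    """Multiple-test correction over ordered distance classes.

    Classes are read outward from the shortest distances, and class k is
    corrected for the k tests performed so far (progressive correction, the
    convention for Mantel correlograms). ``bh`` applies a standard
    Benjamini-Hochberg step-up over all classes instead.
    """
    k = np.arange(1, p.size + 1)
    if method == "bonferroni":
        return np.minimum(p * k, 1.0)
    if method == "holm":
        return np.minimum(np.maximum.accumulate(p * k), 1.0)
    if method == "bh":
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * m / (rank + 1))
            adj[idx] = running
        return adj
    raise ConfigurationError(f"unknown correction {method!r}")


def mantel_correlogram(
    A: SimilarityMatrix,
    D: SimilarityMatrix,
    n_classes: int | str = "auto",
    n_perm: int = 999,
    correction: str = "holm",
    seed: int | None = None,
) -> CorrelogramResult:
    """Mantel correlogram of matrix A over distance classes of D.

    Distances are binned into ``n_classes`` equal-width classes (auto:
    Sturges, ceil(1 + log2(pair count))). For each class the Mantel r between
    A and the class's 0/1 indicator matrix is computed, signed so that a
    positive value means within-class similarity excess (the raw correlation
    is negated when A is itself a distance matrix). Per-class permutation
    p-values are two-sided and corrected progressively.
    """
    if D.kind != "distance":
        raise ConfigurationError("D must be a distance matrix")
    if A.regions != D.regions:
        raise ConfigurationError("matrices must share the same region order")
    n = A.n
    iu, ju = np.triu_indices(n, k=1)
    a_vec = A.values[iu, ju]
    finite_a = np.isfinite(a_vec)
    if finite_a.sum() < 3 or np.ptp(a_vec[finite_a]) == 0:
        raise StatisticError("constant or near-empty data matrix: correlogram undefined")
    d_vec = D.values[iu, ju]
    n_pairs = d_vec.size
    if n_classes == "auto":
        n_classes = int(math.ceil(1 + math.log2(n_pairs)))
    edges = np.linspace(d_vec.min(), d_vec.max(), int(n_classes) + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # right-open bins, top inclusive
    which = np.digitize(d_vec, edges) - 1

    sign = -1.0 if A.kind == "distance" else 1.0
    rng = np.random.default_rng(seed)
    classes: list[tuple[float, float, int]] = []
    dropped: list[tuple[float, float]] = []
    r_list: list[float] = []
    p_list: list[float] = []
    for k in range(int(n_classes)):
        in_class = which == k
        count = int(in_class.sum())
        lo, hi = float(edges[k]), float(min(edges[k + 1], d_vec.max()))
        if count == 0:
            dropped.append((lo, hi))
            continue
        x = in_class.astype(float)
        ok = finite_a
        if np.ptp(x[ok]) == 0:
            # class covers every complete pair: correlation undefined
            dropped.append((lo, hi))
            continue
        r_obs = sign * _pearson(a_vec[ok], x[ok])
        ind = np.zeros((n, n))
        ind[iu, ju] = x
        ind += ind.T
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            xp = _pair_values(ind, perm, iu, ju)
            okp = finite_a
            if np.ptp(xp[okp]) == 0:
                continue
            r_perm = sign * _pearson(a_vec[okp], xp[okp])
            if abs(r_perm) >= abs(r_obs):
                hits += 1
        classes.append((lo, hi, count))
        r_list.append(r_obs)
        p_list.append((hits + 1) / (n_perm + 1))
    if not classes:
        raise StatisticError("all distance classes empty or degenerate")
    p_arr = np.array(p_list)
    return CorrelogramResult(
        classes,
        np.array(r_list),
        p_arr,
        _progressive_correction(p_arr, correction),
        n_perm,
        correction,
        dropped,
    )
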