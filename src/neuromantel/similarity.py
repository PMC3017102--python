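"""Square region-pair matrices consumed by the Mantel machinery.

All comparisons in the analysis happen between square symmetric region-pair
matrices: Pearson correlations of expression profiles, Pearson correlations
of binary connectivity profiles, Euclidean centroid distances (optionally
log-transformed), nomenclature similarity (shared ancestor counts), and the
residuals of regressing one such matrix on another (the proximity-controlled
variants used by the partial Mantel test).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, StatisticError
from .harmonize import ConnectivityData, ExpressionMatrix
from .ontology import RegionOntology

KINDS = ("correlation", "distance", "similarity", "residual")


@dataclass
class SimilarityMatrix:
    """A symmetric region-pair matrix with a semantic kind tag.

    ``kind`` records the orientation convention: ``correlation`` and
    ``similarity`` increase with resemblance, ``distance`` decreases, and
    ``residual`` is a proximity-controlled correlation. Off-diagonal entries
    may be NaN (e.g. too few complete observations for a Pearson r).
    """

    regions: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.regions)
        if self.values.shape != (n, n):
            raise DataError("similarity matrix shape does not match region list")
        if self.kind not in KINDS:
            raise ConfigurationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(self.values[both & ~np.eye(n, dtype=bool)],
                           self.values.T[both & ~np.eye(n, dtype=bool)], atol=1e-12):
            raise DataError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.regions)

    def subset(self, regions: list[str]) -> "SimilarityMatrix":
        idx = [self.regions.index(r) for r in regions]
        return SimilarityMatrix(list(regions), self.values[np.ix_(idx, idx)], self.kind)

    def upper(self) -> "PairVector":
        return upper_triangle(self)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=self.regions, columns=self.regions)
        frame.to_csv(path, sep="\t")
        Path(str(path) + ".json").write_text(json.dumps({"kind": self.kind}))

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str | None = None) -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if kind is None:
            sidecar = Path(str(path) + ".json")
            kind = json.loads(sidecar.read_text())["kind"] if sidecar.exists() else "similarity"
        return cls([str(c) for c in frame.columns], frame.to_numpy(dtype=float), kind)


@dataclass
class PairVector:
    """The upper triangle of a SimilarityMatrix as a flat vector.

    Pairs are ordered row-major over the upper triangle: (0,1), (0,2), ...,
    (1,2), ... in the matrix's region order.
    """

    pairs: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.pairs) != self.values.size:
            raise DataError("pair list and value vector differ in length")


def upper_triangle(matrix: SimilarityMatrix) -> PairVector:
    iu, ju = np.triu_indices(matrix.n, k=1)
    pairs = [(matrix.regions[i], matrix.regions[j]) for i, j in zip(iu, ju)]
    return PairVector(pairs, matrix.values[iu, ju])


def from_pair_vector(vec: PairVector, regions: list[str], kind: str,
                     diagonal: float = 0.0) -> SimilarityMatrix:
    """Reshape a canonical upper-triangle vector back into a square matrix."""
    n = len(regions)
    if vec.values.size != n * (n - 1) // 2:
        raise DataError("pair vector length does not match region count")
    out = np.full((n, n), float(diagonal))
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = vec.values
    out[ju, iu] = vec.values
    return SimilarityMatrix(list(regions), out, kind)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------
def expression_correlation(expr: ExpressionMatrix, min_overlap: int = 10) -> SimilarityMatrix:
    """Pairwise-complete Pearson correlation between region expression profiles.

    Entry (i, j) correlates the expression of regions i and j across the image
    series in which both are observed; pairs with fewer than ``min_overlap``
    complete series, or with zero variance over the complete set, are NaN.
    """
    if expr.n_series < 3 or expr.n_regions < 2:
        raise DataError("need at least 3 series and 2 regions for expression correlation")
    vals = expr.values
    obs = np.isfinite(vals)
    z = np.where(obs, vals, 0.0)
    m = obs.astype(float)
    n = m.T @ m                       # complete-pair counts
    sx = z.T @ m                      # sum of region-i values over joint support (i rows)
    sy = sx.T
    sxx = (z * z).T @ m
    syy = sxx.T
    sxy = z.T @ z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r = cov / np.sqrt(varx * vary)
    bad = (n < max(min_overlap, 2)) | (varx <= 0) | (vary <= 0)
    r = np.where(bad, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(list(expr.regions), r, "correlation")


def connectivity_correlation(conn: ConnectivityData, direction: str) -> SimilarityMatrix:
    """Pearson correlation between binary w-length connectivity profiles.

    Restricted to the direction's analysis set (regions with at least one
    connection); an all-zero profile would make the correlation undefined and
    signals an upstream bookkeeping error.
    """
    regions = conn.analysis_set(direction)
    if not regions:
        raise DataError(f"empty analysis set for direction {direction!r}")
    idx = [conn.common_x.index(r) for r in regions]
    prof = conn.profiles(direction)[idx].astype(float)
    if np.any(prof.std(axis=1) == 0):
        raise StatisticError("constant connectivity profile in analysis set")
    r = np.corrcoef(prof)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(regions, r, "correlation")


def spatial_distance(
    coordinates: dict[str, np.ndarray],
    regions: list[str] | None = None,
    log: bool = False,
    distance_floor: float = 1.0,
) -> SimilarityMatrix:
    """Euclidean centroid distances, optionally natural-log transformed.

    Coincident centroids are clamped to ``distance_floor`` (µm) before the log
    so log-distances stay finite; a warning is emitted when clamping occurs.
    """
    if regions is None:
        regions = sorted(coordinates)
    missing = [r for r in regions if r not in coordinates]
    if missing:
        raise DataError(f"regions without coordinates: {missing[:5]}")
    pts = np.asarray([coordinates[r] for r in regions], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(len(regions), dtype=bool)
    if log:
        if np.any(d[off] < distance_floor):
            warnings.warn(
                f"coincident or sub-floor centroid distances clamped to {distance_floor} um",
                stacklevel=2,
            )
        d = np.where(off, np.log(np.maximum(d, distance_floor)), 0.0)
    return SimilarityMatrix(list(regions), d, "distance")


def nomenclature_similarity(ontology: RegionOntology, regions: list[str]) -> SimilarityMatrix:
    """Shared-ancestor counts: entry (i, j) = |ancestors(i) ∩ ancestors(j)|.

    Ancestors exclude the region itself and include the root, so any two
    distinct regions share at least the root. Reported on the similarity
    orientation (larger = nomenclaturally closer).
    """
    anc = {r: set(ontology.ancestors(r)) for r in regions}
    n = len(regions)
    out = np.zeros((n, n))
    for i, ri in enumerate(regions):
        out[i, i] = len(anc[ri])
        for j in range(i + 1, n):
            shared = len(anc[ri] & anc[regions[j]])
            out[i, j] = out[j, i] = shared
    return SimilarityMatrix(list(regions), out, "similarity")


def residualize(target: SimilarityMatrix, covariate: SimilarityMatrix) -> SimilarityMatrix:
    """Regress the target's pair vector on the covariate's; return residuals.

    Simple one-covariate OLS over region pairs, as in partial-Mantel practice.
    NaN target pairs stay NaN; the covariate must be complete. A constant
    covariate degenerates to centering the target (with a warning).
    """
    if target.regions != covariate.regions:
        raise DataError("target and covariate must share region order")
    y = upper_triangle(target).values
    x = upper_triangle(covariate).values
    if not np.all(np.isfinite(x)):
        raise DataError("covariate matrix has missing off-diagonal entries")
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise StatisticError("too few complete pairs to residualize")
    resid = np.full_like(y, np.nan)
    if np.ptp(x[ok]) == 0:
        warnings.warn("constant covariate: residualizing reduces to centering", stacklevel=2)
        resid[ok] = y[ok] - y[ok].mean()
    else:
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        resid[ok] = y[ok] - (slope * x[ok] + intercept)
    return from_pair_vector(PairVector(upper_triangle(target).pairs, resid),
                            target.regions, "residual")
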