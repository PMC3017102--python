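"""Auxiliary statistics: degree analyses, group comparisons and enrichment.

Covers the descriptive and follow-up analyses around the Mantel machinery:
per-region connection degree and its Spearman correlation with each gene's
expression (Bonferroni-corrected), the connected-versus-unconnected
expression-similarity comparison, hypergeometric set-overlap tests, and
generic over-representation analysis (ORA) of a query gene set against GMT
annotation collections with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError, StatisticError
from .harmonize import ConnectivityData, ExpressionMatrix
from .similarity import SimilarityMatrix


# ---------------------------------------------------------------------------
# degree analyses
# ---------------------------------------------------------------------------
def region_degree(conn: ConnectivityData) -> dict[str, int]:
    """Connection degree per common region: outgoing + incoming profile sums."""
    out = conn.outgoing_profiles.sum(axis=1)
    inc = conn.incoming_profiles.sum(axis=1)
    return {r: int(o + i) for r, o, i in zip(conn.common_x, out, inc)}


def degree_expression_correlation(
    expr: ExpressionMatrix, degrees: dict[str, int]
) -> pd.DataFrame:
    """Spearman rho of each image series against the region degree vector.

    Average ranks are used for ties (scipy's convention); p-values get a
    Bonferroni multiplier equal to the number of series actually tested.
    Series that are constant (or nearly unobserved) over the scored regions
    are reported with NaN statistics and excluded from the multiplier.
    """
    regions = [r for r in expr.regions if r in degrees]
    if len(regions) < 5:
        raise DataError("need at least 5 regions with both degree and expression")
    deg = np.asarray([degrees[r] for r in regions], dtype=float)
    idx = [expr.regions.index(r) for r in regions]
    rows = []
    for s, row in zip(expr.series, expr.values[:, idx]):
        ok = np.isfinite(row)
        if ok.sum() < 5 or np.ptp(row[ok]) == 0:
            rows.append((s, expr.gene_of_series[s], np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(row[ok], deg[ok])
        rows.append((s, expr.gene_of_series[s], float(rho), float(p)))
    frame = pd.DataFrame(rows, columns=["series_id", "gene_symbol", "rho", "p"])
    tested = frame["p"].notna().sum()
    frame["p_bonferroni"] = (frame["p"] * tested).clip(upper=1.0)
    return frame


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------
@dataclass
class GroupComparison:
    """Two-group descriptives plus a t-test (NaN when a group is too small)."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float


def _compare(a: np.ndarray, b: np.ndarray, equal_var: bool) -> GroupComparison:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size >= 2 and b.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    else:
        t, p = np.nan, np.nan
    return GroupComparison(
        float(a.mean()) if a.size else np.nan,
        float(a.std(ddof=1)) if a.size > 1 else np.nan,
        int(a.size),
        float(b.mean()) if b.size else np.nan,
        float(b.std(ddof=1)) if b.size > 1 else np.nan,
        int(b.size),
        float(t),
        float(p),
    )


def connected_vs_unconnected(
    expr_corr: SimilarityMatrix, conn: ConnectivityData, equal_var: bool = False
) -> GroupComparison:
    """Compare expression correlations of connected vs unconnected region pairs.

    Pairs are split by the symmetrized adjacency over the correlation
    matrix's regions (connected iff an edge exists in either direction). The
    default test is Welch's t-test; set ``equal_var=True`` for the pooled
    variant.
    """
    regions = expr_corr.regions
    widx = {r: conn.regions_w.index(r) for r in regions}
    n = len(regions)
    iu, ju = np.triu_indices(n, k=1)
    adj = conn.adjacency
    connected = np.array(
        [
            bool(adj[widx[regions[i]], widx[regions[j]]] or adj[widx[regions[j]], widx[regions[i]]])
            for i, j in zip(iu, ju)
        ]
    )
    vals = expr_corr.values[iu, ju]
    return _compare(vals[connected], vals[~connected], equal_var)


def gene_gene_correlation_profile(
    expr: ExpressionMatrix, subset: list[str], min_overlap: int = 10,
    equal_var: bool = False,
) -> GroupComparison:
    """Pairwise series-series correlation distributions: subset vs all series.

    Correlates every pair of image series across regions (pairwise-complete)
    within the subset and within the full series list, and compares the two
    distributions. A diverse optimized gene list shows a subset distribution
    no tighter than the full set's.
    """
    unknown = [s for s in subset if s not in expr.series]
    if unknown:
        raise DataError(f"subset series not in expression matrix: {unknown[:5]}")

    def pair_correlations(series: list[str]) -> np.ndarray:
        idx = [expr.series.index(s) for s in series]
        vals = expr.values[idx]
        out = []
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                ok = np.isfinite(vals[i]) & np.isfinite(vals[j])
                if ok.sum() < max(min_overlap, 3):
                    continue
                a, b = vals[i, ok], vals[j, ok]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    continue
                out.append(float(np.corrcoef(a, b)[0, 1]))
        return np.asarray(out)

    return _compare(pair_correlations(subset), pair_correlations(list(expr.series)), equal_var)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------
def hypergeom_overlap(
    hits: int, list_size: int, category_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= hits).

    ``hits`` successes when drawing ``list_size`` genes from a universe of
    ``universe_size`` containing ``category_size`` category members.
    """
    if not (
        0 <= hits <= min(list_size, category_size)
        and list_size <= universe_size
        and category_size <= universe_size
    ):
        raise ConfigurationError(
            f"inconsistent counts: hits={hits}, list={list_size}, "
            f"category={category_size}, universe={universe_size}"
        )
    return float(stats.hypergeom.sf(hits - 1, universe_size, category_size, list_size))


@dataclass
class AnnotationCollection:
    """Named gene sets restricted to a measured-gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.sets = {name: set(members) & self.universe for name, members in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str]) -> "AnnotationCollection":
        from gseapy import read_gmt

        raw = read_gmt(str(path))
        return cls({name: set(members) for name, members in raw.items()}, set(universe))


def ora(
    query: set[str],
    annotations: AnnotationCollection,
    min_size: int = 5,
    max_size: int = 200,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH-FDR control.

    Annotation groups are filtered to those with ``min_size``–``max_size``
    measured members; each retained group gets an upper-tail hypergeometric
    p-value for its overlap with the query, corrected across groups by the
    Benjamini-Hochberg step-up. Query genes outside the universe are dropped
    with a warning. Rows are sorted by corrected then raw p-value.
    """
    if not query:
        raise DataError("empty query gene set")
    outside = query - annotations.universe
    if outside:
        import warnings

        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
    query = query & annotations.universe
    if not query:
        raise DataError("no query genes inside the universe")
    universe_size = len(annotations.universe)
    rows = []
    for name in sorted(annotations.sets):
        members = annotations.sets[name]
        if not min_size <= len(members) <= max_size:
            continue
        hits = len(query & members)
        p = hypergeom_overlap(hits, len(query), len(members), universe_size)
        rows.append((name, len(members), hits, p))
    if not rows:
        return pd.DataFrame(columns=["name", "group_size", "hits", "p", "p_corrected"])
    frame = pd.DataFrame(rows, columns=["name", "group_size", "hits", "p"])
    frame["p_corrected"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame.sort_values(["p_corrected", "p", "name"], ignore_index=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, exposed for reuse)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise StatisticError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
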