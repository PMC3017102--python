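"""Harmonize raw ontology, connectome and expression inputs into aligned matrices.

The connectome is typically curated on a finer parcellation than the
expression atlas, so edges are *up-propagated*: each endpoint is replaced by
its nearest ancestor inside a target region set. Parcellation mismatches that
up-propagation cannot fix are handled by *virtual regions* whose connectivity
profile is the logical OR of several finer regions. The result is a directed
binary adjacency over the full region universe (w regions) together with the
x-by-w incoming and outgoing profile submatrices for the x regions that also
carry expression data, and a log-scale expression matrix over those regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .ontology import RegionOntology

Edge = tuple[str, str]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class ExpressionMatrix:
    """Image-series by region matrix of log expression energy.

    Rows are ISH image series (a gene may have several independent series);
    columns are regions. Missing measurements are NaN.
    """

    series: list[str]
    gene_of_series: dict[str, str]
    regions: list[str]
    values: np.ndarray  # (n_series, n_regions) float64, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.series), len(self.regions)):
            raise DataError(
                f"expression values shape {self.values.shape} does not match "
                f"{len(self.series)} series x {len(self.regions)} regions"
            )
        if len(set(self.series)) != len(self.series):
            raise DataError("duplicate series ids in expression matrix")
        missing = [s for s in self.series if s not in self.gene_of_series]
        if missing:
            raise DataError(f"series without gene mapping: {missing[:5]}")

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def genes(self) -> set[str]:
        return {self.gene_of_series[s] for s in self.series}

    def subset_regions(self, regions: list[str]) -> "ExpressionMatrix":
        idx = [self.regions.index(r) for r in regions]
        return ExpressionMatrix(
            list(self.series), dict(self.gene_of_series), list(regions), self.values[:, idx]
        )

    def subset_series(self, series: list[str]) -> "ExpressionMatrix":
        idx = [self.series.index(s) for s in series]
        return ExpressionMatrix(
            list(series),
            {s: self.gene_of_series[s] for s in series},
            list(self.regions),
            self.values[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.regions)
        frame.insert(0, "series_id", self.series)
        frame.insert(1, "gene_symbol", [self.gene_of_series[s] for s in self.series])
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        if not {"series_id", "gene_symbol"}.issubset(frame.columns):
            raise DataError("expression table needs series_id and gene_symbol columns")
        regions = [c for c in frame.columns if c not in ("series_id", "gene_symbol")]
        series = [str(s) for s in frame["series_id"]]
        genes = dict(zip(series, (str(g) for g in frame["gene_symbol"])))
        return cls(series, genes, regions, frame[regions].to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ConnectivityData:
    """Directed binary adjacency plus the x-by-w connectivity profile submatrices.

    ``regions_w`` is the full region universe (w regions) over which
    connections are recorded; ``common_x`` the subset (x regions) with
    expression data. ``outgoing_profiles[i]`` is the full w-length efferent
    profile of common region i (its adjacency row); ``incoming_profiles[i]``
    the afferent profile (its adjacency column). Common regions with an
    all-zero profile in one direction are excluded from that direction's
    analysis set but stay in the universe (absence of a documented connection
    is treated as no connection).
    """

    regions_w: list[str]
    adjacency: np.ndarray  # (w, w) uint8, no self-loops
    common_x: list[str]
    outgoing_profiles: np.ndarray = field(init=False)  # (x, w)
    incoming_profiles: np.ndarray = field(init=False)  # (x, w)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        w = len(self.regions_w)
        if self.adjacency.shape != (w, w):
            raise DataError("adjacency shape does not match region list")
        if np.any(np.diag(self.adjacency)):
            raise DataError("adjacency has self-loops")
        unknown = [r for r in self.common_x if r not in set(self.regions_w)]
        if unknown:
            raise DataError(f"common regions not in universe: {unknown[:5]}")
        idx = [self.regions_w.index(r) for r in self.common_x]
        self.outgoing_profiles = self.adjacency[idx, :].copy()
        self.incoming_profiles = self.adjacency[:, idx].T.copy()

    @property
    def w(self) -> int:
        return len(self.regions_w)

    @property
    def x(self) -> int:
        return len(self.common_x)

    def profiles(self, direction: str) -> np.ndarray:
        if direction == "outgoing":
            return self.outgoing_profiles
        if direction == "incoming":
            return self.incoming_profiles
        raise ConfigurationError(f"direction must be incoming or outgoing, got {direction!r}")

    def analysis_set(self, direction: str) -> list[str]:
        """Common regions with at least one connection in ``direction``."""
        prof = self.profiles(direction)
        keep = prof.sum(axis=1) > 0
        return [r for r, k in zip(self.common_x, keep) if k]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def up_propagate(
    edges: list[Edge], ontology: RegionOntology, targets: set[str]
) -> list[Edge]:
    """Coarsen an edge list onto a target region set.

    Each endpoint is replaced by its nearest ancestor (or itself) inside
    ``targets``; edges with an endpoint that has no ancestor in the target set
    are dropped, duplicates are collapsed and self-loops removed. Idempotent.
    """
    cache: dict[str, str | None] = {}

    def lift(rid: str) -> str | None:
        if rid not in ontology:
            raise DataError(f"edge endpoint {rid!r} not in ontology")
        if rid in cache:
            return cache[rid]
        mapped = None
        for cand in [rid] + ontology.ancestors(rid):
            if cand in targets:
                mapped = cand
                break
        cache[rid] = mapped
        return mapped

    out: list[Edge] = []
    seen: set[Edge] = set()
    for src, tgt in edges:
        a, b = lift(src), lift(tgt)
        if a is None or b is None or a == b:
            continue
        if (a, b) not in seen:
            seen.add((a, b))
            out.append((a, b))
    return out


def merge_virtual_regions(
    conn: ConnectivityData, merges: dict[str, set[str]]
) -> ConnectivityData:
    """Merge member regions into virtual regions by OR-ing their profiles.

    The virtual region's adjacency row (column) is the element-wise OR of the
    member rows (columns); members are removed from the universe. Member sets
    of different virtual regions must not overlap.
    """
    all_members: set[str] = set()
    for vid, members in merges.items():
        if not members:
            raise ConfigurationError(f"virtual region {vid!r} has no members")
        overlap = all_members & members
        if overlap:
            raise ConfigurationError(f"regions {sorted(overlap)} in multiple virtual regions")
        all_members |= members
        unknown = members - set(conn.regions_w)
        if unknown:
            raise DataError(f"virtual region {vid!r} members not found: {sorted(unknown)}")

    index = {r: i for i, r in enumerate(conn.regions_w)}
    keep = [r for r in conn.regions_w if r not in all_members]
    new_regions = keep + sorted(merges)
    n = len(new_regions)
    # membership matrix: OR of member rows/columns == positive entry in M A M^T
    members_of = {r: sorted(merges[r]) if r in merges else [r] for r in new_regions}
    member_mat = np.zeros((n, conn.w), dtype=np.int64)
    for i, r in enumerate(new_regions):
        for m in members_of[r]:
            member_mat[i, index[m]] = 1
    adj = (member_mat @ conn.adjacency.astype(np.int64) @ member_mat.T > 0).astype(np.uint8)
    np.fill_diagonal(adj, 0)

    new_common = [r for r in conn.common_x if r not in all_members]
    new_common += [v for v in sorted(merges) if merges[v] & set(conn.common_x)]
    return ConnectivityData(new_regions, adj, new_common)


def exclude_region_connections(
    edges: list[Edge], ontology: RegionOntology, excluded_root: str
) -> list[Edge]:
    """Drop every edge touching ``excluded_root`` or any of its descendants.

    The excluded regions stay in the region universe (they simply count as
    unconnected), mirroring the removal of an atypically well-studied region
    whose documented connections would otherwise dominate.
    """
    if excluded_root not in ontology:
        raise DataError(f"unknown region id {excluded_root!r}")
    banned = ontology.descendants(excluded_root) | {excluded_root}
    return [(s, t) for s, t in edges if s not in banned and t not in banned]


def select_leaf_regions(ontology: RegionOntology, expression_regions: set[str]) -> set[str]:
    """Regions in ``expression_regions`` that have no subpart also in the set.

    Using only such "leaf" regions avoids the nesting-induced correlations a
    parent region would share with its own parts.
    """
    out = set()
    for rid in expression_regions:
        if rid not in ontology:
            raise DataError(f"unknown region id {rid!r}")
        if not (ontology.descendants(rid) & expression_regions):
            out.add(rid)
    return out


def build_expression_matrix(
    raw: pd.DataFrame,
    nonexpressed_genes: set[str] = frozenset(),
    min_region_coverage: float = 0.5,
) -> ExpressionMatrix:
    """Filter and log-transform a raw expression-energy table.

    Series of genes with no detectable expression are dropped; energies are
    natural-log transformed; non-positive or absent energies become missing
    (energy is a nonnegative pixel average, zero means undetected); series
    observed in fewer than ``min_region_coverage`` of regions are dropped.
    """
    em = ExpressionMatrix.from_frame(raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        logged = np.where(em.values > 0, np.log(em.values), np.nan)
    keep = [
        i
        for i, s in enumerate(em.series)
        if em.gene_of_series[s] not in nonexpressed_genes
        and np.isfinite(logged[i]).mean() >= min_region_coverage
    ]
    series = [em.series[i] for i in keep]
    return ExpressionMatrix(
        series, {s: em.gene_of_series[s] for s in series}, em.regions, logged[keep]
    )


def build_profiles(
    edges: list[Edge], regions_w: list[str], common_x: list[str]
) -> ConnectivityData:
    """Assemble the adjacency and x-by-w profile submatrices from an edge list."""
    index = {r: i for i, r in enumerate(regions_w)}
    w = len(regions_w)
    adj = np.zeros((w, w), dtype=np.uint8)
    for src, tgt in edges:
        if src not in index or tgt not in index:
            raise DataError(f"edge ({src!r}, {tgt!r}) outside region universe")
        if src != tgt:
            adj[index[src], index[tgt]] = 1
    return ConnectivityData(regions_w, adj, common_x)


def read_edges_tsv(path: str | Path) -> list[Edge]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source_id", "target_id"}.issubset(frame.columns):
        raise DataError("edge table needs source_id and target_id columns")
    return list(zip(frame["source_id"], frame["target_id"]))


def write_edges_tsv(edges: list[Edge], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["source_id", "target_id"]).to_csv(path, sep="\t", index=False)


def apply_region_mapping(edges: list[Edge], mapping: dict[str, str]) -> list[Edge]:
    """Rename edge endpoints through a cross-nomenclature mapping file.

    Endpoints absent from the mapping are kept unchanged; renaming can create
    duplicates and self-loops, which are collapsed/dropped as in
    :func:`up_propagate`.
    """
    out: list[Edge] = []
    seen: set[Edge] = set()
    for src, tgt in edges:
        a, b = mapping.get(src, src), mapping.get(tgt, tgt)
        if a == b:
            continue
        if (a, b) not in seen:
            seen.add((a, b))
            out.append((a, b))
    return out
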