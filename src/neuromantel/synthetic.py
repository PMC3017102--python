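"""Synthetic study generator: ontology, centroids, connectome and expression.

Real inputs of this kind of analysis — a curated connectome on one
parcellation and an ISH expression atlas on another — are large external
resources. This module fabricates complete miniature studies with the
statistical structure the analysis assumes, plus ground-truth labels:

* a nested region hierarchy (balanced tree with a configurable branching
  factor) whose top-level children act as major brain divisions;
* spatially clustered centroids (division centers scattered widely, leaves
  jittered tightly around them), producing nomenclature/space correlation;
* distance-dependent directed connectivity (logistic in log-distance), so
  nearby regions tend to be connected;
* log-scale expression with four gene archetypes: pure-noise *background*
  genes, *spatial* genes drawn from a Gaussian process with an exponential
  distance kernel (spatial autocorrelation without any connectivity signal),
  *marker* genes elevated in one region (a Pcp2-like restricted pattern) and
  *pair* genes elevated at both endpoints of a random subset of connections
  (a Pgrmc1-like co-expression pattern);
* duplicate image series for a fraction of genes and missing values at
  random.

Every draw is controlled by a single seed; identical configs yield
byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DataError
from .harmonize import Edge, ExpressionMatrix, write_edges_tsv
from .ontology import RegionOntology

TRUTH_LABELS = ("background", "spatial", "marker", "pair")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic study.

    Lengths are in µm; expression effects and noise are in natural-log
    expression-energy units. ``conn_intercept``/``conn_distance_slope``
    parameterize edge probability as logistic(intercept + slope * log d).
    """

    n_leaf_regions: int = 20
    branching: int = 8
    n_genes: int = 100
    frac_marker: float = 0.0
    frac_pair: float = 0.0
    frac_spatial: float = 0.0
    duplicate_rate: float = 0.1
    missing_rate: float = 0.03
    spatial_cluster_scale: float = 300.0
    division_spread: float = 4000.0
    conn_intercept: float = 31.0
    conn_distance_slope: float = -4.0
    conn_long_range: float = 0.0
    pair_effect: float = 3.0
    marker_effect: float = 3.0
    noise_sd: float = 1.0
    gp_length_scale: float = 250.0
    n_pair_edges: int = 15
    distance_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_marker", "frac_pair", "frac_spatial",
                     "duplicate_rate", "missing_rate", "conn_long_range"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_marker + self.frac_pair + self.frac_spatial > 1.0 + 1e-12:
            raise ConfigurationError("gene-archetype fractions must sum to at most 1")
        if self.n_leaf_regions < 8:
            raise ConfigurationError("n_leaf_regions must be at least 8")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.branching < 2:
            raise ConfigurationError("branching must be at least 2")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """A complete generated study with per-series ground truth."""

    ontology: RegionOntology
    coordinates: dict[str, np.ndarray]
    connections: list[Edge]
    expression: ExpressionMatrix
    truth: dict[str, str]  # series id -> archetype label
    config: SyntheticConfig

    def __post_init__(self) -> None:
        leaves = set(self.ontology.leaves())
        if not leaves <= set(self.coordinates):
            raise DataError("every leaf region needs coordinates")
        if set(self.truth) != set(self.expression.series):
            raise DataError("truth labels must cover every image series exactly once")
        for s, t in self.connections:
            if s not in leaves or t not in leaves:
                raise DataError("edge endpoints must be ontology leaves")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.ontology.to_tsv(outdir / "ontology.tsv")
        import pandas as pd

        regs = sorted(self.coordinates)
        pd.DataFrame(
            {
                "region_id": regs,
                "x": [self.coordinates[r][0] for r in regs],
                "y": [self.coordinates[r][1] for r in regs],
                "z": [self.coordinates[r][2] for r in regs],
            }
        ).to_csv(outdir / "coordinates.tsv", sep="\t", index=False)
        write_edges_tsv(self.connections, outdir / "edges.tsv")
        self.expression.to_tsv(outdir / "expression.tsv")
        pd.DataFrame(
            {"series_id": list(self.truth), "label": list(self.truth.values())}
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def generate_ontology(n_leaf_regions: int, branching: int, seed: int = 0) -> RegionOntology:
    """Balanced rooted tree with the requested number of leaves.

    Leaves are split as evenly as possible into at most ``branching`` groups
    at each level; a group of one becomes a leaf. The construction is fully
    deterministic (the seed is accepted for interface uniformity).
    """
    if branching < 2 or n_leaf_regions < branching:
        raise ConfigurationError(
            f"need n_leaf_regions >= branching >= 2, got {n_leaf_regions}, {branching}"
        )
    records: list[tuple[str, str, str | None]] = [("root", "whole brain", None)]
    counter = {"internal": 0, "leaf": 0}

    def build_children(n: int, parent: str) -> None:
        """Split n leaves as evenly as possible into <= branching groups."""
        groups = min(branching, n)
        base, extra = divmod(n, groups)
        sizes = [base + (1 if g < extra else 0) for g in range(groups)]
        for size in sizes:
            if size == 1:
                rid = f"L{counter['leaf']:04d}"
                counter["leaf"] += 1
                records.append((rid, f"region {rid}", parent))
            else:
                rid = f"N{counter['internal']:04d}"
                counter["internal"] += 1
                records.append((rid, f"division {rid}", parent))
                build_children(size, rid)

    build_children(n_leaf_regions, "root")
    return RegionOntology(records)


def generate_coordinates(
    ontology: RegionOntology,
    division_spread: float,
    spatial_cluster_scale: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Leaf centroids: a wide Gaussian per top division, tight jitter per leaf.

    Each child of the root gets a center drawn from an isotropic zero-mean
    Gaussian with sd ``division_spread``; every leaf sits at its division's
    center plus isotropic jitter with sd ``spatial_cluster_scale``. Leaves in
    the same division are therefore closer in expectation than leaves of
    different divisions. Centers are redrawn (up to a bounded number of
    tries) until each is at least one ``division_spread`` from all earlier
    ones: major divisions occupy disjoint territories rather than
    overlapping by chance.
    """
    rng = np.random.default_rng(seed)
    centers: dict[str, np.ndarray] = {}
    placed: list[np.ndarray] = []
    for div in sorted(ontology.children(ontology.root)):
        best, best_sep = None, -np.inf
        for _ in range(200):
            cand = rng.normal(0.0, division_spread, size=3)
            sep = min(
                (float(np.linalg.norm(cand - p)) for p in placed), default=np.inf
            )
            if sep > best_sep:
                best, best_sep = cand, sep
            if sep >= division_spread:
                break
        centers[div] = best
        placed.append(best)
    coords: dict[str, np.ndarray] = {}
    for leaf in sorted(ontology.leaves()):
        div = ontology.top_division(leaf)
        center = centers.get(div, np.zeros(3))
        coords[leaf] = center + rng.normal(0.0, spatial_cluster_scale, size=3)
    return coords


def generate_connectivity(
    coordinates: dict[str, np.ndarray],
    conn_intercept: float,
    conn_distance_slope: float,
    seed: int = 0,
    distance_floor: float = 1.0,
    conn_long_range: float = 0.0,
) -> list[Edge]:
    """Directed edges drawn independently with logistic log-distance odds.

    P(i -> j) combines a distance rule with a small distance-independent
    floor: ``1 - (1 - conn_long_range) * (1 - logistic(intercept + slope *
    log d(i, j)))``. The floor plants occasional long-range projections that
    proximity does not predict, as real connectomes show. No self-edges;
    coincident centroids are clamped to ``distance_floor`` before the log.
    """
    regions = sorted(coordinates)
    if len(regions) < 2:
        raise ConfigurationError("need at least 2 regions for connectivity")
    pts = np.asarray([coordinates[r] for r in regions], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    if np.any((d + np.eye(len(regions))) < distance_floor):
        import warnings

        warnings.warn(
            f"coincident centroids clamped to distance floor {distance_floor} um",
            stacklevel=2,
        )
    d = np.maximum(d, distance_floor)
    logit = conn_intercept + conn_distance_slope * np.log(d)
    prob = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    prob = 1.0 - (1.0 - conn_long_range) * (1.0 - prob)
    np.fill_diagonal(prob, 0.0)
    rng = np.random.default_rng(seed)
    draws = rng.random(prob.shape) < prob
    return [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(len(regions))
        if draws[i, j]
    ]


def _grow_connected_edges(
    connections: list[Edge],
    n_edges: int,
    rng: np.random.Generator,
    seed_candidates: list[int] | None = None,
    allowed_nodes: set[str] | None = None,
) -> set[str]:
    """Endpoint union of a randomly grown dense connected edge subset.

    Starts from a uniformly chosen edge (optionally from ``seed_candidates``)
    and greedily accretes edges until ``n_edges`` are chosen or none remain:
    edges internal to the current node set are absorbed first (densifying
    the cluster), otherwise the cluster expands along an edge to the outside
    region best connected into the set. When ``allowed_nodes`` is given the
    cluster never expands beyond that set. The result is a cluster of highly
    interconnected regions — the structure a pair-archetype gene marks with
    elevated expression.
    """
    chosen: set[int] = set()
    pool = list(seed_candidates) if seed_candidates else list(range(len(connections)))
    first = int(pool[int(rng.integers(len(pool)))])
    chosen.add(first)
    nodes: set[str] = set(connections[first])
    while len(chosen) < n_edges:
        internal = []
        external = []
        for k, (s, t) in enumerate(connections):
            if k in chosen:
                continue
            s_in, t_in = s in nodes, t in nodes
            if s_in and t_in:
                internal.append(k)
            elif s_in or t_in:
                outside = t if s_in else s
                if allowed_nodes is None or outside in allowed_nodes:
                    external.append(k)
        if internal:
            pick = internal[int(rng.integers(len(internal)))]
        elif external:
            # expand toward the neighbour best connected to the cluster
            links: dict[str, int] = {}
            for k in external:
                s, t = connections[k]
                outside = t if s in nodes else s
                links[outside] = links.get(outside, 0) + 1
            best = max(links.values())
            tied = [
                k
                for k in external
                if links[(connections[k][1] if connections[k][0] in nodes else connections[k][0])]
                == best
            ]
            pick = tied[int(rng.integers(len(tied)))]
        else:
            break
        chosen.add(pick)
        nodes.update(connections[pick])
    return nodes


def generate_expression(
    config: SyntheticConfig,
    ontology: RegionOntology,
    coordinates: dict[str, np.ndarray],
    connections: list[Edge],
    seed: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expression matrix with planted archetypes and per-series truth labels.

    Each gene owns a deterministic *pattern* over regions (zero for
    background; a GP draw for spatial genes; an effect at one region for
    markers; an effect on the endpoint union of ``n_pair_edges`` random
    connections for pair genes). Every image series is the gene's pattern
    plus fresh iid Gaussian noise, so duplicate series of one gene agree only
    through the pattern. A ``missing_rate`` fraction of cells is blanked at
    random.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    regions = sorted(ontology.leaves())
    x = len(regions)
    n_marker = round(config.frac_marker * config.n_genes)
    n_pair = round(config.frac_pair * config.n_genes)
    n_spatial = round(config.frac_spatial * config.n_genes)
    n_background = config.n_genes - n_marker - n_pair - n_spatial
    if n_background < 0:
        raise ConfigurationError("archetype fractions exceed the gene budget")
    labels = (
        ["marker"] * n_marker
        + ["pair"] * n_pair
        + ["spatial"] * n_spatial
        + ["background"] * n_background
    )
    if n_pair and not connections:
        raise DataError("pair-type genes requested but the graph has no edges")

    # GP covariance for spatial genes: sd-scaled exponential distance kernel
    chol = None
    if n_spatial:
        pts = np.asarray([coordinates[r] for r in regions])
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.sqrt((diff**2).sum(axis=-1))
        cov = config.noise_sd**2 * np.exp(-dmat / config.gp_length_scale)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(x))

    region_index = {r: i for i, r in enumerate(regions)}

    # pair-gene clusters are grown inside one major division at a time,
    # rotating round-robin over divisions, so the planted clusters tile the
    # connectome instead of clumping by chance and stay anatomically coherent
    divisions = sorted(ontology.children(ontology.root))
    members: dict[str, set[str]] = {
        d: ({d} | ontology.descendants(d)) for d in divisions
    }
    internal_by_division: dict[str, list[int]] = {d: [] for d in divisions}
    for k, (src, tgt) in enumerate(connections):
        for d in divisions:
            if src in members[d] and tgt in members[d]:
                internal_by_division[d].append(k)
                break
    rotation = [d for d in divisions if internal_by_division[d]]

    pair_counter = 0
    patterns = np.zeros((config.n_genes, x))
    for g, label in enumerate(labels):
        if label == "marker":
            patterns[g, rng.integers(x)] += config.marker_effect
        elif label == "pair":
            seed_pool = None
            allowed = None
            if rotation:
                division = rotation[pair_counter % len(rotation)]
                pair_counter += 1
                seed_pool = internal_by_division[division]
                allowed = members[division]
            touched = _grow_connected_edges(
                connections, config.n_pair_edges, rng, seed_pool, allowed
            )
            idx = sorted(region_index[r] for r in touched)
            patterns[g, idx] += config.pair_effect
        elif label == "spatial":
            assert chol is not None
            patterns[g] = chol @ rng.standard_normal(x)

    dup = rng.random(config.n_genes) < config.duplicate_rate
    rows = []
    series: list[str] = []
    gene_of_series: dict[str, str] = {}
    truth: dict[str, str] = {}
    sid = 0
    for g, label in enumerate(labels):
        gene = f"Gene{g:04d}"
        for _ in range(2 if dup[g] else 1):
            name = f"S{sid:05d}"
            sid += 1
            rows.append(patterns[g] + rng.normal(0.0, config.noise_sd, size=x))
            series.append(name)
            gene_of_series[name] = gene
            truth[name] = label
    values = np.asarray(rows)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    return ExpressionMatrix(series, gene_of_series, regions, values), truth


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages from one master seed."""
    ss = np.random.SeedSequence(config.seed)
    s_onto, s_coord, s_conn, s_expr = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    ontology = generate_ontology(config.n_leaf_regions, config.branching, s_onto)
    coords = generate_coordinates(
        ontology, config.division_spread, config.spatial_cluster_scale, s_coord
    )
    connections = generate_connectivity(
        coords, config.conn_intercept, config.conn_distance_slope, s_conn,
        config.distance_floor, config.conn_long_range,
    )
    expression, truth = generate_expression(config, ontology, coords, connections, s_expr)
    return SyntheticDataset(ontology, coords, connections, expression, truth, config)
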