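"""End-to-end orchestration: data -> similarity matrices -> tests -> report.

A run takes either a synthetic-study configuration or a directory of
simulate-format TSVs, builds connectivity profiles and the similarity
matrices, performs plain and proximity-controlled Mantel tests per requested
direction (optionally per major division), runs the backward-elimination
optimizer against the proximity-controlled target, and collects the
downstream statistics into a machine-readable report. All randomness is
derived from one master seed; the resolved configuration and per-stage
counts are embedded in the report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, StatisticError
from .harmonize import ExpressionMatrix, build_profiles, read_edges_tsv
from .mantel import mantel_test, partial_mantel
from .ontology import RegionOntology
from .selection import backward_eliminate, high_confidence_genes, rank_series
from .similarity import (
    SimilarityMatrix,
    connectivity_correlation,
    expression_correlation,
    residualize,
    spatial_distance,
)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset
from .downstream import connected_vs_unconnected, region_degree

logger = logging.getLogger("neuromantel")

DIRECTIONS = ("incoming", "outgoing", "proximity")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    directions: tuple[str, ...] = ("incoming", "outgoing")
    n_perm: int = 999
    k_min: int = 3
    min_overlap: int = 3
    expr_min_overlap: int = 10
    seed: int = 0
    run_selection: bool = True
    per_division: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise ConfigurationError("provide exactly one of synthetic config or input_dir")
        if not self.directions:
            raise ConfigurationError("at least one direction required")
        bad = [d for d in self.directions if d not in DIRECTIONS]
        if bad:
            raise ConfigurationError(f"unknown directions {bad}; choose from {DIRECTIONS}")
        if self.n_perm < 99:
            raise ConfigurationError("n_perm must be at least 99")


@dataclass
class DirectionReport:
    direction: str
    n_regions: int
    mantel_r: float
    mantel_p: float
    partial_r: float | None = None
    partial_p: float | None = None
    peak_r: float | None = None
    peak_size: int | None = None
    terminal_size: int | None = None
    n_high_confidence_genes: int | None = None
    per_division: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class RunReport:
    """Machine-readable summary of one run."""

    version: str
    config: dict[str, Any]
    counts: dict[str, int]
    directions: list[DirectionReport]
    connected_vs_unconnected: dict[str, float]
    degree_summary: dict[str, float]
    stage_seconds: dict[str, float]

    def n_significant(self, alpha: float = 0.05) -> int:
        hits = 0
        for d in self.directions:
            if d.mantel_p <= alpha:
                hits += 1
            if d.partial_p is not None and d.partial_p <= alpha:
                hits += 1
        return hits

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "counts": self.counts,
            "directions": [asdict(d) for d in self.directions],
            "connected_vs_unconnected": self.connected_vs_unconnected,
            "degree_summary": self.degree_summary,
            "stage_seconds": self.stage_seconds,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [f"neuromantel {self.version} run"]
        c = self.counts
        lines.append(
            f"  regions={c['n_regions']} edges={c['n_edges']} series={c['n_series']}"
        )
        for d in self.directions:
            line = (
                f"  {d.direction:9s} n={d.n_regions:3d} "
                f"r={d.mantel_r:+.3f} (p={d.mantel_p:.4g})"
            )
            if d.partial_r is not None:
                line += f"  partial r={d.partial_r:+.3f} (p={d.partial_p:.4g})"
            if d.peak_r is not None:
                line += f"  peak r={d.peak_r:+.3f} @ {d.peak_size} series"
            lines.append(line)
        cc = self.connected_vs_unconnected
        if cc:
            lines.append(
                f"  connected pairs {cc['n_connected']:.0f} (mean r {cc['mean_connected']:.3f})"
                f" vs unconnected {cc['n_unconnected']:.0f} (mean r {cc['mean_unconnected']:.3f})"
                f", t={cc['t']:.2f} p={cc['p']:.3g}"
            )
        return "\n".join(lines)


def load_dataset(input_dir: str | Path) -> SyntheticDataset:
    """Load a simulate-format dataset directory (see SyntheticDataset.write)."""
    input_dir = Path(input_dir)
    ontology = RegionOntology.from_tsv(input_dir / "ontology.tsv")
    coords_frame = pd.read_csv(input_dir / "coordinates.tsv", sep="\t")
    coordinates = {
        str(row.region_id): np.array([row.x, row.y, row.z], dtype=float)
        for row in coords_frame.itertuples()
    }
    edges = read_edges_tsv(input_dir / "edges.tsv")
    expression = ExpressionMatrix.from_tsv(input_dir / "expression.tsv")
    truth_path = input_dir / "truth.tsv"
    truth: dict[str, str] = {}
    if truth_path.exists():
        tf = pd.read_csv(truth_path, sep="\t", dtype=str)
        truth = dict(zip(tf["series_id"], tf["label"]))
    else:
        truth = {s: "background" for s in expression.series}
    cfg_path = input_dir / "config.yaml"
    config = SyntheticConfig.from_yaml(cfg_path) if cfg_path.exists() else SyntheticConfig()
    return SyntheticDataset(ontology, coordinates, edges, expression, truth, config)


def subset_by_division(
    matrices: SimilarityMatrix | Sequence[SimilarityMatrix],
    ontology: RegionOntology,
    division: str,
) -> SimilarityMatrix | list[SimilarityMatrix]:
    """Restrict similarity matrices to leaf regions of one major division.

    ``division`` must be a child of the root; the restriction preserves the
    original region order. Divisions with fewer than 4 retained regions make
    the Mantel test degenerate and raise an error.
    """
    if division not in ontology.children(ontology.root):
        raise ConfigurationError(f"{division!r} is not a child of the ontology root")
    members = ontology.descendants(division) | {division}
    single = isinstance(matrices, SimilarityMatrix)
    mats = [matrices] if single else list(matrices)
    out = []
    for mat in mats:
        keep = [r for r in mat.regions if r in members]
        if len(keep) < 4:
            raise StatisticError(
                f"division {division!r} retains {len(keep)} regions; Mantel degenerate"
            )
        out.append(mat.subset(keep))
    return out[0] if single else out


def run(config: RunConfig) -> RunReport:
    """Execute all pipeline stages and assemble the report."""
    stage_seconds: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        stage_seconds[stage] = round(now - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, now - t0)
        t0 = now

    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic)
    else:
        dataset = load_dataset(config.input_dir)
    tick("ingest")

    leaves = sorted(dataset.ontology.leaves())
    conn = build_profiles(dataset.connections, leaves, list(dataset.expression.regions))
    expr = dataset.expression
    expr_corr_full = expression_correlation(expr, min_overlap=config.expr_min_overlap)
    tick("harmonize")

    ss = np.random.SeedSequence(config.seed)
    streams = iter(ss.spawn(4 * len(config.directions)))

    def next_seed() -> int:
        return int(next(streams).generate_state(1)[0] % (2**31))

    reports: list[DirectionReport] = []
    for direction in config.directions:
        if direction == "proximity":
            regions = expr_corr_full.regions
            dist = spatial_distance(dataset.coordinates, regions, log=True)
            expr_sub = expr_corr_full
            res = mantel_test(expr_sub, dist, config.n_perm, next_seed())
            rep = DirectionReport(direction, len(regions), res.r, res.p)
            # similarity-oriented proximity target for the optimizer
            prox = SimilarityMatrix(regions, -dist.values, "similarity")
            target = prox
        else:
            conn_corr = connectivity_correlation(conn, direction)
            regions = conn_corr.regions
            expr_sub = expr_corr_full.subset(regions)
            dist = spatial_distance(dataset.coordinates, regions, log=True)
            plain = mantel_test(expr_sub, conn_corr, config.n_perm, next_seed())
            part = partial_mantel(expr_sub, conn_corr, dist, config.n_perm, next_seed())
            rep = DirectionReport(
                direction, len(regions), plain.r, plain.p, part.r, part.p
            )
            target = residualize(conn_corr, dist)
            if config.per_division:
                for division in sorted(dataset.ontology.children(dataset.ontology.root)):
                    try:
                        e_div, c_div = subset_by_division(
                            [expr_sub, conn_corr], dataset.ontology, division
                        )
                        res_div = mantel_test(e_div, c_div, config.n_perm, next_seed())
                    except StatisticError:
                        continue
                    rep.per_division[division] = {
                        "r": res_div.r, "p": res_div.p, "n_regions": e_div.n
                    }
        if config.run_selection:
            expr_dir = expr.subset_regions(list(regions))
            trace = backward_eliminate(
                expr_dir, target, k_min=config.k_min, seed=next_seed(),
                min_overlap=config.min_overlap,
            )
            rep.peak_r = trace.peak_r
            rep.peak_size = len(trace.peak_set)
            rep.terminal_size = len(trace.terminal_set)
            rep.n_high_confidence_genes = len(
                high_confidence_genes(trace.peak_set, trace.gene_of_series)
            )
            if config.output_dir is not None:
                outdir = Path(config.output_dir)
                outdir.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(
                    rank_series(trace), columns=["series_id", "rank"]
                ).to_csv(outdir / f"ranking_{direction}.tsv", sep="\t", index=False)
                pd.DataFrame({"r": trace.r_trajectory}).to_csv(
                    outdir / f"trajectory_{direction}.tsv", sep="\t", index=False
                )
        reports.append(rep)
        tick(f"direction_{direction}")

    cvu = connected_vs_unconnected(expr_corr_full, conn)
    degrees = region_degree(conn)
    deg_arr = np.asarray(list(degrees.values()), dtype=float)
    report = RunReport(
        version=__version__,
        config={
            "synthetic": asdict(config.synthetic) if config.synthetic else None,
            "input_dir": config.input_dir,
            "directions": list(config.directions),
            "n_perm": config.n_perm,
            "k_min": config.k_min,
            "seed": config.seed,
        },
        counts={
            "n_regions": len(leaves),
            "n_edges": len(dataset.connections),
            "n_series": expr.n_series,
            "n_genes": len(expr.genes()),
            "n_outgoing_regions": len(conn.analysis_set("outgoing")),
            "n_incoming_regions": len(conn.analysis_set("incoming")),
        },
        directions=reports,
        connected_vs_unconnected={
            "mean_connected": cvu.mean_a,
            "sd_connected": cvu.sd_a,
            "n_connected": cvu.n_a,
            "mean_unconnected": cvu.mean_b,
            "sd_unconnected": cvu.sd_b,
            "n_unconnected": cvu.n_b,
            "t": cvu.t,
            "p": cvu.p,
        },
        degree_summary={
            "mean": float(deg_arr.mean()),
            "max": float(deg_arr.max()),
            "n_isolated": int((deg_arr == 0).sum()),
        },
        stage_seconds=stage_seconds,
    )
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        (outdir / "summary.txt").write_text(report.summary() + "\n")
        if config.synthetic is not None:
            config.synthetic.to_yaml(outdir / "resolved_config.yaml")
    return report
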