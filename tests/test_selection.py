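"""Backward elimination engine: incremental statistics vs naive recomputation."""

import numpy as np
import pytest

from neuromantel import (
    EliminationState,
    EliminationTrace,
    backward_eliminate,
    high_confidence_genes,
    rank_series,
    ranking_auroc,
    shuffled_optimization_control,
)
from .conftest import expression_from_values, random_similarity
from ._naive import naive_backward_eliminate, naive_mantel_r, naive_pairwise_correlation


def make_instance(n_regions, n_series, missing=0.0, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_series, n_regions))
    if missing:
        values[rng.random(values.shape) < missing] = np.nan
    expr = expression_from_values(values)
    target = random_similarity(n_regions, rng)
    return expr, target


class TestEliminationState:
    def test_sufficient_statistics_match_scratch_after_removals(self):
        expr, target = make_instance(8, 12, missing=0.1, seed=1)
        state = EliminationState(expr, target, resync_every=10**9)
        rng = np.random.default_rng(0)
        for _ in range(6):
            state.remove(int(rng.choice(np.flatnonzero(state.active))))
        scratch = naive_pairwise_correlation(
            expr.values[state.active], min_overlap=3
        )
        iu, ju = np.triu_indices(8, k=1)
        pair_r = state._pair_correlations(
            state._n, state._sx, state._sy, state._sxx, state._syy, state._sxy
        )
        assert np.allclose(pair_r, scratch[iu, ju], atol=1e-9, equal_nan=True)

    def test_leave_one_out_matches_scratch_for_every_candidate(self):
        expr, target = make_instance(10, 8, missing=0.1, seed=2)
        state = EliminationState(expr, target)
        cand, r_loo = state.leave_one_out_r()
        tvals = target.values.copy()
        for i, r in zip(cand, r_loo):
            rest = [k for k in range(expr.n_series) if k != i]
            corr = naive_pairwise_correlation(expr.values[rest], min_overlap=3)
            assert r == pytest.approx(naive_mantel_r(corr, tvals), abs=1e-9)

    def test_duplicate_series_are_exchangeable_in_leave_one_out(self):
        # removing either twin leaves the same value multiset, so their
        # leave-one-out statistics must agree exactly; and with only
        # perfectly correlated pairs (r = +-1) the statistic is unchanged
        rng = np.random.default_rng(3)
        values = rng.standard_normal((6, 6))
        values = np.vstack([values, values[0]])  # series 6 duplicates series 0
        expr = expression_from_values(values)
        target = random_similarity(6, rng)
        state = EliminationState(expr, target)
        cand, r_loo = state.leave_one_out_r()
        by_id = dict(zip((state.series[int(c)] for c in cand), r_loo))
        assert by_id["S000"] == by_id["S006"]
        # degenerate two-point-per-pair case: correlations all +-1 and robust
        # to dropping one copy of a duplicated point
        base2 = np.array([[0.0, 1.0, 2.0], [1.0, 3.0, -1.0]])
        vals2 = np.vstack([base2, base2])
        expr2 = expression_from_values(vals2)
        state2 = EliminationState(expr2, random_similarity(3, rng), min_overlap=3)
        base_r = state2.current_r()
        _, loo2 = state2.leave_one_out_r()
        assert np.allclose(loo2, base_r, atol=1e-12)

    def test_constant_series_removal_changes_nothing(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((7, 5))
        values[3] = 2.5  # constant across regions
        expr = expression_from_values(values)
        target = random_similarity(5, rng)
        state = EliminationState(expr, target)
        rest = [k for k in range(7) if k != 3]
        with_const = naive_pairwise_correlation(values, min_overlap=3)
        without = naive_pairwise_correlation(values[rest], min_overlap=3)
        # a constant series contributes equal coordinates to both vectors of
        # every pair; dropping it shifts each pairwise correlation
        cand, r_loo = state.leave_one_out_r()
        by_id = dict(zip((state.series[int(c)] for c in cand), r_loo))
        assert by_id["S003"] == pytest.approx(
            naive_mantel_r(without, target.values), abs=1e-9
        )
        assert np.isfinite(naive_mantel_r(with_const, target.values))


class TestBackwardEliminate:
    @pytest.mark.parametrize("n_regions,n_series,missing,seed", [
        (6, 6, 0.0, 0),
        (10, 12, 0.1, 1),
        (15, 20, 0.1, 2),
    ])
    def test_full_path_matches_naive_reimplementation(
        self, n_regions, n_series, missing, seed
    ):
        expr, target = make_instance(n_regions, n_series, missing, seed)
        trace = backward_eliminate(expr, target, k_min=3)
        order, traj = naive_backward_eliminate(
            expr.values, list(expr.series), target.values, k_min=3
        )
        assert trace.removal_order == order
        assert np.allclose(trace.r_trajectory, traj, atol=1e-9)

    def test_trace_invariants(self):
        expr, target = make_instance(8, 10, 0.05, seed=5)
        trace = backward_eliminate(expr, target, k_min=3)
        assert len(trace.removal_order) + len(trace.terminal_set) == expr.n_series
        assert trace.peak_r == trace.r_trajectory.max()
        assert len(trace.peak_set) == expr.n_series - trace.peak_index
        assert set(trace.peak_set) >= set(trace.terminal_set)

    def test_determinism(self):
        expr, target = make_instance(8, 10, 0.05, seed=6)
        t1 = backward_eliminate(expr, target, seed=1)
        t2 = backward_eliminate(expr, target, seed=1)
        assert t1.removal_order == t2.removal_order
        assert np.array_equal(t1.r_trajectory, t2.r_trajectory)

    def test_dominant_series_survives_to_terminal_set(self):
        # one series reproduces the target's structure; the rest are noise
        rng = np.random.default_rng(7)
        n = 8
        target = random_similarity(n, rng)
        # build a series whose outer sums align with the target: use the
        # leading eigenvector of the target matrix as the expression profile
        w, v = np.linalg.eigh(target.values)
        profile = v[:, -1] * np.sqrt(abs(w[-1])) * 4
        noise = rng.standard_normal((9, n)) * 0.5
        values = np.vstack([profile, noise, profile + 0.01 * rng.standard_normal(n)])
        expr = expression_from_values(values)
        trace = backward_eliminate(expr, target, k_min=3)
        assert "S000" in trace.terminal_set or "S010" in trace.terminal_set

    def test_planted_pair_series_rank_highly_in_signal_mode(self, small_dataset):
        from neuromantel.harmonize import build_profiles
        from neuromantel.similarity import connectivity_correlation

        ds = small_dataset
        leaves = sorted(ds.ontology.leaves())
        conn = build_profiles(ds.connections, leaves, list(ds.expression.regions))
        cc = connectivity_correlation(conn, "incoming")
        expr = ds.expression.subset_regions(cc.regions)
        trace = backward_eliminate(expr, cc)
        planted = {s for s, l in ds.truth.items() if l == "pair"}
        auroc = ranking_auroc(rank_series(trace), planted)
        assert auroc > 0.7


class TestRanking:
    def make_trace(self):
        return EliminationTrace(
            series_initial=["a", "b", "c", "d", "e"],
            removal_order=["d", "a"],
            r_trajectory=np.array([0.1, 0.3, 0.2]),
            gene_of_series={s: f"g{s}" for s in "abcde"},
        )

    def test_terminal_series_share_rank_one_then_reverse_removal(self):
        ranking = dict(rank_series(self.make_trace()))
        assert ranking == {"b": 1, "c": 1, "e": 1, "a": 4, "d": 5}

    def test_ranking_covers_all_series(self):
        assert len(rank_series(self.make_trace())) == 5

    def test_peak_set_from_first_trajectory_maximum(self):
        trace = self.make_trace()
        assert trace.peak_index == 1
        assert trace.peak_set == ["a", "b", "c", "e"]

    def test_auroc_extremes(self):
        ranking = [("p", 1), ("q", 2), ("r", 3), ("s", 4)]
        assert ranking_auroc(ranking, {"p", "q"}) == 1.0
        assert ranking_auroc(ranking, {"r", "s"}) == 0.0


class TestHighConfidence:
    def test_count_rule(self):
        genes = {"s1": "gA", "s2": "gA", "s3": "gB"}
        assert high_confidence_genes(["s1", "s2", "s3"], genes) == {"gA"}
        assert high_confidence_genes(["s1", "s3"], genes) == set()

    def test_duplicated_planted_genes_dominate_high_confidence_set(self):
        from neuromantel import SyntheticConfig, generate_dataset
        from neuromantel.harmonize import build_profiles
        from neuromantel.similarity import connectivity_correlation

        n_hc = n_planted_hc = 0
        for seed in range(5):
            ds = generate_dataset(
                SyntheticConfig(
                    n_leaf_regions=16, branching=4, n_genes=40, frac_pair=0.2,
                    duplicate_rate=0.5, seed=100 + seed,
                )
            )
            leaves = sorted(ds.ontology.leaves())
            conn = build_profiles(ds.connections, leaves, list(ds.expression.regions))
            cc = connectivity_correlation(conn, "incoming")
            expr = ds.expression.subset_regions(cc.regions)
            trace = backward_eliminate(expr, cc)
            hc = high_confidence_genes(trace.peak_set, trace.gene_of_series)
            planted_genes = {
                ds.expression.gene_of_series[s]
                for s, l in ds.truth.items() if l == "pair"
            }
            n_hc += len(hc)
            n_planted_hc += len(hc & planted_genes)
        # concordant duplicates should be dominated by planted genes
        assert n_hc >= 5
        assert n_planted_hc / n_hc >= 0.6


class TestShuffledControl:
    def test_identity_permutation_reproduces_unshuffled_peak(self):
        expr, target = make_instance(8, 10, 0.0, seed=8)
        base = backward_eliminate(expr, target)
        ctrl = shuffled_optimization_control(
            expr, target, k_runs=1, permutations=[np.arange(8)]
        )
        assert ctrl.peaks[0] == pytest.approx(base.peak_r, abs=1e-12)

    def test_records_one_peak_per_run(self):
        expr, target = make_instance(7, 8, 0.0, seed=9)
        ctrl = shuffled_optimization_control(expr, target, k_runs=4, seed=0)
        assert len(ctrl.peaks) == 4
        assert ctrl.max_peak == max(ctrl.peaks)

    def test_shuffled_peaks_below_unshuffled_in_signal_mode(self, small_dataset):
        from neuromantel.harmonize import build_profiles
        from neuromantel.similarity import connectivity_correlation

        ds = small_dataset
        leaves = sorted(ds.ontology.leaves())
        conn = build_profiles(ds.connections, leaves, list(ds.expression.regions))
        cc = connectivity_correlation(conn, "incoming")
        expr = ds.expression.subset_regions(cc.regions)
        base = backward_eliminate(expr, cc)
        ctrl = shuffled_optimization_control(expr, cc, k_runs=3, seed=5)
        assert base.peak_r > np.median(ctrl.peaks)
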