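"""Ontology handling and harmonization algebra."""

import numpy as np
import pandas as pd
import pytest

from neuromantel import (
    ConnectivityData,
    DataError,
    RegionOntology,
    build_expression_matrix,
    build_profiles,
    exclude_region_connections,
    merge_virtual_regions,
    select_leaf_regions,
    up_propagate,
)
from neuromantel.errors import ConfigurationError
from neuromantel.synthetic import generate_ontology


class TestRegionOntology:
    def test_rejects_duplicate_ids_multiple_roots_and_cycles(self):
        with pytest.raises(DataError, match="duplicate"):
            RegionOntology([("r", "r", None), ("a", "a", "r"), ("a", "b", "r")])
        with pytest.raises(DataError, match="root"):
            RegionOntology([("r1", "r1", None), ("r2", "r2", None)])
        with pytest.raises(DataError, match="cycle"):
            RegionOntology([("r", "r", None), ("a", "a", "b"), ("b", "b", "a")])

    def test_ancestors_descendants_and_leaves(self, toy_ontology):
        assert toy_ontology.ancestors("A2a") == ["A2", "A", "root"]
        assert toy_ontology.descendants("A") == {"A1", "A2", "A2a", "A2b"}
        assert set(toy_ontology.leaves()) == {"B", "A1", "A2a", "A2b"}
        assert toy_ontology.top_division("A2b") == "A"

    def test_tsv_round_trip(self, toy_ontology, tmp_path):
        path = tmp_path / "onto.tsv"
        toy_ontology.to_tsv(path)
        back = RegionOntology.from_tsv(path)
        assert back.to_frame().equals(toy_ontology.to_frame())


class TestGenerateOntology:
    def test_balanced_binary_shape(self):
        onto = generate_ontology(4, 2, seed=1)
        leaves = onto.leaves()
        assert len(leaves) == 4
        internal = [r for r in onto.ids if r not in leaves]
        assert len(internal) == 3  # root plus two division nodes

    def test_nine_leaves_three_way_all_leaves_at_depth_two(self):
        onto = generate_ontology(9, 3, seed=7)
        assert all(onto.depth(leaf) >= 2 for leaf in onto.leaves())

    def test_deterministic_given_seed(self):
        a = generate_ontology(13, 3, seed=5).to_frame()
        b = generate_ontology(13, 3, seed=5).to_frame()
        assert a.equals(b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_ontology(3, 4, seed=0)


class TestUpPropagate:
    def test_examples(self, toy_ontology):
        # single parent hop
        assert up_propagate([("A1", "B")], toy_ontology, {"A", "B"}) == [("A", "B")]
        # identity when endpoints already in targets
        assert up_propagate([("A", "B")], toy_ontology, {"A", "B"}) == [("A", "B")]
        # deduplication after mapping
        assert up_propagate(
            [("A1", "B"), ("A2", "B")], toy_ontology, {"A", "B"}
        ) == [("A", "B")]
        # self-loops after mapping are dropped
        assert up_propagate([("A1", "A2")], toy_ontology, {"A", "B"}) == []

    def test_unknown_endpoint_is_an_error(self, toy_ontology):
        with pytest.raises(DataError, match="nope"):
            up_propagate([("nope", "B")], toy_ontology, {"A", "B"})

    def test_idempotent_on_random_ontologies(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            onto = generate_ontology(12, 3, seed=seed)
            ids = onto.ids
            edges = [
                (ids[rng.integers(len(ids))], ids[rng.integers(len(ids))])
                for _ in range(30)
            ]
            targets = set(
                np.random.default_rng(seed).choice(ids, size=6, replace=False)
            )
            once = up_propagate(edges, onto, targets)
            twice = up_propagate(once, onto, targets)
            assert once == twice


class TestMergeVirtualRegions:
    @pytest.fixture
    def conn5(self):
        adj = np.array(
            [
                [0, 1, 0, 0, 0],
                [0, 0, 1, 0, 0],
                [0, 0, 0, 1, 0],
                [1, 0, 0, 0, 1],
                [0, 1, 0, 0, 0],
            ],
            dtype=np.uint8,
        )
        return ConnectivityData(list("abcde"), adj, list("abcde"))

    def test_or_of_member_rows(self, conn5):
        merged = merge_virtual_regions(conn5, {"v": {"a", "c"}})
        i = merged.regions_w.index("v")
        row = {r: merged.adjacency[i, merged.regions_w.index(r)] for r in "bde"}
        assert row == {"b": 1, "d": 1, "e": 0}

    def test_single_member_merge_is_identity_profile(self, conn5):
        merged = merge_virtual_regions(conn5, {"v": {"b"}})
        i = merged.regions_w.index("v")
        out_partners = {
            r for r in merged.regions_w if merged.adjacency[i, merged.regions_w.index(r)]
        }
        assert out_partners == {"c"}

    def test_merged_degree_equals_union_of_partner_sets(self, conn5):
        # set-union oracle on the 5-region toy
        partners = {"a": {"b"}, "c": {"d"}}
        merged = merge_virtual_regions(conn5, {"v": {"a", "c"}})
        i = merged.regions_w.index("v")
        expect = (partners["a"] | partners["c"])
        got = {
            r for r in merged.regions_w if merged.adjacency[i, merged.regions_w.index(r)]
        }
        assert got == expect

    def test_overlapping_member_sets_rejected(self, conn5):
        with pytest.raises(ConfigurationError, match="multiple"):
            merge_virtual_regions(conn5, {"v1": {"a", "b"}, "v2": {"b", "c"}})


class TestExcludeRegions:
    def test_direct_filter_and_leaf_noop(self, toy_ontology):
        edges = [("A1", "B"), ("B", "A2a"), ("A1", "A2a")]
        assert exclude_region_connections(edges, toy_ontology, "B") == [("A1", "A2a")]
        assert exclude_region_connections(edges, toy_ontology, "A2b") == edges

    def test_exclusion_covers_grandchildren(self, toy_ontology):
        edges = [("A2a", "B"), ("B", "A1")]
        # excluding A removes edges of its grandchild A2a and child A1
        assert exclude_region_connections(edges, toy_ontology, "A") == []


class TestSelectLeafRegions:
    def test_parent_with_measured_subpart_excluded(self, toy_ontology):
        assert select_leaf_regions(toy_ontology, {"A", "A1"}) == {"A1"}
        assert select_leaf_regions(toy_ontology, {"B", "A1"}) == {"B", "A1"}

    def test_matches_brute_force_on_random_trees(self):
        for seed in range(10):
            onto = generate_ontology(10, 3, seed=seed)
            rng = np.random.default_rng(seed)
            chosen = set(rng.choice(onto.ids, size=6, replace=False))
            brute = {
                r for r in chosen if not any(d in chosen for d in onto.descendants(r))
            }
            assert select_leaf_regions(onto, chosen) == brute


class TestBuildExpressionMatrix:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["series_id", "gene_symbol", "r1", "r2"])

    def test_natural_log_and_zero_to_missing(self):
        table = self.make_table([("s1", "g1", np.e, 0.0)])
        em = build_expression_matrix(table, min_region_coverage=0.0)
        assert em.values[0, 0] == pytest.approx(1.0)
        assert np.isnan(em.values[0, 1])

    def test_nonexpressed_gene_series_dropped(self):
        table = self.make_table([("s1", "g1", 1.0, 1.0), ("s2", "g2", 1.0, 1.0)])
        em = build_expression_matrix(table, nonexpressed_genes={"g1"})
        assert em.series == ["s2"]

    def test_coverage_filter_counts(self):
        rows = [(f"s{i}", "g", 1.0, 1.0) for i in range(4)]
        rows.append(("s4", "g", 1.0, np.nan))  # 50% coverage on 2 regions
        table = self.make_table(rows)
        em = build_expression_matrix(table, min_region_coverage=0.6)
        assert em.n_series == 4
        assert "s4" not in em.series


class TestBuildProfiles:
    def test_analysis_sets_from_edges(self):
        conn = build_profiles([("A", "B")], ["A", "B", "C"], ["A", "B", "C"])
        assert conn.analysis_set("outgoing") == ["A"]
        assert conn.analysis_set("incoming") == ["B"]

    def test_empty_edge_list_gives_empty_analysis_sets(self):
        conn = build_profiles([], ["A", "B"], ["A", "B"])
        assert conn.analysis_set("outgoing") == []
        assert conn.analysis_set("incoming") == []

    def test_profile_rows_equal_adjacency_rows_and_columns(self):
        edges = [("A", "B"), ("B", "A"), ("A", "C"), ("D", "C")]
        conn = build_profiles(edges, list("ABCD"), list("ABC"))
        for i, r in enumerate(conn.common_x):
            k = conn.regions_w.index(r)
            assert np.array_equal(conn.outgoing_profiles[i], conn.adjacency[k, :])
            assert np.array_equal(conn.incoming_profiles[i], conn.adjacency[:, k])

    def test_edge_conservation_in_profiles(self):
        # all regions common: total ones in each direction equals edge count
        edges = [("A", "B"), ("B", "C"), ("C", "A"), ("A", "C")]
        conn = build_profiles(edges, list("ABC"), list("ABC"))
        assert conn.outgoing_profiles.sum() == len(edges)
        assert conn.incoming_profiles.sum() == len(edges)

    def test_merge_then_exclude_commutes_when_disjoint(self, toy_ontology):
        edges = [("A1", "B"), ("A2a", "B"), ("B", "A2b")]
        universe = ["A1", "A2a", "A2b", "B"]
        # exclusion target B is not a merge member
        excl_first = exclude_region_connections(edges, toy_ontology, "B")
        conn1 = merge_virtual_regions(
            build_profiles(excl_first, universe, universe), {"v": {"A2a", "A2b"}}
        )
        conn2 = merge_virtual_regions(
            build_profiles(edges, universe, universe), {"v": {"A2a", "A2b"}}
        )
        keep = [r for r in conn2.regions_w if r != "B"]
        idx = [conn2.regions_w.index(r) for r in keep]
        sub = conn2.adjacency[np.ix_(idx, idx)]
        idx1 = [conn1.regions_w.index(r) for r in keep]
        assert np.array_equal(conn1.adjacency[np.ix_(idx1, idx1)], sub)
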