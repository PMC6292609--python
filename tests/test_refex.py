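import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netess import refex as rfx
from netess.catalogue import FeatureCatalogue, recursion_depth

import oracles
from conftest import as_network, random_network


class TestGrammar:
    @pytest.mark.parametrize(
        "name,base,depth",
        [
            ("degree", "degree", 0),
            ("sum(degree)", "degree", 1),
            ("mean(sum(wego_out))", "wego_out", 2),
        ],
    )
    def test_parse_and_depth(self, name, base, depth):
        b, ops = rfx.parse_feature(name)
        assert b == base
        assert len(ops) == depth == recursion_depth(name)

    @pytest.mark.parametrize("bad", ["deg", "sum(degree", "max(degree)", "sum()"])
    def test_bad_names_rejected(self, bad):
        with pytest.raises(ValueError, match="unparseable"):
            rfx.parse_feature(bad)


class TestBaseFeatures:
    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.5)
        bf = rfx.base_features(as_network(g))
        a = bf.loc["A"]
        assert a["degree"] == 1
        assert a["wdegree"] == pytest.approx(0.5)
        assert a["ego_within"] == 1
        assert a["ego_out"] == 0
        assert a["wego_within"] == pytest.approx(0.5)

    def test_path_interior_node(self, path4):
        b = rfx.base_features(path4).loc[1]  # egonet {0,1,2}; edge (2,3) leaves it
        assert b["ego_within"] == 2
        assert b["ego_out"] == 1

    def test_star_center_and_leaf(self, star5):
        bf = rfx.base_features(star5)
        assert bf.loc[0, "ego_within"] == 4
        assert bf.loc[0, "ego_out"] == 0
        assert bf.loc[1, "ego_within"] == 1
        assert bf.loc[1, "ego_out"] == 3

    def test_egonet_counts_match_edge_classification(self, rng):
        for _ in range(50):
            net = random_network(rng, n_max=8)
            bf = rfx.base_features(net)
            for v in net.graph:
                within, out = oracles.egonet_counts_brute(net.graph, v)
                assert bf.loc[v, "ego_within"] == within
                assert bf.loc[v, "ego_out"] == out


class TestVerticalLogBin:
    def test_worked_example(self):
        assert rfx.vertical_log_bin([1, 2, 3, 4], 0.5).tolist() == [0, 0, 1, 2]

    def test_all_equal_single_bin(self):
        assert rfx.vertical_log_bin([7, 7, 7], 0.3).tolist() == [0, 0, 0]

    def test_singleton_and_empty(self):
        assert rfx.vertical_log_bin([3.2], 0.5).tolist() == [0]
        assert rfx.vertical_log_bin([], 0.5).tolist() == []

    def test_bins_are_monotone_in_value(self, rng):
        for _ in range(20):
            vals = rng.integers(0, 5, size=12).astype(float)
            bins = rfx.vertical_log_bin(vals, float(rng.uniform(0.2, 0.8)))
            order = np.argsort(vals, kind="stable")
            assert (np.diff(bins[order]) >= 0).all()
            # ties always share a bin
            for a in range(12):
                for b in range(12):
                    if vals[a] == vals[b]:
                        assert bins[a] == bins[b]


class TestPruneFeatures:
    def test_identical_columns_collapse(self):
        m = pd.DataFrame({"degree": [1, 2, 3], "sum(degree)": [1, 2, 3]})
        cat = rfx.prune_features(m, s=0, p=0.5)
        assert cat.names == ["degree"]  # smallest depth wins

    def test_huge_threshold_keeps_one(self):
        m = pd.DataFrame({"degree": [1, 5, 9], "ego_out": [9, 1, 5], "ego_within": [0, 0, 1]})
        assert len(rfx.prune_features(m, s=100, p=0.5)) == 1

    def test_columns_binning_identically_collapse(self):
        # [1,2,3] and [1,2,4] both bin to [0,0,1] at p=0.5, so they are
        # indistinguishable to the pruner and collapse to one representative
        m = pd.DataFrame({"degree": [1, 2, 3], "ego_out": [1, 2, 4]})
        assert rfx.prune_features(m, s=0, p=0.5).names == ["degree"]

    def test_binned_disagreement_keeps_both(self):
        m = pd.DataFrame({"degree": [1, 2, 3, 4], "ego_out": [4, 3, 2, 1]})
        assert len(rfx.prune_features(m, s=0, p=0.5)) == 2


class TestExtractRefex:
    def test_regular_graph_collapses_to_single_feature(self):
        for g in (nx.cycle_graph(8), nx.complete_graph(5), nx.random_regular_graph(3, 10, seed=1)):
            _, cat = rfx.extract_refex(as_network(g))
            assert len(cat) == 1

    def test_star_neighbour_aggregates(self, star5):
        cat = FeatureCatalogue(
            ["mean(degree)", "sum(degree)"], {"mean(degree)": "regional", "sum(degree)": "regional"}
        )
        mat = rfx.compute_named(star5, cat)
        assert mat.loc[0, "mean(degree)"] == pytest.approx(1.0)
        assert mat.loc[0, "sum(degree)"] == pytest.approx(4.0)

    def test_deterministic_across_runs(self, rng):
        net = random_network(rng, n_max=8)
        m1, c1 = rfx.extract_refex(net)
        m2, c2 = rfx.extract_refex(net)
        assert c1 == c2
        pd.testing.assert_frame_equal(m1, m2)

    def test_compute_named_reproduces_extraction(self, rng):
        for _ in range(10):
            net = random_network(rng, n_max=8)
            mat, cat = rfx.extract_refex(net)
            again = rfx.compute_named(net, cat)
            pd.testing.assert_frame_equal(mat, again)

    def test_tighter_pruning_retains_at_least_as_many(self, rng):
        loose = rfx.PruneParams(threshold_schedule=lambda i: i + 1)
        tight = rfx.PruneParams(threshold_schedule=lambda i: 0)
        for _ in range(5):
            net = random_network(rng, n_max=8)
            _, cat_loose = rfx.extract_refex(net, loose)
            _, cat_tight = rfx.extract_refex(net, tight)
            assert len(cat_tight) >= len(cat_loose)


class TestComputeNamed:
    def test_degree_on_complete_graph(self, triangle):
        cat = FeatureCatalogue(["degree"], {"degree": "local"})
        assert rfx.compute_named(triangle, cat)["degree"].tolist() == [2, 2, 2]

    def test_hand_recursion_on_path(self, path4):
        # sum(degree) on path 0-1-2-3: [2, 3, 3, 2]; then mean over neighbours
        cat = FeatureCatalogue(["mean(sum(degree))"], {"mean(sum(degree))": "regional"})
        vals = rfx.compute_named(path4, cat)["mean(sum(degree))"]
        assert vals.tolist() == pytest.approx([3.0, 2.5, 2.5, 3.0])

    def test_unparseable_name_names_offender(self, triangle):
        cat = FeatureCatalogue.__new__(FeatureCatalogue)
        cat.names = ["degree", "bogus(degree)"]
        cat.categories = {"degree": "local", "bogus(degree)": "regional"}
        with pytest.raises(ValueError, match="bogus"):
            rfx.compute_named(triangle, cat)

    def test_catalogue_size_sets_column_count(self, triangle):
        cat = rfx.synthetic_reference_catalogue(36)
        assert rfx.compute_named(triangle, cat).shape[1] == 36


class TestUnionCatalogue:
    def test_union_and_idempotence(self):
        a = FeatureCatalogue(["degree"], {"degree": "local"})
        b = FeatureCatalogue(["degree", "mean(degree)"], {"degree": "local", "mean(degree)": "regional"})
        u = rfx.union_catalogue([a, b])
        assert u.names == ["degree", "mean(degree)"]
        assert rfx.union_catalogue([b, b]) == rfx.union_catalogue([b])

    def test_disjoint_sizes_add(self):
        a = rfx.synthetic_reference_catalogue(3)
        b = FeatureCatalogue(
            ["sum(ego_within)", "sum(wego_out)", "mean(wego_out)", "sum(sum(ego_out))"],
            {n: "regional" for n in ["sum(ego_within)", "sum(wego_out)", "mean(wego_out)", "sum(sum(ego_out))"]},
        )
        assert len(rfx.union_catalogue([a, b])) == 7

    def test_ordered_by_depth_then_name(self):
        b = FeatureCatalogue(
            ["sum(degree)", "degree", "mean(degree)"],
            {"sum(degree)": "regional", "degree": "local", "mean(degree)": "regional"},
        )
        assert rfx.union_catalogue([b]).names == ["degree", "mean(degree)", "sum(degree)"]
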