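import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dgnet.interactome import GeneUniverse
from dgnet.temporal_clustering import (
    DistanceMatrix,
    GeneCluster,
    assign_dgn,
    cut_tree,
    pearson_distance,
    upgma_cluster,
)


def hand_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def frame(rows):
    cols = pd.MultiIndex.from_product([["R"], [f"s{i}" for i in range(len(next(iter(rows.values()))))]])
    return pd.DataFrame.from_dict(rows, orient="index").set_axis(cols, axis=1)


class TestPearsonDistance:
    def test_perfect_correlation(self):
        d = pearson_distance(frame({"a": [1, 2, 3], "b": [2, 4, 6]}))
        assert d.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        d = pearson_distance(frame({"a": [1, 2, 3], "b": [3, 2, 1]}))
        assert d.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x, y = [1, 2, 4], [1, 3, 3]
        d = pearson_distance(frame({"a": x, "b": y}))
        assert d.d[0, 1] == pytest.approx(1 - hand_pearson(x, y), abs=1e-12)

    def test_pairwise_complete_ignores_missing(self):
        # shared positions of (a, b) are 0, 1, 3 where both observed
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 1.0, 5.0, 8.0]
        d = pearson_distance(frame({"a": x, "b": y}))
        want = 1 - hand_pearson([1, 2, 4], [2, 1, 8])
        assert d.d[0, 1] == pytest.approx(want, abs=1e-12)

    def test_too_few_shared_positions_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            pearson_distance(frame({"a": [1.0, np.nan, 3.0], "b": [np.nan, 2.0, 4.0]}))

    def test_zero_variance_profile_named(self):
        with pytest.raises(ValueError, match="a"):
            pearson_distance(frame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(0.1, 50.0), st.floats(-20.0, 20.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 6))
        d1 = pearson_distance(pd.DataFrame(X))
        X2 = X.copy()
        X2[0] = a * X2[0] + b  # positive scaling of one row
        d2 = pearson_distance(pd.DataFrame(X2))
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-9)


class TestUPGMA:
    def test_two_items(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        dend = upgma_cluster(d)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(0.4)

    def test_three_item_hand_trace(self):
        # d(A,B)=2, d(A,C)=6, d(B,C)=4: merge (A,B)@2 then with C at (6+4)/2=5
        m = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 4.0], [6.0, 4.0, 0.0]])
        dend = upgma_cluster(DistanceMatrix(["A", "B", "C"], m))
        np.testing.assert_allclose(dend.merges[:, 2], [2.0, 5.0])
        clusters = cut_tree(dend, 2)
        assert sorted(sorted(c.genes) for c in clusters) == [["A", "B"], ["C"]]

    def test_heights_monotone_on_random_matrices(self, rng):
        for _ in range(20):
            n = 10
            X = rng.normal(size=(n, 6))
            d = pearson_distance(pd.DataFrame(X, index=[f"g{i}" for i in range(n)]))
            dend = upgma_cluster(d)
            heights = dend.merges[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            upgma_cluster(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestCutTree:
    @pytest.fixture
    def dend(self, rng):
        X = rng.normal(size=(8, 5))
        return upgma_cluster(pearson_distance(pd.DataFrame(X, index=[f"g{i}" for i in range(8)])))

    def test_k_one_is_everything(self, dend):
        clusters = cut_tree(dend, 1)
        assert len(clusters) == 1 and len(clusters[0].genes) == 8

    def test_k_n_is_singletons(self, dend):
        clusters = cut_tree(dend, 8)
        assert sorted(len(c.genes) for c in clusters) == [1] * 8

    def test_out_of_range_k(self, dend):
        with pytest.raises(ValueError):
            cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cut_tree(dend, 9)

    def test_nested_refinement(self, dend):
        for k in range(1, 8):
            coarse = cut_tree(dend, k)
            fine = cut_tree(dend, k + 1)
            for f in fine:
                assert any(f.genes <= c.genes for c in coarse)

    def test_ids_follow_leaf_order(self, dend):
        clusters = cut_tree(dend, 3)
        assert [c.id for c in clusters] == ["A", "B", "C"]
        leaf_order = dend.leaf_order()
        first_leaf_position = [min(leaf_order.index(g) for g in c.genes) for c in clusters]
        assert first_leaf_position == sorted(first_leaf_position)


class TestAssignDGN:
    def test_pure_subcluster_gets_its_affiliation(self):
        universe = GeneUniverse({f"g{i}" for i in range(60)})
        sz = {f"g{i}" for i in range(20)}
        pd_u = {f"g{i}" for i in range(20, 40)}
        shared = {f"g{i}" for i in range(40, 60)}
        subs = [GeneCluster("A", set(list(sz)[:15])), GeneCluster("B", set(list(pd_u)[:15]))]
        dgns = assign_dgn(subs, {"SZ-unique": sz, "PD-unique": pd_u, "shared": shared}, universe)
        by_sub = {d.subcluster_ids[0]: d.affiliation for d in dgns}
        assert by_sub == {"A": "SZ-unique", "B": "PD-unique"}
        assert all(d.dgn_id.startswith("DGN") for d in dgns)

    def test_no_signal_is_unassigned(self, rng):
        universe = GeneUniverse({f"g{i}" for i in range(300)})
        genes = sorted(universe.genes)
        affs = {
            "SZ-unique": set(genes[:100]),
            "PD-unique": set(genes[100:200]),
            "shared": set(genes[200:]),
        }
        # a cluster sampled uniformly from the universe is enriched for nothing
        sub = GeneCluster("A", set(rng.choice(genes, 30, replace=False)))
        dgns = assign_dgn([sub], affs, universe)
        assert dgns[0].affiliation == "unassigned"

    def test_overlapping_affiliations_rejected(self):
        universe = GeneUniverse({"a", "b", "c"})
        with pytest.raises(ValueError, match="partition"):
            assign_dgn(
                [GeneCluster("A", {"a"})],
                {"SZ-unique": {"a", "b"}, "shared": {"b", "c"}},
                universe,
            )

    def test_merge_requires_quadrant_evidence(self):
        from dgnet.pca_quadrants import QuadrantAssignment

        universe = GeneUniverse({f"g{i}" for i in range(40)})
        sz = {f"g{i}" for i in range(20)}
        other = {f"g{i}" for i in range(20, 40)}
        subs = [
            GeneCluster("A", set(list(sz)[:10])),
            GeneCluster("B", set(list(sz)[10:])),
        ]
        affs = {"SZ-unique": sz, "PD-unique": other}
        # without quadrants: no merging
        dgns = assign_dgn(subs, affs, universe)
        assert len(dgns) == 2
        # same dominant quadrant: merged into one DGN
        quads = QuadrantAssignment({g: "I" for g in sz})
        merged = assign_dgn(subs, affs, universe, pca_quadrants=quads)
        assert len(merged) == 1 and merged[0].subcluster_ids == ["A", "B"]
        # different dominant quadrants: kept separate
        quads2 = QuadrantAssignment(
            {g: ("I" if g in subs[0].genes else "IV") for g in sz}
        )
        separate = assign_dgn(subs, affs, universe, pca_quadrants=quads2)
        assert len(separate) == 2
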