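import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from dgnet.enrichment_profiles import (
    EnrichmentResult,
    bh_adjust,
    build_profile_matrix,
    cluster_profiles,
    hypergeom_ora,
    hypergeom_tail,
    inverse_normal_z,
)
from dgnet.io_formats import GeneSetCollection


def bh_oracle(p):
    """Independent quadratic-time step-up implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.array([min(1.0, raw[i:].min()) for i in range(m)])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_hand_traced_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_adjusted_preserves_order(self, ps):
        adj = bh_adjust(ps)
        idx = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[idx]) >= -1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)


class TestHypergeomORA:
    def test_query_equal_to_set_is_minimal(self, simple_collection):
        uni = set("ABCDEFGHIJ")
        res = hypergeom_ora({"A", "B", "C", "D"}, simple_collection, uni)
        by_set = {r.set_id: r for r in res}
        assert by_set["S1"].k == 4
        best = min(res, key=lambda r: r.p_value)
        assert best.set_id == "S1"

    def test_shared_enumeration_example(self):
        # N=10, K=4, n=5, k=3 -> p = 66/252
        uni = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection("t", sets={"S": [f"g{i}" for i in range(4)]})
        query = {"g0", "g1", "g2", "g5", "g6"}
        res = hypergeom_ora(query, sets, uni)
        assert res[0].p_value == pytest.approx(66 / 252, rel=1e-12)

    def test_single_gene_query_closed_form(self):
        uni = {f"g{i}" for i in range(20)}
        sets = GeneSetCollection("t", sets={"S": [f"g{i}" for i in range(5)]})
        res = hypergeom_ora({"g0"}, sets, uni)
        assert res[0].p_value == pytest.approx(5 / 20, rel=1e-12)

    def test_empty_query_after_intersection_rejected(self, simple_collection):
        with pytest.raises(ValueError, match="empty"):
            hypergeom_ora({"zz"}, simple_collection, {"A", "B"})

    def test_extreme_tail_survives_in_log_space(self):
        p = hypergeom_tail(1232, 17992, 3200, 2662)
        assert 0.0 < p < 1e-300


class TestBuildProfileMatrix:
    def _res(self, entity, set_id, p):
        return EnrichmentResult(entity, set_id, 1, 1, 1, 10, p)

    def test_exact_log_values(self):
        mat = build_profile_matrix({"E": [self._res("E", "a", 1.0), self._res("E", "b", 0.001)]})
        assert mat.loc["a", "E"] == 0.0
        assert mat.loc["b", "E"] == pytest.approx(3.0)

    def test_three_by_two_fixture(self):
        ps = {"E1": {"a": 0.1, "b": 0.01, "c": 1.0}, "E2": {"a": 1e-5, "b": 0.5, "c": 0.25}}
        mat = build_profile_matrix(
            {e: [self._res(e, s, p) for s, p in d.items()] for e, d in ps.items()}
        )
        for e, d in ps.items():
            for s, p in d.items():
                assert mat.loc[s, e] == pytest.approx(-np.log10(p))

    def test_floor_keeps_values_finite(self):
        mat = build_profile_matrix({"E": [self._res("E", "a", 0.0)]})
        assert np.isfinite(mat.loc["a", "E"]) and mat.loc["a", "E"] == pytest.approx(300.0)

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_profile_matrix({"E": [self._res("E", "a", 0.1), self._res("E", "a", 0.2)]})


class TestInverseNormalZ:
    def test_median_of_odd_vector_is_zero(self):
        mat = pd.DataFrame({"E": [3.0, 1.0, 2.0, 5.0, 4.0]})
        z = inverse_normal_z(mat)
        # the median value (3.0, at row 0) sits at midrank -> z exactly 0
        assert z.loc[0, "E"] == pytest.approx(0.0, abs=1e-12)
        assert (z["E"] != 0).sum() == 4

    def test_three_distinct_values_blom_quantiles(self):
        mat = pd.DataFrame({"E": [10.0, 30.0, 20.0]})
        z = inverse_normal_z(mat)
        want = norm.ppf([(1 - 0.375) / 3.25, (2 - 0.375) / 3.25, (3 - 0.375) / 3.25])
        np.testing.assert_allclose(np.sort(z["E"]), np.sort(want), atol=1e-9)
        np.testing.assert_allclose(z["E"], want[[0, 2, 1]], atol=1e-9)

    def test_monotone_rescaling_invariance(self, rng):
        v = rng.uniform(size=12)
        mat = pd.DataFrame({"E": v})
        z1 = inverse_normal_z(mat)
        z2 = inverse_normal_z(pd.DataFrame({"E": np.exp(3 * v)}))
        np.testing.assert_allclose(z1["E"], z2["E"], atol=1e-12)

    def test_tie_free_vector_has_zero_mean(self, rng):
        v = rng.permutation(np.arange(15, dtype=float))
        z = inverse_normal_z(pd.DataFrame({"E": v}))
        assert abs(z["E"].mean()) < 1e-9

    def test_all_equal_vector_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            z = inverse_normal_z(pd.DataFrame({"E": [1.0, 1.0, 1.0]}))
        np.testing.assert_allclose(z["E"], 0.0)

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_z(pd.DataFrame({"E": [1.0, 2.0]}))


class TestClusterProfiles:
    def test_identical_columns_merge_at_zero(self, rng):
        v = rng.normal(size=10)
        z = pd.DataFrame({"E1": v, "E2": v, "E3": -v, "E4": -v})
        _, col_dend, groups = cluster_profiles(z)
        assert col_dend.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert groups["E1"] == groups["E2"] != groups["E3"] == groups["E4"]

    def test_row_permutation_invariance(self, rng):
        z = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        _, _, g1 = cluster_profiles(z)
        perm = z.sample(frac=1.0, random_state=7)
        _, _, g2 = cluster_profiles(perm)
        same = {c: g1[c] == g1["a"] for c in z.columns}
        same2 = {c: g2[c] == g2["a"] for c in z.columns}
        assert same == same2

    def test_nonfinite_rejected(self):
        z = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            cluster_profiles(z)
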