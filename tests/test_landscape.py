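import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cellplast import (
    ValidationError,
    VRConfig,
    landscape_grid,
    rank_apexes,
    ridge_component,
    scale_unit,
    valley_component,
    vr_score,
)


def cells_df(samples, clusters, xy=None, ids=None):
    n = len(samples)
    xy = np.asarray(xy, float) if xy is not None else np.zeros((n, 2))
    ids = ids or [f"c{i}" for i in range(n)]
    return pd.DataFrame(
        {"sample": samples, "cluster": clusters, "x": xy[:, 0], "y": xy[:, 1]}, index=ids
    )


class TestScaleUnit:
    def test_affine_map(self):
        np.testing.assert_allclose(scale_unit([2, 4, 6]), [0, 0.5, 1])

    def test_constant_vector_maps_to_zero(self):
        np.testing.assert_array_equal(scale_unit([5, 5, 5]), [0, 0, 0])

    def test_empty_vector_errors(self):
        with pytest.raises(ValidationError):
            scale_unit([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
    def test_endpoints(self, xs):
        out = scale_unit(xs)
        assert out.min() == 0.0
        assert out.max() in (0.0, 1.0)  # 0 for constant vectors
        assert ((out >= 0) & (out <= 1)).all()


class TestValley:
    def test_odd_and_even_medians(self):
        cells = cells_df(["A"] * 5, ["k1"] * 3 + ["k2"] * 2)
        ccat = pd.Series([0.2, 0.4, 0.6, 0.2, 0.6], index=cells.index)
        valley = valley_component(ccat, cells)
        assert valley[("A", "k1")] == pytest.approx(0.4)
        assert valley[("A", "k2")] == pytest.approx(0.4)

    def test_undefined_cells_excluded(self):
        cells = cells_df(["A"] * 3, ["k"] * 3)
        ccat = pd.Series([0.2, np.nan, 0.8], index=cells.index)
        assert valley_component(ccat, cells)[("A", "k")] == pytest.approx(0.5)

    def test_all_undefined_group_flagged_missing(self):
        cells = cells_df(["A", "A"], ["k1", "k2"])
        ccat = pd.Series([np.nan, 0.3], index=cells.index)
        valley = valley_component(ccat, cells)
        assert np.isnan(valley[("A", "k1")]) and valley[("A", "k2")] == pytest.approx(0.3)

    def test_matches_sort_and_pick_oracle(self, rng):
        vals = rng.normal(size=101)
        cells = cells_df(["A"] * 101, ["k"] * 101)
        valley = valley_component(pd.Series(vals, index=cells.index), cells)
        assert valley[("A", "k")] == np.sort(vals)[50]


class TestRidge:
    def test_six_cell_worked_fixture(self):
        """Hand-computed pipeline: cap L=0 inverse, global unit scale, product of medians.

        lengths [0, 1, 2, 4, 0.5, 1] -> inverses [inf,1,.5,.25,2,1] -> cap inf at 2
        -> scale by (x-.25)/1.75 -> [1, 3/7, 1/7, 0, 1, 3/7]
        group g1 (first 4): median = 2/7; scaled distances [0,.2,.6,1] -> median .4
        group g2 (last 2): median = (3/7+1)/2 = 5/7; distances [0,1] -> median .5
        """
        cells = cells_df(["A"] * 6, ["g1"] * 4 + ["g2"] * 2)
        lengths = pd.Series([0.0, 1.0, 2.0, 4.0, 0.5, 1.0], index=cells.index)
        centrality = pd.DataFrame(
            {"scaled_distance": [0.0, 0.2, 0.6, 1.0, 0.0, 1.0]}, index=cells.index
        )
        ridge = ridge_component(lengths, centrality, cells, VRConfig())
        assert ridge[("A", "g1")] == pytest.approx((2 / 7) * 0.4, abs=1e-12)
        assert ridge[("A", "g2")] == pytest.approx((5 / 7) * 0.5, abs=1e-12)

    def test_product_example(self):
        # median scaled inverse 0.4 and median scaled centrality 0.5 -> 0.2
        cells = cells_df(["A"] * 3, ["k"] * 3)
        # lengths chosen so global scaled inverses are [0, 0.4, 1]
        inv = np.array([1.0, 1.4, 2.0])
        lengths = pd.Series(1.0 / inv, index=cells.index)
        centrality = pd.DataFrame(
            {"scaled_distance": [0.1, 0.5, 0.9]}, index=cells.index
        )
        ridge = ridge_component(lengths, centrality, cells, VRConfig())
        assert ridge[("A", "k")] == pytest.approx(0.2, abs=1e-12)

    def test_constant_lengths_give_zero_ridge(self):
        cells = cells_df(["A"] * 4, ["k"] * 4)
        lengths = pd.Series([2.0] * 4, index=cells.index)
        centrality = pd.DataFrame({"scaled_distance": [0.0, 0.3, 0.7, 1.0]}, index=cells.index)
        assert ridge_component(lengths, centrality, cells)[("A", "k")] == 0.0

    def test_all_zero_lengths_give_zero_ridge(self):
        cells = cells_df(["A"] * 3, ["k"] * 3)
        lengths = pd.Series([0.0] * 3, index=cells.index)
        centrality = pd.DataFrame({"scaled_distance": [0.0, 0.5, 1.0]}, index=cells.index)
        assert ridge_component(lengths, centrality, cells)[("A", "k")] == 0.0

    def test_bounded(self, rng):
        n = 60
        cells = cells_df(
            rng.choice(["A", "B"], n), rng.choice(["k1", "k2", "k3"], n)
        )
        lengths = pd.Series(rng.exponential(size=n), index=cells.index)
        centrality = pd.DataFrame({"scaled_distance": rng.uniform(size=n)}, index=cells.index)
        for scope in ("global", "per_sample"):
            ridge = ridge_component(lengths, centrality, cells, VRConfig(scaling_scope=scope))
            assert ridge.between(0, 1).all()


class TestVRScore:
    def test_default_weight_examples(self):
        assert vr_score(1.0, 0.0) == pytest.approx(0.9)
        assert vr_score(0.0, 1.0) == pytest.approx(0.1)
        assert vr_score(0.5, 0.2) == pytest.approx(0.47)

    def test_table_form_and_exact_identity(self, rng):
        idx = pd.MultiIndex.from_product([["A", "B"], ["k1", "k2"]])
        valley = pd.Series(rng.uniform(-1, 1, 4), index=idx)
        ridge = pd.Series(rng.uniform(0, 1, 4), index=idx)
        tab = vr_score(valley, ridge)
        np.testing.assert_array_equal(
            tab["vr"].to_numpy(), (0.9 * valley + 0.1 * ridge).to_numpy()
        )
        assert tab["vr"].between(-0.9, 1.0).all()

    def test_key_mismatch_lists_orphans(self):
        valley = pd.Series([0.1], index=pd.MultiIndex.from_tuples([("A", "k1")]))
        ridge = pd.Series([0.2], index=pd.MultiIndex.from_tuples([("A", "k2")]))
        with pytest.raises(ValidationError, match="k2"):
            vr_score(valley, ridge)

    @given(
        v1=st.floats(-1, 1), v2=st.floats(-1, 1), r=st.floats(0, 1)
    )
    def test_strictly_increasing_in_valley(self, v1, v2, r):
        if v1 < v2:
            assert vr_score(v1, r) < vr_score(v2, r)


def _vr_table(entries):
    idx = pd.MultiIndex.from_tuples(list(entries), names=["sample", "cluster"])
    df = pd.DataFrame(index=idx)
    df["valley"] = [v for v in entries.values()]
    df["ridge"] = 0.0
    df["vr"] = df["valley"] * 0.9
    return df


class TestLandscapeAndApexes:
    def test_constant_field(self, rng):
        cells = cells_df(["A"] * 30, ["k"] * 30, xy=rng.normal(size=(30, 2)))
        vr = _vr_table({("A", "k"): 0.5 / 0.9})
        grid = landscape_grid(cells, vr, resolution=16)
        np.testing.assert_allclose(grid.heights, 0.5, atol=1e-9)

    def test_two_separated_clusters(self, rng):
        xy = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(0, 0.1, (40, 2)) + 100])
        cells = cells_df(["A"] * 80, ["k1"] * 40 + ["k2"] * 40, xy=xy)
        vr = _vr_table({("A", "k1"): 1.0, ("A", "k2"): 1 / 9})
        vr["vr"] = [0.9, 0.1]
        grid = landscape_grid(cells, vr, resolution=101, bandwidth=0.5)
        xmin, xmax, ymin, ymax = grid.extent
        gx = np.linspace(xmin, xmax, 101)
        gy = np.linspace(ymin, ymax, 101)
        # grid height near each cluster center equals that cluster's vr: every
        # cell within kernel reach shares the same score
        for center, expect in [((0.0, 0.0), 0.9), ((100.0, 100.0), 0.1)]:
            j = np.argmin(np.abs(gx - center[0]))
            i = np.argmin(np.abs(gy - center[1]))
            assert grid.heights[i, j] == pytest.approx(expect, abs=1e-6)

    def test_infinite_bandwidth_limit(self, rng):
        xy = rng.normal(size=(50, 2))
        clusters = ["k1"] * 25 + ["k2"] * 25
        cells = cells_df(["A"] * 50, clusters, xy=xy)
        vr = _vr_table({("A", "k1"): 0.8, ("A", "k2"): 0.2})
        vr["vr"] = [0.72, 0.18]
        grid = landscape_grid(cells, vr, resolution=8, bandwidth=1e9)
        np.testing.assert_allclose(grid.heights, (0.72 + 0.18) / 2, atol=1e-6)

    def test_apex_ranking_and_delta(self):
        idx = pd.MultiIndex.from_tuples(
            [("A", "c1"), ("A", "c2"), ("B", "c1"), ("B", "c2"), ("B", "c3")],
            names=["sample", "cluster"],
        )
        vr = pd.DataFrame(
            {"valley": [0.5, 0.2, 0.7, 0.1, 0.9], "ridge": 0.0}, index=idx
        )
        vr["vr"] = [0.4, 0.3, 0.6, 0.25, 0.8]
        apex = rank_apexes(vr, ["A", "B"])
        assert apex.ranking["A"] == ["c1", "c2"]
        assert apex.ranking["B"] == ["c3", "c1", "c2"]
        assert apex.delta.loc["c1", "delta_vr"] == pytest.approx(0.2)
        assert apex.unique["B"] == ["c3"]
        assert apex.unique["A"] == []
        assert "c3" not in apex.delta.index

    def test_unknown_sample_errors(self):
        vr = _vr_table({("A", "k"): 0.1})
        with pytest.raises(ValidationError, match="unknown sample"):
            rank_apexes(vr, ["A", "Z"])
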