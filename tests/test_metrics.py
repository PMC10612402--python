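import numpy as np
import pytest
from scipy.stats import rankdata

import spotvae as sv
from spotvae.errors import DomainError
from spotvae.metrics import MarkerSet, SpatialGraph


def _props_from_vector(v, type_order=("A", "B")):
    V = np.column_stack([v, 1 - v])
    ids = [f"s{i}" for i in range(len(v))]
    return sv.ProportionMatrix(V, ids, list(type_order))


def _counts_from_column(col, gene="gA"):
    ids = [f"s{i}" for i in range(len(col))]
    return sv.CountMatrix(np.asarray(col, dtype=int)[:, None], ids, [gene])


class TestMarkerCorrelation:
    def test_perfect_and_reversed_monotone(self):
        expr = np.array([1, 2, 3, 4, 5])
        props = _props_from_vector(np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
        markers = MarkerSet({"A": ["gA"]})
        out = sv.marker_correlation(props, _counts_from_column(expr), markers)
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)
        rev = sv.marker_correlation(
            props, _counts_from_column(expr[::-1]), markers
        )
        assert rev.loc[0, "spearman_rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_with_tie(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([5, 4, 3, 1, 2])  # last two swapped
        props = _props_from_vector(x)
        out = sv.marker_correlation(props, _counts_from_column(y), MarkerSet({"A": ["gA"]}))
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.loc[0, "spearman_rho"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_as_nan_not_zero(self):
        props = _props_from_vector(np.full(5, 0.5))
        out = sv.marker_correlation(
            props, _counts_from_column([1, 2, 3, 4, 5]), MarkerSet({"A": ["gA"]})
        )
        assert np.isnan(out.loc[0, "spearman_rho"])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 0.95, size=30)
        y = rng.poisson(10.0, size=30)
        props = _props_from_vector(x)
        base = sv.marker_correlation(props, _counts_from_column(y), MarkerSet({"A": ["gA"]}))
        trans = sv.marker_correlation(
            props, _counts_from_column(y * 7 + 3), MarkerSet({"A": ["gA"]})
        )
        assert base.loc[0, "spearman_rho"] == pytest.approx(trans.loc[0, "spearman_rho"])


class TestMoransI:
    def test_alternating_line_is_minus_one(self):
        """4 spots on a line, values (1,-1,1,-1), adjacent-neighbor weights
        row-standardized: I = -1 by direct hand evaluation."""
        graph = SpatialGraph(
            row_ids=["a", "b", "c", "d"],
            neighbors=np.array([[1, 1], [0, 2], [1, 3], [2, 2]]),
            weights=np.full((4, 2), 0.5),
        )
        I = sv.morans_i(np.array([1.0, -1.0, 1.0, -1.0]), graph)
        assert I == pytest.approx(-1.0, abs=1e-12)

    def test_smooth_gradient_positive(self):
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        coords = sv.SpotCoordinates(
            [f"s{i}" for i in range(100)],
            np.column_stack([xs.ravel(), ys.ravel()]).astype(float),
        )
        graph = SpatialGraph.from_coordinates(coords, k=4)
        assert sv.morans_i(ys.ravel().astype(float), graph) > 0

    def test_permutation_null_centers_near_minus_one_over_n_minus_1(self):
        rng = np.random.default_rng(1)
        xs, ys = np.meshgrid(np.arange(10), np.arange(10))
        coords = sv.SpotCoordinates(
            [f"s{i}" for i in range(100)],
            np.column_stack([xs.ravel(), ys.ravel()]).astype(float),
        )
        graph = SpatialGraph.from_coordinates(coords, k=4)
        vals = ys.ravel().astype(float)
        null = np.array(
            [sv.morans_i(rng.permutation(vals), graph) for _ in range(200)]
        )
        expected = -1.0 / (100 - 1)
        assert abs(null.mean() - expected) < 3 * null.std() / np.sqrt(200)
        # a single permuted draw lies inside the null band
        one = sv.morans_i(rng.permutation(vals), graph)
        assert abs(one - expected) < 3 * null.std() + 1e-12

    def test_constant_vector_is_nan_and_magnitude_bounded(self):
        coords = sv.SpotCoordinates(
            [f"s{i}" for i in range(20)],
            np.column_stack([np.arange(20), np.zeros(20)]).astype(float),
        )
        graph = SpatialGraph.from_coordinates(coords, k=2)
        assert np.isnan(sv.morans_i(np.ones(20), graph))
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert abs(sv.morans_i(rng.normal(size=20), graph)) <= 1.5


class TestJSDistance:
    def test_identity_disjoint_and_symmetry(self):
        assert sv.js_distance([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert sv.js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-12)
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            assert sv.js_distance(p, q) == pytest.approx(sv.js_distance(q, p))
            assert 0.0 <= sv.js_distance(p, q) <= 1.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            p, q, r = rng.dirichlet(np.ones(5), size=3)
            assert sv.js_distance(p, r) <= sv.js_distance(p, q) + sv.js_distance(q, r) + 1e-12

    def test_negative_entries_rejected(self):
        with pytest.raises(DomainError):
            sv.js_distance([-0.1, 1.1], [0.5, 0.5])


class TestEvaluateRun:
    def test_report_rows_and_self_consistency(self, small_sim):
        markers = sv.true_markers(small_sim["config"])
        report = sv.evaluate_run(
            small_sim["true_props"],
            small_sim["spatial"],
            small_sim["coords"],
            markers,
        )
        types = small_sim["true_props"].type_order
        assert len(report) == len(types) + 1  # one per type + summary
        per_type = report[report["cell_type"] != "__summary__"]
        # true proportions of a banded tissue: spatially structured and
        # positively associated with their own markers
        assert (per_type["morans_i"] > 0).all()
        assert per_type["median_marker_rho"].median() > 0.2

    def test_shuffled_proportions_lose_spatial_signal(self, small_sim):
        rng = np.random.default_rng(5)
        shuffled = sv.ProportionMatrix(
            rng.permutation(small_sim["true_props"].values),
            list(small_sim["true_props"].row_ids),
            list(small_sim["true_props"].type_order),
        )
        markers = sv.true_markers(small_sim["config"])
        report = sv.evaluate_run(
            shuffled, small_sim["spatial"], small_sim["coords"], markers
        )
        per_type = report[report["cell_type"] != "__summary__"]
        n = small_sim["spatial"].n_rows
        assert per_type["morans_i"].abs().median() < 0.1  # near the null ~ -1/(n-1)
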