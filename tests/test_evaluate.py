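"""Evaluation-point sampling, fixed bootstrap, scenarios and ANOVA."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from sors.evaluate import (
    BootstrapSet,
    ScoreMatrix,
    StudyData,
    anova_f,
    draw_bootstrap,
    relative_influence,
    run_all_scenarios,
    run_scenario,
    sample_evaluation_points,
    table2_scenarios,
)
from sors.geodata_io import BoundaryPolygon
from sors.interpolate import interp_nearest
from sors.kde_score import exact_box, grid_for, kde_surface, pooled_os_bandwidth, sors_surface
from sors.preprocess import PlanarPoints


def _unit_boundary():
    return BoundaryPolygon(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), crs_state="planar")


def _study_data(rng, n_pos=30, n_neg=30):
    coords = rng.random((n_pos + n_neg, 2))
    layer = np.array(
        ["obesogenic"] * n_pos + ["protective"] * n_neg, dtype=object
    )
    subs = np.array(["Fast_food"] * n_pos + ["supermarket"] * (n_neg // 2) + ["Park"] * (n_neg - n_neg // 2), dtype=object)
    pts = PlanarPoints(
        x=coords[:, 0], y=coords[:, 1], layer=layer, subcategory=subs, weights=np.ones(n_pos + n_neg)
    )
    return StudyData(points=pts, boundary=_unit_boundary())


class TestScenarioTable:
    def test_nineteen_scenarios_in_five_families(self):
        scenarios = table2_scenarios()
        assert len(scenarios) == 19
        families = {}
        for s in scenarios:
            families.setdefault(s.parameter, []).append(s)
        assert {k: len(v) for k, v in families.items()} == {
            "bandwidth": 5,
            "edge_correction": 5,
            "grid_points": 3,
            "interpolation": 4,
            "weighting": 2,
        }

    def test_base_case_appears_in_every_family(self):
        scenarios = table2_scenarios()
        base_ids = [s.level_id for s in scenarios if s.is_base_case]
        assert base_ids == ["BW3", "EC1", "GP1", "INT1", "WT1"]

    def test_scenario_settings(self):
        by_id = {s.level_id: s for s in table2_scenarios()}
        assert by_id["BW1"].bandwidth_multiplier == pytest.approx(1 / 3)
        assert by_id["BW5"].bandwidth_multiplier == pytest.approx(5 / 3)
        assert by_id["EC5"].expansion_factor == 3.0
        assert by_id["GP3"].grid_n == 105
        assert by_id["INT4"].interp_method == "kriging"
        assert by_id["WT2"].weighting == "double_supermarket_gym"


class TestEvaluationPoints:
    def test_all_points_inside_polygon(self):
        poly = Polygon([(0, 0), (2, 0), (1, 1.5)])
        b = BoundaryPolygon(poly, crs_state="planar")
        pts = sample_evaluation_points(b, N=200, seed=5)
        assert all(poly.contains(Point(x, y)) for x, y in pts)

    def test_seed_determinism(self):
        b = _unit_boundary()
        a = sample_evaluation_points(b, N=50, seed=9)
        c = sample_evaluation_points(b, N=50, seed=9)
        d = sample_evaluation_points(b, N=50, seed=10)
        np.testing.assert_array_equal(a, c)
        assert not np.array_equal(a, d)

    def test_uniform_over_unit_square(self):
        pts = sample_evaluation_points(_unit_boundary(), N=10_000, seed=1)
        se = 1.0 / np.sqrt(12 * len(pts))  # sd of uniform mean
        assert np.all(np.abs(pts.mean(axis=0) - 0.5) < 3 * se)


class TestBootstrap:
    def test_resample_shapes(self):
        boots = draw_bootstrap(17, 23, B=50, seed=2)
        assert boots.pos_idx.shape == (50, 17)
        assert boots.neg_idx.shape == (50, 23)
        assert boots.pos_idx.max() < 17 and boots.neg_idx.max() < 23

    def test_single_point_layer_resamples_itself(self):
        boots = draw_bootstrap(1, 5, B=10, seed=0)
        assert (boots.pos_idx == 0).all()

    def test_expected_distinct_fraction(self):
        # with-replacement combinatorics: P(index appears) -> 1 - 1/e
        n = 500
        boots = draw_bootstrap(n, 2, B=200, seed=3)
        distinct = np.array([len(np.unique(row)) for row in boots.pos_idx]) / n
        assert distinct.mean() == pytest.approx(1 - np.exp(-1), abs=0.01)


class TestAnovaF:
    def test_textbook_two_group_example(self):
        # groups {0,2} and {1,3}: between = 2*(0.5^2+0.5^2)/1 = 1,
        # within = (1+1+1+1)/(2*1)... direct oracle value is 0.5
        m = ScoreMatrix(values=np.array([[0.0, 2.0], [1.0, 3.0]]), scenario_id="t")
        assert anova_f(m) == pytest.approx(0.5)

    def test_all_equal_cells_gives_sentinel(self):
        m = ScoreMatrix(values=np.ones((3, 4)), scenario_id="t")
        with pytest.warns(UserWarning):
            assert anova_f(m) == np.inf

    def test_matches_brute_force_sums_of_squares(self, rng):
        for _ in range(100):
            y = rng.normal(size=(rng.integers(2, 8), rng.integers(2, 9)))
            n, b = y.shape
            grand = y.mean()
            between = sum(b * (y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
            within = sum(
                (y[i, j] - y[i].mean()) ** 2 for i in range(n) for j in range(b)
            ) / (n * (b - 1))
            expected = between / within
            assert anova_f(ScoreMatrix(values=y, scenario_id="r")) == pytest.approx(
                expected, abs=1e-9 * max(1.0, abs(expected))
            )

    def test_invariant_under_affine_score_transform(self, rng):
        y = rng.normal(size=(10, 20))
        f0 = anova_f(ScoreMatrix(values=y, scenario_id="a"))
        f1 = anova_f(ScoreMatrix(values=3.7 * y - 11.0, scenario_id="b"))
        assert f1 == pytest.approx(f0, rel=1e-12)

    def test_null_distribution_center(self, rng):
        # all groups identically distributed: F concentrates near 1
        from scipy import stats

        y = rng.normal(size=(50, 1000))
        f = anova_f(ScoreMatrix(values=y, scenario_id="null"))
        lo, hi = stats.f.ppf([0.005, 0.995], 49, 50 * 999)
        assert lo < f < hi


class TestRunScenario:
    def _setup(self, rng):
        data = _study_data(rng)
        eps = sample_evaluation_points(data.boundary, N=10, seed=0)
        return data, eps

    def test_duplicated_bootstrap_columns_are_identical(self, rng):
        data, eps = self._setup(rng)
        idx_pos = np.tile(rng.integers(0, 30, size=(1, 30)), (2, 1))
        idx_neg = np.tile(rng.integers(0, 30, size=(1, 30)), (2, 1))
        boots = BootstrapSet(pos_idx=idx_pos, neg_idx=idx_neg, seed=0)
        spec = table2_scenarios()[2]  # base case
        m = run_scenario(spec, data, eps, boots)
        np.testing.assert_array_equal(m.values[:, 0], m.values[:, 1])

    def test_weighting_scenarios_coincide_without_target_subcategories(self, rng):
        data = _study_data(rng)
        data.points.subcategory[:] = "Fast_food"  # no supermarkets or gyms
        eps = sample_evaluation_points(data.boundary, N=8, seed=1)
        boots = draw_bootstrap(30, 30, B=5, seed=2)
        by_id = {s.level_id: s for s in table2_scenarios()}
        m1 = run_scenario(by_id["WT1"], data, eps, boots)
        m2 = run_scenario(by_id["WT2"], data, eps, boots)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_identity_resample_matches_direct_surface_at_node(self, rng):
        # B = 1 with the identity resample and nearest interpolation at an
        # exact grid node must reproduce the node value built directly
        data = _study_data(rng)
        boots = BootstrapSet(
            pos_idx=np.arange(30)[None, :], neg_idx=np.arange(30)[None, :], seed=0
        )
        grid = grid_for(exact_box(data.boundary), 1.4)
        xs, ys = grid.node_axes()
        node_p = (xs[17], ys[20])  # interior node
        spec = next(s for s in table2_scenarios() if s.interp_method == "nearest")
        m = run_scenario(spec, data, np.array([node_p, node_p]), boots)
        pos = data.points.select_layer("obesogenic")
        neg = data.points.select_layer("protective")
        h = pooled_os_bandwidth(pos, neg)
        direct = sors_surface(kde_surface(pos, h, grid), kde_surface(neg, h, grid))
        assert m.values[0, 0] == pytest.approx(interp_nearest(direct, node_p), abs=1e-12)
        assert m.values[0, 0] == pytest.approx(direct.values[17, 20], abs=1e-12)


class TestFullGridAndInfluence:
    def test_f_table_complete_and_deterministic(self, rng):
        data = _study_data(rng)
        eps = sample_evaluation_points(data.boundary, N=12, seed=3)
        boots = draw_bootstrap(30, 30, B=20, seed=4)
        ft1 = run_all_scenarios(data, eps, boots, area="test")
        ft2 = run_all_scenarios(data, eps, boots, area="test")
        assert len(ft1.rows) == 19
        assert [r.f_value for r in ft1.rows] == [r.f_value for r in ft2.rows]
        assert all(r.f_value > 0 for r in ft1.rows)

    def test_fixed_bootstrap_makes_f_depend_on_settings_only(self, rng):
        # same scenario, same bootstrap set -> same F, across two EP seeds
        data = _study_data(rng)
        boots = draw_bootstrap(30, 30, B=10, seed=5)
        spec = table2_scenarios()[0]
        for ep_seed in (6, 7):
            eps = sample_evaluation_points(data.boundary, N=9, seed=ep_seed)
            f1 = anova_f(run_scenario(spec, data, eps, boots))
            f2 = anova_f(run_scenario(spec, data, eps, boots))
            assert f1 == f2

    def test_relative_influence_examples(self):
        from sors.evaluate import FRow, FTable

        rows = [
            FRow("a", "BW1", "bandwidth", 50.0),
            FRow("a", "BW2", "bandwidth", 150.0),
            FRow("a", "BW3", "bandwidth", 100.0),
            FRow("a", "BW4", "bandwidth", 100.0),
            FRow("a", "BW5", "bandwidth", 100.0),
            FRow("a", "WT1", "weighting", 80.0),
            FRow("a", "WT2", "weighting", 80.0),
        ]
        infl = relative_influence(FTable(rows=rows))
        assert infl["bandwidth"] == pytest.approx(1.0)  # (150 - 50) / 100
        assert infl["weighting"] == 0.0
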