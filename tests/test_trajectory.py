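"""Branch selection, trajectory curve, joint density and proportions."""

import numpy as np
import pytest

from celldensity.containers import StateMatrix
from celldensity.trajectory import (
    BranchThreshold,
    FateAnnotatedCells,
    JointDensityGrid,
    TrajectoryCurve,
    assign_celltype,
    branch_threshold,
    fit_trajectory_curve,
    marginal_proportions,
    select_branch_cells,
)


def _cells(pt, fp, coords=None):
    n = len(pt)
    if coords is None:
        coords = np.column_stack([np.asarray(pt), np.zeros(n)])
    return FateAnnotatedCells(StateMatrix(coords), np.asarray(pt), np.asarray(fp))


WORKED_PT = [0.1, 0.2, 0.3, 0.4, 0.5]
WORKED_FP = [0.1, 0.2, 0.5, 0.9, 0.95]


class TestBranchThreshold:
    def test_constant_probability(self):
        cells = _cells([0.1, 0.4, 0.7], [0.3, 0.3, 0.3])
        thr = branch_threshold(cells, grid_points=100)
        populated = thr.grid >= 0.1
        np.testing.assert_allclose(thr.values[populated], 0.3)

    def test_nondecreasing(self):
        rng = np.random.default_rng(0)
        cells = _cells(rng.uniform(size=80), rng.uniform(size=80))
        thr = branch_threshold(cells)
        assert np.all(np.diff(thr.values) >= 0)

    def test_worked_example_percentile(self):
        cells = _cells(WORKED_PT, WORKED_FP)
        thr = branch_threshold(cells, grid_points=501)  # grid hits 0.3 exactly
        # at t=0.3 the prefix is {0.1, 0.2, 0.5}; 99th linear percentile:
        expected = np.percentile([0.1, 0.2, 0.5], 99)
        g = np.argmin(np.abs(thr.grid - 0.3))
        assert thr.values[g] == pytest.approx(expected)

    def test_evaluation_uses_next_larger_grid_point_and_clamps(self):
        thr = BranchThreshold(np.array([0.0, 0.5, 1.0]), np.array([0.1, 0.2, 0.3]))
        assert thr(0.4) == pytest.approx(0.2)
        assert thr(0.5) == pytest.approx(0.2)
        assert thr(2.0) == pytest.approx(0.3)  # beyond grid: final point


class TestSelectBranchCells:
    def test_equal_probabilities_select_all(self):
        cells = _cells([0.1, 0.5, 0.9], [0.4, 0.4, 0.4])
        assert select_branch_cells(cells).size == 3

    def test_worked_example_against_brute_force(self):
        cells = _cells(WORKED_PT, WORKED_FP)
        thr = branch_threshold(cells, grid_points=500)
        chosen = select_branch_cells(cells, epsilon=0.01, threshold=thr)
        expected = [
            i
            for i in range(5)
            if WORKED_FP[i] > thr(WORKED_PT[i]) - 0.01
        ]
        np.testing.assert_array_equal(chosen, expected)

    def test_monotone_in_epsilon(self):
        rng = np.random.default_rng(1)
        cells = _cells(rng.uniform(size=60), rng.uniform(size=60))
        small = set(select_branch_cells(cells, epsilon=0.01).tolist())
        large = set(select_branch_cells(cells, epsilon=0.2).tolist())
        assert small <= large


class TestTrajectoryCurve:
    def test_recovers_straight_segment(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(size=200)
        X = np.column_stack([s, 2 * s]) + rng.normal(scale=0.01, size=(200, 2))
        cells = _cells(s, np.ones(200), coords=X)
        curve = fit_trajectory_curve(cells)
        grid = np.linspace(0.1, 0.9, 30)
        vals = curve(grid)
        assert np.max(np.abs(vals[:, 0] - grid)) < 0.05
        assert np.max(np.abs(vals[:, 1] - 2 * grid)) < 0.05

    def test_constant_coordinate_gives_mean(self):
        s = np.linspace(0, 1, 50)
        X = np.column_stack([s, np.full(50, 7.0)])
        cells = _cells(s, np.ones(50), coords=X)
        curve = fit_trajectory_curve(cells)
        np.testing.assert_allclose(curve(np.linspace(0, 1, 9))[:, 1], 7.0, atol=1e-6)

    def test_too_few_cells_rejected(self):
        cells = _cells([0.1, 0.2], [1.0, 1.0], coords=np.zeros((2, 2)) + [[0], [1]])
        with pytest.raises(ValueError):
            fit_trajectory_curve(cells, branch_indices=[0, 1])


class _GaussianDensity:
    """Stand-in log-density function peaked at a centre (synthetic)."""

    def __init__(self, center, scale=1.0, offset=0.0):
        self.center = np.asarray(center, dtype=float)
        self.scale = scale
        self.offset = offset

    def predict(self, X):
        X = np.atleast_2d(X)
        return (
            -0.5 * np.sum((X - self.center) ** 2, axis=1) / self.scale**2
            + self.offset
        )


class TestAssignCelltype:
    def _line_curve(self):
        s = np.linspace(0, 1, 80)
        X = np.column_stack([s, np.zeros(80)])
        cells = _cells(s, np.ones(80), coords=X)
        return fit_trajectory_curve(cells)

    def test_single_type_everywhere(self):
        curve = self._line_curve()
        lab = assign_celltype(curve, {"only": _GaussianDensity([0.5, 0.0])}, [0.1, 0.9])
        assert set(lab) == {"only"}

    def test_two_types_switch_once_at_crossing(self):
        curve = self._line_curve()
        dens = {
            "early": _GaussianDensity([0.0, 0.0]),
            "late": _GaussianDensity([1.0, 0.0]),
        }
        s_grid = np.linspace(0.05, 0.95, 91)
        lab = assign_celltype(curve, dens, s_grid)
        switches = np.sum(lab[:-1] != lab[1:])
        assert switches == 1
        assert lab[0] == "early" and lab[-1] == "late"

    def test_common_offset_invariance(self):
        curve = self._line_curve()
        s_grid = np.linspace(0, 1, 41)
        base = assign_celltype(
            curve,
            {"a": _GaussianDensity([0.2, 0]), "b": _GaussianDensity([0.8, 0])},
            s_grid,
        )
        shifted = assign_celltype(
            curve,
            {
                "a": _GaussianDensity([0.2, 0], offset=3.3),
                "b": _GaussianDensity([0.8, 0], offset=3.3),
            },
            s_grid,
        )
        np.testing.assert_array_equal(base, shifted)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            assign_celltype(self._line_curve(), {}, [0.5])


class TestMarginalProportions:
    def _uniform_grid(self, n_s=201, n_t=4):
        s = np.linspace(0, 1, n_s)
        t = np.arange(n_t, dtype=float)
        return JointDensityGrid(s, t, np.zeros((n_s, n_t)))

    def test_rows_sum_to_one(self):
        grid = self._uniform_grid()
        rng = np.random.default_rng(3)
        grid = JointDensityGrid(
            grid.s_grid, grid.t_grid, rng.normal(size=grid.log_density.shape)
        )
        ann = np.where(grid.s_grid < 0.6, "a", "b")
        props = marginal_proportions(grid, ann)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-8)

    def test_single_type_is_one(self):
        grid = self._uniform_grid()
        props = marginal_proportions(grid, np.full(201, "only"))
        np.testing.assert_allclose(props.to_numpy(), 1.0)

    def test_uniform_density_segment_lengths(self):
        # constant density, types occupying segments 0.3 / 0.7: the boundary
        # 0.3 falls exactly on a grid point of the 201-point grid
        grid = self._uniform_grid()
        ann = np.where(grid.s_grid < 0.3, "short", "long")
        props = marginal_proportions(grid, ann)
        np.testing.assert_allclose(props["short"], 0.3, atol=1e-3)
        np.testing.assert_allclose(props["long"], 0.7, atol=1e-3)


class TestFateAnnotatedCells:
    def test_rescales_pseudotime_outside_unit_interval(self):
        cells = _cells([0.0, 5.0, 10.0], [0.1, 0.2, 0.3])
        assert cells.pseudotime_rescaled
        np.testing.assert_allclose(cells.pseudotime, [0.0, 0.5, 1.0])

    def test_rejects_bad_fate_probability(self):
        with pytest.raises(ValueError):
            _cells([0.0, 0.5, 1.0], [0.1, 0.2, 1.5])
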