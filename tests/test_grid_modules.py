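"""Single-module math: transform, path integration, rhombus metric, readout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridcolumn import grid_modules as gm

SQRT3 = math.sqrt(3.0)


def params_with(scale=1.0, orientation=0.0, w=6):
    return gm.GridModuleParams(
        scale=scale,
        orientation=orientation,
        cells_per_axis=w,
        bump_sigma=0.18172 * 6 / w,
        readout_resolution=(1 / 3) * 6 / w,
    )


# -- transform ---------------------------------------------------------


class TestMakeTransform:
    def test_axis_aligned_unit_scale(self):
        M = gm.make_transform(params_with(scale=1.0))
        expected = np.array([[1.0, -1.0 / SQRT3], [0.0, 2.0 / SQRT3]])
        np.testing.assert_allclose(M, expected, atol=1e-12)

    def test_transform_scales_inversely_with_lattice_period(self):
        M1 = gm.make_transform(params_with(scale=1.0))
        M2 = gm.make_transform(params_with(scale=2.0))
        np.testing.assert_allclose(M2, M1 / 2.0, atol=1e-12)

    @pytest.mark.parametrize("scale,orientation", [(1.0, 0.0), (1.5, 6.0), (0.7, 59.0)])
    def test_matches_matrix_inverse_oracle(self, scale, orientation):
        t = math.radians(orientation)
        basis = scale * np.array(
            [
                [math.cos(t), math.cos(t + math.pi / 3)],
                [math.sin(t), math.sin(t + math.pi / 3)],
            ]
        )
        M = gm.make_transform(params_with(scale=scale, orientation=orientation))
        np.testing.assert_allclose(M, np.linalg.inv(basis), atol=1e-12)

    @given(
        scale=st.floats(0.1, 10.0),
        orientation=st.floats(0.0, 59.999),
    )
    @settings(deadline=None, max_examples=50)
    def test_first_basis_vector_maps_to_unit_phase_step(self, scale, orientation):
        p = params_with(scale=scale, orientation=orientation)
        M = gm.make_transform(p)
        t = math.radians(orientation)
        first_basis = scale * np.array([math.cos(t), math.sin(t)])
        np.testing.assert_allclose(M @ first_basis, [1.0, 0.0], atol=1e-9)

    def test_rejects_nonfinite_params(self):
        with pytest.raises(ValueError):
            params_with(scale=float("nan"))


# -- path integration --------------------------------------------------


class TestPathIntegrate:
    def test_zero_movement_is_identity(self):
        state = gm.ModuleBumpState([[0.2, 0.7]])
        M = gm.make_transform(params_with())
        out = gm.path_integrate(state, [0.0, 0.0], M)
        np.testing.assert_allclose(out.bumps, state.bumps)

    def test_known_shift(self):
        # M @ (0.5, 0) = (0.5, 0) for the unit axis-aligned module
        state = gm.ModuleBumpState([[0.2, 0.2]])
        M = gm.make_transform(params_with(scale=1.0))
        out = gm.path_integrate(state, [0.5, 0.0], M)
        np.testing.assert_allclose(out.bumps, [[0.7, 0.2]], atol=1e-12)

    def test_union_bump_count_preserved(self, rng):
        state = gm.ModuleBumpState(rng.random((5, 2)))
        M = gm.make_transform(params_with(scale=1.5, orientation=24.0))
        out = gm.path_integrate(state, rng.normal(size=2), M)
        assert out.num_bumps == 5

    def test_rejects_nonfinite_movement(self):
        state = gm.ModuleBumpState([[0.2, 0.2]])
        M = gm.make_transform(params_with())
        with pytest.raises(ValueError):
            gm.path_integrate(state, [np.inf, 0.0], M)

    @given(
        moves=st.lists(
            st.tuples(st.floats(-3, 3), st.floats(-3, 3)), min_size=1, max_size=6
        ),
        orientation=st.floats(0, 59.9),
        scale=st.floats(0.5, 3.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_closed_path_returns_to_start(self, moves, orientation, scale):
        """Any movement sequence summing to zero restores every bump phase."""
        M = gm.make_transform(params_with(scale=scale, orientation=orientation))
        start = gm.ModuleBumpState([[0.3, 0.8], [0.11, 0.45]])
        state = start
        for m in moves:
            state = gm.path_integrate(state, m, M)
        total = np.sum(np.asarray(moves), axis=0)
        state = gm.path_integrate(state, -total, M)
        diff = np.abs(state.bumps - start.bumps)
        wrap = np.minimum(diff, 1.0 - diff)
        assert np.all(wrap < 1e-9)

    @given(
        d1=st.tuples(st.floats(-2, 2), st.floats(-2, 2)),
        d2=st.tuples(st.floats(-2, 2), st.floats(-2, 2)),
        orientation=st.floats(0, 59.9),
    )
    @settings(deadline=None, max_examples=60)
    def test_group_property(self, d1, d2, orientation):
        """Integrating d1 then d2 equals integrating d1 + d2 (mod 1)."""
        M = gm.make_transform(params_with(orientation=orientation))
        start = gm.ModuleBumpState([[0.25, 0.6]])
        two_step = gm.path_integrate(gm.path_integrate(start, d1, M), d2, M)
        one_step = gm.path_integrate(start, np.add(d1, d2), M)
        diff = np.abs(two_step.bumps - one_step.bumps)
        wrap = np.minimum(diff, 1.0 - diff)
        assert np.all(wrap < 1e-9)


# -- rhombus metric ----------------------------------------------------


class TestRhombusDistance:
    def test_zero_iff_equal(self):
        assert gm.rhombus_distance([0.3, 0.4], [0.3, 0.4]) == 0.0
        assert gm.rhombus_distance([0.3, 0.4], [0.31, 0.4]) > 0.0

    def test_wraps_across_edge(self):
        assert gm.rhombus_distance([0.0, 0.0], [0.9, 0.0]) == pytest.approx(0.1)

    def test_diagonal_with_wrap_offset(self):
        # minimizing offset is (0, -1): B @ (0.5, -0.5) has norm 0.5
        assert gm.rhombus_distance([0.0, 0.0], [0.5, 0.5]) == pytest.approx(0.5)

    @given(
        a=st.tuples(st.floats(0, 0.999), st.floats(0, 0.999)),
        b=st.tuples(st.floats(0, 0.999), st.floats(0, 0.999)),
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetric_and_wider_offset_search_agrees(self, a, b):
        """The 3x3 wrap-offset search is sufficient: a brute-force 5x5 search
        never finds a shorter distance, and the metric is symmetric."""
        d = gm.rhombus_distance(a, b)
        assert d == pytest.approx(gm.rhombus_distance(b, a), abs=1e-12)
        diff = np.subtract(a, b)
        brute = min(
            np.linalg.norm(gm.RHOMBUS_BASIS @ (diff + [i, j]))
            for i in range(-2, 3)
            for j in range(-2, 3)
        )
        assert d == pytest.approx(brute, abs=1e-12)


# -- bump readout ------------------------------------------------------


class TestBumpActivation:
    def test_cell_at_bump_center_fully_active(self, baseline_params):
        grid = gm.CellPhaseGrid(6)
        state = gm.ModuleBumpState([grid.phases[14]])
        a = gm.bump_activation(grid, state, baseline_params.bump_sigma)
        assert a[14] == pytest.approx(1.0)

    def test_single_bump_at_distance_sigma(self):
        sigma = 0.1
        grid = gm.CellPhaseGrid(1)  # single cell at (0.5, 0.5)
        state = gm.ModuleBumpState([[0.5 + sigma, 0.5]])
        a = gm.bump_activation(grid, state, sigma)
        assert a[0] == pytest.approx(math.exp(-0.5), rel=1e-9)

    def test_probabilistic_or_of_two_half_activations(self):
        # place two bumps each at the distance giving a_{c,b} = 0.5
        sigma = 0.1
        d_half = sigma * math.sqrt(2 * math.log(2))
        grid = gm.CellPhaseGrid(1)
        state = gm.ModuleBumpState(
            [[0.5 + d_half, 0.5], [0.5 - d_half, 0.5]]
        )
        a = gm.bump_activation(grid, state, sigma)
        assert a[0] == pytest.approx(0.75, rel=1e-9)

    def test_empty_bump_set_gives_all_zero(self, baseline_params):
        grid = gm.CellPhaseGrid(6)
        a = gm.bump_activation(grid, gm.ModuleBumpState(), baseline_params.bump_sigma)
        assert np.all(a == 0.0)

    def test_adding_a_bump_never_decreases_activation(self, rng, baseline_params):
        """Probabilistic-OR bound: union activation >= max single-bump
        activation, <= 1, and monotone in the bump set."""
        grid = gm.CellPhaseGrid(6)
        sigma = baseline_params.bump_sigma
        bumps = rng.random((4, 2))
        a_union = gm.bump_activation(grid, gm.ModuleBumpState(bumps), sigma)
        singles = [
            gm.bump_activation(grid, gm.ModuleBumpState([b]), sigma) for b in bumps
        ]
        assert np.all(a_union <= 1.0 + 1e-12)
        assert np.all(a_union >= np.max(singles, axis=0) - 1e-12)
        a_three = gm.bump_activation(grid, gm.ModuleBumpState(bumps[:3]), sigma)
        assert np.all(a_union >= a_three - 1e-12)


class TestActivationThreshold:
    def test_approaches_one_as_resolution_vanishes(self):
        assert gm.activation_threshold(1e-9, 0.18172) == pytest.approx(1.0)

    def test_baseline_value(self):
        # exp(-((1/6) * 2/sqrt(3))^2 / (2 * 0.18172^2))
        assert gm.activation_threshold(1 / 3, 0.18172) == pytest.approx(0.5708, abs=1e-4)

    def test_strictly_decreasing_in_resolution(self):
        values = [gm.activation_threshold(d, 0.18172) for d in (0.1, 0.2, 0.4, 0.8)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestActiveCells:
    @pytest.mark.parametrize("w", [6, 12])
    def test_single_bump_activates_four_to_seven_cells(self, w):
        """With the bump size fixed relative to the cells, any single bump
        activates between 4 and 7 cells (coarse sweep; the dense sweep is in
        the acceptance suite)."""
        counts = gm.sweep_active_cell_counts(params_with(w=w), resolution=60)
        assert counts.min() == 4
        assert counts.max() == 7

    def test_readout_coverage_no_gaps(self):
        """Every bump position activates at least one cell."""
        counts = gm.sweep_active_cell_counts(params_with(w=6), resolution=120)
        assert counts.min() >= 1

    def test_all_zero_activation_gives_no_active_cells(self):
        assert not np.any(gm.active_cells(np.zeros(36), 0.5))


class TestWinnerCell:
    def test_bump_on_cell_phase_wins(self, baseline_params):
        grid = gm.CellPhaseGrid(6)
        state = gm.ModuleBumpState([grid.phases[21]])
        a = gm.bump_activation(grid, state, baseline_params.bump_sigma)
        assert gm.winner_cell(a) == 21

    def test_tie_breaks_to_lowest_index(self):
        a = np.array([0.2, 0.9, 0.9, 0.1])
        assert gm.winner_cell(a) == 1

    def test_empty_activation_raises(self):
        with pytest.raises(ValueError):
            gm.winner_cell(np.zeros(36))

    def test_winner_is_always_an_active_cell(self, rng, baseline_params):
        """Learning resolution is finer than readout resolution, so the
        winner always clears the readout threshold."""
        grid = gm.CellPhaseGrid(6)
        thr = gm.activation_threshold(
            baseline_params.readout_resolution, baseline_params.bump_sigma
        )
        for _ in range(200):
            state = gm.ModuleBumpState([rng.random(2)])
            a = gm.bump_activation(grid, state, baseline_params.bump_sigma)
            assert a[gm.winner_cell(a)] >= thr


class TestDedup:
    def test_merges_phases_within_tolerance(self):
        phases = np.array([[0.5, 0.5], [0.5005, 0.5], [0.2, 0.2]])
        out = gm.dedup_phases(phases, 0.01)
        assert len(out) == 2
        np.testing.assert_allclose(out[0], [0.5, 0.5])

    def test_merges_across_wrap(self):
        phases = np.array([[0.999, 0.5], [0.001, 0.5]])
        assert len(gm.dedup_phases(phases, 0.01)) == 1

    def test_keeps_separated_phases(self):
        phases = np.array([[0.1, 0.1], [0.5, 0.5]])
        assert len(gm.dedup_phases(phases, 0.05)) == 2


class TestCodeCapacity:
    def test_joint_state_count(self):
        assert gm.joint_state_count(10, 25) == 25**10

    def test_readout_position_count(self):
        assert gm.readout_position_count(1 / 4) == 16
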