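"""Basin finding, minimax paths vs exhaustive enumeration, TI, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covfes.analysis import (
    LambdaSchedule,
    ReactionPath,
    WATERSWAP_LAMBDAS,
    activation_reaction_energies,
    aggregate_replicates,
    find_minima,
    minimax_path,
    nearest_basin,
    profile_delta,
    ti_integrate,
)
from covfes.fes import FreeEnergySurface


def grid_fes(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    centers = tuple(np.arange(n, dtype=float) for n in values.shape)
    return FreeEnergySurface(centers, values, mask)


def _neighbors8(c, shape):
    i, j = c
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < shape[0] and 0 <= b < shape[1]:
                yield (a, b)


def brute_force_minimax(values, start, end):
    """Independent bottleneck oracle: the smallest level L, scanned over the
    sorted cell energies, at which start and end are BFS-connected within
    the sublevel set {A <= L}."""
    values = np.asarray(values, dtype=float)

    def connected(level):
        if values[start] > level or values[end] > level:
            return False
        seen = {start}
        queue = [start]
        while queue:
            cell = queue.pop()
            if cell == end:
                return True
            for nb in _neighbors8(cell, values.shape):
                if nb not in seen and values[nb] <= level:
                    seen.add(nb)
                    queue.append(nb)
        return False

    for level in np.unique(values):
        if connected(level):
            return float(level)
    raise AssertionError("grid must be connected at its maximum level")


def enumerate_paths_minimax(values, start, end):
    """Truly exhaustive enumeration of all simple paths (small grids only)."""
    best = [np.inf]

    def dfs(cell, seen, cur_max):
        if cell == end:
            best[0] = min(best[0], cur_max)
            return
        for nb in _neighbors8(cell, values.shape):
            if nb not in seen:
                dfs(nb, seen | {nb}, max(cur_max, values[nb]))

    dfs(start, {start}, values[start])
    return best[0]


class TestFindMinima:
    def test_single_well_paraboloid(self):
        x = np.arange(9) - 4.0
        values = x[:, None] ** 2 + x[None, :] ** 2
        basins = find_minima(grid_fes(values))
        assert len(basins) == 1
        assert basins[0].min_cell == (4, 4)
        assert len(basins[0].cells) == 81

    def test_uniform_grid_is_one_degenerate_basin(self):
        basins = find_minima(grid_fes(np.zeros((5, 5))))
        assert len(basins) == 1 and basins[0].degenerate

    def test_two_well_surface_minima_near_well_centers(self, surface_78):
        x = np.linspace(*surface_78.bounds[0], 45)
        y = np.linspace(*surface_78.bounds[1], 57)
        values = surface_78.energy_xy(x[:, None], y[None, :])
        fes = FreeEnergySurface((x, y), values, np.zeros_like(values, dtype=bool))
        basins = sorted(find_minima(fes), key=lambda b: b.a_min)[:2]
        found = [(x[b.min_cell[0]], y[b.min_cell[1]]) for b in basins]
        dx = x[1] - x[0]
        dy = y[1] - y[0]
        for well in surface_78.wells:
            assert any(
                abs(fx - well.center[0]) <= dx + 1e-9
                and abs(fy - well.center[1]) <= dy + 1e-9
                for fx, fy in found
            )

    def test_every_unmasked_cell_assigned_once(self, rng):
        values = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) < 0.2
        if mask.all():
            mask[0, 0] = False
        basins = find_minima(grid_fes(values, mask))
        all_cells = sorted(c for b in basins for c in b.cells)
        assert all_cells == sorted(
            tuple(int(i) for i in c) for c in np.argwhere(~mask)
        )

    def test_minimum_cell_not_above_neighbors(self, rng):
        values = rng.normal(size=(10, 10))
        fes = grid_fes(values)
        for b in find_minima(fes):
            i, j = b.min_cell
            patch = values[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            assert values[i, j] <= patch.min() + 1e-12


class TestMinimaxPath:
    def test_start_equals_end_single_cell(self):
        fes = grid_fes(np.arange(16.0).reshape(4, 4))
        path = minimax_path(fes, (2, 2), (2, 2))
        assert path.cells == [(2, 2)]
        energies = activation_reaction_energies(fes, path)
        assert energies["delta_a_act"] == 0.0

    @pytest.mark.parametrize("size", [(4, 4), (5, 5)])
    def test_matches_level_scan_oracle(self, size, rng):
        for _ in range(100):
            values = rng.integers(0, 10, size=size).astype(float)
            start = (0, 0)
            end = (size[0] - 1, size[1] - 1)
            path = minimax_path(grid_fes(values), start, end)
            oracle = brute_force_minimax(values, start, end)
            assert path.max_energy == oracle
            # path validity: endpoints and 8-adjacency
            assert path.cells[0] == start and path.cells[-1] == end
            for a, b in zip(path.cells, path.cells[1:]):
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) == 1

    def test_matches_full_path_enumeration_on_3x3(self, rng):
        for _ in range(50):
            values = rng.integers(0, 10, size=(3, 3)).astype(float)
            path = minimax_path(grid_fes(values), (0, 0), (2, 2))
            assert path.max_energy == enumerate_paths_minimax(values, (0, 0), (2, 2))

    def test_symmetric_bottleneck(self, rng):
        values = rng.normal(size=(6, 6))
        fes = grid_fes(values)
        fwd = minimax_path(fes, (0, 0), (5, 5))
        rev = minimax_path(fes, (5, 5), (0, 0))
        assert fwd.max_energy == pytest.approx(rev.max_energy)

    def test_ts_not_below_either_end(self, rng):
        for _ in range(20):
            values = rng.normal(size=(6, 6))
            fes = grid_fes(values)
            path = minimax_path(fes, (0, 0), (5, 5))
            assert path.max_energy >= max(path.energies[0], path.energies[-1])

    def test_masked_disconnect_raises(self):
        values = np.zeros((5, 5))
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True  # wall
        with pytest.raises(ValueError, match="disconnected"):
            minimax_path(grid_fes(values, mask), (0, 0), (0, 4))

    def test_deterministic_under_repeats(self, rng):
        values = rng.integers(0, 4, size=(5, 5)).astype(float)
        fes = grid_fes(values)
        p1 = minimax_path(fes, (0, 0), (4, 4))
        p2 = minimax_path(fes, (0, 0), (4, 4))
        assert p1.cells == p2.cells


class TestActivationEnergies:
    def test_arithmetic_example(self):
        fes = grid_fes(np.zeros((3, 3)))
        path = ReactionPath([(0, 0), (1, 1), (2, 2)], np.array([0.0, 5.0, -3.0]))
        energies = activation_reaction_energies(fes, path)
        assert energies["delta_a_act"] == 5.0
        assert energies["delta_a_reac"] == -3.0

    def test_monotone_downhill_has_zero_activation(self):
        fes = grid_fes(np.zeros((3, 3)))
        path = ReactionPath([(0, 0), (1, 1), (2, 2)], np.array([2.0, 1.0, 0.0]))
        assert activation_reaction_energies(fes, path)["delta_a_act"] == 0.0

    def test_constant_shift_invariance(self, rng):
        values = rng.normal(size=(6, 6))
        fes = grid_fes(values)
        path = minimax_path(fes, (0, 0), (5, 5))
        e1 = activation_reaction_energies(fes, path)
        shifted = grid_fes(values + 7.3)
        path2 = minimax_path(shifted, (0, 0), (5, 5))
        e2 = activation_reaction_energies(shifted, path2)
        assert e1["delta_a_act"] == pytest.approx(e2["delta_a_act"])
        assert e1["delta_a_reac"] == pytest.approx(e2["delta_a_reac"])


class TestProfileDelta:
    def _profile_fes(self, fn, lo=-1.5, hi=1.5, n=301):
        x = np.linspace(lo, hi, n)
        v = fn(x)
        return FreeEnergySurface((x,), v, np.zeros_like(v, dtype=bool))

    def test_symmetric_double_well_is_zero(self):
        fes = self._profile_fes(lambda x: (x**2 - 1) ** 2)
        assert profile_delta(fes, (0.5, 1.5), (-1.5, -0.5)) == pytest.approx(0.0)

    def test_asymmetric_double_well_matches_minimum_difference(self):
        fes = self._profile_fes(lambda x: (x**2 - 1) ** 2 + 0.8 * x)
        delta = profile_delta(fes, (-1.5, -0.5), (0.5, 1.5))
        x = np.linspace(-1.5, 1.5, 30_001)
        v = (x**2 - 1) ** 2 + 0.8 * x
        expected = v[x > 0.5].min() - v[x < -0.5].min()
        assert delta == pytest.approx(expected, abs=1e-3)

    def test_single_well_missing_basin(self):
        fes = self._profile_fes(lambda x: x**2)
        with pytest.raises(ValueError, match="no free-energy minimum"):
            profile_delta(fes, (-1.5, -0.5), (0.5, 1.5))

    def test_2d_surface_rejected(self):
        fes = grid_fes(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            profile_delta(fes, (0, 1), (1, 2))


class TestThermodynamicIntegration:
    def test_printed_schedule_has_16_windows(self):
        schedule = LambdaSchedule(WATERSWAP_LAMBDAS)
        assert len(schedule) == 16

    def test_schedule_parsing_round_trip(self):
        text = ", ".join(str(v) for v in WATERSWAP_LAMBDAS)
        assert LambdaSchedule.from_text(text).values == WATERSWAP_LAMBDAS

    def test_constant_gradient_closed_form(self):
        schedule = LambdaSchedule(WATERSWAP_LAMBDAS)
        g = -35.0
        expected = g * (0.995 - 0.005)
        assert ti_integrate(schedule, [g] * 16) == pytest.approx(expected, abs=1e-12)

    def test_linear_gradient_trapezoid_exact(self):
        schedule = LambdaSchedule(WATERSWAP_LAMBDAS)
        grads = [2 * lam for lam in schedule.values]
        expected = 0.995**2 - 0.005**2  # = 0.990000
        assert ti_integrate(schedule, grads) == pytest.approx(expected, abs=1e-12)

    def test_burn_in_discards_leading_third(self):
        schedule = LambdaSchedule((0.25, 0.75))
        # first third of each series is junk; remainder is the true gradient
        g1 = np.concatenate([np.full(10, 1e6), np.full(20, 2.0)])
        g2 = np.concatenate([np.full(10, -1e6), np.full(20, 4.0)])
        assert ti_integrate(schedule, [g1, g2]) == pytest.approx(3.0 * 0.5)

    def test_extrapolation_flag_extends_endpoints(self):
        schedule = LambdaSchedule(WATERSWAP_LAMBDAS)
        val = ti_integrate(schedule, [1.0] * 16, extrapolate=True)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ti_integrate(LambdaSchedule((0.1, 0.9)), [1.0])

    @pytest.mark.parametrize(
        "bad", [(0.5,), (0.0, 0.5), (0.5, 0.5), (0.2, 0.1), (0.5, 1.0)]
    )
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(ValueError):
            LambdaSchedule(bad)


class TestAggregateReplicates:
    def test_identical_values(self):
        agg = aggregate_replicates([1.0, 1.0, 1.0])
        assert (agg.mean, agg.sd, agg.sem) == (1.0, 0.0, 0.0)

    def test_arithmetic_example(self):
        agg = aggregate_replicates([7.7, 7.8, 7.9], mode="SD")
        assert agg.mean == pytest.approx(7.8)
        assert agg.sd == pytest.approx(0.1, abs=1e-12)
        assert agg.sem == pytest.approx(0.1 / np.sqrt(3))

    def test_single_value_flagged(self):
        agg = aggregate_replicates([2.5])
        assert agg.single and agg.sd == 0.0 and agg.sem == 0.0

    def test_sem_of_standard_normal_draws(self, rng):
        draws = rng.normal(0, 1, 10)
        agg = aggregate_replicates(draws)
        expected = 1 / np.sqrt(10)
        # sampling error of the SD estimate: sigma/sqrt(2(n-1))
        tol = 3 * expected / np.sqrt(2 * 9)
        assert abs(agg.sem - expected) < tol

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10))
    def test_sem_is_sd_over_sqrt_n(self, values):
        agg = aggregate_replicates(values)
        assert agg.sem == pytest.approx(agg.sd / np.sqrt(agg.n))


class TestNearestBasin:
    def test_picks_closest_minimum(self):
        values = np.array([[0.0, 5.0, 1.0]])
        fes = FreeEnergySurface(
            (np.array([0.0]), np.array([0.0, 1.0, 2.0])),
            values,
            np.zeros_like(values, dtype=bool),
        )
        basins = find_minima(fes)
        assert nearest_basin(basins, fes, (0.0, 2.1)).min_cell == (0, 2)
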