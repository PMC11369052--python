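from math import factorial

import numpy as np
import pytest

from eex import applications as app
from eex import exact_solutions as ex
from eex import ode_numerics as ode
from eex.model import TimeGrid, Trajectory, make_simple_spec
from eex.simulator import ensemble, simulate


def _synthetic_trajectory(times, counts):
    """Hand-built trajectory carrier for closed-form diversity checks."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    return Trajectory(
        times=np.asarray(times, dtype=float),
        counts=counts,
        arrivals=np.full(n, np.nan),
        extinctions=np.full(n, np.nan),
        censored=np.zeros(n, dtype=bool),
        seed=None,
        spec=make_simple_spec(n),
    )


class TestShannon:
    def test_single_type_zero_diversity(self):
        traj = _synthetic_trajectory([0, 1, 2], [[5, 0], [3, 0], [7, 0]])
        assert np.allclose(app.shannon(traj).shannon, 0.0)

    def test_equal_proportions_maximal(self):
        traj = _synthetic_trajectory([0.0], [[4, 4, 4]])
        assert app.shannon(traj).shannon[0] == pytest.approx(np.log(3))

    def test_extinct_population_is_missing(self):
        traj = _synthetic_trajectory([0, 1], [[2, 1], [0, 0]])
        h = app.shannon(traj).shannon
        assert np.isfinite(h[0]) and np.isnan(h[1])

    def test_two_phase_replacement_closed_form(self):
        # type 1 linearly replaced by type 2: H' rises to log 2 then returns to 0
        ks = np.arange(0, 11)
        counts = np.stack([10 - ks, ks], axis=1)
        traj = _synthetic_trajectory(ks.astype(float), counts)
        h = app.shannon(traj).shannon
        p = ks / 10.0
        with np.errstate(divide="ignore", invalid="ignore"):
            expect = -np.where(p > 0, p * np.log(p), 0) - np.where(
                (1 - p) > 0, (1 - p) * np.log(1 - p), 0
            )
        assert np.allclose(h, expect)
        assert h[5] == pytest.approx(np.log(2)) and h[0] == h[10] == 0.0

    def test_log_base_flag(self):
        traj = _synthetic_trajectory([0.0], [[4, 4]])
        assert app.shannon(traj, base=2).shannon[0] == pytest.approx(1.0)

    def test_peak_near_last_arrival_then_decline(self):
        # ensemble-mean H' of the 4-type chain peaks after the last type
        # arrives, then declines as that type takes over
        spec = make_simple_spec(4)
        grid = TimeGrid.linear(25.0, 26)
        h_sum = np.zeros(len(grid))
        h_cnt = np.zeros(len(grid))
        for r in range(200):
            traj = simulate(spec, 25.0, seed=np.random.SeedSequence((55, r)),
                            record="grid", t_grid=grid)
            h = app.shannon(traj).shannon
            ok = ~np.isnan(h)
            h_sum[ok] += h[ok]
            h_cnt[ok] += 1
        mean_h = h_sum / np.maximum(h_cnt, 1)
        peak = np.argmax(mean_h)
        assert 0 < peak < len(grid) - 1
        assert mean_h[-1] < 0.6 * mean_h[peak]


class TestExpectedTypes:
    def test_starts_at_one_and_bounded(self):
        grid = TimeGrid(np.concatenate([[0], np.geomspace(0.05, 100, 80)]))
        for n in (1, 2, 4):
            K = app.expected_types(n, grid).expected_types
            assert K[0] == pytest.approx(1.0)
            assert np.all(K <= n + 1e-9)

    def test_single_type_equals_survival(self):
        grid = TimeGrid(np.concatenate([[0], np.geomspace(0.1, 50, 40)]))
        K = app.expected_types(1, grid).expected_types
        assert np.allclose(K, ex.single_type_survival(grid.points))

    def test_two_types_decomposition(self):
        grid = TimeGrid(np.concatenate([[0], np.geomspace(0.1, 50, 40)]))
        K = app.expected_types(2, grid).expected_types
        Q12 = ode.solve_presence(2, grid).component(1)
        S11 = ex.single_type_survival(grid.points)
        assert np.allclose(K, S11 + Q12, atol=1e-9)
        assert np.all(Q12 <= ode.solve_survival(2, grid).component(1) + 1e-10)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_single_interior_maximum(self, n):
        grid = TimeGrid(np.concatenate([[0], np.geomspace(0.02, 500, 300)]))
        K = app.expected_types(n, grid).expected_types
        i = int(np.argmax(K))
        assert 0 < i < len(K) - 1
        d = np.diff(K)
        assert np.all(d[:i] > -1e-12) and np.all(d[i:] < 1e-12)

    def test_large_time_decay_exponent(self):
        # K_n(t) * t^{chi_n} approaches a constant: slope check on a log grid
        grid = TimeGrid(np.concatenate([[0], np.geomspace(0.1, 3e4, 150)]))
        K = app.expected_types(3, grid).expected_types
        t = grid.points
        i = np.argmin(np.abs(t - 3e3))
        slope = (np.log(K[-1]) - np.log(K[i])) / (np.log(t[-1]) - np.log(t[i]))
        assert slope == pytest.approx(-0.25, abs=0.03)


class TestSurvivalDesignQuantities:
    def test_single_type_ten_generations(self):
        assert app.survival_after_generations(1, 10.0) == pytest.approx(1 / 11)
        assert app.generations_to_survival(1, 0.1) == pytest.approx(9.0)

    def test_two_type_crossing_just_above_hundred(self):
        t10 = app.generations_to_survival(2, 0.1)
        assert 100 < t10 < 110
        assert ex.two_type_survival(t10) == pytest.approx(0.1, abs=1e-9)

    def test_five_types_half_life_order_1e5(self):
        t50 = app.generations_to_survival(5, 0.5)
        assert 4.5 < np.log10(t50) < 5.5

    def test_forward_inverse_consistency_ode_path(self):
        t = app.generations_to_survival(3, 0.3)
        assert app.survival_after_generations(3, t) == pytest.approx(0.3, rel=1e-3)

    def test_expansion_fast_path_close_at_large_t(self):
        t = 500.0
        exact = app.survival_after_generations(2, t)
        approx = app.survival_after_generations(2, t, method="expansion")
        assert approx == pytest.approx(exact, rel=0.01)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            app.generations_to_survival(2, 1.5)


class TestColonySize:
    def test_single_type_constant(self):
        assert app.expected_colony_size(1, 7.0) == pytest.approx(1.0)

    def test_two_types_linear_growth(self):
        assert app.expected_colony_size(2, 20.0) == pytest.approx(21.0)

    def test_partial_sum_formula(self):
        # against the literal truncated exponential series
        t, n = 20.0, 6
        expect = sum(t**k / factorial(k) for k in range(n))
        assert app.expected_colony_size(n, t) == pytest.approx(expect, rel=1e-12)

    def test_plateaus_at_yule_reference(self):
        size, ref = app.expected_colony_size(60, 20.0, with_reference=True)
        assert size == pytest.approx(ref, rel=1e-9)
        assert app.expected_colony_size(3, 20.0) < ref
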