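import numpy as np
import pytest

from eex import exact_solutions as ex
from eex import gf_inversion as gfi
from eex import ode_numerics as ode
from eex.model import ProcessSpec, TimeGrid, make_simple_spec
from eex.simulator import (
    CapExceededError,
    empirical_pmf,
    ensemble,
    simulate,
    simulate_until_extinction,
)


class TestSimulate:
    def test_empty_initial_state_returns_immediately(self):
        spec = make_simple_spec(3, initial=[0, 0, 0])
        traj = simulate(spec, 5.0, seed=0)
        assert np.all(traj.counts == 0)
        assert np.all(np.isnan(traj.arrivals)) and np.all(np.isnan(traj.extinctions))
        traj = simulate_until_extinction(spec, seed=0)
        assert len(traj.times) == 1  # just the initial record

    def test_determinism_same_seed_same_trajectory(self):
        spec = make_simple_spec(3)
        a = simulate(spec, 8.0, seed=99, record="events")
        b = simulate(spec, 8.0, seed=99, record="events")
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)
        c = simulate(spec, 8.0, seed=100, record="events")
        assert not np.array_equal(a.times, c.times)

    def test_counts_conserve_event_logic(self):
        # consecutive event states differ by exactly one birth/death/mutation
        traj = simulate(make_simple_spec(3), 6.0, seed=5, record="events")
        diffs = np.diff(traj.counts, axis=0)
        for d in diffs:
            nz = d[d != 0]
            assert set(nz).issubset({1, -1}) and abs(d.sum()) <= 1

    def test_arrival_before_extinction(self):
        traj = simulate_until_extinction(make_simple_spec(4), seed=3)
        for k in range(4):
            if not np.isnan(traj.arrivals[k]):
                assert traj.extinctions[k] >= traj.arrivals[k]
        assert traj.arrivals[0] == 0.0  # initial type-1 cell

    def test_event_cap_raises_with_partial_run(self):
        supercritical = ProcessSpec(birth=[2.0], death=[0.0], mutation=[0.0])
        with pytest.raises(CapExceededError) as err:
            simulate_until_extinction(supercritical, seed=1, max_events=500)
        assert err.value.trajectory.capped

    def test_stop_on_arrival(self):
        traj = simulate(make_simple_spec(2), 100.0, seed=17, record="events",
                        stop_on_type=2)
        assert traj.counts[-1, 1] == 1
        assert traj.arrivals[1] == traj.times[-1]


class TestAgainstExactLaws:
    def test_single_type_survival_curve(self, single_type_ensemble):
        # fraction alive tracks 1/(1+t); e.g. 0.2 at t = 4
        summ = single_type_ensemble
        exact = ex.single_type_survival(summ.t_grid.points)
        assert np.all(
            np.abs(summ.survival_any - exact) <= 4 * summ.survival_any_halfwidth
        )

    def test_single_type_mean_conserved(self, single_type_ensemble):
        # E Z_1(t) = 1 for all t: criticality conservation
        summ = single_type_ensemble
        dev = np.abs(summ.mean_counts[0, 1:] - 1.0)
        assert np.all(dev <= 4 * summ.sem_counts[0, 1:])

    def test_conditional_geometric_at_t1(self, single_type_ensemble):
        # Z_1(1) | survival ~ Geo(1/2)
        pmf = empirical_pmf(single_type_ensemble, 1.0, which=1, conditional=True)
        n_surv = int(round(single_type_ensemble.survival_any[1] * single_type_ensemble.reps))
        for a in range(1, 6):
            p = 2.0**-a
            se = np.sqrt(p * (1 - p) / n_surv)
            assert pmf[a] == pytest.approx(p, abs=4 * se)

    def test_mass_at_zero_complements_survival(self, single_type_ensemble):
        pmf = empirical_pmf(single_type_ensemble, 4.0, which=1)
        assert pmf[0] == pytest.approx(1 - single_type_ensemble.survival_any[4], abs=1e-12)

    def test_mean_counts_factorial_growth(self):
        # E Z_i(t) = t^{i-1}/(i-1)! for every type
        grid = TimeGrid([0.0, 2.0, 5.0])
        summ = ensemble(make_simple_spec(4), grid, reps=20000, seed=7)
        for i in range(1, 5):
            for j, t in enumerate(grid.points[1:], start=1):
                expect = ex.mean_counts(i, t)
                dev = abs(summ.mean_counts[i - 1, j] - expect)
                assert dev <= 4 * max(summ.sem_counts[i - 1, j], 1e-12)

    def test_total_mean_is_yule_with_many_types(self):
        # with more types than can arrive, the total population is Yule: E Z = e^t
        grid = TimeGrid([0.0, 3.0])
        summ = ensemble(make_simple_spec(12), grid, reps=3000, seed=11)
        total = summ.mean_counts[:, 1].sum()
        sem = np.sqrt((summ.sem_counts[:, 1] ** 2).sum())
        assert abs(total - np.exp(3.0)) <= 4 * sem

    def test_survival_matches_ode_three_types(self):
        grid = TimeGrid([0.0, 1.0, 3.0, 7.0, 12.0, 20.0])
        summ = ensemble(make_simple_spec(3), grid, reps=3000, seed=23)
        S = ode.solve_survival(3, grid).component(1)
        assert np.all(np.abs(summ.survival_any - S) <= 4 * summ.survival_any_halfwidth)

    def test_type2_histogram_matches_inverted_gf(self):
        # binned empirical law of Z_2(6) against the FFT-inverted exact pmf
        t = 6.0
        grid = TimeGrid([0.0, t])
        summ = ensemble(make_simple_spec(2), grid, reps=20000, seed=31, keep_counts=True)
        emp = empirical_pmf(summ, t, which=2)
        pm = gfi.marginal_type2_pmf(t, 400, radius=0.99)
        edges = [(0, 1), (1, 4), (4, 16), (16, 64), (64, 400)]
        for lo, hi in edges:
            obs = emp[lo:hi].sum() if lo < len(emp) else 0.0
            pred = pm.values[lo:hi].sum()
            se = np.sqrt(pred * (1 - pred) / summ.reps)
            assert obs == pytest.approx(pred, abs=4 * max(se, 1e-4))


class TestExtinctionTimes:
    def test_exit_identity_pure_birth_mutation(self):
        # {E_n > t} = {system alive at t}, replicate by replicate
        spec = make_simple_spec(3)
        grid = TimeGrid([0.0, 15.0])
        for r in range(300):
            traj = simulate(spec, 15.0, seed=np.random.SeedSequence((77, r)),
                            record="grid", t_grid=grid)
            alive = traj.counts[-1].sum() > 0
            last_type_open = traj.censored[2] or (
                not np.isnan(traj.extinctions[2]) and traj.extinctions[2] >= 15.0
            )
            assert alive == last_type_open

    def test_single_type_extinction_law(self):
        # P(E_1 > t) = 1/(1+t): check at a few horizons via censoring counts
        spec = make_simple_spec(1)
        reps = 4000
        alive_at = {2.0: 0, 8.0: 0}
        for r in range(reps):
            traj = simulate(spec, 8.0, seed=np.random.SeedSequence((13, r)),
                            record="grid", t_grid=TimeGrid([0.0, 2.0, 8.0]))
            for j, t in enumerate((2.0, 8.0), start=1):
                alive_at[t] += traj.counts[j, 0] > 0
        for t, k in alive_at.items():
            p = ex.single_type_survival(t)
            se = np.sqrt(p * (1 - p) / reps)
            assert k / reps == pytest.approx(p, abs=4 * se)


class TestEnsembleStructure:
    def test_survival_ordering_and_bounds(self, single_type_ensemble):
        s = single_type_ensemble
        assert np.all(s.survival_type_n <= s.survival_any + 1e-12)
        assert np.all((0 <= s.survival_any) & (s.survival_any <= 1))
        assert np.all(s.mean_counts >= 0)

    def test_reproducible_and_seed_sensitive(self):
        grid = TimeGrid([0.0, 2.0])
        a = ensemble(make_simple_spec(2), grid, reps=200, seed=1)
        b = ensemble(make_simple_spec(2), grid, reps=200, seed=1)
        c = ensemble(make_simple_spec(2), grid, reps=200, seed=2)
        assert np.array_equal(a.mean_counts, b.mean_counts)
        assert not np.array_equal(a.mean_counts, c.mean_counts)

    def test_empirical_pmf_needs_recorded_time(self, single_type_ensemble):
        with pytest.raises(ValueError):
            empirical_pmf(single_type_ensemble, 2.5, which=1)

    def test_tidy_export(self, single_type_ensemble):
        df = single_type_ensemble.to_frame()
        assert set(df.columns) == {"time", "type", "mean_count", "sem"}
        assert len(df) == len(single_type_ensemble.t_grid)
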