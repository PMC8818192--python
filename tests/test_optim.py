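"""Optimizer tests: mass/force/step primitives against hand-rolled oracles,
chaotic stream, convergence, determinism, and the NLLS fitter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepakin.model import KineticParams, TissueCurve
from hepakin.optim import (
    ChaoticSequence,
    GsaConfig,
    SearchSpace,
    Swarm,
    TacObjective,
    dcgsa_step,
    dynamic_gravitational_constant,
    fitness,
    gravitational_constant,
    gsa_step,
    inertia_weight,
    kbest_size,
    logistic_step,
    minimize,
    nlls_fit,
    pairwise_force,
    resultant_force,
    update_masses,
)


def make_swarm(positions, fitness_values, space=None, n_iters=500, velocities=None,
               chaotic_state=None):
    positions = np.asarray(positions, dtype=float)
    n, d = positions.shape
    space = space or SearchSpace(np.full(d, -10.0), np.full(d, 10.0))
    return Swarm(
        positions=positions,
        velocities=np.zeros((n, d)) if velocities is None else np.asarray(velocities, float),
        fitness=np.asarray(fitness_values, dtype=float),
        masses=update_masses(fitness_values),
        t=0,
        n_iters=n_iters,
        space=space,
        chaotic_state=chaotic_state,
    )


class TestMasses:
    def test_hand_evaluated_example(self):
        # fit [2,4,10]: raw m = [1, 0.75, 0], normalized [4/7, 3/7, 0]
        np.testing.assert_allclose(update_masses([2.0, 4.0, 10.0]), [4 / 7, 3 / 7, 0.0])

    def test_all_equal_fitness_uniform(self):
        np.testing.assert_allclose(update_masses([3.0, 3.0, 3.0, 3.0]), 0.25)

    @settings(deadline=None)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=30))
    def test_normalization_and_range(self, values):
        m = update_masses(values)
        assert m.sum() == pytest.approx(1.0)
        assert np.all((m >= 0) & (m <= 1))


class TestGravitationalConstants:
    def test_classic_schedule_closed_forms(self):
        cfg = GsaConfig(g0=100.0, alpha=20.0, n_iters=500)
        assert gravitational_constant(0, cfg) == 100.0
        assert gravitational_constant(500, cfg) == pytest.approx(100.0 * math.exp(-20))
        assert gravitational_constant(250, cfg) == pytest.approx(100.0 * math.exp(-10))

    def test_classic_strictly_decreasing(self):
        cfg = GsaConfig(n_iters=100)
        g = [gravitational_constant(t, cfg) for t in range(101)]
        assert np.all(np.diff(g) < 0)

    def test_dynamic_at_zero_is_g0_for_any_rand(self):
        cfg = GsaConfig(g0=50.0, n_iters=200)
        for seed in range(5):
            assert dynamic_gravitational_constant(0, cfg, np.random.default_rng(seed)) == 50.0

    def test_dynamic_closed_form_at_final_iteration(self):
        cfg = GsaConfig(g0=100.0, n_iters=400)

        class RandOne:
            def uniform(self):
                return 1.0

        a = cfg.effective_alpha_dynamic
        expected = 100.0 * math.exp(-2.0 * a / math.sqrt(400))
        assert dynamic_gravitational_constant(400, cfg, RandOne()) == pytest.approx(expected)

    def test_dynamic_bounded_by_g0(self):
        cfg = GsaConfig(n_iters=300)
        rng = np.random.default_rng(0)
        assert all(
            dynamic_gravitational_constant(t, cfg, rng) <= cfg.g0 for t in range(0, 301, 10)
        )

    def test_dynamic_expectation_matches_closed_form(self):
        # E[e^{-c(rand + b)}] = e^{-cb} (1 - e^{-c}) / c for rand ~ U(0,1)
        cfg = GsaConfig(g0=1.0, n_iters=100)
        t = 60
        a = cfg.effective_alpha_dynamic
        c = a * t / cfg.n_iters**1.5
        b = t / cfg.n_iters
        expected = math.exp(-c * b) * (1.0 - math.exp(-c)) / c
        rng = np.random.default_rng(1)
        mc = np.mean(
            [dynamic_gravitational_constant(t, cfg, rng) for _ in range(100_000)]
        )
        assert mc == pytest.approx(expected, rel=5e-3)


class TestForces:
    def test_zero_mass_gives_zero_force(self):
        pos = np.array([[0.0, 0.0], [1.0, 1.0]])
        f = pairwise_force(0, 1, pos, np.array([0.0, 0.5]), g=1.0, epsilon=0.0)
        np.testing.assert_array_equal(f, 0.0)

    def test_coincident_positions_zero_force(self):
        pos = np.array([[1.0, 2.0], [1.0, 2.0]])
        f = pairwise_force(0, 1, pos, np.array([0.5, 0.5]), g=1.0, epsilon=1e-9)
        np.testing.assert_array_equal(f, 0.0)

    def test_one_dimensional_magnitude(self):
        # M=0.5 each at x=0,1, G=1, eps=0: |F| = 1*0.25/1*1 = 0.25, attractive
        pos = np.array([[0.0], [1.0]])
        f = pairwise_force(0, 1, pos, np.array([0.5, 0.5]), g=1.0, epsilon=0.0)
        assert f[0] == pytest.approx(0.25)  # points from particle 0 toward 1

    def test_resultant_kbest_one(self):
        sw = make_swarm([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]], [1.0, 2.0, 3.0])
        # particle 0 is the best: with Kbest=1 it feels nothing
        f = resultant_force(0, sw, g=1.0, kbest=1, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(f, 0.0)
        # others feel only particle 0
        f1 = resultant_force(1, sw, g=1.0, kbest=1, rng=np.random.default_rng(0))
        assert f1[0] < 0  # pulled toward the best at the origin

    def test_resultant_zero_when_attractors_massless(self):
        sw = make_swarm([[0.0], [1.0], [2.0]], [1.0, 2.0, 3.0])
        sw.masses = np.array([0.0, 1.0, 0.0])
        f = resultant_force(1, sw, g=1.0, kbest=3, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(f, 0.0)

    def test_resultant_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        pos = rng.uniform(-3, 3, size=(3, 4))
        fit = np.array([5.0, 1.0, 9.0])
        sw = make_swarm(pos, fit)
        g, eps, kbest = 2.5, 1e-9, 3
        got = resultant_force(1, sw, g, kbest, np.random.default_rng(7), epsilon=eps)
        # independent double loop, same draw order (ascending particle index)
        rng2 = np.random.default_rng(7)
        expected = np.zeros(4)
        for j in range(3):
            if j == 1:
                continue
            w = rng2.uniform()
            r = np.sqrt(np.sum((pos[j] - pos[1]) ** 2))
            expected += w * g * sw.masses[1] * sw.masses[j] / (r + eps) * (pos[j] - pos[1])
        np.testing.assert_allclose(got, expected, rtol=1e-14)


class TestSteps:
    def test_coincident_swarm_is_fixed_point(self):
        # all particles at one interior point: zero forces, zero velocities
        pos = np.tile([[1.0, -2.0]], (4, 1))
        sw = make_swarm(pos, [1.0, 2.0, 3.0, 4.0])
        gsa_step(sw, GsaConfig(n_particles=4), np.random.default_rng(0))
        np.testing.assert_array_equal(sw.positions, pos)

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            GsaConfig(n_particles=1)

    def test_kbest_schedule_endpoints(self):
        cfg = GsaConfig(n_particles=50, n_iters=500)
        assert kbest_size(0, cfg) == 50
        assert kbest_size(500, cfg) == 1

    def test_gsa_step_matches_sequenced_oracle(self):
        rng0 = np.random.default_rng(3)
        pos = rng0.uniform(-5, 5, size=(3, 2))
        vel = rng0.uniform(-1, 1, size=(3, 2))
        fit = np.array([4.0, 1.0, 10.0])
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        cfg = GsaConfig(n_particles=3, n_iters=100, g0=10.0, alpha=20.0)
        sw = make_swarm(pos.copy(), fit, space=space, n_iters=100, velocities=vel.copy())
        gsa_step(sw, cfg, np.random.default_rng(11))

        # oracle: mass, G, pairwise-force, resultant, acceleration, velocity,
        # position rules applied step by step with the same random stream
        rng = np.random.default_rng(11)
        m = (fit - fit.max()) / (fit.min() - fit.max())
        m = m / m.sum()
        g = 10.0 * math.exp(-20.0 * 0.0 / 100)
        w = rng.uniform(size=(3, 3))  # per (i, j in elite) weights
        acc = np.zeros((3, 2))
        for i in range(3):
            for jj, j in enumerate(range(3)):  # elite = all 3, ascending index
                if j == i:
                    continue
                r = np.sqrt(np.sum((pos[j] - pos[i]) ** 2))
                acc[i] += w[i, jj] * g * m[j] / (r + cfg.epsilon) * (pos[j] - pos[i])
        rand_i = rng.uniform(size=3)[:, None]
        v_new = rand_i * vel + acc
        x_new = np.clip(pos + v_new, -10, 10)
        np.testing.assert_allclose(sw.positions, x_new, rtol=1e-12)
        np.testing.assert_allclose(sw.masses, m, rtol=1e-12)

    def test_dcgsa_step_matches_sequenced_oracle(self):
        rng0 = np.random.default_rng(5)
        pos = rng0.uniform(-5, 5, size=(3, 2))
        vel = rng0.uniform(-1, 1, size=(3, 2))
        fit = np.array([2.0, 7.0, 3.0])
        chaos = np.array([0.3, 0.6, 0.9])
        space = SearchSpace(np.full(2, -10.0), np.full(2, 10.0))
        cfg = GsaConfig(n_particles=3, n_iters=100, g0=10.0)
        sw = make_swarm(pos.copy(), fit, space=space, n_iters=100,
                        velocities=vel.copy(), chaotic_state=chaos.copy())
        sw.t = 50
        dcgsa_step(sw, cfg, np.random.default_rng(13))

        rng = np.random.default_rng(13)
        m = (fit - fit.max()) / (fit.min() - fit.max())
        m = m / m.sum()
        rand_t = rng.uniform()
        a_dyn = cfg.effective_alpha_dynamic
        g = 10.0 * math.exp(-a_dyn * (50 / 100**1.5) * (rand_t + 0.5))
        # Kbest at t=50 of T=100: ceil(3 - 2 * 0.5) = 2 elite particles,
        # which are indices 0 and 2 (fitness 2.0 and 3.0)
        elite = [0, 2]
        w = rng.uniform(size=(3, 2))
        acc = np.zeros((3, 2))
        for i in range(3):
            for jj, j in enumerate(elite):
                if j == i:
                    continue
                r = np.sqrt(np.sum((pos[j] - pos[i]) ** 2))
                acc[i] += w[i, jj] * g * m[j] / (r + cfg.epsilon) * (pos[j] - pos[i])
        W = 0.7 - (0.7 - 0.1) * 50 / 100  # inertia weight at mid-run
        v_new = W * vel + acc
        c_new = 4.0 * chaos * (1.0 - chaos)
        x_new = np.clip(pos + v_new * c_new[:, None], -10, 10)
        np.testing.assert_allclose(sw.positions, x_new, rtol=1e-12)
        np.testing.assert_allclose(sw.chaotic_state, c_new, rtol=1e-15)

    def test_inertia_weight_schedule(self):
        cfg = GsaConfig(n_iters=500)
        assert inertia_weight(0, cfg) == pytest.approx(0.7)
        assert inertia_weight(250, cfg) == pytest.approx(0.4)
        assert inertia_weight(500, cfg) == pytest.approx(0.1)

    def test_positions_stay_in_bounds_and_masses_normalized(self):
        space = SearchSpace(np.zeros(3), np.ones(3))
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 1, size=(8, 3))
        sw = make_swarm(pos, rng.uniform(1, 5, size=8), space=space, n_iters=50)
        cfg = GsaConfig(n_particles=8, n_iters=50)
        for _ in range(50):
            gsa_step(sw, cfg, rng)
            sw.fitness = np.sum(sw.positions**2, axis=1)
            assert np.all(sw.positions >= 0.0) and np.all(sw.positions <= 1.0)
            assert sw.masses.sum() == pytest.approx(1.0)


class TestChaoticSequence:
    @pytest.mark.parametrize("seed", [0.0, 0.25, 0.5, 0.75, 1.0, -0.1, 1.1])
    def test_degenerate_seeds_rejected(self, seed):
        with pytest.raises(ValueError):
            ChaoticSequence(seed)

    def test_direct_iteration(self):
        seq = ChaoticSequence(0.3)
        assert seq.next() == pytest.approx(0.84)
        assert seq.next() == pytest.approx(0.5376)

    def test_degenerate_orbit_of_half(self):
        # 0.5 -> 1 -> 0 -> 0: exactly why 0.5 is rejected as a seed
        assert logistic_step(0.5) == 1.0
        assert logistic_step(1.0) == 0.0

    def test_iterates_fill_unit_interval_non_uniformly(self):
        from scipy.stats import kstest

        seq = ChaoticSequence(0.123)
        xs = np.array([seq.next() for _ in range(100_000)])
        assert np.all((xs > 0) & (xs < 1))
        # invariant density is arcsine-like: mass piles up near 0 and 1
        ks = kstest(xs, "uniform").statistic
        assert ks > 0.1
        assert np.mean(xs < 0.1) > np.mean((xs > 0.45) & (xs < 0.55))


class TestMinimize:
    def test_sphere_quick_convergence(self):
        space = SearchSpace(np.full(5, -5.0), np.full(5, 5.0))
        cfg = GsaConfig(n_particles=30, n_iters=200, seed=0)
        res = minimize(lambda x: float(np.sum(x**2)), space, cfg)
        assert res.fun < 1e-3

    def test_trace_non_increasing_and_deterministic(self):
        space = SearchSpace(np.full(3, -2.0), np.full(3, 2.0))
        for variant in ("gsa", "dcgsa"):
            cfg = GsaConfig(n_particles=10, n_iters=50, variant=variant, seed=9)
            obj = lambda x: float(np.sum(x**2))
            a = minimize(obj, space, cfg)
            b = minimize(obj, space, cfg)
            assert np.all(np.diff(a.trace) <= 0)
            assert len(a.trace) == 51
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.trace, b.trace)
            assert a.fun == b.fun

    def test_non_finite_objective_survives(self):
        space = SearchSpace(np.full(2, -1.0), np.full(2, 1.0))

        def holey(x):
            return np.nan if x[0] > 0.5 else float(np.sum(x**2))

        res = minimize(holey, space, GsaConfig(n_particles=10, n_iters=30, seed=1))
        assert np.isfinite(res.fun)


class TestFitnessFunction:
    def test_zero_at_true_parameters(self, hcc_params, noiseless_tac, arterial, portal):
        f = fitness(hcc_params, noiseless_tac, arterial, portal)
        assert f <= 1e-12 * float(noiseless_tac.values @ noiseless_tac.values)

    def test_constant_offset(self, hcc_params, noiseless_tac, arterial, portal, schedule):
        d = 0.37
        shifted = TissueCurve(schedule, noiseless_tac.values + d)
        assert fitness(hcc_params, shifted, arterial, portal) == pytest.approx(
            16 * d**2, rel=1e-9
        )

    def test_matches_elementwise_sum_oracle(self, noiseless_tac, arterial, portal):
        rng = np.random.default_rng(0)
        cand = KineticParams(0.4, 0.8, 0.2, 0.1, 0.3)
        obs = TissueCurve(noiseless_tac.schedule, rng.uniform(0, 5, 16))
        obj = TacObjective(obs, arterial, portal)
        model = obj.model_frames(cand.to_vector())
        expected = sum((o - m) ** 2 for o, m in zip(obs.values, model))
        assert obj(cand.to_vector()) == pytest.approx(expected, rel=1e-14)

    def test_schedule_longer_than_grid_rejected(self, arterial, portal):
        from hepakin.model import FrameSchedule

        long_sched = FrameSchedule.from_run_lengths([[12, 5], [10, 60]])
        obs = TissueCurve(long_sched, np.zeros(22))
        with pytest.raises(ValueError, match="extends past"):
            TacObjective(obs, arterial, portal)


class TestNlls:
    def test_start_at_truth_converges_to_zero(self, hcc_params, noiseless_tac, arterial, portal):
        res = nlls_fit(noiseless_tac, arterial, portal,
                       starts=hcc_params.to_vector()[None, :])
        assert res.fun < 1e-16

    def test_multistart_recovers_truth(self, hcc_params, noiseless_tac, arterial, portal):
        res = nlls_fit(noiseless_tac, arterial, portal, n_starts=10, seed=0)
        true = hcc_params.to_vector()
        np.testing.assert_allclose(res.x, true, rtol=0.02, atol=0.01)
        assert res.method == "nlls"
        assert np.all(np.diff(res.trace) <= 0)

    def test_single_poor_start_shows_local_minimum_sensitivity(
        self, noiseless_tac, arterial, portal
    ):
        bad = np.array([[2.9, 0.05, 0.95, 0.49, 0.02]])
        res_bad = nlls_fit(noiseless_tac, arterial, portal, starts=bad)
        res_multi = nlls_fit(noiseless_tac, arterial, portal, n_starts=10, seed=0)
        assert res_multi.fun <= res_bad.fun
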