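"""Rate-dynamics unit and property tests: threshold, integration, noise,
rectification, and network wiring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amygsim import (NetworkParams, PopulationState, Projection, build_network,
                     compute_rate, sigmoid, step_potential, threshold_F)
from amygsim.params import ConfigError


class TestThreshold:
    @pytest.mark.parametrize("x,expected", [
        (0.3, 0.001),   # at threshold, floor applies
        (1.0, 0.7),
        (0.0, 0.001),   # negative argument floored
        (-5.0, 0.001),
    ])
    def test_values(self, params, x, expected):
        assert threshold_F(x, params) == pytest.approx(expected)

    def test_rejects_non_finite(self, params):
        with pytest.raises(ValueError):
            threshold_F(float("nan"), params)

    @given(x=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_floor_invariant(self, x):
        p = NetworkParams()
        assert threshold_F(x, p) >= p.min_value


class TestStepPotential:
    def test_zero_input_fixed_point(self, quiet_params):
        # with no drive, V relaxes to F(0) = min_value and stays
        pop = PopulationState("LA", np.full(10, 1e-3), np.zeros(10))
        v_before = pop.V.copy()
        step_potential(pop, [], quiet_params)
        assert pop.V == pytest.approx(v_before)

    def test_single_euler_step(self, quiet_params):
        # dt/tau = 0.02: one step from V=0 with drive 1.0 gives 0.02*0.7
        p = quiet_params
        assert p.dt / p.tau == pytest.approx(0.02)
        pop = PopulationState("LA", np.zeros(1), np.zeros(1))
        proj = Projection("Cortex", "LA", np.ones((1, 1)), "excitatory")
        step_potential(pop, [(proj, np.array([1.0]))], p)
        assert pop.V[0] == pytest.approx(0.014)

    def test_relaxation_matches_exponential(self, quiet_params):
        """Constant drive 1.0: V(t) = 0.7 + (V0-0.7) exp(-t/tau), within
        Euler error O(dt)."""
        p = quiet_params
        pop = PopulationState("LA", np.zeros(1), np.zeros(1))
        proj = Projection("Cortex", "LA", np.ones((1, 1)), "excitatory")
        n_steps = int(np.ceil(7 * p.tau / p.dt))
        for k in range(n_steps):
            step_potential(pop, [(proj, np.array([1.0]))], p)
        t = n_steps * p.dt
        analytic = 0.7 + (0.0 - 0.7) * np.exp(-t / p.tau)
        assert pop.V[0] == pytest.approx(analytic, abs=1e-3)

    def test_shape_mismatch(self, quiet_params):
        pop = PopulationState("LA", np.zeros(10), np.zeros(10))
        proj = Projection("Cortex", "LA", np.ones((10, 10)), "excitatory")
        with pytest.raises(ValueError):
            step_potential(pop, [(proj, np.ones(3))], quiet_params)


class TestComputeRate:
    def test_sigmoid_midpoint(self, quiet_params):
        pop = PopulationState("CeLOn", np.array([quiet_params.sigmoid_mid]),
                              np.zeros(1))
        compute_rate(pop, [], quiet_params)
        assert pop.U[0] == pytest.approx(0.5)

    def test_inhibition_and_rectified_export(self, quiet_params):
        # sigmoid(V)=0.4, one inhibitory source 0.25 * 2.0 -> U = -0.1
        p = quiet_params
        v = p.sigmoid_mid + np.log(0.4 / 0.6) / p.sigmoid_gain
        pop = PopulationState("CeLOn", np.array([v]), np.zeros(1))
        proj = Projection("CeLOff", "CeLOn", np.array([[0.25]]), "inhibitory")
        compute_rate(pop, [(proj, np.array([2.0]))], p)
        assert pop.U[0] == pytest.approx(-0.1, abs=1e-9)
        assert pop.rates[0] == 0.0

    def test_noise_distribution(self, params, rng):
        """1e4 draws at fixed V: mean within 3 SE of sigmoid(V), every draw
        within +/- 0.5% of it."""
        v = 0.6
        s = float(sigmoid(v, params))
        pop = PopulationState("LA", np.full(10_000, v), np.zeros(10_000))
        compute_rate(pop, [], params, rng)
        half = params.noise_level / 2 * s
        assert np.all(pop.U >= s - half - 1e-12)
        assert np.all(pop.U <= s + half + 1e-12)
        se = np.std(pop.U) / np.sqrt(pop.U.size)
        assert abs(np.mean(pop.U) - s) < 3 * se


class TestBuildNetwork:
    def test_wiring_counts_and_ranges(self, params):
        net = build_network(params, 0)
        plastic = net.plastic_projections
        fixed = [p for p in net.projections.values() if not p.plastic]
        assert len(plastic) == 3
        # 4 fixed excitatory + LA lateral + 2 BA mutual + 2 CeL mutual
        assert len(fixed) == 9
        for proj in plastic:
            assert np.all(proj.W >= params.wmin) and np.all(proj.W <= params.wmax)
        for name in ("LA->CeLOn", "BAf->CeLOn"):
            W = net.projections[name].W
            assert np.all(W >= 0.18) and np.all(W <= 0.22)

    def test_population_sizes(self, params):
        net = build_network(params, 0)
        sizes = {n: p.V.size for n, p in net.pops.items()}
        assert sizes == {"LA": 10, "BAf": 10, "BAe": 10, "CeLOn": 1, "CeLOff": 1}

    def test_deterministic_under_seed(self, params):
        a = build_network(params, 42)
        b = build_network(params, 42)
        for name in a.projections:
            np.testing.assert_array_equal(a.projections[name].W,
                                          b.projections[name].W)

    def test_invalid_size_rejected(self):
        with pytest.raises(ConfigError):
            NetworkParams(la_size=0)

    def test_no_self_inhibition_in_la(self, params):
        net = build_network(params, 3)
        assert np.all(np.diag(net.projections["LA->LA"].W) == 0)


class TestPhaseDynamics:
    def test_baseline_fixed_point(self, quiet_params):
        """No external input, no noise: every population settles within one
        phase and stays there."""
        net = build_network(quiet_params, 0)
        rng = np.random.default_rng(0)
        net.run_phase({}, quiet_params.cycles_per_phase, rng)
        snapshot = {n: p.U.copy() for n, p in net.pops.items()}
        net.run_phase({}, quiet_params.cycles_per_phase, rng)
        for name, pop in net.pops.items():
            np.testing.assert_allclose(pop.U, snapshot[name], atol=1e-4)

    def test_exported_rates_nonnegative(self, params):
        net = build_network(params, 7)
        rng = np.random.default_rng(7)
        net.run_phase({"Cortex": np.full(10, 1.5)}, 300, rng, ach_level=2.5)
        for pop in net.pops.values():
            assert np.all(pop.rates >= 0)

    def test_trajectory_determinism(self, params):
        nets = []
        for _ in range(2):
            net = build_network(params, 11)
            net.run_phase({"Hippo": np.ones(10)}, 200,
                          np.random.default_rng(11))
            nets.append(net)
        for name in nets[0].pops:
            np.testing.assert_array_equal(nets[0].pops[name].U,
                                          nets[1].pops[name].U)
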