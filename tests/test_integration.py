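"""Stochastic Euler stepping, clock policy, and multi-rate scheduling."""

import time

import numpy as np
import pytest

from dynfield.coupling import CouplingSpec, DimensionMap
from dynfield.graph import ArchitectureGraph, ComponentSpec, StepGroup
from dynfield.integration import (
    ClockPolicy,
    SimulationDiverged,
    Simulator,
    euler_maruyama_step,
)


def node_graph(n=3, tau=50.0, c_noise=1.0, groups=None):
    comps = [
        ComponentSpec(f"n{i}", "node", {"tau": tau, "h": -5.0, "c_noise": c_noise})
        for i in range(n)
    ]
    return ArchitectureGraph(comps, [], groups or [])


class TestEulerMaruyamaStep:
    def test_pure_decay_reaches_zero_in_one_tau_step(self):
        # dt = tau cancels the state exactly for rate = -u
        assert euler_maruyama_step(1.0, -1.0, dt=100.0, tau=100.0) == 0.0

    def test_zero_dt_leaves_state_unchanged(self, rng):
        u = rng.random(16)
        new = euler_maruyama_step(u, rng.random(16), 0.0, 100.0, 1.0,
                                  rng.standard_normal(16))
        np.testing.assert_array_equal(new, u)

    def test_noise_scales_with_sqrt_dt(self):
        got = euler_maruyama_step(0.0, 0.0, dt=4.0, tau=2.0, c_noise=3.0,
                                  noise=1.0)
        assert got == pytest.approx(np.sqrt(4.0) * 3.0 / 2.0)

    def test_non_finite_state_halts_with_component_name(self):
        with pytest.raises(SimulationDiverged, match="percept"):
            euler_maruyama_step(np.inf, 0.0, 1.0, 1.0, component="percept")

    def test_ou_stationary_variance_matches_closed_form(self):
        """tau u' = -u + c xi: the Euler chain has stationary variance
        c^2 / (2 tau - dt); an ensemble estimate lands within 5%."""
        tau, dt, c = 100.0, 1.0, 2.0
        rng = np.random.default_rng(7)
        u = np.zeros(64)
        samples = []
        for i in range(30_000):
            u = euler_maruyama_step(u, -u, dt, tau, c, rng.standard_normal(64))
            if i >= 3_000:
                samples.append(u.copy())
        var = np.asarray(samples).var()
        assert var == pytest.approx(c * c / (2 * tau - dt), rel=0.05)

    def test_accumulated_noise_variance_independent_of_dt(self):
        """A pure-noise integrator (zero deterministic rate) reaches the
        same terminal variance over a fixed duration for any step size."""
        tau, c, T = 100.0, 1.5, 2000.0
        rng = np.random.default_rng(11)
        variances = []
        for dt in (tau / 100, tau / 20):
            u = np.zeros(4000)
            for _ in range(int(T / dt)):
                u = euler_maruyama_step(u, 0.0, dt, tau, c,
                                        rng.standard_normal(4000))
            variances.append(u.var())
        assert variances[0] == pytest.approx(variances[1], rel=0.10)
        assert variances[0] == pytest.approx(T * c * c / tau**2, rel=0.10)


class TestFreeRunning:
    def test_same_seed_gives_bit_identical_trajectories(self):
        g = node_graph()
        s1, s2 = Simulator(g, seed=9), Simulator(g, seed=9)
        s1.run(500, ClockPolicy(5.0))
        s2.run(500, ClockPolicy(5.0))
        for name in s1.components:
            assert s1.components[name].state.u == s2.components[name].state.u

    def test_different_seeds_diverge(self):
        g = node_graph()
        s1, s2 = Simulator(g, seed=1), Simulator(g, seed=2)
        s1.run(200, ClockPolicy(5.0))
        s2.run(200, ClockPolicy(5.0))
        assert s1.components["n0"].state.u != s2.components["n0"].state.u

    def test_step_log_times_are_consistent(self):
        g = node_graph(c_noise=0.0)
        sim = Simulator(g, seed=0)
        logs = sim.run(100, ClockPolicy(5.0))
        assert len(logs) == 20
        t = 0.0
        for log in logs:
            t += log.dt_actual
            assert log.t_sim == pytest.approx(t)
            assert not log.extended

    def test_coarse_step_warns_against_smallest_tau(self):
        g = node_graph(tau=50.0)
        sim = Simulator(g, seed=0)
        with pytest.warns(UserWarning, match="time constant"):
            sim.run(50, ClockPolicy(dt_planned=10.0))


class TestRealtime:
    def test_wall_clock_tracks_simulated_time(self):
        g = node_graph(n=1, tau=200.0, c_noise=0.0)
        sim = Simulator(g, seed=0)
        t0 = time.perf_counter()
        logs = sim.run(400, ClockPolicy(dt_planned=20.0, realtime=True))
        wall_ms = (time.perf_counter() - t0) * 1000
        assert abs(sum(l.dt_actual for l in logs) - wall_ms) <= 25.0

    def test_injected_stall_extends_exactly_one_step(self):
        g = node_graph(n=1, tau=200.0, c_noise=0.0)
        sim = Simulator(g, seed=0)
        dt = 20.0

        def hook(i):
            if i == 5:
                time.sleep(3 * dt / 1000.0)

        t0 = time.perf_counter()
        logs = sim.run(400, ClockPolicy(dt_planned=dt, realtime=True,
                                        max_extension_ratio=5.0),
                       compute_hook=hook)
        wall_ms = (time.perf_counter() - t0) * 1000
        extended = [l for l in logs if l.extended]
        assert len(extended) == 1 and extended[0].i == 5
        assert extended[0].dt_actual == pytest.approx(3 * dt, rel=0.25)
        # simulated time stays aligned with wall time to within one step
        assert abs(sim.t_sim - wall_ms) <= dt + 5.0

    def test_meter_warns_when_extensions_are_frequent(self):
        g = node_graph(n=1, tau=2000.0, c_noise=0.0)
        sim = Simulator(g, seed=0)

        def hook(i):
            time.sleep(0.004)  # every step overruns a 2 ms plan

        with pytest.warns(UserWarning, match="larger"):
            sim.run(40, ClockPolicy(dt_planned=2.0, realtime=True,
                                    max_extension_ratio=10.0),
                    compute_hook=hook)


class TestMultirate:
    def test_equal_dt_groups_reproduce_single_group_run_exactly(self):
        groups = [StepGroup(("n0", "n1"), 5.0, "a"), StepGroup(("n2",), 5.0, "b")]
        s_single = Simulator(node_graph(), seed=3)
        s_single.run(500, ClockPolicy(5.0))
        s_multi = Simulator(node_graph(groups=groups), seed=3)
        s_multi.multirate_run(500)
        for name in s_single.components:
            assert (
                s_single.components[name].state.u
                == s_multi.components[name].state.u
            )

    def test_slow_source_yields_piecewise_constant_input(self):
        comps = [
            ComponentSpec("src", "node", {"tau": 50.0, "h": -5.0, "c_noise": 1.0}),
            ComponentSpec("dst", "node", {"tau": 50.0, "h": -5.0}),
        ]
        cpl = [CouplingSpec("src", "dst", DimensionMap(()), gain=1.0)]
        groups = [StepGroup(("src",), 10.0, "slow"), StepGroup(("dst",), 1.0, "fast")]
        sim = Simulator(ArchitectureGraph(comps, cpl, groups), seed=5)
        seen = []
        orig = sim._gather

        def spy(members):
            inputs = orig(members)
            if "dst" in members and "dst" in inputs:
                seen.append(float(inputs["dst"]))
            return inputs

        sim._gather = spy
        sim.multirate_run(100)
        changes = np.flatnonzero(np.diff(seen))
        assert len(seen) == 100
        # the reader's input changes only on the step after the slow group
        # publishes, i.e. every 10th fast step
        assert len(changes) > 0
        assert all(c % 10 == 0 for c in changes)

    def test_staleness_never_exceeds_largest_group_dt(self):
        comps = [
            ComponentSpec("a", "node", {"tau": 50.0, "c_noise": 0.5}),
            ComponentSpec("b", "node", {"tau": 50.0}),
        ]
        cpl = [
            CouplingSpec("a", "b", DimensionMap(()), gain=1.0),
            CouplingSpec("b", "a", DimensionMap(()), gain=0.5),
        ]
        groups = [StepGroup(("a",), 5.0, "slow"), StepGroup(("b",), 1.0, "fast")]
        sim = Simulator(ArchitectureGraph(comps, cpl, groups), seed=0)
        sim.multirate_run(500)
        assert 0.0 < sim.max_staleness <= 5.0


class TestAttractorRobustness:
    def test_peak_holds_location_at_coarse_sampling(self, geo1d):
        """A self-stabilized peak survives dt = tau / 10 with drift below
        one grid cell (attractors stabilize crude sampling)."""
        from dynfield.demo import detect_peaks
        from dynfield.kernels import KernelSpec
        from tests.conftest import gaussian_bump

        geo = geo1d
        comps = [
            ComponentSpec(
                "f",
                "field",
                {
                    "geometry": {
                        "dim_names": ["x"], "lower": [0.0], "upper": [10.0],
                        "n_samples": [100],
                    },
                    "tau": 100.0,
                    "h": -5.0,
                    "c_noise": 0.5,
                    "sigmoid": {"kind": "logistic", "beta": 4.0},
                    "kernel": {"c_exc": 15.0, "sigma_exc": 0.5, "c_glob": 1.0,
                               "truncation": 4.0},
                },
            )
        ]
        sim = Simulator(ArchitectureGraph(comps, []), seed=2)
        sim.external_inputs["f"] = gaussian_bump(geo, (5.0,), (0.4,), 6.0)
        sim.run(2000, ClockPolicy(dt_planned=10.0))
        first = detect_peaks(sim.components["f"].state.u, geo)
        sim.run(3000, ClockPolicy(dt_planned=10.0))
        last = detect_peaks(sim.components["f"].state.u, geo)
        assert len(first) == 1 and len(last) == 1
        drift = abs(first[0].centroid[0] - last[0].centroid[0])
        assert drift < geo.spacing[0]
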