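"""Field, node, and memory-trace rate equations and sigmoid nonlinearities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynfield.dynamics import (
    FieldState,
    MemoryTraceState,
    NodeState,
    SigmoidSpec,
    field_rate_of_change,
    memory_trace_rate,
    node_rate_of_change,
    sigmoid,
)


class TestSigmoid:
    @pytest.mark.parametrize(
        "kind, beta, u, expected",
        [
            ("abs_approx", 4.0, 0.0, 0.5),  # symmetry at the threshold
            ("abs_approx", 1.0, 0.0, 0.5),
            ("abs_approx", 4.0, 10.0, 0.5 * (1 + 40.0 / 41.0)),
            ("logistic", 4.0, 0.0, 0.5),
            ("step", 1.0, -1.0, 0.0),
            ("step", 1.0, 0.2, 1.0),
        ],
    )
    def test_pointwise_values(self, kind, beta, u, expected):
        spec = SigmoidSpec(kind, beta, 0.0)
        assert sigmoid(spec, u) == pytest.approx(expected, abs=1e-12)

    def test_step_is_amari_hard_threshold(self):
        spec = SigmoidSpec("step", 1.0, 0.0)
        np.testing.assert_array_equal(
            sigmoid(spec, np.array([-1.0, 0.2])), [0.0, 1.0]
        )

    @pytest.mark.parametrize("kind", ["step", "logistic", "abs_approx"])
    def test_range_and_monotonicity_on_dense_grid(self, kind):
        spec = SigmoidSpec(kind, 4.0, 0.3)
        u = np.linspace(-50, 50, 100_001)
        out = sigmoid(spec, u)
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert np.all(np.diff(out) >= 0.0)

    @given(
        u=st.floats(-1e6, 1e6),
        beta=st.floats(0.1, 50.0),
        theta=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_smooth_variants_agree_at_threshold_and_stay_bounded(
        self, u, beta, theta
    ):
        for kind in ("abs_approx", "logistic"):
            spec = SigmoidSpec(kind, beta, theta)
            v = float(sigmoid(spec, u))
            assert 0.0 <= v <= 1.0
            assert float(sigmoid(spec, theta)) == pytest.approx(0.5, abs=1e-12)

    def test_rejects_non_finite_activation(self):
        with pytest.raises(FloatingPointError, match="percept"):
            sigmoid(SigmoidSpec(), np.array([1.0, np.nan]), component="percept")


class TestFieldRate:
    def test_resting_state_is_fixed_point(self, geo1d):
        f = FieldState(geo1d, h=-5.0)
        np.testing.assert_allclose(field_rate_of_change(f), 0.0)

    def test_direct_substitution_from_zero_activation(self, geo1d):
        f = FieldState(geo1d, h=-5.0, u=np.zeros(100))
        np.testing.assert_allclose(field_rate_of_change(f), -5.0)

    def test_input_shifts_the_attractor(self, geo1d):
        f = FieldState(geo1d, h=-5.0, inputs=np.full(100, 2.0))
        # fixed point at u = h + s
        f.u = np.full(100, -3.0)
        np.testing.assert_allclose(field_rate_of_change(f), 0.0)

    def test_shape_mismatch_rejected(self, geo1d):
        f = FieldState(geo1d)
        f.inputs = np.zeros(17)
        with pytest.raises(ValueError, match="shape"):
            field_rate_of_change(f)

    def test_relaxation_is_exactly_exponential_in_discrete_time(self, geo1d):
        """Without interaction the Euler trajectory follows a closed-form
        exponential relaxation to h + s (discrete decay rate)."""
        tau, dt, s, u0 = 100.0, 1.0, 2.0, 0.0
        f = FieldState(geo1d, tau=tau, h=-5.0, u=np.full(100, u0),
                       inputs=np.full(100, s))
        target = f.h + s
        n_steps = int(10 * tau / dt)
        traj = np.empty(n_steps)
        for i in range(n_steps):
            f.u = f.u + (dt / tau) * field_rate_of_change(f)
            traj[i] = f.u[0]
        n = np.arange(1, n_steps + 1)
        closed = target + (u0 - target) * (1.0 - dt / tau) ** n
        assert np.max(np.abs(traj - closed) / np.abs(target)) < 1e-12

    def test_euler_converges_to_continuous_solution_first_order(self):
        """Against the continuous-time exponential, halving dt roughly
        halves the terminal error (first-order convergence)."""
        tau, T, u0, target = 100.0, 500.0, 1.0, 0.0

        def terminal(dt):
            u = u0
            for _ in range(int(T / dt)):
                u += (dt / tau) * (-u)
            return u

        exact = u0 * np.exp(-T / tau)
        e1 = abs(terminal(tau / 10) - exact)
        e2 = abs(terminal(tau / 20) - exact)
        assert 1.7 < e1 / e2 < 2.3


class TestNodeRate:
    def test_resting_fixed_point(self):
        n = NodeState(h=-5.0, c_uu=0.0)
        assert node_rate_of_change(n) == pytest.approx(0.0)

    @pytest.mark.parametrize("c_uu, stays_on", [(25.0, True), (0.0, False)])
    def test_self_excitation_sustains_activation(self, c_uu, stays_on):
        """With strong self-excitation a node stays active after its input
        returns to zero (working memory); without it, activation decays."""
        n = NodeState(tau=50.0, h=-5.0, c_uu=c_uu,
                      sigmoid=SigmoidSpec("logistic", 4.0, 0.0))
        dt = 5.0
        for _ in range(200):  # transient s > -h
            n.u += (dt / n.tau) * node_rate_of_change(n, s=8.0)
        assert n.u > 0
        for _ in range(600):  # input removed
            n.u += (dt / n.tau) * node_rate_of_change(n, s=0.0)
        assert (n.u > 0) == stays_on


class TestMemoryTrace:
    def test_trace_at_source_output_is_stationary(self, geo1d):
        m = MemoryTraceState(geo1d, p=np.full(100, 0.4))
        np.testing.assert_allclose(
            memory_trace_rate(m, np.full(100, 0.4)), 0.0
        )

    def test_buildup_follows_low_pass_closed_form(self, geo1d):
        """Constant unit output from p=0 builds as 1 - exp(-t/tau_build)
        (discrete-time closed form, exact)."""
        tau_b, dt = 1000.0, 10.0
        m = MemoryTraceState(geo1d, tau_build=tau_b, tau_decay=5000.0)
        src = np.ones(100)
        traj = []
        for _ in range(300):
            m.p = m.p + dt * memory_trace_rate(m, src)
            traj.append(m.p[0])
        n = np.arange(1, 301)
        closed = 1.0 - (1.0 - dt / tau_b) ** n
        np.testing.assert_allclose(traj, closed, atol=1e-12)

    def test_decay_is_slower_than_buildup(self, geo1d):
        """Over the same span of time the trace gains more under a unit
        source than it loses after the source is removed (slower decay)."""
        m = MemoryTraceState(geo1d, tau_build=500.0, tau_decay=5000.0)
        src, zero = np.ones(100), np.zeros(100)
        dt, n = 10.0, 100
        for _ in range(n):
            m.p = m.p + dt * memory_trace_rate(m, src)
        gained = m.p[0]
        for _ in range(n):
            m.p = m.p + dt * memory_trace_rate(m, zero)
        lost = gained - m.p[0]
        assert 0 < lost < gained

    def test_trace_stays_in_unit_interval(self, geo1d, rng):
        m = MemoryTraceState(geo1d, tau_build=300.0, tau_decay=1000.0)
        for _ in range(500):
            src = rng.random(100)
            m.p = m.p + 10.0 * memory_trace_rate(m, src)
        assert m.p.min() >= 0.0 and m.p.max() <= 1.0


class TestZeroDimensionalEquivalence:
    def test_node_equals_zero_d_field_with_self_excitatory_kernel(self):
        """A 0-D field whose kernel contributes k(0) * g(u) reproduces a
        node with c_uu = k(0) step for step under identical seeds."""
        from dynfield.graph import ArchitectureGraph, ComponentSpec
        from dynfield.integration import ClockPolicy, Simulator

        sig = {"kind": "logistic", "beta": 4.0, "threshold": 0.0}
        node_graph = ArchitectureGraph(
            [ComponentSpec("n", "node",
                           {"tau": 50.0, "h": -5.0, "c_uu": 7.0,
                            "c_noise": 0.5, "sigmoid": sig})]
        )
        field_graph = ArchitectureGraph(
            [ComponentSpec("n", "field",
                           {"geometry": {"dim_names": [], "lower": [],
                                         "upper": [], "n_samples": []},
                            "tau": 50.0, "h": -5.0, "c_noise": 0.5,
                            "sigmoid": sig,
                            "kernel": {"c_exc": 7.0}})]
        )
        s1 = Simulator(node_graph, seed=42)
        s2 = Simulator(field_graph, seed=42)
        s1.external_inputs["n"] = 6.0
        s2.external_inputs["n"] = 6.0
        pol = ClockPolicy(dt_planned=5.0)
        for _ in range(3):
            s1.step(5.0)
            s2.step(5.0)
        for _ in range(100):
            s1.step(5.0)
            s2.step(5.0)
            assert float(s1.components["n"].state.u) == float(
                np.asarray(s2.components["n"].state.u)
            )
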