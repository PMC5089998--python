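"""Fixed-step stochastic integration and the architecture runtime.

All components of an architecture are advanced by the forward stochastic
Euler (Euler-Maruyama) method with a fixed planned step: for the dynamics
tau * du/dt = f(u) + c_noise * xi(t),

    u(t_i) = u(t_{i-1}) + (dt_i / tau) f(u(t_{i-1}))
                        + sqrt(dt_i) (c_noise / tau) xi_{i-1}

The deterministic term is linear in the step while the noise increment
scales with its square root, so noise statistics are step-size invariant.
Higher-order or adaptive-step integrators are deliberately not offered:
sensor streams arrive at a fixed cadence, and the attractor states of the
dynamics stabilize the numerics, permitting steps only one order of
magnitude below the relaxation time.

When a run drives (or emulates driving) real hardware, simulated time must
track wall-clock time. In real-time mode the runtime waits out the
remainder of each planned step; if a computation occasionally overruns the
planned step, that step alone is lengthened to the realized duration
("extended") so that simulated time snaps back in line with physical time.
A meter counts extensions and warns when they are frequent enough that the
planned step should be retuned.

Updates are synchronous: every coupling reads the source output published
at the end of the previous step, so evaluation order within a step never
matters. Multi-rate execution assigns components to step groups with their
own dt; groups due at the same instant are gathered jointly before any of
them publishes, which makes equal-dt groups bit-identical to a single-group
run and bounds cross-group staleness by the largest group step.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import graph as graph_mod
from .coupling import (
    CouplingSpec,
    boost,
    half_space_input,
    peak_detector_input,
    project,
    sheet_input,
)
from .dynamics import (
    FieldState,
    MemoryTraceState,
    NodeState,
    field_rate_of_change,
    memory_trace_rate,
    node_rate_of_change,
)
from .geometry import FieldGeometry
from .graph import ArchitectureGraph, StepGroup, validate
from .kernels import lateral_input
from .sensor_motor import (
    ReadoutState,
    encode_space_code,
    proprioceptive_input,
    readout_rate,
    render_scene,
)

__all__ = [
    "ClockPolicy",
    "StepLog",
    "StepGroup",
    "euler_maruyama_step",
    "SimulationDiverged",
    "Simulator",
]


class SimulationDiverged(RuntimeError):
    """Raised when a component's activation becomes non-finite."""


@dataclass(frozen=True)
class ClockPolicy:
    """How simulated steps relate to wall-clock time.

    ``realtime=False`` runs free (as fast as possible, fully deterministic
    per seed); ``realtime=True`` waits out each step to ``dt_planned`` ms.
    ``max_extension_ratio`` flags any single step stretched beyond that
    multiple of the plan; ``meter_fraction`` is the meter's alarm threshold
    on the fraction of extended steps.
    """

    dt_planned: float = 10.0
    realtime: bool = False
    max_extension_ratio: float = 3.0
    meter_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.dt_planned > 0:
            raise ValueError("dt_planned must be > 0")
        if self.max_extension_ratio < 1:
            raise ValueError("max_extension_ratio must be >= 1")


@dataclass
class StepLog:
    """Bookkeeping for one realized integration step."""

    i: int
    t_sim: float  # simulated time after the step, ms
    dt_actual: float  # realized step, ms
    extended: bool
    compute_ms: float


def euler_maruyama_step(
    state: np.ndarray | float,
    rate: np.ndarray | float,
    dt: float,
    tau: float,
    c_noise: float = 0.0,
    noise: np.ndarray | float = 0.0,
    component: str = "",
):
    """One stochastic Euler update; ``rate`` is the tau-scaled deterministic
    rate f(u) and ``noise`` a standard-normal sample of the state's shape."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    new = state + (dt / tau) * rate
    if c_noise > 0:
        new = new + np.sqrt(dt) * (c_noise / tau) * noise
    if not np.all(np.isfinite(new)):
        where = f" in component {component!r}" if component else ""
        raise SimulationDiverged(f"non-finite activation{where}; halting run")
    return new


# ----------------------------------------------------------------------
# runtime components


class _Component:
    kind = ""

    def __init__(self, name: str):
        self.name = name
        self._rate = None

    geometry: Optional[FieldGeometry] = None

    def initial_output(self):
        raise NotImplementedError

    def compute_rate(self, input_sum) -> None:
        self._rate = None

    def apply_step(self, dt: float, rng: np.random.Generator) -> None:
        pass

    def output(self):
        raise NotImplementedError

    def max_activation(self) -> float:
        return -np.inf


class _FieldComponent(_Component):
    kind = "field"

    def __init__(self, name, state: FieldState, padding="periodic", conv_method="auto"):
        super().__init__(name)
        self.state = state
        self.geometry = state.geometry
        self.padding = padding
        self.conv_method = conv_method

    def initial_output(self):
        return self.state.output()

    def compute_rate(self, input_sum) -> None:
        self.state.inputs = np.broadcast_to(
            np.asarray(input_sum, dtype=float), self.geometry.shape
        )
        lateral = 0.0
        if self.state.kernel is not None:
            if self.geometry.ndim == 0:
                # 0-D field: the kernel degenerates to scalar self-interaction
                # of strength k(0), matching a node's c_uu term
                k = self.state.kernel
                lateral = (k.c_exc - k.c_inh - k.c_glob) * self.state.output()
            else:
                lateral = lateral_input(
                    self.state.output(),
                    self.state.kernel,
                    self.geometry,
                    padding=self.padding,
                    method=self.conv_method,
                )
        self._rate = field_rate_of_change(self.state, lateral, component=self.name)

    def apply_step(self, dt, rng) -> None:
        noise = (
            rng.standard_normal(self.geometry.shape)
            if self.state.c_noise > 0
            else 0.0
        )
        self.state.u = euler_maruyama_step(
            self.state.u, self._rate, dt, self.state.tau,
            self.state.c_noise, noise, component=self.name,
        )

    def output(self):
        return self.state.output()

    def max_activation(self) -> float:
        return float(np.max(self.state.u))


class _NodeComponent(_Component):
    kind = "node"

    def __init__(self, name, state: NodeState):
        super().__init__(name)
        self.state = state

    def initial_output(self):
        return self.state.output()

    def compute_rate(self, input_sum) -> None:
        self._rate = node_rate_of_change(self.state, float(input_sum))

    def apply_step(self, dt, rng) -> None:
        noise = rng.standard_normal() if self.state.c_noise > 0 else 0.0
        self.state.u = float(
            euler_maruyama_step(
                self.state.u, self._rate, dt, self.state.tau,
                self.state.c_noise, noise, component=self.name,
            )
        )

    def output(self):
        return self.state.output()

    def max_activation(self) -> float:
        return float(self.state.u)


class _MemoryTraceComponent(_Component):
    kind = "memory_trace"

    def __init__(self, name, state: MemoryTraceState):
        super().__init__(name)
        self.state = state
        self.geometry = state.geometry

    def initial_output(self):
        return self.state.p.copy()

    def compute_rate(self, input_sum) -> None:
        source = np.clip(
            np.broadcast_to(np.asarray(input_sum, dtype=float), self.geometry.shape),
            0.0, 1.0,
        )
        # rate is dp/dt directly (the trace has its own time constants)
        self._rate = memory_trace_rate(self.state, source)

    def apply_step(self, dt, rng) -> None:
        self.state.p = euler_maruyama_step(
            self.state.p, self._rate, dt, tau=1.0, component=self.name
        )

    def output(self):
        return self.state.p.copy()


class _CameraSensor(_Component):
    """Static scene camera: renders and space-codes its scene once."""

    kind = "sensor"

    def __init__(self, name, geometry, scene, hue_smoothing_sigma=0.0, gain=1.0):
        super().__init__(name)
        self.geometry = geometry
        self.scene = scene
        image = render_scene(scene)
        self.tensor = encode_space_code(
            image, geometry, hue_smoothing_sigma, gain
        ).tensor

    def initial_output(self):
        return self.tensor

    def output(self):
        return self.tensor


class _ProprioSensor(_Component):
    """Gaussian bump over the table at the position fed in from a readout."""

    kind = "sensor"

    def __init__(self, name, geometry, amplitude=1.0, sigma=0.05):
        super().__init__(name)
        self.geometry = geometry
        self.amplitude = amplitude
        self.sigma = sigma
        self.grid = geometry.zeros()
        self._position = None

    def initial_output(self):
        return self.grid

    def compute_rate(self, input_sum) -> None:
        self._position = input_sum

    def apply_step(self, dt, rng) -> None:
        if self._position is not None:
            self.grid = proprioceptive_input(
                self._position, self.geometry, self.amplitude, self.sigma
            )

    def output(self):
        return self.grid


class _ReadoutComponent(_Component):
    kind = "readout"

    def __init__(self, name, geometry: FieldGeometry, state: ReadoutState):
        super().__init__(name)
        self.geometry = geometry
        self.state = state

    def initial_output(self):
        return self.state.x_ctrl.copy()

    def compute_rate(self, input_sum) -> None:
        grid = np.broadcast_to(
            np.asarray(input_sum, dtype=float), self.geometry.shape
        )
        self._rate = readout_rate(self.state, np.clip(grid, 0.0, None), self.geometry)

    def apply_step(self, dt, rng) -> None:
        self.state.x_ctrl = euler_maruyama_step(
            self.state.x_ctrl, self._rate, dt, self.state.tau_ctrl,
            component=self.name,
        )

    def output(self):
        return self.state.x_ctrl.copy()


# ----------------------------------------------------------------------
# builder


def _build_component(spec: graph_mod.ComponentSpec) -> _Component:
    p = spec.parameters
    if spec.kind == "field":
        geo = graph_mod.parse_geometry(p["geometry"])
        state = FieldState(
            geometry=geo,
            tau=float(p.get("tau", 100.0)),
            h=float(p.get("h", -5.0)),
            c_noise=float(p.get("c_noise", 0.0)),
            sigmoid=graph_mod.parse_sigmoid(p.get("sigmoid")),
            kernel=graph_mod.parse_kernel(p.get("kernel")),
        )
        return _FieldComponent(
            spec.name, state, p.get("padding", "periodic"), p.get("conv_method", "auto")
        )
    if spec.kind == "node":
        state = NodeState(
            tau=float(p.get("tau", 100.0)),
            h=float(p.get("h", -5.0)),
            c_noise=float(p.get("c_noise", 0.0)),
            c_uu=float(p.get("c_uu", 0.0)),
            sigmoid=graph_mod.parse_sigmoid(p.get("sigmoid")),
        )
        return _NodeComponent(spec.name, state)
    if spec.kind == "memory_trace":
        geo = graph_mod.parse_geometry(p["geometry"])
        state = MemoryTraceState(
            geometry=geo,
            tau_build=float(p.get("tau_build", 1000.0)),
            tau_decay=float(p.get("tau_decay", 10000.0)),
            feedback_gain=float(p.get("feedback_gain", 0.0)),
        )
        return _MemoryTraceComponent(spec.name, state)
    if spec.kind == "sensor":
        geo = graph_mod.parse_geometry(p["geometry"])
        if p.get("subkind", "camera") == "camera":
            return _CameraSensor(
                spec.name, geo, graph_mod.parse_scene(p["scene"]),
                float(p.get("hue_smoothing_sigma", 0.0)), float(p.get("gain", 1.0)),
            )
        return _ProprioSensor(
            spec.name, geo, float(p.get("amplitude", 1.0)), float(p.get("sigma", 0.05))
        )
    if spec.kind == "readout":
        geo = graph_mod.parse_geometry(p["geometry"])
        init = p.get("init", [0.5 * (lo + up) for lo, up in zip(geo.lower, geo.upper)])
        fixed = {int(k): float(v) for k, v in p.get("fixed_components", {}).items()}
        state = ReadoutState(
            np.asarray(init, dtype=float),
            tau_ctrl=float(p.get("tau_ctrl", 200.0)),
            fixed_components=fixed,
        )
        return _ReadoutComponent(spec.name, geo, state)
    raise ValueError(f"unknown component kind {spec.kind!r}")


def _contribution(
    cpl: CouplingSpec, source: _Component, target: _Component, source_output
):
    if cpl.special == "none":
        return project(
            np.asarray(source_output, dtype=float)
            if source.geometry is not None
            else np.asarray(source_output),
            cpl,
            source.geometry or FieldGeometry(()),
            target.geometry or FieldGeometry(()),
        )
    if cpl.special == "boost":
        return boost(float(source_output), target.geometry, cpl.gain)
    if cpl.special == "peak_detector":
        return peak_detector_input(
            np.asarray(source_output), source.geometry.cell_volume, cpl.gain
        )
    if cpl.special == "sheet":
        return sheet_input(
            float(source_output),
            float(cpl.params["hue_center"]),
            float(cpl.params["hue_sigma"]),
            target.geometry,
            cpl.gain,
            hue_dim=cpl.params.get("hue_dim", "hue"),
        )
    if cpl.special == "half_space":
        return half_space_input(
            float(source_output),
            cpl.params["side"],
            float(cpl.params.get("softness", 0.05)),
            target.geometry,
            cpl.gain,
            axis_dim=cpl.params.get("axis_dim", "x"),
        )
    if cpl.special == "proprio":
        return np.asarray(source_output, dtype=float)  # position passthrough
    raise ValueError(f"unsupported coupling special {cpl.special!r}")


# ----------------------------------------------------------------------
# the simulator


class Simulator:
    """Executable instance of a validated architecture graph.

    Noise is drawn from one child generator per component, spawned from the
    master seed, so free-running trajectories are reproducible bit-for-bit
    and independent of scheduling order. ``external_inputs`` maps component
    names to additional input terms (scalars or grids) that protocols may
    set between steps (user cues, probe inputs).
    """

    def __init__(self, graph: ArchitectureGraph, seed: int = 0, check: bool = True):
        if check:
            diags = validate(graph)
            if diags:
                raise ValueError(
                    "invalid architecture graph:\n  " + "\n  ".join(diags)
                )
        self.graph = graph
        self.components: dict[str, _Component] = {}
        for spec in graph.components:
            self.components[spec.name] = _build_component(spec)
        self.couplings = list(graph.couplings)
        seeds = np.random.SeedSequence(seed).spawn(len(self.components))
        self._rngs = {
            name: np.random.default_rng(s)
            for name, s in zip(self.components, seeds)
        }
        self.external_inputs: dict[str, object] = {}
        self.last_inputs: dict[str, object] = {}
        self.published = {
            name: comp.initial_output() for name, comp in self.components.items()
        }
        self._published_at = {name: 0.0 for name in self.components}
        self.t_sim = 0.0
        self.max_staleness = 0.0

    # -- state inspection ------------------------------------------------
    def component(self, name: str) -> _Component:
        return self.components[name]

    def max_activation(self, name: str) -> float:
        return self.components[name].max_activation()

    def suprathreshold(self, name: str) -> bool:
        return self.max_activation(name) > 0.0

    # -- stepping --------------------------------------------------------
    def _gather(self, members) -> dict:
        inputs: dict[str, object] = {}
        for cpl in self.couplings:
            if cpl.target not in members:
                continue
            src = self.components[cpl.source]
            tgt = self.components[cpl.target]
            contrib = _contribution(cpl, src, tgt, self.published[cpl.source])
            gap = abs(self.t_sim - self._published_at[cpl.source])
            if gap > self.max_staleness:
                self.max_staleness = gap
            if cpl.special == "proprio":
                inputs[cpl.target] = contrib  # position, not additive input
            elif cpl.target in inputs:
                inputs[cpl.target] = inputs[cpl.target] + contrib
            else:
                inputs[cpl.target] = contrib
        for name in members:
            if name in self.external_inputs:
                ext = self.external_inputs[name]
                inputs[name] = inputs.get(name, 0.0) + ext
        return inputs

    def _compute_rates(self, members, inputs) -> None:
        for name in members:
            self.last_inputs[name] = inputs.get(name, 0.0)
            self.components[name].compute_rate(inputs.get(name, 0.0))

    def _apply(self, members, dt: float) -> None:
        for name in members:
            self.components[name].apply_step(dt, self._rngs[name])

    def _publish(self, members, t: float) -> None:
        for name in members:
            self.published[name] = self.components[name].output()
            self._published_at[name] = t

    def step(self, dt: float) -> None:
        """One synchronous free-running step of every component."""
        members = list(self.components)
        inputs = self._gather(members)
        self._compute_rates(members, inputs)
        self._apply(members, dt)
        self.t_sim += dt
        self._publish(members, self.t_sim)

    # -- runs ------------------------------------------------------------
    def _warn_dt(self, dt: float) -> None:
        taus = [
            c.state.tau
            for c in self.components.values()
            if isinstance(c, (_FieldComponent, _NodeComponent))
        ]
        if taus and dt > min(taus) / 10.0 + 1e-12:
            warnings.warn(
                f"planned step {dt} ms exceeds one tenth of the smallest "
                f"time constant ({min(taus)} ms); numerics may be crude",
                stacklevel=3,
            )

    def run(
        self,
        duration: float,
        policy: Optional[ClockPolicy] = None,
        callback: Optional[Callable[["Simulator", StepLog], Optional[bool]]] = None,
        compute_hook: Optional[Callable[[int], None]] = None,
        recorder=None,
    ) -> list[StepLog]:
        """Integrate all components for ``duration`` ms.

        In real-time mode each step waits out the remainder of the planned
        step; a step whose computation overruns the plan is extended to the
        realized duration to re-align simulated with physical time. Returns
        the per-step log ("the meter"); a warning recommends a larger step
        when extensions are too frequent.
        """
        policy = policy or ClockPolicy()
        self._warn_dt(policy.dt_planned)
        n_steps = int(round(duration / policy.dt_planned))
        logs: list[StepLog] = []
        members = list(self.components)
        # absolute deadlines: waiting targets the end of each planned step,
        # so sleep jitter does not accumulate into drift between simulated
        # and physical time
        wall_origin = time.perf_counter()
        deadline_ms = 0.0
        for i in range(n_steps):
            step_start = time.perf_counter()
            inputs = self._gather(members)
            self._compute_rates(members, inputs)
            if compute_hook is not None:
                compute_hook(i)
            compute_ms = (time.perf_counter() - step_start) * 1000.0
            deadline_ms += policy.dt_planned
            now_ms = (time.perf_counter() - wall_origin) * 1000.0
            extended = policy.realtime and now_ms > deadline_ms
            if extended:
                # lengthen only this step to bring simulated time back in
                # line with physical time; the next step reverts to the plan
                dt_actual = policy.dt_planned + (now_ms - deadline_ms)
                deadline_ms = now_ms
            else:
                dt_actual = policy.dt_planned
            self._apply(members, dt_actual)
            self.t_sim += dt_actual
            self._publish(members, self.t_sim)
            if extended and dt_actual > policy.max_extension_ratio * policy.dt_planned:
                warnings.warn(
                    f"step {i} extended to {dt_actual:.1f} ms "
                    f"(> {policy.max_extension_ratio} x planned)",
                    stacklevel=2,
                )
            log = StepLog(i, self.t_sim, dt_actual, extended, compute_ms)
            logs.append(log)
            if recorder is not None:
                recorder.observe(self, log)
            if callback is not None and callback(self, log):
                break
            if policy.realtime and not extended:
                remaining_s = deadline_ms / 1000.0 - (
                    time.perf_counter() - wall_origin
                )
                if remaining_s > 0:
                    time.sleep(remaining_s)
        if logs:
            frac = sum(l.extended for l in logs) / len(logs)
            if frac > policy.meter_fraction:
                warnings.warn(
                    f"{frac:.0%} of steps were extended; consider a larger "
                    "planned Euler step",
                    stacklevel=2,
                )
        return logs

    def multirate_run(
        self,
        duration: float,
        recorder=None,
    ) -> dict[str, list[StepLog]]:
        """Free-running multi-rate execution over the graph's step groups.

        Each group steps on its own schedule; couplings across groups read
        the producing group's most recently published output, so input
        staleness never exceeds the largest group step. Groups due at the
        same instant gather their inputs jointly before any publishes,
        preserving the synchronous-update contract.
        """
        groups = self.graph.groups
        if not groups:
            raise ValueError("multirate_run requires step groups in the graph")
        for g in groups:
            self._warn_dt(g.dt)
        logs: dict[str, list[StepLog]] = {
            (g.name or f"group{gi}"): [] for gi, g in enumerate(groups)
        }
        counts = [0] * len(groups)
        eps = 1e-9
        while True:
            due_times = [counts[gi] * g.dt for gi, g in enumerate(groups)]
            t = min(due_times)
            if t >= duration - eps:
                break
            due = [
                gi for gi, g in enumerate(groups) if due_times[gi] <= t + eps
            ]
            # gather for all due groups against the same published state
            self.t_sim = t
            gathered = {}
            for gi in due:
                members = list(groups[gi].members)
                gathered[gi] = (members, self._gather(members))
            for gi in due:
                members, inputs = gathered[gi]
                self._compute_rates(members, inputs)
            for gi in due:
                members, _ = gathered[gi]
                dt = groups[gi].dt
                self._apply(members, dt)
                self._publish(members, t + dt)
                counts[gi] += 1
                name = groups[gi].name or f"group{gi}"
                logs[name].append(
                    StepLog(counts[gi] - 1, t + dt, dt, False, 0.0)
                )
            self.t_sim = min(counts[gi] * g.dt for gi, g in enumerate(groups))
            if recorder is not None:
                recorder.observe(self, None)
        self.t_sim = max(counts[gi] * g.dt for gi, g in enumerate(groups))
        return logs
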