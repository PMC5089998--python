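"""Feature-search-and-point exemplar architecture and trial machinery.

The task: a camera looks at colored objects on a tabletop; the system is
cued with a color concept ("green") and a spatial term ("left"), selects
the matching object, moves a (simulated) pointer to it, detects its own
arrival, and resets, ready for the next cue.

The architecture wires up the concepts of the framework end to end:

* four bistable cue nodes (red, green, left, right), flipped on by a
  transient user boost and staying on via self-excitation;
* a 3-D perceptual field over (table-x, table-y, hue) in the single-peak
  regime, receiving space-coded camera input, hue-localized "sheets" from
  the color nodes, and soft half-space ramps from the spatial nodes — a
  peak forms only where camera input overlaps both cues;
* a normalization-free attractor readout contracting the perceptual output
  over hue and steering the pointer to the peak location;
* a 2-D condition-of-satisfaction (CoS) field receiving the (individually
  subthreshold) target projection and a proprioceptive bump at the pointer
  position; their overlap on arrival drives the CoS through a detection
  instability, and its peak inhibits the perceptual field and all cue
  nodes, resetting the whole architecture below threshold.

A small condition/action trial runner automates cue delivery and outcome
classification, and ``regime_scan`` maps the detection / reverse-detection
/ selection instabilities of an isolated probe field by ramping a parameter
up and down while counting suprathreshold peaks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dfield
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .coupling import CouplingSpec, DimensionMap
from .dynamics import FieldState, SigmoidSpec, field_rate_of_change
from .geometry import FieldGeometry
from .graph import ArchitectureGraph, ComponentSpec, validate
from .integration import ClockPolicy, Simulator, euler_maruyama_step
from .kernels import KernelSpec, lateral_input
from .sensor_motor import SceneObject, SceneSpec

__all__ = [
    "DEMO_DEFAULTS",
    "default_scene",
    "build_demo",
    "TrialRule",
    "TrialProtocol",
    "TrialOutcome",
    "cue_protocol",
    "run_trial",
    "detect_peaks",
    "regime_scan",
    "ScanReport",
]

# hue values of the cue colors (fractions of the hue circle)
CUE_HUES = {"red": 0.0, "green": 1.0 / 3.0}
CUE_SIDES = ("left", "right")

# Shipped default tuning of the exemplar. The contracts it realizes (and
# that the test suite audits): camera input alone keeps the perceptual
# field subthreshold; camera + one cue stays subthreshold; camera + both
# cues pushes exactly one peak through the detection instability at the
# matching object; both CoS inputs are individually subthreshold and
# jointly suprathreshold; after the CoS event everything returns below
# threshold.
DEMO_DEFAULTS: dict = {
    "table": {"lower": [0.0, 0.0], "upper": [1.0, 1.0], "n_xy": 24, "n_hue": 16},
    "image_size": [48, 48],
    "perceptual": {
        "tau": 100.0,
        "h": -5.0,
        "c_noise": 1.0,
        "sigmoid": {"kind": "logistic", "beta": 4.0, "threshold": 0.0},
        "kernel": {
            "c_exc": 1300.0,
            "sigma_exc": [0.07, 0.07, 0.09],
            "c_inh": 0.0,
            "sigma_inh": [0.14, 0.14, 0.18],
            "c_glob": 220.0,
            "truncation": 4.5,
        },
    },
    "cos": {
        "tau": 100.0,
        "h": -5.0,
        "c_noise": 1.0,
        "sigmoid": {"kind": "logistic", "beta": 4.0, "threshold": 0.0},
        # commit-then-release regime: a peak self-stabilizes decisively at
        # the combined (target + proprioceptive) input but cannot survive on
        # the proprioceptive bump alone, so the CoS event terminates itself
        "kernel": {
            "c_exc": 600.0,
            "sigma_exc": [0.06, 0.06],
            "c_inh": 0.0,
            "sigma_inh": [0.12, 0.12],
            "c_glob": 150.0,
            "truncation": 4.5,
        },
    },
    "nodes": {"tau": 100.0, "h": -5.0, "c_uu": 7.0, "c_noise": 0.2,
        "sigmoid": {"kind": "logistic", "beta": 4.0, "threshold": 0.0}},
    "camera_gain": 3.5,
    "hue_smoothing_sigma": 0.03,
    "sheet_gain": 1.6,
    "sheet_sigma": 0.07,
    "half_space_gain": 1.6,
    "half_space_softness": 0.08,
    "readout": {"tau_ctrl": 60.0, "init": [0.5, 0.5], "input_gain": 60.0},
    "proprio": {"amplitude": 2.6, "sigma": 0.07},
    "cos_target_gain": 60.0,
    "cos_smoothing_sigma": 0.05,
    "cos_to_perceptual_gain": -400.0,
    "cos_to_node_gain": -450.0,
}


def default_scene(image_size: Sequence[int] = (48, 48)) -> SceneSpec:
    """Four-object scene: green/red objects on the left/right half."""
    return SceneSpec(
        image_size=tuple(image_size),
        objects=(
            SceneObject(center=(0.25, 0.3), radius=4.5, hue=CUE_HUES["green"]),
            SceneObject(center=(0.75, 0.3), radius=4.5, hue=CUE_HUES["green"]),
            SceneObject(center=(0.25, 0.7), radius=4.5, hue=CUE_HUES["red"]),
            SceneObject(center=(0.75, 0.7), radius=4.5, hue=CUE_HUES["red"]),
        ),
    )


def _merge(base: dict, overrides: Optional[dict]) -> dict:
    out = copy.deepcopy(base)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def build_demo(
    scene: Optional[SceneSpec] = None, overrides: Optional[dict] = None
) -> ArchitectureGraph:
    """Assemble the fully parameterized feature-search graph.

    ``overrides`` is a nested mapping merged over :data:`DEMO_DEFAULTS`
    (e.g. ``{"perceptual": {"kernel": {"c_glob": 100.0}}}``).
    """
    p = _merge(DEMO_DEFAULTS, overrides)
    t = p["table"]
    scene = scene or default_scene(p["image_size"])

    geo3 = {
        "dim_names": ["x", "y", "hue"],
        "lower": [t["lower"][0], t["lower"][1], 0.0],
        "upper": [t["upper"][0], t["upper"][1], 1.0],
        "n_samples": [t["n_xy"], t["n_xy"], t["n_hue"]],
        "circular": [False, False, True],
    }
    geo2 = {
        "dim_names": ["x", "y"],
        "lower": list(t["lower"]),
        "upper": list(t["upper"]),
        "n_samples": [t["n_xy"], t["n_xy"]],
        "circular": [False, False],
    }
    scene_dict = {
        "image_size": list(scene.image_size),
        "table_lower": list(scene.table_lower),
        "table_upper": list(scene.table_upper),
        "background_value": scene.background_value,
        "objects": [
            {
                "center": list(o.center),
                "radius": o.radius,
                "hue": o.hue,
                "saturation": o.saturation,
            }
            for o in scene.objects
        ],
    }

    components = [
        ComponentSpec(
            "camera",
            "sensor",
            {
                "subkind": "camera",
                "geometry": geo3,
                "scene": scene_dict,
                "hue_smoothing_sigma": p["hue_smoothing_sigma"],
                "gain": p["camera_gain"],
            },
        ),
        ComponentSpec("perceptual", "field", {"geometry": geo3, **p["perceptual"]}),
        ComponentSpec("cos", "field", {"geometry": geo2, **p["cos"]}),
        ComponentSpec(
            "readout",
            "readout",
            {
                "geometry": geo2,
                "tau_ctrl": p["readout"]["tau_ctrl"],
                "init": list(p["readout"]["init"]),
            },
        ),
        ComponentSpec(
            "proprio",
            "sensor",
            {"subkind": "proprio", "geometry": geo2, **p["proprio"]},
        ),
    ]
    for name in ("red", "green", "left", "right"):
        components.append(ComponentSpec(name, "node", dict(p["nodes"])))

    couplings = [
        # camera space code drives the perceptual field one-to-one
        CouplingSpec("camera", "perceptual", DimensionMap.identity(3), gain=1.0),
        # color cue sheets: localized along hue, homogeneous over space
        *[
            CouplingSpec(
                color,
                "perceptual",
                special="sheet",
                gain=p["sheet_gain"],
                params={"hue_center": CUE_HUES[color], "hue_sigma": p["sheet_sigma"]},
            )
            for color in ("red", "green")
        ],
        # spatial cue half-space ramps, homogeneous along hue
        *[
            CouplingSpec(
                side,
                "perceptual",
                special="half_space",
                gain=p["half_space_gain"],
                params={"side": side, "softness": p["half_space_softness"]},
            )
            for side in CUE_SIDES
        ],
        # perceptual -> readout: contract hue, positive weight
        CouplingSpec(
            "perceptual",
            "readout",
            DimensionMap(((0, 0), (1, 1))),
            gain=p["readout"]["input_gain"],
        ),
        # perceptual -> CoS: hue-contracted, kernel-smoothed target bump
        CouplingSpec(
            "perceptual",
            "cos",
            DimensionMap(((0, 0), (1, 1))),
            gain=p["cos_target_gain"],
            smoothing=KernelSpec(
                c_exc=1.0 / (2.0 * np.pi * p["cos_smoothing_sigma"] ** 2),
                sigma_exc=(p["cos_smoothing_sigma"], p["cos_smoothing_sigma"]),
            ),
        ),
        # effector loop: readout position -> proprioceptive bump -> CoS
        CouplingSpec("readout", "proprio", special="proprio"),
        CouplingSpec("proprio", "cos", DimensionMap.identity(2), gain=1.0),
        # CoS peak inhibits the perceptual field homogeneously (its output
        # mass is contracted to a scalar and broadcast over all of x/y/hue,
        # so the reverse detection cannot be escaped by peak drift) ...
        CouplingSpec(
            "cos",
            "perceptual",
            DimensionMap(()),
            gain=p["cos_to_perceptual_gain"],
        ),
        # ... and all cue nodes (contraction into a scalar inhibition)
        *[
            CouplingSpec(
                "cos", node, special="peak_detector", gain=p["cos_to_node_gain"]
            )
            for node in ("red", "green", "left", "right")
        ],
    ]
    graph = ArchitectureGraph(
        components, couplings, metadata={"demo": "feature_search"}
    )
    diags = validate(graph)
    if diags:
        raise ValueError("demo graph failed validation:\n  " + "\n  ".join(diags))
    return graph


# ----------------------------------------------------------------------
# condition/action trial runner


@dataclass
class TrialRule:
    """One condition -> action rule; evaluated once per step, fires once.

    Conditions: ``("at_time", t_ms)``, ``("suprathreshold", component)``,
    ``("subthreshold", component)``. Actions: ``("boost", component,
    amplitude, duration_ms)``, ``("release", component)``,
    ``("set_external", component, value)``, ``("end_trial", delay_ms)``.
    """

    condition: tuple
    action: tuple
    fired: bool = False

    def condition_met(self, sim: Simulator, t: float) -> bool:
        kind = self.condition[0]
        if kind == "at_time":
            return t >= self.condition[1]
        if kind == "suprathreshold":
            return sim.suprathreshold(self.condition[1])
        if kind == "subthreshold":
            return not sim.suprathreshold(self.condition[1])
        raise ValueError(f"unknown condition {kind!r}")


@dataclass
class TrialProtocol:
    """Ordered condition/action rules plus a hard timeout."""

    rules: list[TrialRule]
    timeout: float = 5000.0  # ms
    dt: float = 10.0


@dataclass
class TrialOutcome:
    """Classification of one trial of the feature-search task."""

    selected_object: Optional[int]
    cos_triggered: bool
    reset_clean: bool
    latency: Optional[float]  # ms, first cue boost -> CoS detection
    final_position: Optional[np.ndarray] = None


def cue_protocol(
    color: str,
    side: str,
    boost_amplitude: float = 8.0,
    boost_duration: float = 300.0,
    t_cue: float = 100.0,
    settle_after_cos: float = 2000.0,
    timeout: float = 5000.0,
    dt: float = 10.0,
) -> TrialProtocol:
    """Standard single-cue trial: boost both cue nodes at ``t_cue``, end
    ``settle_after_cos`` ms after the CoS detection (or at the timeout)."""
    rules = [
        TrialRule(("at_time", t_cue), ("boost", color, boost_amplitude, boost_duration)),
        TrialRule(("at_time", t_cue), ("boost", side, boost_amplitude, boost_duration)),
        TrialRule(("suprathreshold", "cos"), ("end_trial", settle_after_cos)),
    ]
    return TrialProtocol(rules, timeout=timeout, dt=dt)


def run_trial(
    graph: ArchitectureGraph,
    protocol: TrialProtocol,
    seed: int = 0,
    recorder=None,
    sim: Optional[Simulator] = None,
) -> TrialOutcome:
    """Execute one condition/action trial on the feature-search graph.

    Free-running (deterministic per seed). Returns the classified outcome;
    ``cos_triggered=False`` marks a timeout. Pass an existing ``sim`` to run
    a second protocol on the same architecture state (e.g. a second cue
    after a reset).
    """
    sim = sim or Simulator(graph, seed=seed)
    rules = [TrialRule(r.condition, r.action) for r in protocol.rules]
    active_boosts: dict[str, list[list[float]]] = {}
    state = {
        "cue_time": None,
        "cos_time": None,
        "end_time": None,
    }

    def apply_action(action: tuple, t: float) -> None:
        kind = action[0]
        if kind == "boost":
            _, comp, amplitude, duration = action
            active_boosts.setdefault(comp, []).append([amplitude, t + duration])
            if state["cue_time"] is None:
                state["cue_time"] = t
        elif kind == "release":
            active_boosts.pop(action[1], None)
        elif kind == "set_external":
            sim.external_inputs[action[1]] = action[2]
        elif kind == "end_trial":
            delay = action[1] if len(action) > 1 else 0.0
            state["end_time"] = t + delay
        else:
            raise ValueError(f"unknown action {kind!r}")

    def callback(sim_: Simulator, log) -> bool:
        t = sim_.t_sim
        for rule in rules:
            if not rule.fired and rule.condition_met(sim_, t):
                rule.fired = True
                apply_action(rule.action, t)
        # refresh transient boosts
        for comp, entries in list(active_boosts.items()):
            entries[:] = [e for e in entries if e[1] > t]
            total = sum(e[0] for e in entries)
            if total:
                sim_.external_inputs[comp] = total
            else:
                sim_.external_inputs.pop(comp, None)
                if not entries:
                    del active_boosts[comp]
        if state["cos_time"] is None and sim_.suprathreshold("cos"):
            state["cos_time"] = t
        return state["end_time"] is not None and t >= state["end_time"]

    sim.run(
        protocol.timeout,
        ClockPolicy(dt_planned=protocol.dt, realtime=False),
        callback=callback,
        recorder=recorder,
    )

    cos_triggered = state["cos_time"] is not None
    latency = (
        state["cos_time"] - state["cue_time"]
        if cos_triggered and state["cue_time"] is not None
        else None
    )
    dynamic = [
        c.name
        for c in sim.components.values()
        if c.kind in ("field", "node")
    ]
    reset_clean = all(sim.max_activation(n) < 0.0 for n in dynamic)

    selected = None
    final_pos = None
    if "readout" in sim.components:
        final_pos = sim.components["readout"].state.x_ctrl.copy()
    if cos_triggered and final_pos is not None:
        cam = sim.components.get("camera")
        objects = getattr(getattr(cam, "scene", None), "objects", ())
        if objects:
            dists = [
                float(np.hypot(*(final_pos - np.asarray(o.center))))
                for o in objects
            ]
            selected = int(np.argmin(dists))
    return TrialOutcome(selected, cos_triggered, reset_clean, latency, final_pos)


# ----------------------------------------------------------------------
# instability diagnostics


@dataclass
class Peak:
    """One suprathreshold connected component of a field."""

    centroid: np.ndarray
    mass: float
    n_cells: int


def detect_peaks(
    u: np.ndarray, geometry: FieldGeometry, min_cells: int = 2
) -> list[Peak]:
    """Suprathreshold peaks: connected components of u > 0 (face
    connectivity), ignoring single-cell noise excursions; centroid is the
    output-weighted mean restricted to the component."""
    mask = u > 0.0
    labels, n = ndimage.label(mask)  # default structure = face connectivity
    mesh = geometry.meshgrid()
    peaks = []
    for lab in range(1, n + 1):
        cells = labels == lab
        count = int(cells.sum())
        if count < min_cells:
            continue
        w = np.where(cells, u, 0.0)
        mass = float(w.sum())
        centroid = np.array([float((m * w).sum()) / mass for m in mesh])
        peaks.append(Peak(centroid, mass * geometry.cell_volume, count))
    return peaks


@dataclass
class ScanLevel:
    level: float
    n_peaks: int
    locations: list[np.ndarray]
    max_u: float


@dataclass
class ScanReport:
    """Result of an up/down parameter ramp on an isolated probe field."""

    up: list[ScanLevel] = dfield(default_factory=list)
    down: list[ScanLevel] = dfield(default_factory=list)
    detection_level: Optional[float] = None  # first peak going up
    reverse_level: Optional[float] = None  # last level with a peak going down
    sustained: bool = False  # peak survives down to the lowest level

    @property
    def hysteresis_width(self) -> Optional[float]:
        if self.detection_level is None or self.reverse_level is None:
            return None
        return self.detection_level - self.reverse_level


def regime_scan(
    geometry: FieldGeometry,
    kernel: KernelSpec,
    probe: np.ndarray | Callable[[float], np.ndarray],
    levels: Sequence[float],
    scan: str = "input_gain",
    h: float = -5.0,
    tau: float = 100.0,
    c_noise: float = 0.0,
    sigmoid: Optional[SigmoidSpec] = None,
    dt: float = 10.0,
    hold_steps: int = 120,
    seed: int = 0,
    down: bool = True,
    min_cells: int = 2,
) -> ScanReport:
    """Ramp a parameter up (then down) on an isolated field and record the
    suprathreshold peak count and locations at the end of each plateau.

    ``scan`` selects what the level means: ``input_gain`` scales the probe
    input pattern; ``kernel.c_glob`` / ``kernel.c_exc`` / ``kernel.c_inh``
    rebuild the kernel at each level with the probe held fixed. Activation
    carries over between plateaus, which is what exposes hysteresis between
    the detection and reverse-detection instabilities.
    """
    sigmoid = sigmoid or SigmoidSpec()
    rng = np.random.default_rng(seed)
    state = FieldState(
        geometry, tau=tau, h=h, c_noise=c_noise, sigmoid=sigmoid, kernel=kernel
    )

    def configure(level: float) -> tuple[np.ndarray, KernelSpec]:
        if callable(probe):
            base = np.asarray(probe(level), dtype=float)
        else:
            base = np.asarray(probe, dtype=float)
        if scan == "input_gain":
            return level * base, kernel
        if scan.startswith("kernel."):
            attr = scan.split(".", 1)[1]
            return base, KernelSpec(
                **{
                    **{
                        "c_exc": kernel.c_exc,
                        "sigma_exc": kernel.sigma_exc,
                        "c_inh": kernel.c_inh,
                        "sigma_inh": kernel.sigma_inh,
                        "c_glob": kernel.c_glob,
                        "truncation": kernel.truncation,
                    },
                    attr: level,
                }
            )
        raise ValueError(f"unknown scan axis {scan!r}")

    def run_plateau(level: float) -> ScanLevel:
        s, k = configure(level)
        state.kernel = k
        state.inputs = s
        for _ in range(hold_steps):
            lateral = lateral_input(
                state.output(), k, geometry, padding="periodic", method="auto"
            )
            rate = field_rate_of_change(state, lateral)
            noise = rng.standard_normal(geometry.shape) if c_noise > 0 else 0.0
            state.u = euler_maruyama_step(
                state.u, rate, dt, tau, c_noise, noise
            )
        peaks = detect_peaks(state.u, geometry, min_cells=min_cells)
        return ScanLevel(
            level, len(peaks), [p.centroid for p in peaks], float(state.u.max())
        )

    report = ScanReport()
    for level in levels:
        sl = run_plateau(level)
        report.up.append(sl)
        if report.detection_level is None and sl.n_peaks > 0:
            report.detection_level = level
    if down:
        for level in list(levels)[::-1]:
            sl = run_plateau(level)
            report.down.append(sl)
            if sl.n_peaks > 0:
                report.reverse_level = level
        if report.down and report.down[-1].n_peaks > 0:
            report.sustained = True
    return report
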