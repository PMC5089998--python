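"""Architecture graphs: data model, JSON config serialization, validation.

An architecture is a named set of components — dynamic fields, nodes,
memory traces, sensors, and readouts — plus directed couplings between
them and optional step groups for multi-rate integration. Graphs may (and
usually do) contain cycles: recurrence is the norm, not an error.

The on-disk format is a single JSON document mirroring the dataclasses
here. Unknown keys are rejected on load (a silently ignored typo in a
parameter name is the classic tuning hazard); parameter *ranges* are not
enforced on load but reported by :func:`validate`, which is total — it
never raises on structurally well-formed input, it returns every violation
it finds.

Dimension-order convention: 3-D fields are (table-x, table-y, hue); grids
are flattened row-major wherever a flat order is needed (recording, docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .coupling import CouplingSpec, DimensionMap
from .dynamics import SIGMOID_KINDS, SigmoidSpec
from .geometry import FieldGeometry
from .kernels import CONV_METHODS, PADDING_MODES, KernelSpec
from .sensor_motor import SceneObject, SceneSpec

__all__ = [
    "ComponentSpec",
    "StepGroup",
    "ArchitectureGraph",
    "validate",
    "serialize",
    "deserialize",
    "save",
    "load",
]

COMPONENT_KINDS = ("field", "node", "memory_trace", "sensor", "readout")

_PARAM_KEYS = {
    "field": {"geometry", "tau", "h", "c_noise", "sigmoid", "kernel", "padding", "conv_method"},
    "node": {"tau", "h", "c_noise", "c_uu", "sigmoid"},
    "memory_trace": {"geometry", "tau_build", "tau_decay", "feedback_gain"},
    "sensor": {"subkind", "geometry", "scene", "hue_smoothing_sigma", "gain", "amplitude", "sigma"},
    "readout": {"geometry", "tau_ctrl", "init", "fixed_components"},
}
_GEOMETRY_KEYS = {"dim_names", "lower", "upper", "n_samples", "circular"}
_SIGMOID_KEYS = {"kind", "beta", "threshold"}
_KERNEL_KEYS = {"c_exc", "sigma_exc", "c_inh", "sigma_inh", "c_glob", "truncation"}
_SCENE_KEYS = {"image_size", "table_lower", "table_upper", "objects", "background_value"}
_OBJECT_KEYS = {"center", "radius", "hue", "saturation"}
_COUPLING_KEYS = {"source", "target", "map", "gain", "smoothing", "special", "params", "resample"}
_GROUP_KEYS = {"name", "members", "dt"}
_COMPONENT_KEYS = {"name", "kind", "parameters"}
_TOP_KEYS = {"components", "couplings", "groups", "metadata"}


@dataclass
class ComponentSpec:
    """One named component with a kind-specific parameter block (plain dict,
    keys as in the config schema)."""

    name: str
    kind: str
    parameters: dict = field(default_factory=dict)


@dataclass
class StepGroup:
    """Components integrated together on a shared Euler step of ``dt`` ms."""

    members: tuple[str, ...]
    dt: float
    name: str = ""

    def __post_init__(self) -> None:
        self.members = tuple(self.members)


@dataclass
class ArchitectureGraph:
    components: list[ComponentSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    groups: list[StepGroup] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"no component named {name!r}")

    def names(self) -> list[str]:
        return [c.name for c in self.components]


# ----------------------------------------------------------------------
# typed parameter parsing (shared by validation and the runtime builder)


def parse_geometry(d: dict) -> FieldGeometry:
    return FieldGeometry(
        tuple(d["dim_names"]),
        tuple(d["lower"]),
        tuple(d["upper"]),
        tuple(d["n_samples"]),
        tuple(d.get("circular", ())),
    )


def parse_sigmoid(d: Optional[dict]) -> SigmoidSpec:
    d = d or {}
    return SigmoidSpec(
        kind=d.get("kind", "abs_approx"),
        beta=float(d.get("beta", 4.0)),
        threshold=float(d.get("threshold", 0.0)),
    )


def _tuple_or_scalar(v):
    return tuple(float(x) for x in v) if isinstance(v, (list, tuple)) else float(v)


def parse_kernel(d: Optional[dict]) -> Optional[KernelSpec]:
    if d is None:
        return None
    return KernelSpec(
        c_exc=float(d.get("c_exc", 0.0)),
        sigma_exc=_tuple_or_scalar(d.get("sigma_exc", 1.0)),
        c_inh=float(d.get("c_inh", 0.0)),
        sigma_inh=_tuple_or_scalar(d.get("sigma_inh", 1.0)),
        c_glob=float(d.get("c_glob", 0.0)),
        truncation=float(d.get("truncation", 5.0)),
    )


def parse_scene(d: dict) -> SceneSpec:
    return SceneSpec(
        image_size=tuple(int(v) for v in d["image_size"]),
        table_lower=tuple(float(v) for v in d.get("table_lower", (0.0, 0.0))),
        table_upper=tuple(float(v) for v in d.get("table_upper", (1.0, 1.0))),
        objects=tuple(
            SceneObject(
                center=tuple(float(v) for v in o["center"]),
                radius=float(o["radius"]),
                hue=float(o["hue"]),
                saturation=float(o.get("saturation", 1.0)),
            )
            for o in d.get("objects", ())
        ),
        background_value=float(d.get("background_value", 0.5)),
    )


# ----------------------------------------------------------------------
# validation


def _geometry_diagnostics(d: Any, where: str) -> list[str]:
    out: list[str] = []
    if not isinstance(d, dict):
        return [f"{where}: geometry must be a mapping"]
    unknown = set(d) - _GEOMETRY_KEYS
    if unknown:
        out.append(f"{where}: unknown geometry keys {sorted(unknown)}")
    missing = {"dim_names", "lower", "upper", "n_samples"} - set(d)
    if missing:
        out.append(f"{where}: missing geometry keys {sorted(missing)}")
        return out
    nd = len(d["dim_names"])
    if nd > 3:
        out.append(f"{where}: at most 3 dimensions supported, got {nd}")
    for key in ("lower", "upper", "n_samples"):
        if len(d[key]) != nd:
            out.append(f"{where}: {key} must have {nd} entries")
            return out
    for lo, up in zip(d["lower"], d["upper"]):
        if not lo < up:
            out.append(f"{where}: need lower < upper, got [{lo}, {up}]")
    if any(n < 1 for n in d["n_samples"]):
        out.append(f"{where}: n_samples must be >= 1")
    return out


def _positive(params: dict, key: str, where: str, default=None) -> list[str]:
    v = params.get(key, default)
    if v is None:
        return [f"{where}: missing required parameter {key!r}"]
    if not v > 0:
        return [f"{where}: {key} must be > 0, got {v}"]
    return []


def _non_negative(params: dict, key: str, where: str, default=0.0) -> list[str]:
    v = params.get(key, default)
    if v < 0:
        return [f"{where}: {key} must be >= 0, got {v}"]
    return []


def _sigmoid_diagnostics(d: Any, where: str) -> list[str]:
    if d is None:
        return []
    out = []
    if d.get("kind", "abs_approx") not in SIGMOID_KINDS:
        out.append(f"{where}: sigmoid kind must be one of {SIGMOID_KINDS}")
    if not d.get("beta", 4.0) > 0:
        out.append(f"{where}: sigmoid beta must be > 0")
    return out


def _kernel_diagnostics(d: Any, where: str) -> list[str]:
    if d is None:
        return []
    out = []
    for key in ("c_exc", "c_inh", "c_glob"):
        if d.get(key, 0.0) < 0:
            out.append(f"{where}: kernel {key} must be >= 0")
    if not d.get("truncation", 5.0) > 0:
        out.append(f"{where}: kernel truncation must be > 0")
    se, si = d.get("sigma_exc", 1.0), d.get("sigma_inh", 1.0)
    for name, v in (("sigma_exc", se), ("sigma_inh", si)):
        vals = v if isinstance(v, (list, tuple)) else [v]
        if any(x <= 0 for x in vals):
            out.append(f"{where}: kernel {name} must be > 0")
    if d.get("c_inh", 0.0) > 0:
        se_t = np.atleast_1d(se)
        si_t = np.atleast_1d(si)
        if se_t.shape == si_t.shape and np.any(si_t < se_t):
            out.append(f"{where}: sigma_inh must be >= sigma_exc")
    return out


def _component_ndim(comp: ComponentSpec) -> Optional[int]:
    """Dimensionality of the component's output, None if indeterminate."""
    if comp.kind == "node":
        return 0
    geo = comp.parameters.get("geometry")
    if isinstance(geo, dict) and "dim_names" in geo:
        return len(geo["dim_names"])
    return None


def _component_geometry(comp: ComponentSpec) -> Optional[FieldGeometry]:
    geo = comp.parameters.get("geometry")
    if isinstance(geo, dict):
        try:
            return parse_geometry(geo)
        except Exception:
            return None
    return None


def validate(graph: ArchitectureGraph) -> list[str]:
    """Check an architecture graph; returns all diagnostics (empty = valid).

    Covers name uniqueness, parameter ranges, dimension-map consistency,
    bounds compatibility along couplings, and step-group partition. Never
    raises on structurally well-formed input.
    """
    out: list[str] = []
    names = graph.names()
    seen = set()
    for n in names:
        if n in seen:
            out.append(f"duplicate component name {n!r}")
        seen.add(n)
    by_name = {c.name: c for c in graph.components}

    for comp in graph.components:
        where = f"component {comp.name!r}"
        p = comp.parameters
        if comp.kind not in COMPONENT_KINDS:
            out.append(f"{where}: unknown kind {comp.kind!r}")
            continue
        if comp.kind == "field":
            out += _geometry_diagnostics(p.get("geometry"), where)
            out += _positive(p, "tau", where, default=100.0)
            out += _non_negative(p, "c_noise", where)
            out += _sigmoid_diagnostics(p.get("sigmoid"), where)
            out += _kernel_diagnostics(p.get("kernel"), where)
            if p.get("padding", "periodic") not in PADDING_MODES:
                out.append(f"{where}: padding must be one of {PADDING_MODES}")
            if p.get("conv_method", "auto") not in CONV_METHODS:
                out.append(f"{where}: conv_method must be one of {CONV_METHODS}")
        elif comp.kind == "node":
            out += _positive(p, "tau", where, default=100.0)
            out += _non_negative(p, "c_noise", where)
            out += _non_negative(p, "c_uu", where)
            out += _sigmoid_diagnostics(p.get("sigmoid"), where)
        elif comp.kind == "memory_trace":
            out += _geometry_diagnostics(p.get("geometry"), where)
            out += _positive(p, "tau_build", where, default=1000.0)
            out += _positive(p, "tau_decay", where, default=10000.0)
            out += _non_negative(p, "feedback_gain", where)
        elif comp.kind == "sensor":
            sub = p.get("subkind", "camera")
            if sub not in ("camera", "proprio"):
                out.append(f"{where}: sensor subkind must be 'camera' or 'proprio'")
            out += _geometry_diagnostics(p.get("geometry"), where)
            if sub == "camera":
                if "scene" not in p:
                    out.append(f"{where}: camera sensor requires a 'scene' block")
                out += _non_negative(p, "hue_smoothing_sigma", where)
            else:
                out += _positive(p, "amplitude", where, default=1.0)
                out += _positive(p, "sigma", where, default=0.05)
        elif comp.kind == "readout":
            out += _geometry_diagnostics(p.get("geometry"), where)
            out += _positive(p, "tau_ctrl", where, default=200.0)

    for cpl in graph.couplings:
        where = f"coupling {cpl.source!r} -> {cpl.target!r}"
        missing = [n for n in (cpl.source, cpl.target) if n not in by_name]
        for n in missing:
            out.append(f"{where}: references nonexistent component {n!r}")
        if missing:
            continue
        src, tgt = by_name[cpl.source], by_name[cpl.target]
        src_nd, tgt_nd = _component_ndim(src), _component_ndim(tgt)
        if cpl.special in ("none",) and src_nd is not None and tgt_nd is not None:
            out += [f"{where}: {m}" for m in cpl.map.diagnostics(src_nd, tgt_nd)]
            # bounds compatibility of mapped dims (unless a resample is declared)
            sg, tg = _component_geometry(src), _component_geometry(tgt)
            if sg is not None and tg is not None and cpl.resample is None:
                for s, t in cpl.map.pairs:
                    if s < sg.ndim and t < tg.ndim:
                        if (
                            sg.n_samples[s] != tg.n_samples[t]
                            or sg.lower[s] != tg.lower[t]
                            or sg.upper[s] != tg.upper[t]
                        ):
                            out.append(
                                f"{where}: mapped dimension {s}->{t} has "
                                "incompatible sampling and no resample declared"
                            )
        if cpl.special == "boost" and src.kind != "node":
            out.append(f"{where}: boost couplings require a node source")
        if cpl.special == "peak_detector" and tgt.kind != "node":
            out.append(f"{where}: peak_detector couplings require a node target")
        if cpl.special in ("sheet", "half_space") and src.kind != "node":
            out.append(f"{where}: {cpl.special} couplings require a node source")
        if cpl.special == "proprio":
            if src.kind != "readout":
                out.append(f"{where}: proprio couplings require a readout source")
            if tgt.kind != "sensor" or tgt.parameters.get("subkind") != "proprio":
                out.append(f"{where}: proprio couplings require a proprio sensor target")

    if graph.groups:
        assigned: dict[str, int] = {}
        for gi, grp in enumerate(graph.groups):
            if not grp.dt > 0:
                out.append(f"group {gi}: dt must be > 0, got {grp.dt}")
            for m in grp.members:
                if m not in by_name:
                    out.append(f"group {gi}: unknown member {m!r}")
                elif m in assigned:
                    out.append(f"component {m!r} appears in more than one group")
                else:
                    assigned[m] = gi
        for n in names:
            if n not in assigned:
                out.append(f"component {n!r} is not assigned to any group")
    return out


# ----------------------------------------------------------------------
# serialization


def _check_keys(d: dict, allowed: set, required: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ValueError(f"{where}: missing required keys {sorted(missing)}")


def _coupling_to_dict(c: CouplingSpec) -> dict:
    d: dict[str, Any] = {
        "source": c.source,
        "target": c.target,
        "map": {"pairs": [list(p) for p in c.map.pairs]},
        "gain": c.gain,
        "special": c.special,
    }
    if c.smoothing is not None:
        d["smoothing"] = _kernel_to_dict(c.smoothing)
    if c.params:
        d["params"] = dict(c.params)
    if c.resample is not None:
        d["resample"] = c.resample
    return d


def _kernel_to_dict(k: KernelSpec) -> dict:
    def sig(v):
        return list(v) if isinstance(v, tuple) else v

    return {
        "c_exc": k.c_exc,
        "sigma_exc": sig(k.sigma_exc),
        "c_inh": k.c_inh,
        "sigma_inh": sig(k.sigma_inh),
        "c_glob": k.c_glob,
        "truncation": k.truncation,
    }


def _coupling_from_dict(d: dict) -> CouplingSpec:
    _check_keys(d, _COUPLING_KEYS, {"source", "target"}, "coupling")
    m = d.get("map", {"pairs": []})
    _check_keys(m, {"pairs"}, set(), "coupling map")
    smoothing = d.get("smoothing")
    if smoothing is not None:
        _check_keys(smoothing, _KERNEL_KEYS, set(), "coupling smoothing")
        smoothing = parse_kernel(smoothing)
    return CouplingSpec(
        source=d["source"],
        target=d["target"],
        map=DimensionMap(tuple((int(s), int(t)) for s, t in m.get("pairs", []))),
        gain=float(d.get("gain", 1.0)),
        smoothing=smoothing,
        special=d.get("special", "none"),
        params=dict(d.get("params", {})),
        resample=d.get("resample"),
    )


def serialize(graph: ArchitectureGraph) -> str:
    """Serialize a graph to a JSON document (round-trips bit-exactly)."""
    doc = {
        "metadata": graph.metadata,
        "components": [
            {"name": c.name, "kind": c.kind, "parameters": c.parameters}
            for c in graph.components
        ],
        "couplings": [_coupling_to_dict(c) for c in graph.couplings],
        "groups": [
            {"name": g.name, "members": list(g.members), "dt": g.dt}
            for g in graph.groups
        ],
    }
    return json.dumps(doc, indent=2)


def deserialize(text: str) -> ArchitectureGraph:
    """Parse a JSON config into a graph, rejecting unknown/missing keys.

    Parameter ranges are not checked here; run :func:`validate` on the
    result to collect range diagnostics.
    """
    doc = json.loads(text)
    _check_keys(doc, _TOP_KEYS, {"components"}, "architecture")
    components = []
    for cd in doc["components"]:
        _check_keys(cd, _COMPONENT_KEYS, {"name", "kind"}, "component")
        kind = cd["kind"]
        params = dict(cd.get("parameters", {}))
        if kind in _PARAM_KEYS:
            _check_keys(params, _PARAM_KEYS[kind], set(), f"component {cd['name']!r}")
            if isinstance(params.get("geometry"), dict):
                _check_keys(
                    params["geometry"], _GEOMETRY_KEYS, set(),
                    f"component {cd['name']!r} geometry",
                )
            if isinstance(params.get("sigmoid"), dict):
                _check_keys(
                    params["sigmoid"], _SIGMOID_KEYS, set(),
                    f"component {cd['name']!r} sigmoid",
                )
            if isinstance(params.get("kernel"), dict):
                _check_keys(
                    params["kernel"], _KERNEL_KEYS, set(),
                    f"component {cd['name']!r} kernel",
                )
            if isinstance(params.get("scene"), dict):
                _check_keys(
                    params["scene"], _SCENE_KEYS, set(),
                    f"component {cd['name']!r} scene",
                )
                for o in params["scene"].get("objects", []):
                    _check_keys(o, _OBJECT_KEYS, {"center", "radius", "hue"}, "scene object")
        components.append(ComponentSpec(cd["name"], kind, params))
    couplings = [_coupling_from_dict(cd) for cd in doc.get("couplings", [])]
    groups = []
    for gd in doc.get("groups", []):
        _check_keys(gd, _GROUP_KEYS, {"members", "dt"}, "group")
        groups.append(StepGroup(tuple(gd["members"]), float(gd["dt"]), gd.get("name", "")))
    return ArchitectureGraph(components, couplings, groups, dict(doc.get("metadata", {})))


def save(graph: ArchitectureGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(graph))


def load(path) -> ArchitectureGraph:
    with open(path, "r", encoding="utf-8") as fh:
        return deserialize(fh.read())
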