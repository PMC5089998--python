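"""The constrained coupling algebra between fields and nodes.

A coupling carries the sigmoided output of a source component, transformed
through a short chain of steps, as an additive input contribution to a
target component. The algebra is deliberately narrow:

* one-to-one coupling aligns dimensions (possibly permuted/resampled);
* contraction integrates out source dimensions absent from the target
  (rectangle rule, so gains are invariant under grid refinement);
* expansion broadcasts along target dimensions absent from the source,
  producing ridge/tube/sheet inputs that are constant along the new
  dimensions;
* an optional kernel smoothing spreads input to neighboring feature values;
* a scalar gain sets strength and sign (negative = inhibitory).

Convenience constructors cover the recurring patterns: a homogeneous boost
from a node to a field, a peak detector contracting a field into a node, a
hue-localized sheet, and a soft half-space ramp grounding spatial terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import FieldGeometry
from .kernels import KernelSpec, resample as _resample, smooth as _smooth

__all__ = [
    "DimensionMap",
    "CouplingSpec",
    "project",
    "boost",
    "peak_detector_input",
    "sheet_input",
    "half_space_input",
]

SPECIAL_KINDS = ("none", "boost", "peak_detector", "sheet", "half_space", "space_code", "proprio")


@dataclass(frozen=True)
class DimensionMap:
    """Pairing of source and target dimensions of a coupling.

    ``pairs`` lists (source_dim_index, target_dim_index) for the mapped
    dimensions. Source dimensions absent from the pairs are contracted
    (integrated out); target dimensions absent are expanded (broadcast).
    """

    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((int(s), int(t)) for s, t in self.pairs)
        )

    @classmethod
    def identity(cls, ndim: int) -> "DimensionMap":
        return cls(tuple((d, d) for d in range(ndim)))

    def mapped_source(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.pairs)

    def mapped_target(self) -> tuple[int, ...]:
        return tuple(t for _, t in self.pairs)

    def contracted(self, source_ndim: int) -> tuple[int, ...]:
        mapped = set(self.mapped_source())
        return tuple(d for d in range(source_ndim) if d not in mapped)

    def expanded(self, target_ndim: int) -> tuple[int, ...]:
        mapped = set(self.mapped_target())
        return tuple(d for d in range(target_ndim) if d not in mapped)

    def kind(self, source_ndim: int, target_ndim: int) -> str:
        has_con = bool(self.contracted(source_ndim))
        has_exp = bool(self.expanded(target_ndim))
        if has_con and has_exp:
            return "mixed"
        if has_con:
            return "contraction"
        if has_exp:
            return "expansion"
        return "one-to-one"

    def diagnostics(self, source_ndim: int, target_ndim: int) -> list[str]:
        """Structural violations (injectivity, index range); empty = valid."""
        out = []
        src, tgt = self.mapped_source(), self.mapped_target()
        if len(set(src)) != len(src):
            out.append("dimension map uses a source dimension more than once")
        if len(set(tgt)) != len(tgt):
            out.append("dimension map uses a target dimension more than once")
        for s, t in self.pairs:
            if not 0 <= s < source_ndim:
                out.append(f"source dimension index {s} out of range")
            if not 0 <= t < target_ndim:
                out.append(f"target dimension index {t} out of range")
        return out


@dataclass
class CouplingSpec:
    """Directed projection from one component's output to another's input.

    ``special`` selects a non-generic input pattern (boost, peak detector,
    sheet, half-space, sensor space-code, proprioceptive bump); parameters
    of the special patterns live in ``params``. ``resample`` enables
    interpolation when mapped dimensions are sampled differently.
    """

    source: str
    target: str
    map: DimensionMap = field(default_factory=DimensionMap)
    gain: float = 1.0
    smoothing: Optional[KernelSpec] = None
    special: str = "none"
    params: dict = field(default_factory=dict)
    resample: Optional[str] = None  # "linear" | "nearest"

    def __post_init__(self) -> None:
        if self.special not in SPECIAL_KINDS:
            raise ValueError(f"special must be one of {SPECIAL_KINDS}")
        if self.resample not in (None, "linear", "nearest"):
            raise ValueError("resample must be None, 'linear', or 'nearest'")

    @property
    def sign(self) -> int:
        return int(np.sign(self.gain))


def _restrict(geometry: FieldGeometry, dims: tuple[int, ...]) -> FieldGeometry:
    return FieldGeometry(
        tuple(geometry.dim_names[d] for d in dims),
        tuple(geometry.lower[d] for d in dims),
        tuple(geometry.upper[d] for d in dims),
        tuple(geometry.n_samples[d] for d in dims),
        tuple(geometry.circular[d] for d in dims),
    )


def project(
    output: np.ndarray,
    spec: CouplingSpec,
    source_geometry: FieldGeometry,
    target_geometry: FieldGeometry,
) -> np.ndarray:
    """Apply the generic coupling chain to a source output grid.

    Steps, in order: permute mapped dimensions into target order; contract
    unmapped source dimensions by the rectangle-rule integral; resample
    mapped dimensions if their sampling differs (requires ``spec.resample``);
    expand along unmapped target dimensions by broadcasting; smooth with the
    optional kernel; multiply by the gain.
    """
    output = np.asarray(output, dtype=float)
    if not source_geometry.conforms(output):
        raise ValueError("output does not conform to source geometry")
    m = spec.map
    src_nd, tgt_nd = source_geometry.ndim, target_geometry.ndim
    bad = m.diagnostics(src_nd, tgt_nd)
    if bad:
        raise ValueError("; ".join(bad))

    # (1) permute mapped source dims into target order, contracted dims last
    order_pairs = sorted(m.pairs, key=lambda st: st[1])
    mapped_src = [s for s, _ in order_pairs]
    mapped_tgt = [t for _, t in order_pairs]
    contracted = list(m.contracted(src_nd))
    perm = mapped_src + contracted
    value = np.transpose(output, perm) if src_nd else output

    # (2) contract trailing unmapped source dims (integral: sum x cell size)
    if contracted:
        weight = float(np.prod([source_geometry.spacing[d] for d in contracted]))
        axes = tuple(range(len(mapped_src), src_nd))
        value = value.sum(axis=axes) * weight

    # (3) align sampling of the mapped dims with the target grid
    if mapped_src:
        src_sub = _restrict(source_geometry, tuple(mapped_src))
        tgt_sub = _restrict(target_geometry, tuple(mapped_tgt))
        if src_sub.n_samples != tgt_sub.n_samples or not all(
            np.allclose(src_sub.coords(d), tgt_sub.coords(d))
            for d in range(src_sub.ndim)
        ):
            if spec.resample is None:
                raise ValueError(
                    f"coupling {spec.source}->{spec.target}: mapped dimensions "
                    "are sampled differently and no resample method is declared"
                )
            value = _resample(value, src_sub, tgt_sub, method=spec.resample)

    # (4) expand along unmapped target dims by broadcasting
    expanded = m.expanded(tgt_nd)
    if tgt_nd:
        shape = [1] * tgt_nd
        for k, t in enumerate(mapped_tgt):
            shape[t] = value.shape[k] if np.ndim(value) else 1
        value = np.reshape(value, shape)
        value = np.broadcast_to(value, target_geometry.shape).copy()

    # (5) optional kernel smoothing on the target grid
    if spec.smoothing is not None and tgt_nd:
        value = _smooth(value, spec.smoothing, target_geometry)

    # (6) gain
    return spec.gain * value


# ----------------------------------------------------------------------
# recurring special patterns


def boost(
    node_output: float, target_geometry: FieldGeometry, gain: float
) -> np.ndarray:
    """Homogeneous input gain * g(u) from a node to every field location.

    Equivalent to :func:`project` with an all-expanded dimension map; the
    standard mechanism for pushing a field through a detection instability.
    """
    return target_geometry.full(gain * float(node_output))


def peak_detector_input(
    field_output: np.ndarray, cell_volume: float, gain: float
) -> float:
    """Contract a field's output into scalar input gain * int g(u) dx."""
    return gain * cell_volume * float(np.sum(field_output))


def sheet_input(
    node_output: float,
    hue_center: float,
    hue_sigma: float,
    geometry: FieldGeometry,
    gain: float,
    hue_dim: str = "hue",
) -> np.ndarray:
    """Input localized along the hue dimension, homogeneous over space.

    A Gaussian profile (circular distance if the hue dimension wraps) along
    hue, broadcast over the remaining dimensions and scaled by
    gain * node output. This is the cue pattern a color-concept node sends
    into a (space x space x hue) perceptual field.
    """
    axis = geometry.axis_of(hue_dim)
    coords = geometry.coords(axis)
    d = coords - hue_center
    if geometry.circular[axis]:
        span = geometry.upper[axis] - geometry.lower[axis]
        d = (d + span / 2.0) % span - span / 2.0
    profile = np.exp(-(d**2) / (2.0 * hue_sigma**2))
    shape = [1] * geometry.ndim
    shape[axis] = len(coords)
    grid = np.broadcast_to(profile.reshape(shape), geometry.shape)
    return gain * float(node_output) * grid


def half_space_input(
    node_output: float,
    side: str,
    softness: float,
    geometry: FieldGeometry,
    gain: float,
    axis_dim: str = "x",
) -> np.ndarray:
    """Soft half-space ramp grounding a spatial term ("left"/"right").

    A logistic step at the midline of the named axis with steepness
    1/softness, constant along every other dimension. The left and right
    profiles are complementary: they sum to gain * node output everywhere.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    axis = geometry.axis_of(axis_dim)
    coords = geometry.coords(axis)
    mid = 0.5 * (geometry.lower[axis] + geometry.upper[axis])
    z = (coords - mid) / softness
    if side == "left":
        z = -z
    profile = 1.0 / (1.0 + np.exp(-z))
    shape = [1] * geometry.ndim
    shape[axis] = len(coords)
    grid = np.broadcast_to(profile.reshape(shape), geometry.shape)
    return gain * float(node_output) * grid
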