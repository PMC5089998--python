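"""Sensor and motor adapters: space-code encoding and attractor readout.

The sensor side turns a color image of a tabletop scene into input for a
three-dimensional field over (table-x, table-y, hue): each pixel deposits
its saturation at the grid cell matching its position and hue, and zero
everywhere else along the hue axis (a space code: the feature *value* is
where the input lands, its *strength* is the saturation). A synthetic scene
renderer stands in for the camera; it draws anti-aliased colored disks on a
neutral gray background directly in allocentric table coordinates (the
camera-to-table calibration of a physical rig is an identity here).

The motor side reads a movement target out of a field. The naive estimate
(normalized centroid of the suprathreshold output) divides by the output
mass N and is undefined when no peak exists. The attractor readout avoids
normalization entirely: a control variable x_ctrl follows

    tau_ctrl * dx_ctrl/dt = -int (x_ctrl - x) g(u(x)) dx

which has an attractor at the peak centroid with stiffness N and becomes
marginally stable (x_ctrl freezes) as N -> 0. A point effector whose
position is x_ctrl itself, plus a Gaussian proprioceptive bump at that
position, closes the loop into the architecture.

Image convention: arrays are indexed (x, y, 3) with axis 0 = table-x and
axis 1 = table-y, RGB in [0, 1], matching the field dimension order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage

from .geometry import FieldGeometry

__all__ = [
    "SceneObject",
    "SceneSpec",
    "SpaceCodeInput",
    "ReadoutState",
    "CentroidResult",
    "render_scene",
    "encode_space_code",
    "peak_centroid",
    "readout_rate",
    "proprioceptive_input",
    "Effector",
]


@dataclass(frozen=True)
class SceneObject:
    """A colored disk on the table: center in table coordinates, radius in
    pixels, hue in [0, 1) and saturation in (0, 1] at full value."""

    center: tuple[float, float]
    radius: float
    hue: float
    saturation: float = 1.0

    def __post_init__(self) -> None:
        if not self.saturation > 0:
            raise ValueError("object saturation must be > 0")
        if self.radius <= 0:
            raise ValueError("object radius must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic tabletop scene: image size, table bounds, and objects.

    The image maps 1:1 onto the table bounds. Objects may overlap; later
    objects win per pixel. The background is zero-saturation gray.
    """

    image_size: tuple[int, int]
    table_lower: tuple[float, float] = (0.0, 0.0)
    table_upper: tuple[float, float] = (1.0, 1.0)
    objects: tuple[SceneObject, ...] = ()
    background_value: float = 0.5

    def pixel_coords(self, axis: int) -> np.ndarray:
        """Table coordinates of pixel centers along image axis 0 or 1."""
        lo, up = self.table_lower[axis], self.table_upper[axis]
        n = self.image_size[axis]
        return lo + (np.arange(n) + 0.5) * (up - lo) / n


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Render the scene to an (nx, ny, 3) RGB array in [0, 1].

    Disks are anti-aliased by edge coverage (alpha-composited in listed
    order, so later objects win where they overlap). Deterministic.
    """
    nx, ny = spec.image_size
    bg = hsv_to_rgb([0.0, 0.0, spec.background_value])
    image = np.broadcast_to(bg, (nx, ny, 3)).copy()
    xs = spec.pixel_coords(0)
    ys = spec.pixel_coords(1)
    # pixel size in table units (needed to express disk radius on the grid)
    px = (spec.table_upper[0] - spec.table_lower[0]) / nx
    py = (spec.table_upper[1] - spec.table_lower[1]) / ny
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for obj in spec.objects:
        dist_px = np.hypot((X - obj.center[0]) / px, (Y - obj.center[1]) / py)
        coverage = np.clip(obj.radius + 0.5 - dist_px, 0.0, 1.0)
        rgb = hsv_to_rgb([obj.hue % 1.0, obj.saturation, 1.0])
        image = image * (1.0 - coverage[..., None]) + rgb * coverage[..., None]
    return image


@dataclass
class SpaceCodeInput:
    """Encoded camera input: a (table-x, table-y, hue) tensor.

    With zero smoothing, each (x, y) column along hue has at most one
    non-zero bin, holding that pixel's saturation times the gain.
    """

    geometry: FieldGeometry
    tensor: np.ndarray
    hue_smoothing_sigma: float = 0.0


def _pool(image: np.ndarray, nx: int, ny: int) -> np.ndarray:
    """Average-pool an (X, Y, 3) image down to (nx, ny, 3)."""
    X, Y = image.shape[:2]
    if X == nx and Y == ny:
        return image
    if X % nx or Y % ny:
        raise ValueError(
            f"image size ({X}, {Y}) must equal or be an integer multiple of "
            f"the spatial grid ({nx}, {ny})"
        )
    return image.reshape(nx, X // nx, ny, Y // ny, 3).mean(axis=(1, 3))


def encode_space_code(
    image: np.ndarray,
    geometry: FieldGeometry,
    hue_smoothing_sigma: float = 0.0,
    gain: float = 1.0,
) -> SpaceCodeInput:
    """Space-code an RGB image into 3-D field input over (x, y, hue).

    Per pixel, ``saturation * gain`` is deposited at the hue bin matching
    the pixel's hue (the hue dimension wraps); everywhere else along hue the
    input is zero. Optional circular Gaussian smoothing along hue only,
    which preserves each column's mass.
    """
    if geometry.ndim != 3:
        raise ValueError("space-code encoding requires a 3-D geometry")
    hue_axis = 2
    nx, ny, nh = geometry.shape
    image = _pool(np.asarray(image, dtype=float), nx, ny)
    hsv = rgb_to_hsv(image)
    hue, sat = hsv[..., 0], hsv[..., 1]

    lo, up = geometry.lower[hue_axis], geometry.upper[hue_axis]
    span = up - lo
    # nearest circular bin of each pixel's hue
    bins = np.round((hue - lo) / span * nh - 0.5).astype(int) % nh
    tensor = np.zeros(geometry.shape)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    np.add.at(tensor, (ix.ravel(), iy.ravel(), bins.ravel()), gain * sat.ravel())

    if hue_smoothing_sigma > 0:
        sigma_cells = hue_smoothing_sigma / geometry.spacing[hue_axis]
        tensor = ndimage.gaussian_filter1d(
            tensor, sigma_cells, axis=hue_axis, mode="wrap"
        )
    return SpaceCodeInput(geometry, tensor, hue_smoothing_sigma)


# ----------------------------------------------------------------------
# motor readout


@dataclass
class CentroidResult:
    """Peak-centroid estimate; ``x_cmd`` is None when the output mass N is
    zero (a legal state, never a division by zero)."""

    x_cmd: Optional[np.ndarray]
    N: float

    @property
    def defined(self) -> bool:
        return self.x_cmd is not None


def peak_centroid(output: np.ndarray, geometry: FieldGeometry) -> CentroidResult:
    """Normalized centroid x_cmd = int x g(u) dx / N with N = int g(u) dx."""
    output = np.asarray(output, dtype=float)
    if not geometry.conforms(output):
        raise ValueError("output does not conform to geometry")
    vol = geometry.cell_volume
    N = vol * float(output.sum())
    if N == 0.0:
        return CentroidResult(None, 0.0)
    mesh = geometry.meshgrid()
    x_cmd = np.array([vol * float((m * output).sum()) / N for m in mesh])
    return CentroidResult(x_cmd, N)


@dataclass
class ReadoutState:
    """Attractor-dynamics control variable tracking a field's peak.

    ``fixed_components`` pins coordinates that the field does not control
    (e.g. the vertical position of a pointer above the table).
    """

    x_ctrl: np.ndarray
    tau_ctrl: float = 200.0
    fixed_components: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_ctrl = np.asarray(self.x_ctrl, dtype=float)
        if not self.tau_ctrl > 0:
            raise ValueError("tau_ctrl must be > 0")
        if not np.all(np.isfinite(self.x_ctrl)):
            raise ValueError("x_ctrl must be finite")


def readout_rate(
    state: ReadoutState, output: np.ndarray, geometry: FieldGeometry
) -> np.ndarray:
    """Normalization-free readout rate tau_ctrl * dx_ctrl/dt.

    Evaluates the single integral -int (x_ctrl - x) g(u(x)) dx directly
    (never via the centroid), so zero output yields exactly zero rate and
    x_ctrl freezes in place.
    """
    output = np.asarray(output, dtype=float)
    if not geometry.conforms(output):
        raise ValueError("output does not conform to geometry")
    if len(state.x_ctrl) != geometry.ndim:
        raise ValueError("x_ctrl dimensionality does not match the geometry")
    vol = geometry.cell_volume
    mesh = geometry.meshgrid()
    rate = np.array(
        [
            -vol * float(((state.x_ctrl[d] - mesh[d]) * output).sum())
            for d in range(geometry.ndim)
        ]
    )
    for d in state.fixed_components:
        rate[d] = 0.0
    return rate


# ----------------------------------------------------------------------
# simulated effector


def proprioceptive_input(
    position: Sequence[float],
    geometry: FieldGeometry,
    amplitude: float = 1.0,
    sigma: float | Sequence[float] = 0.05,
) -> np.ndarray:
    """Gaussian bump at the effector position on a 2-D table grid."""
    position = np.asarray(position, dtype=float)
    if len(position) != geometry.ndim:
        raise ValueError("position dimensionality does not match the geometry")
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (geometry.ndim,))
    mesh = geometry.meshgrid()
    z = sum(
        ((mesh[d] - position[d]) / sig[d]) ** 2 for d in range(geometry.ndim)
    )
    return amplitude * np.exp(-0.5 * z)


class Effector:
    """Point effector whose position is the readout control variable.

    The attractor dynamics of x_ctrl is the controller, so by default the
    end-effector position is x_ctrl itself (the vertical coordinate of a
    physical pointer is pinned and not simulated). An optional first-order
    lag ``tau_lag`` adds plant-like sluggishness for realism.
    """

    def __init__(
        self,
        initial_position: Sequence[float],
        tau_lag: Optional[float] = None,
    ) -> None:
        self.position = np.asarray(initial_position, dtype=float)
        if tau_lag is not None and not tau_lag > 0:
            raise ValueError("tau_lag must be > 0 when given")
        self.tau_lag = tau_lag

    def step(self, x_ctrl: np.ndarray, dt: float) -> np.ndarray:
        if self.tau_lag is None:
            self.position = np.asarray(x_ctrl, dtype=float).copy()
        else:
            self.position = self.position + (dt / self.tau_lag) * (
                np.asarray(x_ctrl) - self.position
            )
        return self.position
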