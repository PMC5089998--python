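"""Lateral-interaction kernels and their application to field output.

The interaction kernel k(dx) of a field is parameterized as a local
difference of Gaussians plus a global constant:

    k(dx) = c_exc * prod_d exp(-dx_d^2 / (2 sigma_exc_d^2))
          - c_inh * prod_d exp(-dx_d^2 / (2 sigma_inh_d^2))
          - c_glob

with c_exc, c_inh, c_glob >= 0 and sigma_inh >= sigma_exc, covering local
excitation, surround inhibition, and inhibition of all distant locations.
The integral term of the field dynamics is evaluated by the rectangle rule:
the sampled local part is correlated with the field output and scaled by the
grid cell volume, and the global part is the exact shortcut
-c_glob * cell_volume * sum(output) (an all-ones kernel without the O(N^2)).

Three interchangeable convolution paths are provided (full-kernel direct,
separable per-axis, FFT); they agree to near machine precision and the
separable/direct paths are bitwise translation-equivariant under periodic
padding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import RegularGridInterpolator

from .geometry import FieldGeometry

__all__ = [
    "KernelSpec",
    "PaddingMode",
    "sample_kernel",
    "lateral_input",
    "resample",
]

PADDING_MODES = ("periodic", "zero", "replicate")
_NDIMAGE_MODE = {"periodic": "wrap", "zero": "constant", "replicate": "nearest"}
CONV_METHODS = ("direct", "separable", "fft", "auto")

# 2-D grids larger than this (total cells) take the FFT path under method="auto"
_FFT_CROSSOVER_2D = 64 * 64


@dataclass(frozen=True)
class KernelSpec:
    """Difference-of-Gaussians interaction profile plus global inhibition.

    Amplitudes are the kernel values at zero distance of each part
    (Gaussians are unnormalized), so k(0) = c_exc - c_inh - c_glob and
    k(dx) -> -c_glob far from zero. ``sigma_exc``/``sigma_inh`` may be a
    scalar (isotropic) or one width per dimension, in feature units.
    ``truncation`` bounds the sampled support at truncation * max(sigma).
    """

    c_exc: float = 0.0
    sigma_exc: tuple[float, ...] | float = 1.0
    c_inh: float = 0.0
    sigma_inh: tuple[float, ...] | float = 1.0
    c_glob: float = 0.0
    truncation: float = 5.0

    def __post_init__(self) -> None:
        for name in ("c_exc", "c_inh", "c_glob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.truncation > 0:
            raise ValueError("truncation must be > 0")
        for name in ("sigma_exc", "sigma_inh"):
            v = getattr(self, name)
            if isinstance(v, (list, tuple, np.ndarray)):
                object.__setattr__(self, name, tuple(float(x) for x in v))
            else:
                object.__setattr__(self, name, float(v))

    def sigmas(self, ndim: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """Per-dimension (sigma_exc, sigma_inh), validated."""
        se = _per_dim(self.sigma_exc, ndim, "sigma_exc")
        si = _per_dim(self.sigma_inh, ndim, "sigma_inh")
        if any(s <= 0 for s in se + si):
            raise ValueError("kernel widths must be > 0")
        if self.c_inh > 0 and any(i < e for e, i in zip(se, si)):
            raise ValueError("sigma_inh must be >= sigma_exc in every dimension")
        return se, si


@dataclass(frozen=True)
class PaddingMode:
    """Boundary handling for the lateral convolution.

    Periodic padding is the default and the only mode allowed in 3-D;
    zero and replicate padding are available for 1-D and 2-D fields.
    """

    mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.mode not in PADDING_MODES:
            raise ValueError(f"padding mode must be one of {PADDING_MODES}")


def _per_dim(value, ndim: int, name: str) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),) * ndim
    out = tuple(float(v) for v in value)
    if len(out) != ndim:
        raise ValueError(f"{name} must be scalar or have {ndim} entries")
    return out


def _radii(spec: KernelSpec, geometry: FieldGeometry) -> list[int]:
    """Per-dimension half-widths of the sampled support, clamped to the grid."""
    se, si = spec.sigmas(geometry.ndim)
    radii = []
    for d, dx in enumerate(geometry.spacing):
        sigma = max(se[d], si[d] if spec.c_inh > 0 else 0.0)
        r = int(np.ceil(spec.truncation * sigma / dx))
        r_max = (geometry.n_samples[d] - 1) // 2
        if r > r_max:
            warnings.warn(
                f"kernel support (radius {r} cells) exceeds grid extent along "
                f"dimension {geometry.dim_names[d]!r}; clamping to {r_max}",
                stacklevel=3,
            )
            r = r_max
        radii.append(r)
    return radii


def _axis_factors(
    spec: KernelSpec, geometry: FieldGeometry, radii: list[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Unit-amplitude per-axis Gaussian factors of the two local parts."""
    se, si = spec.sigmas(geometry.ndim)
    exc, inh = [], []
    for d, r in enumerate(radii):
        off = np.arange(-r, r + 1) * geometry.spacing[d]
        exc.append(np.exp(-(off**2) / (2.0 * se[d] ** 2)))
        inh.append(np.exp(-(off**2) / (2.0 * si[d] ** 2)))
    return exc, inh


def sample_kernel(
    spec: KernelSpec, geometry: FieldGeometry
) -> tuple[np.ndarray, float]:
    """Sample the local kernel part on the grid spacing.

    Returns the centered difference-of-Gaussians grid (odd sample count per
    dimension, truncated at ``truncation * max(sigma)`` and clamped to the
    grid extent with a warning) and the global-inhibition constant separately.
    """
    if geometry.ndim < 1:
        raise ValueError("sample_kernel requires dimensionality >= 1")
    radii = _radii(spec, geometry)
    exc, inh = _axis_factors(spec, geometry, radii)
    local = spec.c_exc * _outer(exc) - spec.c_inh * _outer(inh)
    return local, spec.c_glob


def _outer(factors: list[np.ndarray]) -> np.ndarray:
    out = factors[0]
    for f in factors[1:]:
        out = np.multiply.outer(out, f)
    return out


# ----------------------------------------------------------------------
# convolution paths


def lateral_input(
    output: np.ndarray,
    spec: KernelSpec,
    geometry: FieldGeometry,
    padding: PaddingMode | str = "periodic",
    method: str = "auto",
) -> np.ndarray:
    """Rectangle-rule lateral interaction integral int k(x - x') g(u(x')) dx'.

    The local part is a correlation with the sampled kernel scaled by the
    cell volume; the global part subtracts c_glob * cell_volume * sum(output)
    exactly. ``method`` selects the convolution path; ``auto`` mirrors the
    cost structure (FFT in 3-D, size-dependent in 2-D, separable otherwise).
    """
    if isinstance(padding, str):
        padding = PaddingMode(padding)
    if method not in CONV_METHODS:
        raise ValueError(f"method must be one of {CONV_METHODS}")
    output = np.asarray(output, dtype=float)
    if not geometry.conforms(output):
        raise ValueError("output does not conform to geometry")
    if geometry.ndim == 3 and padding.mode != "periodic":
        raise ValueError("zero/replicate padding is only supported in 1-D and 2-D")

    if method == "auto":
        if geometry.ndim == 3:
            method = "fft"
        elif geometry.ndim == 2:
            method = "fft" if output.size > _FFT_CROSSOVER_2D else "separable"
        else:
            method = "separable"

    vol = geometry.cell_volume
    # fsum: correctly rounded, order-independent reduction, so the global
    # term is identical for circularly shifted inputs
    glob = (
        spec.c_glob * vol * math.fsum(output.ravel()) if spec.c_glob else 0.0
    )

    if spec.c_exc == 0.0 and spec.c_inh == 0.0:
        local = np.zeros_like(output)
    elif method == "direct":
        local = _direct(output, spec, geometry, padding)
    elif method == "separable":
        local = _separable(output, spec, geometry, padding)
    else:
        local = _fft(output, spec, geometry, padding)

    return vol * local - glob


def _direct(output, spec, geometry, padding) -> np.ndarray:
    """Full-kernel correlation as an explicit sum over kernel elements.

    Accumulation order is the kernel-element order for every output cell,
    so under periodic padding a circular shift of the input shifts the
    result bit-exactly.
    """
    kernel, _ = sample_kernel(spec, geometry)
    radii = [(s - 1) // 2 for s in kernel.shape]
    pad_mode = {"periodic": "wrap", "zero": "constant", "replicate": "edge"}
    padded = np.pad(output, [(r, r) for r in radii], mode=pad_mode[padding.mode])
    local = np.zeros_like(output)
    for kidx in np.ndindex(kernel.shape):
        w = kernel[kidx]
        sl = tuple(
            slice(kidx[d], kidx[d] + output.shape[d]) for d in range(output.ndim)
        )
        local += w * padded[sl]
    return local


def _separable(output, spec, geometry, padding) -> np.ndarray:
    mode = _NDIMAGE_MODE[padding.mode]
    radii = _radii(spec, geometry)
    exc, inh = _axis_factors(spec, geometry, radii)
    local = np.zeros_like(output)
    for sign, amp, factors in ((1.0, spec.c_exc, exc), (-1.0, spec.c_inh, inh)):
        if amp == 0.0:
            continue
        part = output
        for axis, f in enumerate(factors):
            part = ndimage.correlate1d(part, f, axis=axis, mode=mode, cval=0.0)
        local = local + sign * amp * part
    return local


def _fft(output, spec, geometry, padding) -> np.ndarray:
    kernel, _ = sample_kernel(spec, geometry)
    if padding.mode == "periodic":
        # circular convolution: embed the centered kernel with wraparound
        embedded = np.zeros_like(output)
        radii = [(s - 1) // 2 for s in kernel.shape]
        slices = tuple(slice(0, s) for s in kernel.shape)
        embedded[slices] = kernel
        embedded = np.roll(embedded, [-r for r in radii], axis=range(output.ndim))
        axes = list(range(output.ndim))
        out_f = np.fft.rfftn(output, axes=axes)
        ker_f = np.fft.rfftn(embedded, axes=axes)
        return np.fft.irfftn(out_f * ker_f, s=output.shape, axes=axes)
    # zero / replicate: pad explicitly by the kernel half-width, then convolve
    radii = [(s - 1) // 2 for s in kernel.shape]
    pad_mode = "constant" if padding.mode == "zero" else "edge"
    padded = np.pad(output, [(r, r) for r in radii], mode=pad_mode)
    # kernel is symmetric along every axis, so convolution == correlation
    return signal.fftconvolve(padded, kernel, mode="valid")


def smooth(
    grid: np.ndarray, spec: KernelSpec, geometry: FieldGeometry
) -> np.ndarray:
    """Rectangle-rule convolution of an input grid with a kernel.

    Used for coupling-stage smoothing (spreading input to neighboring
    feature values). Boundary handling follows the geometry: circular
    dimensions wrap, others replicate their edge value.
    """
    grid = np.asarray(grid, dtype=float)
    if not geometry.conforms(grid):
        raise ValueError("grid does not conform to geometry")
    vol = geometry.cell_volume
    radii = _radii(spec, geometry)
    exc, inh = _axis_factors(spec, geometry, radii)
    local = np.zeros_like(grid)
    for sign, amp, factors in ((1.0, spec.c_exc, exc), (-1.0, spec.c_inh, inh)):
        if amp == 0.0:
            continue
        part = grid
        for axis, f in enumerate(factors):
            mode = "wrap" if geometry.circular[axis] else "nearest"
            part = ndimage.correlate1d(part, f, axis=axis, mode=mode)
        local = local + sign * amp * part
    return vol * local - spec.c_glob * vol * float(grid.sum())


# ----------------------------------------------------------------------
# resampling between grids


def resample(
    grid: np.ndarray,
    from_geometry: FieldGeometry,
    to_geometry: FieldGeometry,
    method: str = "linear",
) -> np.ndarray:
    """Interpolate a grid onto a different sampling of the same space.

    Target coordinates outside the source cell-center range take the edge
    value. Identical geometries return the input unchanged.
    """
    if from_geometry.ndim != to_geometry.ndim:
        raise ValueError(
            f"dimensionality mismatch: {from_geometry.ndim} vs {to_geometry.ndim}"
        )
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    grid = np.asarray(grid, dtype=float)
    if not from_geometry.conforms(grid):
        raise ValueError("grid does not conform to from_geometry")
    if from_geometry.n_samples == to_geometry.n_samples and all(
        np.allclose(from_geometry.coords(d), to_geometry.coords(d))
        for d in range(from_geometry.ndim)
    ):
        return grid.copy()

    # singleton source dimensions carry a constant value: broadcast them
    live = [d for d in range(from_geometry.ndim) if from_geometry.n_samples[d] > 1]
    src_points = [from_geometry.coords(d) for d in live]
    squeezed = grid.reshape([grid.shape[d] for d in live]) if live else grid
    target_axes = [
        np.clip(
            to_geometry.coords(d),
            from_geometry.coords(d)[0],
            from_geometry.coords(d)[-1],
        )
        for d in live
    ]
    if live:
        interp = RegularGridInterpolator(src_points, squeezed, method=method)
        mesh = np.meshgrid(*target_axes, indexing="ij")
        values = interp(np.stack([m.ravel() for m in mesh], axis=-1))
        values = values.reshape([len(a) for a in target_axes])
    else:
        values = squeezed
    # broadcast back over singleton dims at their target sizes
    out_shape = list(to_geometry.shape)
    expand_shape = [
        out_shape[d] if d in live else 1 for d in range(to_geometry.ndim)
    ]
    values = values.reshape(expand_shape)
    return np.broadcast_to(values, out_shape).copy()
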