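"""Sampled geometry of metric feature spaces.

A dynamic neural field is defined over 0-3 continuous metric dimensions
(e.g. table position, hue). Numerics sample each dimension on a regular,
cell-centered grid: cell ``i`` of a dimension with bounds ``[lo, up)`` and
``n`` samples is centered at ``lo + (i + 0.5) * (up - lo) / n``. Cell-centered
sampling makes circular dimensions (hue is an angle) seamless and gives the
rectangle rule a uniform cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FieldGeometry"]


@dataclass(frozen=True)
class FieldGeometry:
    """Regular grid sampling of a 0- to 3-dimensional metric feature space.

    Parameters
    ----------
    dim_names
        Ordered dimension labels, e.g. ``("x", "y", "hue")``. An empty tuple
        describes a zero-dimensional geometry (a node: a single scalar).
    lower, upper
        Per-dimension metric bounds (``lower < upper``).
    n_samples
        Per-dimension positive grid sizes.
    circular
        Per-dimension periodicity flags; a circular dimension wraps at its
        bounds (used for hue).
    """

    dim_names: tuple[str, ...]
    lower: tuple[float, ...] = ()
    upper: tuple[float, ...] = ()
    n_samples: tuple[int, ...] = ()
    circular: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dim_names", tuple(self.dim_names))
        object.__setattr__(self, "lower", tuple(float(v) for v in self.lower))
        object.__setattr__(self, "upper", tuple(float(v) for v in self.upper))
        object.__setattr__(self, "n_samples", tuple(int(v) for v in self.n_samples))
        circ = tuple(bool(v) for v in self.circular)
        if not circ:
            circ = (False,) * len(self.dim_names)
        object.__setattr__(self, "circular", circ)

        nd = len(self.dim_names)
        if nd > 3:
            raise ValueError(f"at most 3 metric dimensions supported, got {nd}")
        for name, seq in (
            ("lower", self.lower),
            ("upper", self.upper),
            ("n_samples", self.n_samples),
            ("circular", self.circular),
        ):
            if len(seq) != nd:
                raise ValueError(f"{name} must have one entry per dimension")
        for lo, up in zip(self.lower, self.upper):
            if not lo < up:
                raise ValueError(f"need lower < upper, got [{lo}, {up}]")
        if any(n < 1 for n in self.n_samples):
            raise ValueError("n_samples entries must be >= 1")

    # ------------------------------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.dim_names)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.n_samples

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(
            (up - lo) / n for lo, up, n in zip(self.lower, self.upper, self.n_samples)
        )

    @property
    def cell_volume(self) -> float:
        """Rectangle-rule weight: product of grid spacings (1.0 for a node)."""
        return float(np.prod(self.spacing)) if self.ndim else 1.0

    def coords(self, dim: int) -> np.ndarray:
        """Cell-center coordinates along dimension ``dim``."""
        lo, up, n = self.lower[dim], self.upper[dim], self.n_samples[dim]
        dx = (up - lo) / n
        return lo + (np.arange(n) + 0.5) * dx

    def meshgrid(self) -> list[np.ndarray]:
        """Cell-center coordinate arrays broadcast to the full grid shape."""
        return list(
            np.meshgrid(*[self.coords(d) for d in range(self.ndim)], indexing="ij")
        )

    def axis_of(self, dim_name: str) -> int:
        try:
            return self.dim_names.index(dim_name)
        except ValueError:
            raise KeyError(
                f"no dimension named {dim_name!r} in {self.dim_names}"
            ) from None

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=float)

    def full(self, value: float) -> np.ndarray:
        return np.full(self.shape, float(value))

    def conforms(self, grid: np.ndarray) -> bool:
        return tuple(np.shape(grid)) == self.shape

    def nearest_index(self, dim: int, value: float) -> int:
        """Index of the cell whose center is closest to ``value``.

        Circular dimensions wrap; non-circular ones clamp to the edge cells.
        """
        lo, up, n = self.lower[dim], self.upper[dim], self.n_samples[dim]
        dx = (up - lo) / n
        i = int(np.floor((value - lo) / dx))
        if self.circular[dim]:
            return i % n
        return min(max(i, 0), n - 1)
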