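"""Core activation dynamics of neural fields, nodes, and memory traces.

A dynamic neural field carries an activation distribution u(x, t) over its
metric dimensions that relaxes, on a time scale tau, toward an attractor set
by the resting level h, external input s(x, t), and lateral interaction:

    tau * du/dt = -u + h + s + (k * g(u))(x) + c_noise * xi(x, t)

where g is a sigmoidal output nonlinearity with range [0, 1] and k an
interaction kernel (local excitation, surround/global inhibition). A node is
the zero-dimensional special case whose only interaction is self-excitation
c_uu * g(u). A memory trace is a slow asymmetric low-pass filter of a field's
output, building up where the field is active and decaying elsewhere.

The functions here return deterministic rates of change scaled by tau
(i.e. the bracket on the right-hand side above, without the noise term);
noise is injected by the stochastic integrator so that it picks up the
correct sqrt(dt) scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import FieldGeometry
from .kernels import KernelSpec

__all__ = [
    "SigmoidSpec",
    "FieldState",
    "NodeState",
    "MemoryTraceState",
    "sigmoid",
    "field_rate_of_change",
    "node_rate_of_change",
    "memory_trace_rate",
]

SIGMOID_KINDS = ("step", "logistic", "abs_approx")


@dataclass(frozen=True)
class SigmoidSpec:
    """Threshold output function g(u) with range [0, 1].

    ``abs_approx`` is the cheap smooth approximation of the logistic,
    g(u) = (1 + beta*(u - theta) / (1 + beta*|u - theta|)) / 2; ``step`` is
    the hard threshold of the classical Amari analysis. ``theta`` is the
    activation at which the smooth variants output 1/2 (zero by convention:
    activation above zero is "suprathreshold").
    """

    kind: str = "abs_approx"
    beta: float = 4.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SIGMOID_KINDS:
            raise ValueError(f"sigmoid kind must be one of {SIGMOID_KINDS}")
        if not self.beta > 0:
            raise ValueError("sigmoid steepness beta must be > 0")

    def __call__(self, u: np.ndarray | float) -> np.ndarray:
        return sigmoid(self, u)


def sigmoid(spec: SigmoidSpec, u: np.ndarray | float, *, component: str = "") -> np.ndarray:
    """Elementwise output nonlinearity; rejects non-finite activation."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        where = f" in component {component!r}" if component else ""
        raise FloatingPointError(f"non-finite activation values{where}")
    z = u - spec.threshold
    if spec.kind == "step":
        return (z >= 0).astype(float)
    if spec.kind == "logistic":
        # split by sign for overflow-free evaluation
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-spec.beta * z[pos]))
        ez = np.exp(spec.beta * z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    bz = spec.beta * z
    return 0.5 * (1.0 + bz / (1.0 + np.abs(bz)))


@dataclass
class FieldState:
    """Activation grid of one dynamic neural field plus its dynamics parameters.

    Attributes
    ----------
    geometry : FieldGeometry
    u : activation grid conforming to ``geometry`` (initialized to ``h``)
    tau : relaxation time constant, ms
    h : resting level (negative by convention)
    c_noise : Gaussian white-noise strength
    sigmoid : output nonlinearity
    kernel : optional lateral-interaction kernel
    inputs : accumulated external input s(x, t) for the current step
    """

    geometry: FieldGeometry
    tau: float = 100.0
    h: float = -5.0
    c_noise: float = 0.0
    sigmoid: SigmoidSpec = field(default_factory=SigmoidSpec)
    kernel: Optional[KernelSpec] = None
    u: np.ndarray = None  # type: ignore[assignment]
    inputs: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.c_noise < 0:
            raise ValueError("c_noise must be >= 0")
        if self.u is None:
            self.u = self.geometry.full(self.h)
        else:
            self.u = np.asarray(self.u, dtype=float)
        if self.inputs is None:
            self.inputs = self.geometry.zeros()
        else:
            self.inputs = np.asarray(self.inputs, dtype=float)
        for name, grid in (("u", self.u), ("inputs", self.inputs)):
            if not self.geometry.conforms(grid):
                raise ValueError(
                    f"{name} shape {np.shape(grid)} does not conform to "
                    f"geometry shape {self.geometry.shape}"
                )

    def output(self) -> np.ndarray:
        return sigmoid(self.sigmoid, self.u)


@dataclass
class NodeState:
    """Zero-dimensional field: a scalar activation with self-excitation c_uu."""

    tau: float = 100.0
    h: float = -5.0
    c_noise: float = 0.0
    c_uu: float = 0.0
    sigmoid: SigmoidSpec = field(default_factory=SigmoidSpec)
    u: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.c_noise < 0 or self.c_uu < 0:
            raise ValueError("c_noise and c_uu must be >= 0")
        if self.u is None:
            self.u = float(self.h)

    def output(self) -> float:
        return float(sigmoid(self.sigmoid, self.u))


@dataclass
class MemoryTraceState:
    """Slow asymmetric low-pass filter of a field's output.

    The trace p grows toward the source output with time constant
    ``tau_build`` where the output exceeds the trace, and decays with the
    (slower) ``tau_decay`` elsewhere; p stays in [0, 1] for outputs in [0, 1].
    ``feedback_gain`` scales the trace when it is fed back into the associated
    field as preshaping input.
    """

    geometry: FieldGeometry
    tau_build: float = 1000.0
    tau_decay: float = 10000.0
    feedback_gain: float = 0.0
    p: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.tau_build > 0 and self.tau_decay > 0):
            raise ValueError("tau_build and tau_decay must be > 0")
        if self.feedback_gain < 0:
            raise ValueError("feedback_gain must be >= 0")
        if self.p is None:
            self.p = self.geometry.zeros()
        else:
            self.p = np.asarray(self.p, dtype=float)
        if not self.geometry.conforms(self.p):
            raise ValueError("p does not conform to geometry")


# ----------------------------------------------------------------------
# rate-of-change computations


def field_rate_of_change(
    f: FieldState, lateral: np.ndarray | float = 0.0, *, component: str = ""
) -> np.ndarray:
    """Deterministic rate tau * du/dt = -u + h + s + lateral.

    ``lateral`` is the kernel-output convolution supplied by the kernels
    module (zero if the field has no kernel). Noise is added by the
    integrator, not here.
    """
    s = f.inputs
    if np.shape(s) != np.shape(f.u):
        raise ValueError(
            f"input shape {np.shape(s)} does not match activation shape "
            f"{np.shape(f.u)}" + (f" in component {component!r}" if component else "")
        )
    return -f.u + f.h + s + lateral


def node_rate_of_change(n: NodeState, s: float = 0.0) -> float:
    """Deterministic rate tau * du/dt = -u + h + c_uu*g(u) + s."""
    return -n.u + n.h + n.c_uu * n.output() + float(s)


def memory_trace_rate(m: MemoryTraceState, source_output: np.ndarray) -> np.ndarray:
    """dp/dt of the trace: build toward the output, decay away from it.

    Stationary at p = source_output; with distinct time constants the trace
    accumulates activation history faster than it forgets it.
    """
    source_output = np.asarray(source_output, dtype=float)
    if np.shape(source_output) != np.shape(m.p):
        raise ValueError("source_output does not conform to trace geometry")
    diff = source_output - m.p
    tau = np.where(diff > 0, m.tau_build, m.tau_decay)
    return diff / tau
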