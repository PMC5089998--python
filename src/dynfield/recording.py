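"""Time-series and snapshot recording of component quantities to CSV.

Any component quantity — activation, sigmoided output, or summed input —
can be registered for recording at a chosen step rate. Each target writes
one CSV file: header row, first column the simulated timestamp in ms
(simulated, not wall time, so free-running and real-time runs are
comparable), then the flattened values. Grids are flattened row-major in
the component's dimension order (3-D fields: table-x, table-y, hue), with
columns labeled by grid index, e.g. ``activation[2,5,0]``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RecordingSpec", "Recorder"]

QUANTITIES = ("activation", "output", "input_sum")
MODES = ("time_series", "snapshot")


@dataclass(frozen=True)
class RecordingSpec:
    """What to record: (component, quantity) targets, every ``rate``-th step."""

    targets: tuple[tuple[str, str], ...]
    rate: int = 1
    mode: str = "time_series"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", tuple((c, q) for c, q in self.targets)
        )
        for _, q in self.targets:
            if q not in QUANTITIES:
                raise ValueError(f"quantity must be one of {QUANTITIES}")
        if self.rate < 1:
            raise ValueError("rate must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _extract(sim, name: str, quantity: str) -> np.ndarray:
    comp = sim.components[name]
    if quantity == "output":
        return np.atleast_1d(np.asarray(comp.output(), dtype=float))
    if quantity == "activation":
        if hasattr(comp, "state"):
            st = comp.state
            for attr in ("u", "p", "x_ctrl"):
                if hasattr(st, attr):
                    return np.atleast_1d(np.asarray(getattr(st, attr), dtype=float))
        return np.atleast_1d(np.asarray(comp.output(), dtype=float))
    # input_sum: the summed coupling + external input gathered last step
    val = sim.last_inputs.get(name, 0.0)
    if comp.geometry is not None and np.ndim(val) == 0:
        val = np.broadcast_to(val, comp.geometry.shape)
    return np.atleast_1d(np.asarray(val, dtype=float))


class Recorder:
    """Collects rows during a run; written to one CSV file per target."""

    def __init__(self, spec: RecordingSpec):
        self.spec = spec
        self.rows: dict[tuple[str, str], list[list[float]]] = {
            t: [] for t in spec.targets
        }
        self._step = 0

    def observe(self, sim, log=None) -> None:
        """Record one row per target if the step rate is due (called by the
        simulator after each publish)."""
        due = self.spec.mode == "time_series" and self._step % self.spec.rate == 0
        self._step += 1
        if not due:
            return
        self.snapshot(sim)

    def snapshot(self, sim) -> None:
        """Record one row per target right now (snapshot mode's entry point)."""
        for name, quantity in self.spec.targets:
            values = _extract(sim, name, quantity).ravel()  # row-major
            self.rows[(name, quantity)].append(
                [float(sim.t_sim), *map(float, values)]
            )

    # ------------------------------------------------------------------
    def _header(self, sim, name: str, quantity: str) -> list[str]:
        values = _extract(sim, name, quantity)
        if values.size == 1:
            return ["t_ms", quantity]
        idx = np.indices(values.shape).reshape(values.ndim, -1).T
        return ["t_ms"] + [
            f"{quantity}[{','.join(map(str, row))}]" for row in idx
        ]

    def write(self, sim, sink) -> dict[tuple[str, str], Path]:
        """Write one CSV per target into directory ``sink``; returns paths."""
        sink = Path(sink)
        sink.mkdir(parents=True, exist_ok=True)
        paths = {}
        for (name, quantity), rows in self.rows.items():
            path = sink / f"{name}_{quantity}.csv"
            try:
                with open(path, "w", newline="", encoding="utf-8") as fh:
                    writer = csv.writer(fh)
                    writer.writerow(self._header(sim, name, quantity))
                    writer.writerows(rows)
            except OSError as err:
                raise OSError(f"failed to write recording {path}: {err}") from err
            paths[(name, quantity)] = path
        return paths
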