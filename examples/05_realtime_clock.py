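"""Synchronizing simulated time with the wall clock.

Runs a small architecture in real-time mode (each step waits out the
remainder of the planned Euler step), injects one artificial compute
stall, and shows how that single step is extended so that simulated time
snaps back in line with physical time.
"""

import time

from dynfield import ClockPolicy, Simulator
from dynfield.graph import ArchitectureGraph, ComponentSpec

graph = ArchitectureGraph(
    [ComponentSpec("n", "node", {"tau": 200.0, "c_noise": 1.0})]
)
sim = Simulator(graph, seed=0)
dt = 20.0


def stall(i):
    if i == 10:
        time.sleep(3 * dt / 1000.0)  # one slow computation


t0 = time.perf_counter()
logs = sim.run(600, ClockPolicy(dt_planned=dt, realtime=True,
                                max_extension_ratio=5.0), compute_hook=stall)
wall_ms = (time.perf_counter() - t0) * 1000

extended = [l for l in logs if l.extended]
print(f"planned step: {dt:.0f} ms, steps run: {len(logs)}")
print(f"extended steps (the 'meter'): {len(extended)}")
for l in extended:
    print(f"  step {l.i}: dt_actual = {l.dt_actual:.1f} ms "
          f"(compute took {l.compute_ms:.1f} ms)")
print(f"simulated time {sim.t_sim:.1f} ms vs wall clock {wall_ms:.1f} ms "
      f"-> aligned to within one planned step "
      f"({abs(sim.t_sim - wall_ms):.1f} ms)")
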