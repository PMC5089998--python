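# Methods

This note documents the model, the numerical choices, the synthetic data,
and the open design decisions behind `dynfield`. It states how quantities
are computed; every empirical number it refers to is produced by the test
suite or by `scripts/acceptance.py`, not asserted here.

## Field, node, and memory-trace dynamics

A field carries an activation grid u over a 0–3-dimensional metric space
and relaxes on a time scale τ (ms) toward an attractor set by the resting
level h, the summed external input s, and the lateral interaction
(kernel-convolved output):

τ u̇ = −u + h + s + (k ∗ g(u)) + c_noise ξ.

The −u term alone makes every subthreshold state an attractor; that
stability is what lets coupled architectures scale and what stabilizes
the numerics. Defaults: τ = 100 ms, h = −5 (activation is dimensionless;
zero is the output threshold), c_noise = 0. A node is the 0-D case with
self-excitation c_uu·g(u) in place of the convolution; the runtime treats
a 0-D field with a kernel as a node with c_uu = k(0), and the two produce
bit-identical trajectories under equal seeds.

Output nonlinearities g(u) ∈ [0, 1]: `logistic` (1 + e^(−β(u−θ)))⁻¹, the
cheap rational approximation `abs_approx` ½(1 + βz/(1+β|z|)) with
z = u − θ, and the hard `step`. β = 4 and θ = 0 by default. The
`abs_approx` variant has polynomially heavy tails (g(−5) ≈ 0.024), which
in large grids produces a non-trivial baseline interaction from fully
subthreshold activation; the shipped demo therefore uses the logistic,
whose subthreshold output is negligible. Both smooth variants output
exactly ½ at θ.

The memory trace is an asymmetric low-pass filter of a field's output:
ṗ = (g − p)/τ_build where g > p, else (g − p)/τ_decay, with
τ_build < τ_decay (defaults 1 s / 10 s) so that activation history
accumulates faster than it is forgotten. Several formulations of trace
dynamics are in circulation; this two-time-constant form is the simplest
one with the required stationary point p = g and bounded range [0, 1],
and growth is effectively gated by the source being suprathreshold
because g ≈ 0 below threshold. Feedback into the host field is an
ordinary coupling whose gain is the trace's `feedback_gain`.

Noise is Gaussian, white in space and time: one independent standard
normal draw per grid cell per step, added to the activation (not the
output), scaled by c_noise. No spatial correlation is imposed.

## Kernels and convolution

k(Δx) = c_exc·Π_d exp(−Δx_d²/2σ_exc,d²) − c_inh·Π_d exp(−Δx_d²/2σ_inh,d²)
− c_glob, with σ_inh ≥ σ_exc elementwise. Gaussians are
amplitude-parameterized (unnormalized), so k(0) = c_exc − c_inh − c_glob.
The local part is sampled on the grid spacing, truncated at
`truncation`·max(σ) (default 5σ), always with an odd sample count, and
clamped (with a warning) when it would exceed the grid.

The interaction integral is the rectangle rule: correlation with the
sampled kernel times the cell volume. The global term is computed as
−c_glob · cell_volume · Σ g exactly (an all-ones kernel without the
O(N²)); its reduction uses `math.fsum`, which is order-independent, so
the global term of circularly shifted inputs is bit-identical. Three
interchangeable paths compute the local part:

* `direct` — explicit padded accumulation over kernel elements in fixed
  order; bitwise translation-equivariant under periodic padding;
* `separable` — per-axis 1-D correlations of the two Gaussian factors
  (the difference-of-Gaussians family is always axis-separable, also with
  anisotropic σ);
* `fft` — circular convolution via rFFT for periodic padding; for
  zero/replicate padding the grid is explicitly padded by the kernel
  half-width first.

`auto` selects FFT in 3-D, FFT above 64×64 in 2-D, separable otherwise —
a performance choice, not semantics; the paths agree to ≲10⁻¹⁴ relative
and the suite cross-checks all of them against a nested-loop brute-force
oracle. Periodic padding is the default and the only mode offered in 3-D;
zero and replicate are available in 1-D/2-D.

Grids are cell-centered: n samples over [lo, up) sit at lo + (i+½)Δ with
Δ = (up−lo)/n. This makes circular dimensions (hue) seamless and gives
every cell the same rectangle-rule weight. Resampling between different
samplings of the same space uses `scipy`'s regular-grid interpolation
(nearest or linear) with target coordinates clamped to the source range
(edge-value extension).

## Coupling algebra

A coupling carries the source's sigmoided output to the target's input
through, in order: permutation of mapped dimensions into target order;
contraction of unmapped source dimensions by the rectangle-rule integral
(sum × cell size, so gains are invariant under grid refinement);
resampling of mapped dimensions when declared; expansion along unmapped
target dimensions by broadcasting (constant ridges/tubes/sheets);
optional kernel smoothing (circular along circular dimensions, edge
replication otherwise); and a signed scalar gain. Recurring patterns are
provided directly: the homogeneous `boost` from a node, the
`peak_detector` contraction into a node, a hue-localized `sheet`
(Gaussian along hue, circular distance), and a `half_space` ramp — a
logistic step at the table midline with steepness 1/softness, chosen over
more elaborate spatial-term kernels because the half-space semantics, not
the exact profile, is what the spatial concepts "left"/"right" need;
left and right profiles sum exactly to the gain.

All couplings read the source output *published at the end of the
previous step* (synchronous update), so evaluation order within a step
can never matter.

## Integration and time

The Euler–Maruyama update is u ← u + (Δt/τ)·f(u) + √Δt·(c_noise/τ)·ξ.
The deterministic term is linear in Δt, the noise term scales with √Δt;
consequently the stationary variance of the discrete
Ornstein–Uhlenbeck chain is c²/(2τ − Δt), the closed form the tests
check, and accumulated noise over a fixed duration is step-size
invariant. Higher-order and adaptive-step integrators are deliberately
not offered: sensor streams arrive at fixed cadence, stochastic
higher-order schemes need many function evaluations, and the attractor
states themselves stabilize the numerics — a step one order of magnitude
below the smallest τ is the working rule (a larger planned step triggers
a warning, not an error), and a self-stabilized peak holds its location
to within one grid cell even at Δt = τ/10. For a linear field the Euler
chain follows h + s + (u₀−h−s)·(1−Δt/τ)^i exactly — an exponential with
rate −ln(1−Δt/τ)/Δt — which is the closed form the linear-regime check
uses at machine precision; a separate test verifies first-order
convergence of the chain to the continuous-time exponential as Δt → 0.

In real-time mode the loop targets absolute deadlines i·Δt_planned on
the wall clock: after computing an update it waits out the remainder of
the planned step (so sleep jitter does not accumulate), and when a
computation overruns its deadline, that single step's Δt is extended to
the realized duration so simulated time snaps back to physical time; the
next step reverts to the plan. The per-step log (index, simulated time,
realized Δt, extended flag, compute time) is the "meter": a warning
recommends a larger planned step when more than `meter_fraction`
(default 5%) of steps were extended, and any single extension beyond
`max_extension_ratio` × plan is flagged immediately. Whether the noise
of an extended step should be redrawn for the extra duration is
unspecified territory; the single draw is scaled by √Δt_actual.

Free-running runs are bit-reproducible: each component draws noise from
its own child generator spawned from the master seed, so trajectories are
independent of scheduling order. That choice also makes multi-rate
execution exact in the degenerate case: step groups due at the same
instant gather their inputs jointly before any of them publishes, hence
equal-Δt groups reproduce the single-group run bit for bit, and
cross-group input staleness is bounded by the largest group step
(audited as `max_staleness`). Multi-rate is implemented as interleaved
sequential scheduling that honors the publish/buffer contract — the
observable semantics of running groups in separate threads, without the
concurrency hazards; real-time multi-rate is not offered.

## Architecture graphs, config, recording

A graph is components (field, node, memory_trace, sensor, readout) +
couplings + optional step groups, serialized as a single JSON document.
Unknown keys are load errors (silent typos are the classic tuning
hazard); parameter ranges are *not* load errors — `validate()` is total,
returning every violation (name collisions, dimension-map injectivity,
bounds compatibility, group partition, ranges) without raising. Floats
round-trip bit-exactly through the JSON dialect. Cycles are expected;
recurrence is the norm.

Recording registers (component, quantity ∈ {activation, output,
input_sum}) targets at a step rate, or as on-demand snapshots, and writes
one CSV per target: header row, first column the *simulated* timestamp in
ms (so free-running and real-time runs are comparable), grids flattened
row-major in the component's dimension order — (table-x, table-y, hue)
for 3-D fields — with columns labeled by grid index.

## Synthetic scenes and the sensor/motor boundary

The camera is synthetic: anti-aliased colored disks (hue, saturation,
full value) on a zero-saturation gray background, rendered directly in
allocentric table coordinates (axis 0 = table-x). The camera-to-table
transform of a physical rig is hardware calibration and is taken as the
identity. Space-code encoding deposits, per pixel, saturation × gain at
the hue bin nearest the pixel's hue — hue is treated as circular
throughout (binning, smoothing, sheet placement) — and zero elsewhere;
optional Gaussian smoothing along hue only is mass-preserving per column.
Images finer than the spatial grid are average-pooled first. What this
generator does *not* emulate: sensor noise, illumination and shading,
occlusion, perspective, or moving objects — passing tests show the
architecture logic is correct under the stated camera contract, not that
it is robust to real-camera nuisances.

The effector is a point: its position *is* the readout control variable
(the attractor dynamics is the controller; an optional first-order lag is
available), with a vertical coordinate conceptually pinned. Proprioception
is a Gaussian bump (amplitude/width configurable) at the current position.
`peak_centroid` implements the normalized-centroid estimate and returns an
explicit undefined flag at N = 0 — it never divides by zero;
`readout_rate` evaluates the single integral −∫(x_ctrl − x) g du directly
and never goes through the centroid, which is what makes N = 0 a
well-defined (frozen) state. The identity rate ≡ −N(x_ctrl − x_cmd) is
verified to 10⁻⁸ on random patterns.

## The feature-search exemplar and its tuning

The demo graph is 9 components: camera sensor, four cue nodes, the 3-D
perceptual field (24×24×16 over a unit table and the hue circle), the 2-D
CoS field (24×24), the readout, and the proprioception source. The tuned
contracts, each audited by tests rather than taken on faith:

* camera alone, and camera + one cue, leave the perceptual field
  subthreshold; camera + both cues push exactly one peak through the
  detection instability at the matching object (single-peak regime via
  global inhibition);
* both CoS inputs (hue-contracted smoothed target projection,
  proprioceptive bump) are individually subthreshold and jointly
  suprathreshold — so the CoS fires only on arrival;
* the CoS field is tuned to a commit-then-release regime: its peak
  self-stabilizes decisively at the combined input but cannot survive on
  the proprioceptive bump alone, so the satisfaction event terminates
  itself once its consequences (below) remove the target input;
* CoS output inhibits every cue node (peak-detector contraction) and the
  perceptual field homogeneously (its output mass is contracted to a
  scalar and broadcast over x/y/hue — a localized inhibition can be
  escaped by peak drift, a homogeneous one cannot);
* the cue nodes are narrowly bistable (c_uu = 7, logistic β = 4: on-state
  u* ≈ 2, extinguished by an inhibition of ≈1.1), so even a brief CoS
  event resets them; with the nodes off, the cue inputs vanish and the
  perceptual peak undergoes its reverse detection, which in turn removes
  the CoS target input and completes the reset. Earlier, broader node
  tuning (c_uu = 10) survived the CoS pulse and produced a relaxation
  oscillation instead of a reset — the narrow bistability is what makes
  the behavioral cycle terminate cleanly.

Movement initiation needs no explicit gate: the readout is marginally
stable at N = 0 and engages automatically when the perceptual peak forms.
No tie-breaking is imposed for symmetric inputs; noise breaks the
symmetry, and the tests assert "exactly one winner", not which one. Cue
entry is a transient additive boost (amplitude 8, 300 ms) that flips the
bistable node on. All parameters live in `DEMO_DEFAULTS` and are
overridable per build (nested merge) and through the JSON config.

Trials run free-running at Δt = 10 ms with all τ ≥ 100 ms, last ≤ 5 s,
and are classified by a condition/action protocol runner (boost/release/
end-trial rules evaluated once per step). A trial is successful when the
pointer's final position is nearest the cued object, the CoS fired, and
every field and node is subthreshold again 2 s after the CoS event. The
problem sizes used throughout the suite and the acceptance script — a
24×24×16 perceptual grid, 100-cell 1-D probe fields, 10 seeds per cue
pair, 20 seeded selection runs, 10⁵-step noise statistics — were chosen
so the complete audit runs in a few minutes on one CPU while keeping every
statistical margin comfortable.

`regime_scan` maps instabilities on an isolated probe field: ramp a level
(input gain or a kernel parameter) up and then down, integrate ~1 s per
plateau with activation carried over (that carry-over is what exposes
hysteresis), and count suprathreshold peaks — connected components of
u > 0 under face connectivity with ≥ 2 cells (single-cell noise
excursions are ignored), centroids output-weighted within each component.

## Known limitations

* Fields are limited to three dimensions; higher-dimensional fields and
  coordinate-transform ("operator") couplings between two source fields
  are out of scope.
* The multi-rate runtime is sequential-deterministic; it does not model
  the timing jitter of a true threaded implementation, only its
  buffering/staleness contract.
* The memory trace ships with the dynamics above but the exemplar does
  not exercise learning; trace-driven adaptation experiments are future
  work.
* The demo's latencies depend on the readout travel time and are not
  calibrated to any biological or robotic reference.
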