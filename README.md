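# dynfield

Simulation framework for **dynamic field theory (DFT)** architectures:
neural population dynamics for embodied cognitive systems — autonomous
robots and artificial perception systems whose "thinking" is carried by
attractor states of continuous-time neural dynamics, coupled in real time
to sensors and effectors.

It is written for researchers who want to build, tune, and evaluate DFT
architectures in Python: assemble fields and nodes into a graph, couple
them through a small constrained algebra, integrate the whole system with
a fixed-step stochastic Euler scheme that can synchronize with the wall
clock, record any quantity to CSV, and probe each component's dynamic
regime with automated instability scans.

## The model

The core element is the dynamic neural field, an activation distribution
u(**x**, t) over up to three continuous feature dimensions (table position,
hue, ...):

    τ u̇(x,t) = −u(x,t) + h + s(x,t) + ∫ k(x−x′) g(u(x′,t)) dx′ + c_noise ξ(x,t)

with time scale τ, resting level h < 0, external input s, Gaussian white
noise ξ, a sigmoidal output nonlinearity g(u) ∈ [0, 1], and a lateral
interaction kernel k (local excitation, surround/global inhibition)
parameterized here as a difference of Gaussians plus a global constant.
Localized suprathreshold *peaks* of activation are the units of
representation; the *instabilities* between attractor states — detection,
reverse detection, selection, sustained activation (working memory) — are
the cognitive events. A node is the zero-dimensional special case
τ u̇ = −u + h + c_uu g(u) + s, representing categorical states.

Components couple only through their sigmoided output: one-to-one,
expansion (broadcast along new dimensions: ridge/tube/sheet inputs),
contraction (rectangle-rule integral over dimensions the target lacks),
optional kernel smoothing, and a signed gain. Sensors enter as space
codes — a camera pixel deposits its saturation at the field position
matching its location and hue — and motor commands leave through the
normalization-free attractor readout

    τ_ctrl ẋ_ctrl = −∫ (x_ctrl − x) g(u(x,t)) dx

which tracks a peak's centroid with stiffness N = ∫ g du and is marginally
stable (frozen) when no peak exists, so no division by N is ever needed.

Everything is integrated with the stochastic (Euler–Maruyama) method,
u(t_i) = u(t_{i−1}) + (Δt/τ) f(u) + √Δt (c_noise/τ) ξ, whose noise term
scales with √Δt; in real-time mode the loop waits out each planned step
and, when a computation occasionally overruns it, extends that one step to
re-align simulated with physical time.

## Worked example

The shipped exemplar (`examples/04_feature_search_trial.py`) assembles the
feature-search-and-point task: a camera over a tabletop with four colored
objects, four bistable cue nodes ("red", "green", "left", "right"), a 3-D
perceptual field over (x, y, hue) in the single-peak regime, an attractor
readout steering a simulated pointer, and a condition-of-satisfaction
(CoS) field that detects arrival and resets the architecture:

```text
$ python examples/04_feature_search_trial.py
scene objects (index: hue @ position):
  0: green @ (0.25, 0.30)
  1: green @ (0.75, 0.30)
  2: red @ (0.25, 0.70)
  3: red @ (0.75, 0.70)

cue 'green' + 'left':
  selected object   0
  CoS triggered     True
  latency           1090 ms (cue -> CoS detection)
  final pointer     (0.297, 0.336)
  clean reset       True (all fields/nodes subthreshold again)

second cue 'red' + 'right' in the same run:
  selected object   3
  CoS triggered     True
```

Reading the numbers: boosting the "green" and "left" nodes makes their
sheet and half-space inputs overlap the camera blob of exactly one object;
the perceptual field goes through a detection instability there (neither
camera input alone nor a single cue suffices — the controls in the test
suite verify this), the readout moves the pointer to the peak, the CoS
field fires when the proprioceptive bump overlaps the target projection
(~1.1 s after the cue), and its peak inhibits the perceptual field and all
cue nodes, returning every component below threshold — ready for the next
cue in the same run.

The other examples are single-capability walkthroughs: `01` relaxation
and detection hysteresis on one field, `02` automated instability scans
(`regime_scan`), `03` space-code encoding and the normalization-free
readout, `05` wall-clock synchronization with an injected stall. A thin
CLI wraps the same machinery (`dynfield validate`, `dynfield run`,
`dynfield demo`); `examples/feature_search.json` is the demo architecture
in the JSON config dialect.

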