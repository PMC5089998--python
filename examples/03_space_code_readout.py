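"""From a camera image to a motor command without normalization.

Renders a synthetic tabletop scene, space-codes it into a 3-D
(x, y, hue) input tensor, and reads the target position out of a
suprathreshold pattern with the attractor dynamics
tau_ctrl dx_ctrl/dt = -int (x_ctrl - x) g(u(x)) dx, which needs no
division by the output mass N and simply freezes when no peak exists.
"""

import numpy as np

from dynfield import (
    FieldGeometry,
    ReadoutState,
    SceneObject,
    SceneSpec,
    encode_space_code,
    peak_centroid,
    readout_rate,
    render_scene,
)

geo3 = FieldGeometry(("x", "y", "hue"), (0, 0, 0), (1, 1, 1),
                     (48, 48, 16), (False, False, True))
scene = SceneSpec(image_size=(48, 48), objects=(
    SceneObject(center=(0.3, 0.7), radius=6.0, hue=1 / 3),))
image = render_scene(scene)
code = encode_space_code(image, geo3, hue_smoothing_sigma=0.0, gain=2.0)
nz = np.nonzero(code.tensor)
print(f"encoded tensor: {len(nz[0])} non-zero cells, all in hue bin(s) "
      f"{sorted(set(nz[2].tolist()))} (green is bin "
      f"{geo3.nearest_index(2, 1 / 3)})")

# pretend the perceptual field has selected this object: contract over hue
geo2 = FieldGeometry(("x", "y"), (0.0, 0.0), (1.0, 1.0), (48, 48))
output = np.clip(code.tensor.sum(axis=2), 0.0, 1.0)

res = peak_centroid(output, geo2)
print(f"peak centroid estimate: x_cmd = ({res.x_cmd[0]:.3f}, {res.x_cmd[1]:.3f}),"
      f" mass N = {res.N:.4f}")

state = ReadoutState(np.array([0.9, 0.1]), tau_ctrl=50.0)
dt = 5.0
for _ in range(int(10 * state.tau_ctrl / res.N / dt)):
    state.x_ctrl = state.x_ctrl + (dt / state.tau_ctrl) * readout_rate(
        state, output, geo2)
print(f"attractor readout converged to ({state.x_ctrl[0]:.3f}, "
      f"{state.x_ctrl[1]:.3f}) — the object sits at (0.300, 0.700)")

before = state.x_ctrl.copy()
for _ in range(100):
    state.x_ctrl = state.x_ctrl + (dt / state.tau_ctrl) * readout_rate(
        state, np.zeros(geo2.shape), geo2)
print(f"with zero output the control variable is frozen: moved "
      f"{np.max(np.abs(state.x_ctrl - before)):.1e}")
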