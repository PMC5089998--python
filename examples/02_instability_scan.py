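"""Mapping dynamic regimes with automated parameter scans.

Ramps the input amplitude of an isolated probe field up and then down and
reports where the detection and reverse-detection instabilities occur
(their gap is the hysteresis window), then shows how raising global
inhibition collapses a two-peak state into a single winner (selection).
"""

import numpy as np

from dynfield import FieldGeometry, KernelSpec
from dynfield.demo import regime_scan

geo = FieldGeometry(("x",), (0.0,), (10.0,), (100,))
x = geo.coords(0)
bump = np.exp(-((x - 5.0) ** 2) / (2 * 0.4**2))
levels = np.linspace(0.0, 8.0, 17)

rep = regime_scan(geo, KernelSpec(c_exc=10.0, sigma_exc=0.5, c_glob=1.0),
                  bump, levels, hold_steps=100)
print(f"detection instability at input  {rep.detection_level:.1f}")
print(f"reverse detection at input      {rep.reverse_level:.1f}")
print(f"hysteresis window               {rep.hysteresis_width:.1f}  (> 0: the "
      "detection decision is stabilized)")

rep = regime_scan(geo, KernelSpec(c_exc=20.0, sigma_exc=0.5, c_glob=1.0),
                  bump, levels, hold_steps=100)
print(f"with doubled self-excitation: sustained = {rep.sustained}  "
      "(peak survives input removal: working memory)")

two = 6.0 * (np.exp(-((x - 3.0) ** 2) / (2 * 0.4**2))
             + np.exp(-((x - 7.0) ** 2) / (2 * 0.4**2)))
for c_glob in (1.0, 4.0):
    rep = regime_scan(geo, KernelSpec(c_exc=10.0, sigma_exc=0.5, c_glob=c_glob),
                      two, [c_glob], scan="kernel.c_glob", hold_steps=300,
                      c_noise=0.5, seed=3, down=False)
    locs = [f"{loc[0]:.1f}" for loc in rep.up[0].locations]
    print(f"two bumps, c_glob = {c_glob:.1f}: {rep.up[0].n_peaks} peak(s) at "
          f"{locs}")
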