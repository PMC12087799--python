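"""Wavelet-scattering descriptors of a centroid trajectory.

Builds the two-order filter bank whose center frequencies span
[0.06, 9.1] Hz and [0.07, 8.3] Hz at 20 Hz, applies it to a trajectory
dominated by the ~0.2 Hz electrode-alternation rhythm, and shows that the
strongest first-order descriptor sits at the band closest to 0.2 Hz.
"""

import numpy as np

from odepkit import scattering_config, wst_descriptors

config = scattering_config(fs=20.0, n_samples=1000)
print(
    f"filter banks: {len(config.f1_hz)} first-order "
    f"({config.f1_hz[-1]:.2f}-{config.f1_hz[0]:.2f} Hz), "
    f"{len(config.f2_hz)} second-order "
    f"({config.f2_hz[-1]:.2f}-{config.f2_hz[0]:.2f} Hz)"
)
print(f"descriptor vector length: {config.n_descriptors} (x and y axes)")

t = np.arange(1000) / 20.0
x = 5.0 * np.sin(2 * np.pi * 0.2 * t) + 0.3 * np.sin(2 * np.pi * 2.1 * t)
y = 0.5 * np.sin(2 * np.pi * 0.11 * t)
values, names = wst_descriptors(x, y, config)

s1x = {n: v for n, v in zip(names, values) if n.startswith("muS1x")}
top = sorted(s1x, key=s1x.get, reverse=True)[:3]
print("strongest first-order x descriptors:")
for n in top:
    print(f"  {n}: {s1x[n]:.3f}")
print("\nThe dominant band matches the 0.2 Hz oscillation of the input.")
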