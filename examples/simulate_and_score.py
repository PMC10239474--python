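"""Simulate a density map from a toy structure and score it against itself.

Builds a 40-atom helix-like trace, evaluates the Gaussian forward model
at 4 A on a 32^3 grid, then degrades the map with SD-1/6 noise and
reports how the map-model FSC-0.5 and real-space correlations respond.
"""

import numpy as np

from cryopolish.fixtures import FixtureSpec, degrade_map, make_toy_structure
from cryopolish.grid import DensityGrid
from cryopolish.metrics import cc_suite, fsc_threshold_resolution, map_model_fsc
from cryopolish.structure import simulate_map

spec = FixtureSpec(n_structures=1, n_atoms=40, map_shape=(32, 32, 32), seed=0)
rng = np.random.default_rng(0)
atoms = make_toy_structure(spec, rng)
template = DensityGrid(np.zeros(spec.map_shape, np.float32), 1.0, 0.0)

clean = simulate_map(atoms, 4.0, template)
noisy = degrade_map(clean, spec, rng, resolution=4.0)

r_clean = fsc_threshold_resolution(map_model_fsc(clean, atoms, 4.0))
r_noisy = fsc_threshold_resolution(map_model_fsc(noisy, atoms, 4.0))
cc = cc_suite(noisy, clean, atoms)

print(f"clean map FSC-0.5 : {r_clean.resolution:.2f} A "
      f"(crossed={r_clean.crossed})")
print(f"noisy map FSC-0.5 : {r_noisy.resolution:.2f} A "
      f"(crossed={r_noisy.crossed})")
print(f"noisy vs clean CC_box {cc.cc_box:.3f}  CC_mask {cc.cc_mask:.3f}  "
      f"CC_peaks {cc.cc_peaks:.3f}")
print("The clean forward-model map correlates perfectly with its own model")
print("(FSC-0.5 at Nyquist); blur+noise push the crossing to coarser")
print("resolution and depress the real-space correlations.")
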