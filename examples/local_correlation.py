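"""Map a local (7^3-neighbourhood) correlation field between two maps.

Compares a degraded map against its clean forward-model target and
prints how the local Pearson correlation distributes over the structure
region versus the solvent background.
"""

import numpy as np

from cryopolish.fixtures import FixtureSpec, build_fixture_set
from cryopolish.grid import near_atom_mask
from cryopolish.metrics import local_correlation_map

fs = build_fixture_set(FixtureSpec(n_structures=1, n_atoms=60,
                                   map_shape=(48, 48, 48), n_val=0, seed=2))
it = fs.items[0]

corr, valid = local_correlation_map(it.degraded, it.clean, box=7)
near = near_atom_mask(it.degraded, it.atoms.coords, 3.0)

struct = corr.values[valid & near]
solvent = corr.values[valid & ~near]
print(f"valid voxels: {valid.sum()} of {valid.size}")
print(f"local correlation near atoms   : mean {struct.mean():.3f}")
print(f"local correlation in solvent   : mean {solvent.mean():.3f}")
print("High local correlation marks regions where the degraded map still")
print("tracks the model density; the noisy solvent shows next to none.")
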