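import numpy as np
import pytest

from cryopolish.grid import DensityGrid
from cryopolish.structure import AtomSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    """A smooth 16^3 test field at 1 A spacing."""
    z, y, x = np.meshgrid(*[np.linspace(0, 1, 16)] * 3, indexing="ij")
    vals = np.exp(-((x - 0.5) ** 2 + (y - 0.5) ** 2 + (z - 0.5) ** 2) * 8)
    return DensityGrid(vals.astype(np.float32), 1.0, 0.0)


@pytest.fixture
def toy_atoms():
    """Five heavy atoms spread around the centre of a 24 A cube."""
    coords = np.array([
        [12.0, 12.0, 12.0],
        [9.5, 12.0, 13.0],
        [14.0, 10.0, 12.5],
        [12.0, 15.0, 10.0],
        [11.0, 11.0, 16.0],
    ])
    return AtomSet(["C", "N", "O", "C", "S"], [6, 7, 8, 6, 16], coords,
                   ["A"] * 5, [1, 1, 2, 2, 3])


def make_pdb(path, records):
    """Write a minimal PDB file; records = (name, element, x, y, z, chain,
    occupancy, altloc)."""
    lines = []
    for i, (name, elem, x, y, z, chain, occ, alt) in enumerate(records, 1):
        lines.append(
            f"ATOM  {i:5d}  {name:<3s}{alt:1s}GLY {chain:1s}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {elem:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
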