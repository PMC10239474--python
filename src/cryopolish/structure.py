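"""Atomic structures and the Gaussian forward model for density simulation.

A map at nominal resolution ``R`` is simulated from the heavy atoms of a
structure as a sum of atom-centred Gaussians,

    rho(x) = sum_i theta * Z_i * exp(-k |x - r_i|^2),

with ``k = (pi / (1.2 + 0.6 R))^2`` and ``theta = (k / pi)^1.5``.  The
scaling makes each atom's Gaussian integrate to its atomic number Z_i.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import gemmi
import numpy as np

from .grid import DensityGrid

__all__ = [
    "AtomSet", "SimulationParams", "load_structure",
    "resolution_to_k", "k_to_theta", "simulate_map",
]


@dataclasses.dataclass
class AtomSet:
    """Heavy atoms of a structure: elements, positions, chain labels."""

    elements: np.ndarray        # element symbols, str
    z: np.ndarray               # atomic numbers, int
    coords: np.ndarray          # (N, 3) Cartesian (x, y, z) in Angstrom
    chains: np.ndarray          # chain identifiers, str
    residues: np.ndarray        # residue sequence numbers, int

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.z = np.asarray(self.z, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.chains = np.asarray(self.chains, dtype=object)
        self.residues = np.asarray(self.residues, dtype=int)
        if len(self) == 0:
            raise ValueError("atom set must contain at least one heavy atom")
        if np.any(self.z < 1):
            raise ValueError("atomic numbers must be >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.z)

    def select_chain(self, chain: str) -> "AtomSet":
        m = self.chains == chain
        return AtomSet(self.elements[m], self.z[m], self.coords[m],
                       self.chains[m], self.residues[m])


@dataclasses.dataclass
class SimulationParams:
    """Resolution-derived Gaussian width and scale for map simulation."""

    resolution: float           # nominal resolution R, Angstrom
    k: float                    # Gaussian decay, 1/A^2
    theta: float                # amplitude scale, dimensionless
    truncation_radius: float    # Gaussian support cutoff, Angstrom

    @classmethod
    def from_resolution(cls, resolution: float,
                        truncation_radius: float | None = None
                        ) -> "SimulationParams":
        k = resolution_to_k(resolution)
        if truncation_radius is None:
            truncation_radius = 5.0 / math.sqrt(k)  # tail below e^-25
        if not truncation_radius > 0:
            raise ValueError("truncation radius must be positive")
        return cls(resolution, k, k_to_theta(k), truncation_radius)


def resolution_to_k(resolution: float) -> float:
    """Gaussian decay constant k = (pi/(1.2 + 0.6 R))^2 in 1/A^2."""
    if not resolution > 0:
        raise ValueError("resolution must be positive")
    return (math.pi / (1.2 + 0.6 * resolution)) ** 2


def k_to_theta(k: float) -> float:
    """Amplitude scale theta = (k/pi)^1.5 normalising each atom to Z."""
    if not k > 0:
        raise ValueError("k must be positive")
    return (k / math.pi) ** 1.5


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def load_structure(path, drop_waters: bool = False) -> AtomSet:
    """Parse heavy atoms from a PDB or mmCIF file.

    Model 1 is used for multi-model files; among alternate locations the
    highest-occupancy conformer of each atom is kept; hydrogens are
    always discarded.  Hetero atoms (ligands, ions, waters) are included
    unless ``drop_waters`` removes the solvent.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    model = st[0]
    elements, zs, coords, chains, residues = [], [], [], [], []
    for chain in model:
        for res in chain:
            if drop_waters and res.name.strip() in _WATER_NAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                elements.append(atom.element.name)
                zs.append(atom.element.atomic_number)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                chains.append(chain.name)
                residues.append(res.seqid.num)
    if not zs:
        raise ValueError(f"structure {path} contains no heavy atoms")
    return AtomSet(elements, zs, coords, chains, residues)


def simulate_map(atoms: AtomSet, resolution: float, template: DensityGrid,
                 truncation_radius: float | None = None) -> DensityGrid:
    """Evaluate the Gaussian forward model on the template's lattice.

    Each atom contributes ``theta * Z * exp(-k d^2)`` at voxel centres
    within ``truncation_radius`` of its position (default ``5/sqrt(k)``,
    where the tail is below e^-25).
    """
    params = SimulationParams.from_resolution(resolution, truncation_radius)
    out = np.zeros(template.shape, dtype=np.float64)
    zax, yax, xax = template.axes()
    axes_xyz = (xax, yax, zax)
    spacing_xyz = template.spacing[::-1]
    rcut = params.truncation_radius
    n_outside = 0
    for zi, pos in zip(atoms.z, atoms.coords):
        lo, hi, offs = [], [], []
        inside = True
        for a in range(3):   # x, y, z
            ax = axes_xyz[a]
            i0 = int(np.ceil((pos[a] - rcut - ax[0]) / spacing_xyz[a]))
            i1 = int(np.floor((pos[a] + rcut - ax[0]) / spacing_xyz[a]))
            i0, i1 = max(i0, 0), min(i1, len(ax) - 1)
            if i0 > i1:
                inside = False
                break
            lo.append(i0)
            hi.append(i1)
            offs.append(ax[i0:i1 + 1] - pos[a])
        if not inside:
            n_outside += 1
            continue
        d2 = (offs[2][:, None, None] ** 2 + offs[1][None, :, None] ** 2
              + offs[0][None, None, :] ** 2)
        contrib = params.theta * zi * np.exp(-params.k * d2)
        contrib[d2 > rcut * rcut] = 0.0
        out[lo[2]:hi[2] + 1, lo[1]:hi[1] + 1, lo[0]:hi[0] + 1] += contrib
    if n_outside == len(atoms):
        warnings.warn("all atoms fall outside the grid; simulated map is zero",
                      stacklevel=2)
    return template.copy_with(out.astype(np.float32))
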