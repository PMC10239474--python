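"""Density volumes in MRC/CCP4 format: reading, writing, regridding,
normalisation and simple combination.

Conventions
-----------
* ``DensityGrid.values`` is indexed ``[z, y, x]``; ``spacing`` and
  ``origin`` are stored in the same axis order.
* Voxel ``(i, j, k)`` has its physical centre at ``origin + (i, j, k) *
  spacing`` (grid-point convention, shared by every module).
* Files with permuted axis order in the header are canonicalised on
  read.  Non-orthogonal cells are rejected.
* When both the ORIGIN header record and NXSTART offsets are present,
  ORIGIN wins (modern single-particle convention).
"""

from __future__ import annotations

import dataclasses
import warnings

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DensityGrid", "NormalizationRecord", "read_map", "write_map",
    "resample_to_spacing", "clip_negative", "normalize_global",
    "average_half_maps", "segment_near_atoms",
]


@dataclasses.dataclass
class DensityGrid:
    """A 3D scalar density field on a regular orthorhombic lattice."""

    values: np.ndarray          # (nz, ny, nx) float32
    spacing: np.ndarray         # Angstrom per voxel, axis order (z, y, x)
    origin: np.ndarray          # position of voxel (0,0,0) in Angstrom (z, y, x)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = np.array(np.broadcast_to(self.spacing, (3,)), dtype=float)
        self.origin = np.array(np.broadcast_to(self.origin, (3,)), dtype=float)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be positive on every axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-centre coordinates along each array axis (z, y, x)."""
        return tuple(self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                     for a in range(3))

    def same_geometry(self, other: "DensityGrid", tol: float = 1e-4) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def copy_with(self, values: np.ndarray) -> "DensityGrid":
        return DensityGrid(values, self.spacing.copy(), self.origin.copy())

    def blank_like(self, dtype=np.float32) -> "DensityGrid":
        return self.copy_with(np.zeros(self.shape, dtype=dtype))


@dataclasses.dataclass
class NormalizationRecord:
    """Provenance of a global map normalisation."""

    scale: float                # the 99.999-percentile divisor, density units
    clip_applied: bool

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("normalisation scale must be positive")


_ORTHO_TOL = 1e-3


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 volume and canonicalise it to (z, y, x) order."""
    m = gemmi.read_ccp4_map(str(path))
    cell = m.grid.unit_cell
    if (abs(cell.alpha - 90) > _ORTHO_TOL or abs(cell.beta - 90) > _ORTHO_TOL
            or abs(cell.gamma - 90) > _ORTHO_TOL):
        raise ValueError(
            f"non-orthogonal cell angles ({cell.alpha}, {cell.beta}, "
            f"{cell.gamma}) are not supported")
    # header words: 5-7 NXSTART along file axes, 17-19 axis order, 50-52 ORIGIN
    axis_of = [m.header_i32(17 + i) - 1 for i in range(3)]  # file axis -> xyz
    nstart_xyz = [0, 0, 0]
    for file_axis in range(3):
        nstart_xyz[axis_of[file_axis]] = m.header_i32(5 + file_axis)
    origin_xyz = np.array([m.header_float(50 + i) for i in range(3)])
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    spacing_xyz = np.array(m.grid.spacing, dtype=float)
    if np.any(origin_xyz != 0.0):
        start_xyz = origin_xyz
    else:
        start_xyz = np.asarray(nstart_xyz, dtype=float) * spacing_xyz
    values = np.ascontiguousarray(
        np.array(m.grid, copy=False).transpose(2, 1, 0), dtype=np.float32)
    return DensityGrid(values, spacing_xyz[::-1], start_xyz[::-1])


def write_map(grid: DensityGrid, path) -> None:
    """Write a volume as a float32 (mode 2) MRC/CCP4 file."""
    nz, ny, nx = grid.shape
    sx, sy, sz = grid.spacing[::-1]
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90, 90, 90))
    g.spacegroup = gemmi.SpaceGroup("P1")
    np.array(g, copy=False)[:] = np.asarray(
        grid.values, dtype=np.float32).transpose(2, 1, 0)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    ox, oy, oz = grid.origin[::-1]
    m.set_header_float(50, float(ox))
    m.set_header_float(51, float(oy))
    m.set_header_float(52, float(oz))
    m.write_ccp4_map(str(path))


def resample_to_spacing(grid: DensityGrid, target: float) -> DensityGrid:
    """Cubic-spline interpolation onto a lattice with spacing ``target`` Å.

    The physical extent and the origin are preserved; points that fall
    outside the source support take the value 0 (solvent).
    """
    if not target > 0:
        raise ValueError("target spacing must be positive")
    new_shape = tuple(
        int(np.floor((n - 1) * s / target + 1e-9)) + 1
        for n, s in zip(grid.shape, grid.spacing))
    # new voxel i sits at physical origin + i*target -> source index i*target/s
    axes = [np.arange(n) * target / s for n, s in zip(new_shape, grid.spacing)]
    coords = np.stack(np.meshgrid(*axes, indexing="ij"))
    # mirror boundary for the spline coefficients (a zero-padded prefilter
    # would corrupt interior voxels near the edges); the preserved extent
    # keeps every target point inside the source support, and any point
    # outside (numerical edge cases) is zero-filled explicitly
    out = ndimage.map_coordinates(
        grid.values.astype(np.float64), coords, order=3,
        mode="mirror", prefilter=True)
    for a in range(3):
        outside = (coords[a] < -1e-9) | (coords[a] > grid.shape[a] - 1 + 1e-9)
        out[outside] = 0.0
    return DensityGrid(out.astype(np.float32), np.full(3, float(target)),
                       grid.origin.copy())


def clip_negative(grid: DensityGrid) -> DensityGrid:
    """Clip density at zero (negative values are solvent/noise artefacts)."""
    return grid.copy_with(np.maximum(grid.values, 0))


def normalize_global(grid: DensityGrid,
                     percentile: float = 99.999
                     ) -> tuple[DensityGrid, NormalizationRecord]:
    """Divide the map by its 99.999-percentile density value.

    The grid should be clipped first (`clip_negative`); a map whose
    percentile is not positive cannot be normalised.
    """
    scale = float(np.percentile(grid.values, percentile))
    if not scale > 0:
        raise ValueError("normalisation percentile is not positive "
                         "(empty or all-zero map)")
    rec = NormalizationRecord(scale=scale,
                              clip_applied=bool(grid.values.min() >= 0))
    return grid.copy_with((grid.values / scale).astype(np.float32)), rec


def average_half_maps(a: DensityGrid, b: DensityGrid) -> DensityGrid:
    """Voxel-wise mean of two half-maps with identical geometry."""
    if not a.same_geometry(b):
        raise ValueError("half-maps must share shape, spacing and origin")
    return a.copy_with(((a.values.astype(np.float64)
                         + b.values.astype(np.float64)) / 2).astype(np.float32))


def near_atom_mask(grid: DensityGrid, coords_xyz: np.ndarray,
                   cutoff: float) -> np.ndarray:
    """Boolean mask of voxels whose centre lies within ``cutoff`` Å of any
    of the given (x, y, z) points."""
    if len(coords_xyz) == 0:
        raise ValueError("empty atom set")
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    zax, yax, xax = grid.axes()
    zz, yy, xx = np.meshgrid(zax, yax, xax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    tree = cKDTree(np.asarray(coords_xyz, dtype=float))
    eps = 1e-9 * cutoff   # keep voxels exactly at the cutoff distance
    dist, _ = tree.query(pts, distance_upper_bound=cutoff + eps)
    return (dist <= cutoff + eps).reshape(grid.shape)


def segment_near_atoms(grid: DensityGrid, atoms, cutoff: float = 4.0,
                       chain: str | None = None) -> DensityGrid:
    """Zero out voxels farther than ``cutoff`` Å from every (selected) atom.

    ``atoms`` is an :class:`~cryopolish.structure.AtomSet`; pass ``chain``
    to segment the density belonging to a single chain.
    """
    coords = atoms.coords if chain is None else atoms.coords[atoms.chains == chain]
    if len(coords) == 0:
        raise ValueError("no atoms selected for segmentation")
    mask = near_atom_mask(grid, coords, cutoff)
    return grid.copy_with(np.where(mask, grid.values, 0).astype(grid.values.dtype))


def warn_if_resampled(spacing: np.ndarray, target: float, tol=1e-3) -> bool:
    """True when a map needs regridding to the working spacing."""
    mismatched = bool(np.any(np.abs(spacing - target) > tol))
    if mismatched:
        warnings.warn(f"map spacing {spacing} differs from working spacing "
                      f"{target} A; resampling", stacklevel=2)
    return mismatched
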