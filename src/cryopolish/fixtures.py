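"""Synthetic structures and degraded/clean map pairs for desk-scale work.

The generator emulates the statistical structure of the training data:
clean target maps are Gaussian forward-model maps of toy heavy-atom
structures at resolutions drawn from 3.0-6.0 Å; degraded "experimental"
inputs are produced by normalising the clean map to 0-1, applying a
resolution-dependent low-pass blur and adding i.i.d. Gaussian noise with
standard deviation 1/6.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib

import numpy as np
from scipy import ndimage

from .grid import DensityGrid
from .structure import AtomSet, simulate_map

__all__ = ["FixtureSpec", "FixtureItem", "FixtureSet",
           "make_toy_structure", "degrade_map", "build_fixture_set"]


@dataclasses.dataclass
class FixtureSpec:
    """Study conditions for a synthetic fixture set."""

    n_structures: int = 20
    n_atoms: int = 500
    style: str = "helix"                 # helix | coil | blob
    resolution_range: tuple[float, float] = (3.0, 6.0)
    map_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.0
    blur: bool = True                    # resolution-dependent low-pass
    noise_sd: float = 1.0 / 6.0
    n_val: int = 3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.resolution_range
        if not (3.0 <= lo <= hi <= 6.0):
            raise ValueError("resolution range must lie within [3.0, 6.0] A")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.style not in ("helix", "coil", "blob"):
            raise ValueError(f"unknown geometry style {self.style!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resolution_range"] = list(self.resolution_range)
        d["map_shape"] = list(self.map_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        d["resolution_range"] = tuple(d["resolution_range"])
        d["map_shape"] = tuple(d["map_shape"])
        return cls(**d)


@dataclasses.dataclass
class FixtureItem:
    atoms: AtomSet
    resolution: float
    clean: DensityGrid           # Gaussian forward-model target
    degraded: DensityGrid        # blurred + noisy "experimental" input


@dataclasses.dataclass
class FixtureSet:
    spec: FixtureSpec
    items: list[FixtureItem]
    train_idx: list[int]
    val_idx: list[int]

    def manifest(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "resolutions": [it.resolution for it in self.items],
            "train_idx": self.train_idx,
            "val_idx": self.val_idx,
        }


_ELEMENTS = [("C", 6), ("N", 7), ("O", 8)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_toy_structure(spec: FixtureSpec, rng: np.random.Generator) -> AtomSet:
    """Generate a heavy-atom pseudo-structure inside the map's bounding box.

    Helix-like traces follow a spiral with 1.5 Å rise and 100° turn per
    atom (consecutive atoms at bond-like 1.4-1.6 Å separation); coils are
    persistent random walks with 1.5 Å steps; blobs are Gaussian clusters.
    """
    n = spec.n_atoms
    if n < 1:
        raise ValueError("need at least one atom")
    if spec.style == "helix":
        radius, rise, turn = 0.25, 1.5, math.radians(100.0)
        # traces longer than the box fold into a 2D raster of antiparallel
        # segments, emulating a compact bundle that fills the volume
        fit = min(spec.map_shape) * spec.spacing - 16.0
        per_seg = max(2, int(fit / rise))
        n_seg = -(-n // per_seg)
        m = max(1, int(math.ceil(math.sqrt(n_seg))))
        i = np.arange(n)
        seg = i // per_seg
        j = np.where(seg % 2 == 0, i % per_seg, per_seg - 1 - (i % per_seg))
        pts = np.column_stack([radius * np.cos(i * turn) + 6.0 * (seg % m),
                               radius * np.sin(i * turn) + 6.0 * (seg // m),
                               rise * (j - (min(n, per_seg) - 1) / 2)])
        pts = pts @ _random_rotation(rng).T
    elif spec.style == "coil":
        steps = rng.standard_normal((n, 3))
        # persistence: blend each step with the previous direction
        for i in range(1, n):
            steps[i] = 0.7 * steps[i - 1] + 0.3 * steps[i]
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pts = np.cumsum(1.5 * steps, axis=0)
        pts -= pts.mean(axis=0)
    else:   # blob
        extent = min(spec.map_shape) * spec.spacing
        pts = rng.standard_normal((n, 3)) * (extent / 8.0)
    # centre in the box and clamp inside with a 6 A margin
    extents = (np.array(spec.map_shape, dtype=float)[::-1] - 1) * spec.spacing
    center = extents / 2.0
    pts = pts - pts.mean(axis=0) + center
    pts = np.clip(pts, 6.0, extents - 6.0)
    elements, zs = zip(*(_ELEMENTS[i % 3] for i in range(n)))
    return AtomSet(np.array(elements, dtype=object), np.array(zs), pts,
                   np.array(["A"] * n, dtype=object), np.arange(1, n + 1))


def degrade_map(clean: DensityGrid, spec: FixtureSpec,
                rng: np.random.Generator,
                resolution: float | None = None) -> DensityGrid:
    """Turn a clean forward-model map into a noisy pseudo-experimental map.

    The clean map is normalised to 0-1, optionally blurred with a
    Gaussian whose width grows with the nominal resolution (sigma = R/6),
    and perturbed with i.i.d. Gaussian noise of the spec's SD.
    """
    vmax = float(clean.values.max())
    vals = clean.values / vmax if vmax > 0 else clean.values.astype(np.float64)
    if spec.blur:
        r = resolution if resolution is not None else spec.resolution_range[0]
        sigma_vox = (r / 6.0) / spec.spacing
        vals = ndimage.gaussian_filter(vals.astype(np.float64), sigma_vox)
    if spec.noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return clean.copy_with(np.asarray(vals, dtype=np.float32))


def pure_noise_grid(spec: FixtureSpec, rng: np.random.Generator) -> DensityGrid:
    """Gaussian white noise (SD 1/6) on an otherwise empty grid."""
    vals = rng.normal(0.0, spec.noise_sd, size=spec.map_shape)
    return DensityGrid(vals.astype(np.float32), np.full(3, spec.spacing),
                       np.zeros(3))


def build_fixture_set(spec: FixtureSpec,
                      out_dir=None) -> FixtureSet:
    """Build the paired (degraded input, clean target) dataset.

    Per-item randomness is derived from the spec seed, so rebuilding from
    a manifest's spec reproduces every map exactly.  The last ``n_val``
    items form the validation/held-out split.
    """
    items: list[FixtureItem] = []
    for i in range(spec.n_structures):
        rng = np.random.default_rng([spec.seed, i])
        atoms = make_toy_structure(spec, rng)
        resolution = float(rng.uniform(*spec.resolution_range))
        template = DensityGrid(np.zeros(spec.map_shape, dtype=np.float32),
                               np.full(3, spec.spacing), np.zeros(3))
        clean = simulate_map(atoms, resolution, template)
        degraded = degrade_map(clean, spec, rng, resolution)
        items.append(FixtureItem(atoms, resolution, clean, degraded))
    idx = list(range(spec.n_structures))
    n_val = min(spec.n_val, spec.n_structures - 1)
    fs = FixtureSet(spec, items, idx[:len(idx) - n_val], idx[len(idx) - n_val:])
    if out_dir is not None:
        _write_fixture_set(fs, pathlib.Path(out_dir))
    return fs


def training_pairs(fs: FixtureSet, indices: list[int], box: int = 32,
                   stride: int = 32, max_per_map: int | None = None,
                   rng: np.random.Generator | None = None):
    """Raw training pairs from fixture maps, preprocessed as real maps are.

    Each degraded map is clipped and globally normalised (the same
    pipeline inference applies) and chunked jointly with its clean
    forward-model target; optionally at most ``max_per_map`` pairs are
    kept per map (random but seeded subsample).
    """
    from .chunking import extract_training_pairs
    from .grid import clip_negative, normalize_global
    pairs = []
    for i in indices:
        it = fs.items[i]
        exp_n, _ = normalize_global(clip_negative(it.degraded))
        ps = extract_training_pairs(exp_n, it.clean, box=box, stride=stride)
        if max_per_map is not None and len(ps) > max_per_map:
            if rng is None:
                rng = np.random.default_rng(fs.spec.seed)
            keep = rng.choice(len(ps), size=max_per_map, replace=False)
            ps = [ps[k] for k in sorted(keep)]
        pairs.extend(ps)
    return pairs


def _write_fixture_set(fs: FixtureSet, out_dir: pathlib.Path) -> None:
    from .grid import write_map
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, it in enumerate(fs.items):
        write_map(it.clean, out_dir / f"fixture_{i:03d}_clean.mrc")
        write_map(it.degraded, out_dir / f"fixture_{i:03d}_degraded.mrc")
        _write_pdb(it.atoms, out_dir / f"fixture_{i:03d}.pdb")
    (out_dir / "manifest.json").write_text(json.dumps(fs.manifest(), indent=2))


def _write_pdb(atoms: AtomSet, path: pathlib.Path) -> None:
    lines = []
    for i in range(len(atoms)):
        e = atoms.elements[i]
        x, y, z = atoms.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {e:<3s} GLY {atoms.chains[i]:1s}"
            f"{atoms.residues[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {e:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
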