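"""Map-quality metrics: Fourier shell correlation, threshold resolution,
real-space correlations and local correlation maps.

These are self-contained proxies for the usual phenix map/model metrics:
the model map is the Gaussian forward model rather than an electron
scattering-factor map, so numerical parity with phenix is not claimed.
All FSC values here are unmasked.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .grid import DensityGrid, near_atom_mask
from .structure import AtomSet, simulate_map

__all__ = ["FscCurve", "FscResolution", "CcReport", "fsc",
           "fsc_threshold_resolution", "map_model_fsc", "cc_suite",
           "local_correlation_map"]


@dataclasses.dataclass
class FscCurve:
    """Per-shell correlation versus spatial frequency (cycles/Angstrom)."""

    freqs: np.ndarray           # shell centre frequencies, 1/A, increasing
    fsc: np.ndarray             # correlation per shell
    n_voxels: np.ndarray        # Fourier voxels per shell
    nyquist: float              # 1/(2 * spacing), 1/A


@dataclasses.dataclass
class FscResolution:
    resolution: float           # Angstrom
    crossed: bool               # False when the curve never falls below


@dataclasses.dataclass
class CcReport:
    cc_box: float
    cc_mask: float
    cc_peaks: float
    mask_voxels: int


def fsc(map_a: DensityGrid, map_b: DensityGrid) -> FscCurve:
    """Unmasked Fourier shell correlation between two volumes.

    Shells are one Fourier voxel wide; frequencies are physical
    (cycles/Angstrom) using the voxel spacing.
    """
    if not map_a.same_geometry(map_b):
        raise ValueError("maps must share shape, spacing and origin")
    fa = np.fft.fftn(map_a.values.astype(np.float64))
    fb = np.fft.fftn(map_b.values.astype(np.float64))
    freqs = [np.fft.fftfreq(n, d=s)
             for n, s in zip(map_a.shape, map_a.spacing)]
    qz, qy, qx = np.meshgrid(*freqs, indexing="ij")
    q = np.sqrt(qz ** 2 + qy ** 2 + qx ** 2)
    # shell width: one Fourier voxel of the largest extent
    df = 1.0 / max(n * s for n, s in zip(map_a.shape, map_a.spacing))
    shell = np.rint(q / df).astype(np.int64).ravel()
    nshell = shell.max() + 1
    num = np.bincount(shell, weights=(fa * np.conj(fb)).real.ravel(),
                      minlength=nshell)
    da = np.bincount(shell, weights=np.abs(fa.ravel()) ** 2, minlength=nshell)
    db = np.bincount(shell, weights=np.abs(fb.ravel()) ** 2, minlength=nshell)
    counts = np.bincount(shell, minlength=nshell)
    nyq = float(min(1.0 / (2.0 * s) for s in map_a.spacing))
    keep = (counts > 0) & (np.arange(nshell) * df <= nyq + 0.5 * df)
    denom = np.sqrt(da[keep] * db[keep])
    vals = np.divide(num[keep], denom, out=np.zeros_like(denom),
                     where=denom > 0)
    return FscCurve(np.arange(nshell)[keep] * df, vals, counts[keep], nyq)


def fsc_threshold_resolution(curve: FscCurve,
                             threshold: float = 0.5) -> FscResolution:
    """Resolution at which the FSC first falls to ``threshold``.

    The crossing is located by linear interpolation between adjacent
    shells (DC shell excluded); when the curve never drops below the
    threshold the Nyquist resolution is returned with ``crossed=False``.
    """
    freqs, vals = curve.freqs, curve.fsc
    if len(freqs) == 0:
        raise ValueError("empty FSC curve")
    nonzero = freqs > 0
    freqs, vals = freqs[nonzero], vals[nonzero]
    for i, v in enumerate(vals):
        if v < threshold:
            if i == 0:
                return FscResolution(1.0 / freqs[0], True)
            f1, f2 = freqs[i - 1], freqs[i]
            v1, v2 = vals[i - 1], vals[i]
            f = f1 + (f2 - f1) * (v1 - threshold) / (v1 - v2)
            return FscResolution(1.0 / f, True)
    return FscResolution(1.0 / curve.nyquist, False)


def map_model_fsc(map_in: DensityGrid, atoms: AtomSet,
                  resolution: float) -> FscCurve:
    """FSC between a map and the Gaussian forward model of a structure."""
    return fsc(map_in, simulate_map(atoms, resolution, map_in))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac * ac).sum() * (bc * bc).sum())
    if denom == 0:
        return 0.0
    return float((ac * bc).sum() / denom)


def _top_v_mask(values: np.ndarray, v: int) -> np.ndarray:
    """Mask of the V highest voxels; ties at the V-th value all included."""
    flat = values.ravel()
    thresh = np.partition(flat, flat.size - v)[flat.size - v]
    return values >= thresh


def cc_suite(map_in: DensityGrid, model_map: DensityGrid, atoms: AtomSet,
             mask_radius: float = 3.0) -> CcReport:
    """Real-space correlations: whole box, atom mask, and density peaks.

    ``cc_peaks`` correlates the union of each map's top-V voxels, with V
    equal to the mask voxel count.
    """
    if not map_in.same_geometry(model_map):
        raise ValueError("maps must share geometry")
    mask = near_atom_mask(map_in, atoms.coords, mask_radius)
    v = int(mask.sum())
    if v == 0:
        raise ValueError("empty atom mask")
    peaks = _top_v_mask(map_in.values, v) | _top_v_mask(model_map.values, v)
    return CcReport(
        cc_box=_pearson(map_in.values, model_map.values),
        cc_mask=_pearson(map_in.values[mask], model_map.values[mask]),
        cc_peaks=_pearson(map_in.values[peaks], model_map.values[peaks]),
        mask_voxels=v)


def local_correlation_map(map_a: DensityGrid, map_b: DensityGrid,
                          box: int = 7) -> tuple[DensityGrid, np.ndarray]:
    """Voxel-wise Pearson correlation over box^3 neighbourhoods.

    The correlation is computed for every voxel of ``map_a`` with a
    positive density value whose full neighbourhood fits inside the map;
    other voxels carry the sentinel 0 and are marked invalid in the
    returned boolean mask.
    """
    if box % 2 == 0:
        raise ValueError("box must be odd")
    if any(box > n for n in map_a.shape):
        raise ValueError("box larger than the map")
    if not map_a.same_geometry(map_b):
        raise ValueError("maps must share geometry")
    a = map_a.values.astype(np.float64)
    b = map_b.values.astype(np.float64)
    size = box

    def boxmean(x):
        return ndimage.uniform_filter(x, size=size, mode="constant")

    ma, mb = boxmean(a), boxmean(b)
    cov = boxmean(a * b) - ma * mb
    va = boxmean(a * a) - ma * ma
    vb = boxmean(b * b) - mb * mb
    denom = np.sqrt(np.maximum(va, 0) * np.maximum(vb, 0))
    corr = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 1e-30)
    m = box // 2
    valid = np.zeros(map_a.shape, dtype=bool)
    valid[m:-m or None, m:-m or None, m:-m or None] = True
    valid &= map_a.values > 0
    out = np.where(valid, corr, 0.0).astype(np.float32)
    return map_a.copy_with(out), valid
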