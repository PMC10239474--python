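"""FSC curves, threshold resolution, real-space correlations, local maps."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from cryopolish.grid import DensityGrid
from cryopolish.metrics import (FscCurve, cc_suite, fsc,
                                fsc_threshold_resolution,
                                local_correlation_map, map_model_fsc)
from cryopolish.structure import AtomSet, simulate_map


def _grid(vals, spacing=1.0):
    return DensityGrid(np.asarray(vals, dtype=np.float32), spacing, 0.0)


def direct_dft_fsc(a, b, spacing=1.0):
    """O(N^6) direct-transform FSC oracle for tiny volumes."""
    n = a.shape[0]
    idx = np.arange(n)
    fa = np.zeros((n, n, n), dtype=complex)
    fb = np.zeros((n, n, n), dtype=complex)
    for kz, ky, kx in itertools.product(range(n), repeat=3):
        phase = np.exp(-2j * np.pi * (
            kz * idx[:, None, None] + ky * idx[None, :, None]
            + kx * idx[None, None, :]) / n)
        fa[kz, ky, kx] = (a * phase).sum()
        fb[kz, ky, kx] = (b * phase).sum()
    freqs = np.fft.fftfreq(n, d=spacing)
    qz, qy, qx = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    q = np.sqrt(qz ** 2 + qy ** 2 + qx ** 2)
    df = 1.0 / (n * spacing)
    shell = np.rint(q / df).astype(int)
    out = {}
    for s in np.unique(shell):
        m = shell == s
        num = (fa[m] * np.conj(fb[m])).real.sum()
        den = np.sqrt((np.abs(fa[m]) ** 2).sum() * (np.abs(fb[m]) ** 2).sum())
        out[s] = num / den if den > 0 else 0.0
    return out, df


class TestFsc:
    def test_self_correlation_is_one(self, small_grid):
        curve = fsc(small_grid, small_grid)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_scale_invariance(self, small_grid):
        doubled = small_grid.copy_with(small_grid.values * 2.0)
        curve = fsc(small_grid, doubled)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-9)

    def test_symmetry(self, rng):
        a = _grid(rng.random((12, 12, 12)))
        b = _grid(rng.random((12, 12, 12)))
        ab, ba = fsc(a, b), fsc(b, a)
        np.testing.assert_array_equal(ab.fsc, ba.fsc)

    def test_matches_direct_dft_oracle(self, rng):
        a = rng.random((8, 8, 8))
        b = rng.random((8, 8, 8))
        curve = fsc(_grid(a), _grid(b))
        oracle, df = direct_dft_fsc(a, b)
        for f, v in zip(curve.freqs, curve.fsc):
            s = int(round(f / df))
            assert v == pytest.approx(oracle[s], abs=1e-6)

    def test_parseval(self, rng):
        a = rng.random((10, 10, 10))
        fa = np.fft.fftn(a)
        assert (np.abs(fa) ** 2).sum() == pytest.approx(
            a.size * (a ** 2).sum(), rel=1e-9)

    def test_geometry_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fsc(_grid(rng.random((8, 8, 8))),
                _grid(rng.random((8, 8, 8)), spacing=2.0))


class TestThresholdResolution:
    def test_interpolated_crossing(self):
        curve = FscCurve(freqs=np.array([0.10, 0.125]),
                         fsc=np.array([0.6, 0.4]),
                         n_voxels=np.array([10, 10]), nyquist=0.5)
        r = fsc_threshold_resolution(curve, 0.5)
        assert r.crossed
        assert r.resolution == pytest.approx(1.0 / 0.1125, rel=1e-9)

    def test_never_crossing_returns_nyquist_with_flag(self):
        curve = FscCurve(freqs=np.linspace(0.01, 0.5, 20),
                         fsc=np.ones(20), n_voxels=np.ones(20), nyquist=0.5)
        r = fsc_threshold_resolution(curve)
        assert not r.crossed
        assert r.resolution == pytest.approx(2.0)

    def test_stronger_degradation_worsens_resolution(self, toy_atoms):
        # FSC is per-shell normalised, so isotropic blur alone cannot move
        # it; blur in the presence of fixed noise lowers per-shell SNR and
        # must monotonically worsen the threshold resolution
        rng = np.random.default_rng(3)
        template = _grid(np.zeros((32, 32, 32)))
        clean = simulate_map(toy_atoms, 3.0, template)
        noise = rng.normal(0, 0.05 * clean.values.max(), clean.shape)
        res = []
        for sigma in (0.0, 0.8, 1.6, 2.4):
            sig = ndimage.gaussian_filter(clean.values.astype(float), sigma) \
                if sigma else clean.values.astype(float)
            degraded = clean.copy_with((sig + noise).astype(np.float32))
            r = fsc_threshold_resolution(fsc(degraded, clean))
            res.append(r.resolution)
        assert np.all(np.diff(res) > 0)

    def test_empty_curve_rejected(self):
        curve = FscCurve(np.array([]), np.array([]), np.array([]), 0.5)
        with pytest.raises(ValueError):
            fsc_threshold_resolution(curve)


class TestMapModelFsc:
    def test_simulated_map_self_consistency(self, toy_atoms):
        template = _grid(np.zeros((24, 24, 24)))
        sim = simulate_map(toy_atoms, 4.0, template)
        curve = map_model_fsc(sim, toy_atoms, 4.0)
        np.testing.assert_allclose(curve.fsc, 1.0, atol=1e-6)

    def test_noise_decorrelates_high_frequencies(self, toy_atoms, rng):
        template = _grid(np.zeros((24, 24, 24)))
        sim = simulate_map(toy_atoms, 4.0, template)
        noisy = sim.copy_with(sim.values
                              + rng.normal(0, 0.05, sim.shape).astype(np.float32))
        curve = map_model_fsc(noisy, toy_atoms, 4.0)
        lo = curve.fsc[(curve.freqs > 0) & (curve.freqs < 0.1)].mean()
        hi = curve.fsc[curve.freqs > 0.35].mean()
        assert hi < lo

    def test_support_mask_denoiser_improves_noisy_fsc05(self, toy_atoms, rng):
        # any per-shell (linear, isotropic) filter leaves FSC unchanged;
        # real-space solvent suppression — the mechanism the enhancement
        # network learns — genuinely improves it.  Oracle: zero the map
        # outside the known atomic envelope.
        from cryopolish.grid import segment_near_atoms
        template = _grid(np.zeros((32, 32, 32)))
        sim = simulate_map(toy_atoms, 3.5, template)
        scaled = sim.values / sim.values.max()
        noise = rng.normal(0, 1 / 6, sim.shape)
        noisy = sim.copy_with((scaled + noise).astype(np.float32))
        denoised = segment_near_atoms(noisy, toy_atoms, cutoff=4.0)
        r_noisy = fsc_threshold_resolution(map_model_fsc(noisy, toy_atoms, 3.5))
        r_den = fsc_threshold_resolution(map_model_fsc(denoised, toy_atoms, 3.5))
        assert r_den.resolution < r_noisy.resolution


def hand_pearson(a, b):
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    am, bm = a - a.mean(), b - b.mean()
    return (am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum())


class TestCcSuite:
    def test_identical_maps_all_one(self, toy_atoms):
        template = _grid(np.zeros((24, 24, 24)))
        sim = simulate_map(toy_atoms, 4.0, template)
        rep = cc_suite(sim, sim, toy_atoms)
        assert rep.cc_box == pytest.approx(1.0)
        assert rep.cc_mask == pytest.approx(1.0)
        assert rep.cc_peaks == pytest.approx(1.0)

    def test_negated_map_all_minus_one(self, toy_atoms):
        template = _grid(np.zeros((24, 24, 24)))
        sim = simulate_map(toy_atoms, 4.0, template)
        neg = sim.copy_with(-sim.values)
        rep = cc_suite(sim, neg, toy_atoms)
        for v in (rep.cc_box, rep.cc_mask, rep.cc_peaks):
            assert v == pytest.approx(-1.0)

    def test_small_toy_pair_matches_hand_pearson(self, rng):
        atoms = AtomSet(["C", "O"], [6, 8],
                        [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], ["A", "A"], [1, 2])
        ga = _grid(rng.random((4, 4, 4)))
        gb = _grid(rng.random((4, 4, 4)))
        a, b = ga.values, gb.values   # float32-stored values feed the oracle
        rep = cc_suite(ga, gb, atoms, mask_radius=1.2)
        assert rep.cc_box == pytest.approx(hand_pearson(a, b), rel=1e-9)
        from cryopolish.grid import near_atom_mask
        mask = near_atom_mask(ga, atoms.coords, 1.2)
        assert rep.mask_voxels == mask.sum()
        assert rep.cc_mask == pytest.approx(hand_pearson(a[mask], b[mask]),
                                            rel=1e-9)
        v = rep.mask_voxels
        ta = a >= np.partition(a.ravel(), a.size - v)[a.size - v]
        tb = b >= np.partition(b.ravel(), b.size - v)[b.size - v]
        peaks = ta | tb
        assert rep.cc_peaks == pytest.approx(
            hand_pearson(a[peaks], b[peaks]), rel=1e-9)

    def test_scale_invariance_of_cc_box(self, toy_atoms, rng):
        a = _grid(rng.random((24, 24, 24)) + 0.2)
        scaled = a.copy_with(a.values * 17.0)
        rep = cc_suite(a, scaled, toy_atoms)
        assert rep.cc_box == pytest.approx(1.0)


class TestLocalCorrelation:
    def test_identical_maps_give_one_on_valid_voxels(self, small_grid):
        corr, valid = local_correlation_map(small_grid, small_grid)
        assert valid.any()
        np.testing.assert_allclose(corr.values[valid], 1.0, atol=1e-6)

    def test_constant_offset_invariance(self, small_grid):
        shifted = small_grid.copy_with(small_grid.values + 5.0)
        corr, valid = local_correlation_map(small_grid, shifted)
        np.testing.assert_allclose(corr.values[valid], 1.0, atol=1e-6)

    def test_matches_brute_force_pearson(self, rng):
        a = _grid(rng.random((16, 16, 16)) + 0.1)
        b = _grid(rng.random((16, 16, 16)))
        corr, valid = local_correlation_map(a, b, box=7)
        for (z, y, x) in [(8, 8, 8), (5, 9, 7), (10, 4, 11)]:
            assert valid[z, y, x]
            wa = a.values[z - 3:z + 4, y - 3:y + 4, x - 3:x + 4]
            wb = b.values[z - 3:z + 4, y - 3:y + 4, x - 3:x + 4]
            assert corr.values[z, y, x] == pytest.approx(
                hand_pearson(wa, wb), abs=1e-6)

    def test_nonpositive_and_border_voxels_invalid(self, rng):
        vals = rng.random((12, 12, 12)).astype(np.float32)
        vals[6, 6, 6] = 0.0
        a = _grid(vals)
        corr, valid = local_correlation_map(a, a)
        assert not valid[6, 6, 6] and corr.values[6, 6, 6] == 0
        assert not valid[0].any()   # border slab has no full neighbourhood

    def test_even_box_rejected(self, small_grid):
        with pytest.raises(ValueError):
            local_correlation_map(small_grid, small_grid, box=6)
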