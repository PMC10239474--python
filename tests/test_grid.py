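"""Volume I/O, regridding, normalisation and geometry operations."""

import gemmi
import numpy as np
import pytest

from cryopolish.grid import (DensityGrid, average_half_maps, clip_negative,
                             normalize_global, read_map, resample_to_spacing,
                             segment_near_atoms, write_map)


class TestMapIO:
    def test_round_trip_preserves_values_and_geometry(self, small_grid, tmp_path):
        small_grid.origin[:] = (3.0, -2.0, 1.5)
        p = tmp_path / "a.mrc"
        write_map(small_grid, p)
        back = read_map(p)
        np.testing.assert_allclose(back.values, small_grid.values, rtol=1e-6)
        np.testing.assert_allclose(back.spacing, small_grid.spacing)
        np.testing.assert_allclose(back.origin, small_grid.origin, atol=1e-5)

    def test_permuted_axis_header_reads_same_physical_field(self, tmp_path):
        """The same field stored with two axis-order headers must
        canonicalise to identical arrays."""
        rng = np.random.default_rng(0)
        field = rng.random((4, 5, 6)).astype(np.float32)   # (z, y, x)

        def write_with_axes(path, mapc, mapr, maps):
            # header-construction oracle: permute the data to the claimed
            # file axis order and fix the axis-order and sampling words
            order = [mapc - 1, mapr - 1, maps - 1]          # file axis -> xyz
            xyz = field.transpose(2, 1, 0)                   # (x, y, z)
            g = gemmi.FloatGrid(*[xyz.shape[o] for o in order])
            np.array(g, copy=False)[:] = np.transpose(xyz, order)
            cell = [xyz.shape[0] * 1.0, xyz.shape[1] * 1.0, xyz.shape[2] * 1.0]
            g.set_unit_cell(gemmi.UnitCell(*cell, 90, 90, 90))
            m = gemmi.Ccp4Map()
            m.grid = g
            m.update_ccp4_header()
            for i, v in enumerate((mapc, mapr, maps)):
                m.set_header_i32(17 + i, v)
            for i in range(3):                               # MX, MY, MZ
                m.set_header_i32(8 + i, xyz.shape[i])
            for i in range(3):                               # cell lengths
                m.set_header_float(11 + i, cell[i])
            m.write_ccp4_map(str(path))

        a = tmp_path / "xyz.mrc"
        b = tmp_path / "zyx.mrc"
        write_with_axes(a, 1, 2, 3)
        write_with_axes(b, 3, 2, 1)
        ga, gb = read_map(a), read_map(b)
        np.testing.assert_allclose(ga.values, field, rtol=1e-6)
        np.testing.assert_array_equal(ga.values, gb.values)
        np.testing.assert_allclose(ga.spacing, gb.spacing)

    def test_non_orthogonal_cell_rejected(self, tmp_path):
        g = gemmi.FloatGrid(4, 4, 4)
        g.set_unit_cell(gemmi.UnitCell(4, 4, 4, 90, 90, 120))
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        p = tmp_path / "skew.mrc"
        m.write_ccp4_map(str(p))
        with pytest.raises(ValueError, match="non-orthogonal"):
            read_map(p)


class TestResample:
    def test_constant_map_stays_constant(self):
        g = DensityGrid(np.full((10, 10, 10), 3.25, np.float32), 0.8, 0.0)
        out = resample_to_spacing(g, 1.0)
        np.testing.assert_allclose(out.values, 3.25, rtol=1e-6)

    def test_linear_ramp_exact_at_interior(self):
        # cubic interpolation is exact on polynomials of degree <= 3; the
        # spline boundary influence decays geometrically, so points well
        # inside the support reproduce the ramp to float precision
        n, s = 41, 0.8
        x = np.arange(n) * s
        vals = np.broadcast_to(x, (n, n, n)).astype(np.float64)
        g = DensityGrid(vals.copy(), s, 0.0)
        out = resample_to_spacing(g, 1.0)
        xs = np.arange(out.shape[2]) * 1.0
        interior = slice(10, -10)
        expected = np.broadcast_to(xs, out.shape)
        np.testing.assert_allclose(out.values[interior, interior, interior],
                                   expected[interior, interior, interior],
                                   rtol=1e-6, atol=1e-6)

    def test_extent_arithmetic(self):
        # ~48 A extent at 0.65 A spacing resamples to ~48 voxels at 1.0 A
        n = int(round(48 / 0.65)) + 1
        g = DensityGrid(np.zeros((n, n, n), np.float32), 0.65, 0.0)
        out = resample_to_spacing(g, 1.0)
        assert out.shape == (49, 49, 49)

    def test_round_trip_smooth_field(self, small_grid):
        down = resample_to_spacing(small_grid, 0.8)
        back = resample_to_spacing(down, 1.0)
        i = slice(3, 13)
        orig = small_grid.values[i, i, i]
        np.testing.assert_allclose(back.values[i, i, i], orig,
                                   atol=1e-3 * np.abs(orig).max())

    def test_invalid_target_rejected(self, small_grid):
        with pytest.raises(ValueError):
            resample_to_spacing(small_grid, -1.0)


class TestClipNormalize:
    def test_clip_zeroes_negatives_only(self, rng):
        vals = rng.normal(0, 1, (8, 8, 8)).astype(np.float32)
        g = DensityGrid(vals, 1.0, 0.0)
        out = clip_negative(g)
        assert out.values.min() >= 0
        np.testing.assert_allclose(out.values.sum(),
                                   vals[vals > 0].sum(), rtol=1e-5)
        # all-positive map unchanged
        pos = clip_negative(DensityGrid(np.abs(vals) + 0.1, 1.0, 0.0))
        np.testing.assert_array_equal(pos.values, np.abs(vals) + 0.1)

    def test_normalize_uses_high_percentile(self):
        vals = np.linspace(0, 10.0, 9 ** 3).reshape(9, 9, 9).astype(np.float32)
        g = DensityGrid(vals, 1.0, 0.0)
        out, rec = normalize_global(g)
        expected = np.percentile(vals, 99.999)
        assert rec.scale == pytest.approx(expected)
        assert out.values.max() == pytest.approx(10.0 / expected, rel=1e-6)

    def test_normalize_idempotent_at_unit_scale(self):
        vals = np.linspace(0, 1.0, 5 ** 3).reshape(5, 5, 5)
        # force the percentile to be exactly 1 by a constant map at 1
        g = DensityGrid(np.ones((5, 5, 5), np.float32), 1.0, 0.0)
        out, rec = normalize_global(g)
        assert rec.scale == 1.0
        np.testing.assert_array_equal(out.values, g.values)

    def test_normalize_then_rescale_recovers_input(self, small_grid):
        out, rec = normalize_global(small_grid)
        np.testing.assert_allclose(out.values * rec.scale, small_grid.values,
                                   rtol=1e-6)

    def test_all_zero_map_rejected(self):
        g = DensityGrid(np.zeros((4, 4, 4), np.float32), 1.0, 0.0)
        with pytest.raises(ValueError):
            normalize_global(g)


class TestHalfMaps:
    def test_average_matches_elementwise_mean(self, rng):
        a = DensityGrid(rng.random((6, 6, 6)).astype(np.float32), 1.0, 0.0)
        b = DensityGrid(rng.random((6, 6, 6)).astype(np.float32), 1.0, 0.0)
        out = average_half_maps(a, b)
        np.testing.assert_allclose(out.values, (a.values + b.values) / 2,
                                   rtol=1e-6)
        same = average_half_maps(a, a)
        np.testing.assert_allclose(same.values, a.values, rtol=1e-7)
        neg = average_half_maps(a, a.copy_with(-a.values))
        np.testing.assert_allclose(neg.values, 0.0, atol=1e-7)

    def test_geometry_mismatch_rejected(self, rng):
        a = DensityGrid(rng.random((6, 6, 6)).astype(np.float32), 1.0, 0.0)
        b = DensityGrid(rng.random((6, 6, 6)).astype(np.float32), 1.1, 0.0)
        with pytest.raises(ValueError):
            average_half_maps(a, b)


class TestSegmentNearAtoms:
    def test_matches_brute_force_distances(self, toy_atoms):
        g = DensityGrid(np.ones((24, 24, 24), np.float32), 1.0, 0.0)
        out = segment_near_atoms(g, toy_atoms, cutoff=4.0)
        zax, yax, xax = g.axes()
        zz, yy, xx = np.meshgrid(zax, yax, xax, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)
        d = np.min(np.linalg.norm(
            pts[..., None, :] - toy_atoms.coords[None, None, None], axis=-1),
            axis=-1)
        np.testing.assert_array_equal(out.values > 0, d <= 4.0)

    def test_huge_cutoff_keeps_everything(self, toy_atoms):
        g = DensityGrid(np.ones((24, 24, 24), np.float32), 1.0, 0.0)
        out = segment_near_atoms(g, toy_atoms, cutoff=1000.0)
        np.testing.assert_array_equal(out.values, g.values)

    def test_chain_selection_zeroes_other_chain(self):
        from cryopolish.structure import AtomSet
        atoms = AtomSet(["C", "C"], [6, 6],
                        [[4.0, 8.0, 8.0], [12.0, 8.0, 8.0]],
                        ["A", "B"], [1, 1])
        g = DensityGrid(np.ones((16, 16, 16), np.float32), 1.0, 0.0)
        out = segment_near_atoms(g, atoms, cutoff=2.0, chain="A")
        # voxel at chain B's atom position is zeroed
        assert out.values[8, 8, 12] == 0
        assert out.values[8, 8, 4] == 1
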