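"""Map rasterization, radial ray sampling, height maps, cross-reference integrity."""

import numpy as np
import pytest
from scipy import ndimage

from spheremap.ellipsoid import ReferenceEllipsoid
from spheremap.phantoms import PhantomSpec, make_spheroid_stack
from spheremap.projections import ProjectionSpec, projection_domain_mask
from spheremap.stack_io import ImageStack, VoxelSpacing
from spheremap.unfolding import (
    HeightMap,
    UnfoldOptions,
    apply_hypsometric_lut,
    build_direction_grid,
    load_crossref_table,
    sample_radial_ray,
    save_crossref_table,
    unfold_height,
    unfold_intensity,
)


def _uniform_stack(value=5.0, n=48):
    vals = np.full((1, 1, n, n, n), value, dtype=np.float32)
    return ImageStack(values=vals, axis_labels="TCZYX")


def _count_components_seam_aware(binary):
    """Connected components on a map raster, merging across the lon seam."""
    lbl, n = ndimage.label(binary)
    for r in range(binary.shape[0]):
        a, b = lbl[r, 0], lbl[r, -1]
        if a and b and a != b:
            lbl[lbl == b] = a
    return len(np.unique(lbl)) - 1


class TestDirectionGrid:
    def test_equirectangular_4x2_pixel_centers(self):
        opts = UnfoldOptions(map_width=4, map_height=2)
        phi, lam, _, mask = build_direction_grid(opts)
        assert mask.all()
        np.testing.assert_allclose(np.unique(np.round(phi, 12)), [-np.pi / 4, np.pi / 4])
        np.testing.assert_allclose(
            np.unique(np.round(lam, 12)),
            [-3 * np.pi / 4, -np.pi / 4, np.pi / 4, 3 * np.pi / 4],
        )

    def test_mask_matches_projection_domain_mask(self):
        spec = ProjectionSpec("mollweide")
        opts = UnfoldOptions(projection=spec, map_width=64, map_height=32)
        _, _, _, mask = build_direction_grid(opts)
        np.testing.assert_array_equal(mask, projection_domain_mask(spec, 64, 32))

    def test_unfold_axis_moves_pole_cap(self):
        # bright cap along +X: at the top edge for axis X, at the equator center for axis Z
        spec = PhantomSpec(shape=(64, 64, 64), semi_axes_um=(20, 20, 20), shell_thickness_um=2.0)
        stack, truth = make_spheroid_stack(spec)
        lat, lon, r = np.broadcast_arrays(
            *np.meshgrid(np.arange(64), np.arange(64), np.arange(64), indexing="ij")[:1] * 3
        )
        # carve: keep signal only within 25 deg of the +X direction
        vals = stack.values.copy()
        z, y, x = np.meshgrid(*(np.arange(64) + 0.5,) * 3, indexing="ij")
        v = np.stack([x - 32, y - 32, z - 32], axis=-1)
        ang = np.arccos(np.clip(v[..., 0] / np.linalg.norm(v, axis=-1), -1, 1))
        vals[0, 0][ang > np.deg2rad(25)] = 0
        capped = ImageStack(values=vals, axis_labels="TCZYX")
        for axis, where in (("X", "top"), ("Z", "equator")):
            opts = UnfoldOptions(map_width=72, map_height=36, unfold_axis=axis)
            m = unfold_intensity(capped, truth.ellipsoid, opts)
            img = np.nan_to_num(m.values)
            rows = np.nonzero(img > 0.5 * img.max())[0]
            if where == "top":
                assert rows.max() < 8
            else:
                assert abs(rows.mean() - 18) < 3


class TestSampleRadialRay:
    def test_uniform_stack_statistics(self):
        stack = _uniform_stack(5.0)
        e = ReferenceEllipsoid(center=(24, 24, 24), semi_axes=(12, 12, 12))
        for stat, expect_const in (("max", True), ("mean", True), ("sum", False)):
            opts = UnfoldOptions(map_width=8, map_height=4, ray_statistic=stat)
            out = sample_radial_ray(stack, e, 0.3, 1.1, opts)
            assert out is not None
            value = out[0]
            if expect_const:
                assert value == pytest.approx(5.0)
            else:
                assert value > 5.0  # sum over many samples

    def test_delta_shell_peak_radius(self):
        spec = PhantomSpec(shape=(64, 64, 64), semi_axes_um=(20, 20, 20), shell_thickness_um=1.0)
        stack, truth = make_spheroid_stack(spec)
        opts = UnfoldOptions(map_width=16, map_height=8)
        step = opts.step_um(stack.spacing)
        for lat, lon in [(0.0, 0.0), (0.7, -2.0), (-1.1, 2.5)]:
            _, r_star, _ = sample_radial_ray(stack, truth.ellipsoid, lat, lon, opts)
            assert abs(r_star - 20.0) <= step / 2 + np.sqrt(3) / 2

    def test_ray_outside_volume_returns_none(self):
        stack = _uniform_stack(1.0, n=32)
        e = ReferenceEllipsoid(center=(200.0, 200.0, 200.0), semi_axes=(5, 5, 5))
        opts = UnfoldOptions(map_width=8, map_height=4)
        assert sample_radial_ray(stack, e, 0.0, 0.0, opts) is None


class TestUnfoldIntensity:
    def test_checkerboard_tile_layout(self, checker_phantom):
        stack, truth = checker_phantom
        opts = UnfoldOptions(map_width=160, map_height=80)
        m = unfold_intensity(stack, truth.ellipsoid, opts)
        img = np.nan_to_num(m.values)
        bright = img > 0.7 * img.max()
        # per latitude band of 20 rows: 8 longitude tiles -> 4 bright segments
        for band in range(4):
            rows = bright[band * 20 + 5 : band * 20 + 15]
            segs = _count_components_seam_aware(rows)
            assert segs == 4, f"band {band}: {segs} bright segments"
        # tile boundaries fall on the analytic longitudes within 1 map pixel
        row = bright[40]
        edges = np.nonzero(np.diff(row.astype(int)) != 0)[0]
        expect = np.arange(1, 8) * 20  # every 45 deg on a 160-px equator
        for e_col in expect:
            assert np.min(np.abs(edges - e_col)) <= 1

    @pytest.mark.parametrize("n_rings", [3, 5, 9])
    def test_ring_phantoms_keep_component_count(self, n_rings):
        rng = np.random.default_rng(n_rings)
        rings = []
        while len(rings) < n_rings:
            lat = np.arcsin(rng.uniform(-0.9, 0.9))
            lon = rng.uniform(-np.pi, np.pi)
            from spheremap.phantoms import angular_distance

            if all(angular_distance(lat, lon, r[0], r[1]) > 0.75 for r in rings):
                rings.append((lat, lon, 0.25))
        spec = PhantomSpec(
            shape=(64, 64, 64), semi_axes_um=(22, 22, 22), shell_thickness_um=2.0,
            pattern=("rings", rings),
        )
        stack, truth = make_spheroid_stack(spec)
        opts = UnfoldOptions(map_width=180, map_height=90)
        m = unfold_intensity(stack, truth.ellipsoid, opts)
        img = np.nan_to_num(m.values)
        found = _count_components_seam_aware(img > 0.5 * img.max())
        assert found == n_rings

    def test_masked_count_matches_domain_mask_when_inside(self, sphere_phantom):
        stack, truth = sphere_phantom
        spec = ProjectionSpec("mollweide")
        opts = UnfoldOptions(projection=spec, map_width=80, map_height=40)
        m = unfold_intensity(stack, truth.ellipsoid, opts)
        assert m.mask.sum() == projection_domain_mask(spec, 80, 40).sum()

    def test_ellipsoid_outside_stack_raises(self):
        stack = _uniform_stack(1.0, n=32)
        e = ReferenceEllipsoid(center=(500.0, 500.0, 500.0), semi_axes=(10, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            unfold_intensity(stack, e, UnfoldOptions(map_width=16, map_height=8))

    def test_deterministic_bit_identical(self, sphere_phantom):
        stack, truth = sphere_phantom
        opts = UnfoldOptions(map_width=64, map_height=32)
        m1 = unfold_intensity(stack, truth.ellipsoid, opts)
        m2 = unfold_intensity(stack, truth.ellipsoid, opts)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.crossref.equals(m2.crossref)

    def test_crossref_integrity_nearest_max(self, sphere_phantom):
        """With nearest-voxel sampling and max statistic the table is exact."""
        stack, truth = sphere_phantom
        opts = UnfoldOptions(map_width=90, map_height=45, interpolated=False)
        m = unfold_intensity(stack, truth.ellipsoid, opts)
        tab = m.crossref
        stack_vals = stack.values[tab["t"], tab["c"], tab["z"], tab["y"], tab["x"]]
        map_vals = m.values[tab["map_y"], tab["map_x"]]
        np.testing.assert_array_equal(np.asarray(stack_vals, dtype=float), map_vals)

    def test_seam_split_feature_shares_rows(self):
        # one ring centered on the seam (lon = pi) must appear at both map edges
        spec = PhantomSpec(
            shape=(64, 64, 64), semi_axes_um=(20, 20, 20), shell_thickness_um=2.0,
            pattern=("rings", [(0.0, np.pi, 0.3)]),
        )
        stack, truth = make_spheroid_stack(spec)
        m = unfold_intensity(stack, truth.ellipsoid, UnfoldOptions(map_width=120, map_height=60))
        img = np.nan_to_num(m.values)
        bright = img > 0.5 * img.max()
        left_rows = set(np.nonzero(bright[:, 0])[0])
        right_rows = set(np.nonzero(bright[:, -1])[0])
        assert left_rows and left_rows == right_rows

    def test_equal_area_banding_uniform_shell(self, sphere_phantom):
        stack, truth = sphere_phantom
        opts = UnfoldOptions(
            projection=ProjectionSpec("lambert_cylindrical"), map_width=90, map_height=45
        )
        m = unfold_intensity(stack, truth.ellipsoid, opts)
        img = np.where(m.mask, m.values, np.nan)
        global_mean = np.nanmean(img)
        band_means = [np.nanmean(img[i : i + 9]) for i in range(0, 45, 9)]
        np.testing.assert_allclose(band_means, global_mean, rtol=0.01)

    def test_crossref_table_round_trips_as_text(self, sphere_phantom, tmp_path):
        stack, truth = sphere_phantom
        m = unfold_intensity(stack, truth.ellipsoid, UnfoldOptions(map_width=32, map_height=16))
        p = tmp_path / "xref.tsv"
        save_crossref_table(m.crossref, p)
        back = load_crossref_table(p)
        np.testing.assert_array_equal(back["z"], m.crossref["z"])
        np.testing.assert_allclose(back["r_star"], m.crossref["r_star"])


class TestHeightMap:
    def test_on_ellipsoid_shell_elevation_near_zero(self, sphere_phantom):
        stack, truth = sphere_phantom
        opts = UnfoldOptions(map_width=90, map_height=45)
        h = unfold_height(stack, truth.ellipsoid, opts)
        step = opts.step_um(stack.spacing)
        assert np.nanmax(np.abs(h.elevation[h.mask])) <= step / 2 + np.sqrt(3) / 2

    @pytest.mark.parametrize("height", [3.0, -3.0])
    def test_bump_and_indentation_recovery(self, height):
        spec = PhantomSpec(
            shape=(80, 80, 80), spacing=VoxelSpacing(0.75, 0.75, 0.75),
            semi_axes_um=(20, 20, 20), shell_thickness_um=1.5,
            bumps=[(0.5, 1.0, height, np.deg2rad(10))],
        )
        stack, truth = make_spheroid_stack(spec)
        opts = UnfoldOptions(map_width=120, map_height=60)
        h = unfold_height(stack, truth.ellipsoid, opts)
        step = opts.step_um(stack.spacing)
        tol = step / 2 + np.sqrt(3) * 0.75 / 2
        extreme = np.nanmax(h.elevation[h.mask]) if height > 0 else np.nanmin(h.elevation[h.mask])
        assert extreme == pytest.approx(height, abs=tol)


class TestHypsometricLut:
    def _hm(self, elev):
        elev = np.asarray(elev, dtype=float)[None, :]
        return HeightMap(elevation=elev, mask=np.isfinite(elev), options=UnfoldOptions(map_width=4, map_height=2))

    def test_all_zero_elevations_render_uniform_midpoint(self):
        rgb = apply_hypsometric_lut(self._hm([0.0, 0.0, 0.0]))
        assert len(np.unique(rgb.reshape(-1, 3), axis=0)) == 1

    def test_extremes_hit_table_endpoints_and_zero_the_midpoint(self):
        from spheremap.stack_io import get_lut

        rgb = apply_hypsometric_lut(self._hm([-3.0, 0.0, 3.0]))
        base = get_lut("hypsometric")
        np.testing.assert_array_equal(rgb[0, 0], np.round(base[0] * 255))
        np.testing.assert_array_equal(rgb[0, 2], np.round(base[-1] * 255))
        mid = apply_hypsometric_lut(self._hm([0.0]))[0, 0]
        np.testing.assert_array_equal(rgb[0, 1], mid)

    def test_override_range_confines_colors_to_center(self):
        rgb_wide = apply_hypsometric_lut(self._hm([-3.0, 3.0]), symmetric_range=10.0)
        rgb_full = apply_hypsometric_lut(self._hm([-10.0, 10.0]), symmetric_range=10.0)
        # +-3 in a +-10 range stays inside the central 30% of the table, so
        # colors are strictly less extreme than the full-range endpoints
        assert not np.array_equal(rgb_wide[0, 0], rgb_full[0, 0])
        assert not np.array_equal(rgb_wide[0, 1], rgb_full[0, 1])

    def test_empty_mask_raises(self):
        hm = self._hm([np.nan, np.nan])
        with pytest.raises(ValueError, match="empty mask"):
            apply_hypsometric_lut(hm)
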