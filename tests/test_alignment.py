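import numpy as np
import pytest

from spavg.alignment import (
    OrientationError,
    PoleAxisAmbiguousError,
    accumulate_map,
    assign_mother,
    extract_aligned_plane,
    orient_plane,
    particle_frame,
    register_maps,
    Particle,
    ProbabilityMap,
)
from spavg.detection import fit_gaussian_1d
from spavg.fit3d import fit_dual_spot, fit_single_spot
from spavg.io_volumes import SeedPair, Volume
from spavg.mapstats import axis_profile, fit_profile
from spavg.synthetic import make_scene, render_scene, generate_dataset
from tests.conftest import seedpair_from_truth


def trilinear_oracle(data3d, z, y, x):
    """Independent trilinear interpolation at one fractional voxel coordinate."""
    z0, y0, x0 = int(np.floor(z)), int(np.floor(y)), int(np.floor(x))
    fz, fy, fx = z - z0, y - y0, x - x0
    total = 0.0
    for dz_ in (0, 1):
        for dy_ in (0, 1):
            for dx_ in (0, 1):
                zz, yy, xx = z0 + dz_, y0 + dy_, x0 + dx_
                if not (0 <= zz < data3d.shape[0] and 0 <= yy < data3d.shape[1] and 0 <= xx < data3d.shape[2]):
                    continue
                w = (fz if dz_ else 1 - fz) * (fy if dy_ else 1 - fy) * (fx if dx_ else 1 - fx)
                total += w * data3d[zz, yy, xx]
    return total


def fit_and_assign(spec, volume, use_reference=True):
    sp = seedpair_from_truth(spec)
    fit = fit_dual_spot(volume, sp)
    ref_center = None
    if use_reference and spec.reference_channel is not None:
        rf = fit_single_spot(volume, spec.reference_channel, sp.mother_seed)
        ref_center = np.asarray(rf.spot.center)
    return assign_mother(fit, ref_center)


class TestAssignMother:
    def test_fiducial_proximity(self, pair_scene):
        spec, volume, _, seeds = pair_scene
        fit = fit_dual_spot(volume, seeds)
        near_b = np.asarray(fit.spot_b.center) + np.array([50.0, 0.0, 0.0])
        particle = assign_mother(fit, near_b)
        assert np.allclose(particle.mother_center, fit.spot_b.center)
        assert particle.mother_rule == "fiducial-proximity"

    def test_brightness_rule(self, pair_scene):
        spec, volume, _, seeds = pair_scene
        fit = fit_dual_spot(volume, seeds)
        particle = assign_mother(fit, None)
        # mother spot (amp 100) is brighter than the satellite (100/1.9)
        assert np.allclose(particle.mother_center, fit.spot_a.center)
        assert particle.mother_rule == "brightness"

    def test_exact_tie_flags_and_uses_seed_order(self, pair_scene):
        _, volume, _, seeds = pair_scene
        fit = fit_dual_spot(volume, seeds)
        fit.spot_b.amplitude = fit.spot_a.amplitude
        particle = assign_mother(fit, None)
        assert particle.tie_flag
        assert np.allclose(particle.mother_center, fit.spot_a.center)

    def test_degenerate_fit_rejected(self, pair_scene):
        _, volume, _, seeds = pair_scene
        fit = fit_dual_spot(volume, seeds)
        fit.degenerate = True
        with pytest.raises(ValueError):
            assign_mother(fit, None)


class TestExtractAlignedPlane:
    def test_centers_land_on_horizontal_axis(self, pair_scene):
        spec, volume, _, _ = pair_scene
        particle = fit_and_assign(spec, volume)
        plane = extract_aligned_plane(volume, particle)
        d = particle.separation_nm
        r0, c0 = plane.origin
        ch = spec.fit_channel
        # sub-pixel peak positions from a two-Gaussian fit of the x profile
        band = plane.grid[ch][r0 - 15 : r0 + 16, :].mean(axis=0)
        x_nm = (np.arange(band.size) - c0) * plane.pixel_size
        from spavg.mapstats import AxisProfile, fit_profile as fp

        pf = fp(AxisProfile(x_nm, band), n_components=2, n_mc=0, window_nm=500.0)
        assert abs(pf.components[0].center - (-d / 2.0)) < plane.pixel_size / 2.0
        assert abs(pf.components[1].center - (d / 2.0)) < plane.pixel_size / 2.0

    def test_matches_trilinear_oracle(self, pair_scene):
        spec, volume, _, _ = pair_scene
        particle = fit_and_assign(spec, volume)
        plane = extract_aligned_plane(volume, particle)
        mid, u, v = particle_frame(particle)
        dz, dy, dxv = volume.voxel_size
        r0, c0 = plane.origin
        rng = np.random.default_rng(0)
        for _ in range(25):
            i = rng.integers(r0 - 40, r0 + 40)
            j = rng.integers(c0 - 40, c0 + 40)
            pos = mid + (j - c0) * plane.pixel_size * u + (i - r0) * plane.pixel_size * v
            expected = trilinear_oracle(volume.data[0], pos[2] / dz, pos[1] / dy, pos[0] / dxv)
            assert plane.grid[0][i, j] == pytest.approx(expected, abs=1e-9)

    def test_rotated_scene_consistency(self):
        # render the same particle geometry at two in-plane angles; the
        # extracted (axis-aligned) planes must agree up to interpolation error
        planes = []
        for seed in (3, 3):
            pass
        spec_a = make_scene("pair", rng_seed=6)
        volume_a, _ = render_scene(spec_a)
        # re-render with identical jitter/orientation except rotated 25 deg:
        p = spec_a.particles[0]
        u = np.asarray(p.axis_u)
        theta = np.radians(25.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0.0], [np.sin(theta), np.cos(theta), 0.0], [0.0, 0.0, 1.0]]
        )
        center = (np.asarray(p.mother_position) + np.asarray(p.distal_position)) / 2.0
        import copy

        spec_b = copy.deepcopy(spec_a)
        pb = spec_b.particles[0]
        for ch, ems in pb.emitters.items():
            for em in ems:
                em.position = tuple(center + rot @ (np.asarray(em.position) - center))
        pb.mother_position = tuple(center + rot @ (np.asarray(p.mother_position) - center))
        pb.distal_position = tuple(center + rot @ (np.asarray(p.distal_position) - center))
        pb.axis_u = tuple(rot @ u)
        volume_b, _ = render_scene(spec_b)
        for spec, volume in ((spec_a, volume_a), (spec_b, volume_b)):
            particle = fit_and_assign(spec, volume)
            planes.append(extract_aligned_plane(volume, particle))
        a, b = planes
        r0, c0 = a.origin
        wa = a.grid[0][r0 - 30 : r0 + 31, c0 - 30 : c0 + 31]
        wb = b.grid[0][r0 - 30 : r0 + 31, c0 - 30 : c0 + 31]
        nrms = np.sqrt(np.mean((wa - wb) ** 2)) / wa.max()
        assert nrms < 0.02

    def test_vertical_axis_rejected(self, pair_scene):
        spec, volume, _, _ = pair_scene
        particle = fit_and_assign(spec, volume)
        vertical = Particle(
            image_id="v",
            mother_center=np.array([1000.0, 1000.0, 0.0]),
            distal_center=np.array([1050.0, 1000.0, 500.0]),  # ~84 deg tilt
            fit=particle.fit,
        )
        with pytest.raises(PoleAxisAmbiguousError):
            extract_aligned_plane(volume, vertical)


class TestOrientPlane:
    def _oriented_plane(self, seed=13, noise=0.0):
        params = {"noise_sd": noise} if noise else None
        spec = make_scene("pair", params=params, rng_seed=seed)
        volume, _ = render_scene(spec)
        particle = fit_and_assign(spec, volume)
        return spec, extract_aligned_plane(volume, particle)

    def test_already_oriented_unchanged(self):
        spec, plane = self._oriented_plane()
        out = orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
        # mother (brighter, fiducial-marked) is already on the negative-x side
        assert not out.h_flipped
        assert np.array_equal(out.grid[1], plane.grid[1]) or out.v_flipped

    def test_idempotent(self):
        spec, plane = self._oriented_plane(seed=17)
        once = orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
        twice = orient_plane(once, spec.query_channel, reference_channel=spec.reference_channel)
        assert np.array_equal(once.grid, twice.grid)
        assert once.h_flipped == twice.h_flipped
        assert once.v_flipped == twice.v_flipped

    def test_mirrored_input_gives_same_output(self):
        spec, plane = self._oriented_plane(seed=19)
        from dataclasses import replace

        mirrored = replace(plane, grid=plane.grid[:, :, ::-1].copy(), coverage=plane.coverage[:, ::-1].copy())
        out1 = orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
        out2 = orient_plane(mirrored, spec.query_channel, reference_channel=spec.reference_channel)
        assert np.allclose(out1.grid, out2.grid)

    def test_zero_channel_is_error(self):
        spec, plane = self._oriented_plane(seed=23)
        plane.grid[spec.reference_channel][:] = 0.0
        with pytest.raises(OrientationError):
            orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)


class TestAccumulateMap:
    def _planes(self, n, noise=0.0, seed0=300):
        planes = []
        for i in range(n):
            params = {"noise_sd": noise} if noise else None
            spec = make_scene("pair", params=params, rng_seed=seed0 + i)
            volume, _ = render_scene(spec)
            particle = fit_and_assign(spec, volume)
            plane = extract_aligned_plane(volume, particle)
            planes.append(orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel))
        return planes

    def test_single_plane_identity(self):
        (plane,) = self._planes(1)
        pmap = accumulate_map([plane])
        assert np.array_equal(pmap.grid, plane.grid)
        assert pmap.n_particles == 1

    def test_linearity(self):
        (plane,) = self._planes(1)
        pmap = accumulate_map([plane, plane])
        assert np.allclose(pmap.grid, 2.0 * plane.grid)
        assert pmap.n_particles == 2

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            accumulate_map([])

    def test_mixed_pixel_size_is_error(self):
        from dataclasses import replace

        (plane,) = self._planes(1)
        other = replace(plane, pixel_size=plane.pixel_size * 2)
        with pytest.raises(ValueError, match="pixel size"):
            accumulate_map([plane, other])

    def test_17_particle_separation_recovery(self):
        planes = self._planes(17, noise=2.0, seed0=400)
        pmap = accumulate_map(planes)
        pf = fit_profile(
            axis_profile(pmap, 0, "x", perp_window_nm=300.0), n_components=2, n_mc=0, window_nm=600.0
        )
        sep = pf.components[1].center - pf.components[0].center
        assert abs(sep - 225.0) < 5.0

    def test_x_profile_symmetric_about_zero(self):
        planes = self._planes(5, noise=1.0, seed0=500)
        pmap = accumulate_map(planes)
        pf = fit_profile(
            axis_profile(pmap, 0, "x", perp_window_nm=300.0), n_components=2, n_mc=0, window_nm=600.0
        )
        c0, c1 = pf.components[0].center, pf.components[1].center
        assert abs(c0 + c1) < pmap.pixel_size  # within 1 interpolated px

    def test_averaging_sharpens(self):
        # identical particle geometry, independent noise realizations
        import copy

        base = make_scene("pair", params={"noise_sd": 3.0}, rng_seed=600)
        planes = []
        for i in range(9):
            spec = copy.deepcopy(base)
            spec.rng_seed = 600 + i  # new noise, same emitters/orientation
            volume, _ = render_scene(spec)
            particle = fit_and_assign(spec, volume)
            plane = extract_aligned_plane(volume, particle)
            planes.append(
                orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
            )

        def fwhm_of(map_):
            pf = fit_profile(
                axis_profile(map_, 1, "x", perp_window_nm=300.0), n_components=1, n_mc=0, window_nm=400.0
            )
            return pf.components[0].fwhm

        single = np.median([fwhm_of(accumulate_map([p])) for p in planes])
        averaged = fwhm_of(accumulate_map(planes))
        assert averaged <= single * 1.02

    def test_amplitude_ratio_preserved(self):
        for ratio in (1.0, 1.9, 2.8):
            planes = []
            for i in range(6):
                spec = make_scene(
                    "pair", params={"noise_sd": 1.0, "amplitude_ratio": ratio}, rng_seed=700 + i
                )
                volume, _ = render_scene(spec)
                particle = fit_and_assign(spec, volume)
                plane = extract_aligned_plane(volume, particle)
                planes.append(
                    orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
                )
            pmap = accumulate_map(planes)
            pf = fit_profile(
                axis_profile(pmap, 0, "x", perp_window_nm=300.0), n_components=2, n_mc=0, window_nm=600.0
            )
            if ratio == 1.0:
                fitted = pf.components[0].amplitude / pf.components[1].amplitude
                assert abs(fitted - ratio) / ratio < 0.1
            else:
                fitted = pf.components[0].amplitude / pf.components[1].amplitude
                assert abs(fitted - ratio) / ratio < 0.1

    def test_planted_query_offset_recovery(self):
        # plant a (12, 15) nm query offset; map profile fits recover both
        planes = []
        for i in range(20):
            spec = make_scene(
                "bent_triplet",
                params={"noise_sd": 2.0, "bend_angle_deg": 0.0, "query_offset_nm": (12.0, 15.0)},
                rng_seed=800 + i,
            )
            volume, _ = render_scene(spec)
            particle = fit_and_assign(spec, volume, use_reference=False)
            plane = extract_aligned_plane(volume, particle)
            planes.append(orient_plane(plane, 0, reference_channel=1))
        pmap = accumulate_map(planes)
        qx = fit_profile(
            axis_profile(pmap, 0, "x", perp_window_nm=300.0), n_components=1, n_mc=0, window_nm=600.0
        )
        qy = fit_profile(
            axis_profile(pmap, 0, "y", perp_window_nm=300.0), n_components=1, n_mc=0, window_nm=600.0
        )
        assert abs(qx.components[0].center - 12.0) < 3.0
        assert abs(qy.components[0].center - 15.0) < 3.0


class TestRegisterMaps:
    def _map(self, seed=900):
        spec = make_scene("pair", rng_seed=seed)
        volume, _ = render_scene(spec)
        particle = fit_and_assign(spec, volume)
        plane = extract_aligned_plane(volume, particle)
        plane = orient_plane(plane, spec.query_channel, reference_channel=spec.reference_channel)
        return accumulate_map([plane])

    def test_cocentered_maps_unchanged(self):
        m = self._map()
        out = register_maps([m, m], fiducial_channel=1)
        assert np.allclose(out[0].grid, m.grid)
        assert np.allclose(out[1].grid, m.grid, atol=1e-9)

    def test_integer_shift_restored(self):
        from dataclasses import replace

        m = self._map(seed=901)
        shifted = replace(m, grid=np.roll(m.grid, 3, axis=1))
        out = register_maps([m, shifted], fiducial_channel=1)
        r0 = m.origin[0]
        window = slice(r0 - 60, r0 + 61)
        assert np.allclose(out[1].grid[:, window, :], m.grid[:, window, :], atol=1e-6 * m.grid.max())

    def test_subpixel_shift_alignment(self):
        from dataclasses import replace
        from scipy import ndimage as ndi

        m = self._map(seed=902)
        shifted = replace(
            m, grid=np.stack([ndi.shift(m.grid[c], (1.5, 0.0), order=1) for c in range(2)])
        )
        out = register_maps([m, shifted], fiducial_channel=1)
        c_ref = fit_gaussian_1d(out[0].grid[1].mean(axis=1))[1]
        c_shift = fit_gaussian_1d(out[1].grid[1].mean(axis=1))[1]
        assert abs(c_ref - c_shift) < 0.1
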