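"""Forward projector: Siddon path lengths, Beer-Lambert, poly/mono pairing."""

import numpy as np
import pytest

from vmono import physics as P
from vmono.phantoms import (AugmentationSpec, VoxelPhantom,
                            make_cylinder_phantom, make_dataset)
from vmono.projector import (Geometry, ProjectionSet, flood_field,
                             project_mono, project_poly, siddon_raypaths,
                             simulate_pair)


def _sphere_phantom(radius_mm=10.0, voxel=0.4, n=64, material=None):
    material = material or P.tissue("water")
    half = n * voxel / 2
    ax = -half + voxel * (np.arange(n) + 0.5)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    labels = (x**2 + y**2 + z**2 <= radius_mm**2).astype(np.int16)
    return VoxelPhantom(labels, (voxel,) * 3, (-half,) * 3,
                        {0: P.tissue("air"), 1: material})


def _uniform_phantom(n=32, voxel=0.5):
    labels = np.ones((n, n, n), dtype=np.int16)
    half = n * voxel / 2
    return VoxelPhantom(labels, (voxel,) * 3, (-half,) * 3,
                        {0: P.tissue("air"), 1: P.tissue("water")})


def _ray_through_pixel(geometry, iv, iu, angle=0.0):
    """Source position and pixel position of one detector ray (lab frame)."""
    g = geometry
    a = np.radians(-angle)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    src = rot @ np.array([-g.sid_mm, 0.0, 0.0])
    u = (iu - (g.n_u - 1) / 2) * g.pixel_mm[0]
    v = (iv - (g.n_v - 1) / 2) * g.pixel_mm[1]
    pix = rot @ np.array([g.idd_mm, u, v])
    return src, pix


class TestGeometry:
    def test_default_pixel_counts(self):
        g = Geometry()
        assert (g.n_u, g.n_v) == (352, 256)
        assert g.sdd_mm == pytest.approx(624.4)

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            Geometry(sid_mm=-1.0)

    def test_projection_set_validation(self, desk_geometry):
        imgs = np.zeros((2, 64, 64), np.float32)
        with pytest.raises(ValueError):
            ProjectionSet(imgs, [0.0, 380.0], desk_geometry, "mono")
        with pytest.raises(ValueError):
            ProjectionSet(imgs, [0.0], desk_geometry, "mono")
        with pytest.raises(ValueError):
            ProjectionSet(np.zeros((2, 32, 32), np.float32), [0, 1],
                          desk_geometry, "mono")
        with pytest.raises(ValueError):
            ProjectionSet(imgs, [0, 1], desk_geometry, "polychromatic")


class TestSiddon:
    def test_central_chord_through_sphere(self, desk_geometry):
        ph = _sphere_phantom(10.0)
        paths = siddon_raypaths(ph, desk_geometry, 0.0)
        g = desk_geometry
        # exact chord of the ray through the nearest-to-axis pixel
        iu = iv = g.n_u // 2
        src, pix = _ray_through_pixel(g, iv, iu)
        d = (pix - src) / np.linalg.norm(pix - src)
        b = np.linalg.norm(np.cross(-src, d))  # impact parameter vs origin
        chord_mm = 2 * np.sqrt(100.0 - b * b)
        got_mm = paths.lengths[iv, iu, 1] * 10
        assert got_mm == pytest.approx(chord_mm, abs=0.5 * 0.4)

    def test_offset_chord_matches_formula(self, desk_geometry):
        ph = _sphere_phantom(10.0)
        g = desk_geometry
        paths = siddon_raypaths(ph, g, 0.0)
        iv = g.n_v // 2
        for iu in (40, 45):  # rays at a few mm lateral offset
            src, pix = _ray_through_pixel(g, iv, iu)
            d = (pix - src) / np.linalg.norm(pix - src)
            b = np.linalg.norm(np.cross(-src, d))
            chord_mm = 2 * np.sqrt(max(0.0, 100.0 - b * b))
            # voxel-center surface classification quantizes each of the two
            # crossings by up to half a voxel
            assert paths.lengths[iv, iu, 1] * 10 == pytest.approx(
                chord_mm, abs=0.4)

    def test_total_path_equals_grid_segment(self, desk_geometry):
        """Sum of per-material lengths equals the in-grid ray segment."""
        ph = _uniform_phantom()
        g = desk_geometry
        paths = siddon_raypaths(ph, g, 30.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            iv = int(rng.integers(0, g.n_v))
            iu = int(rng.integers(0, g.n_u))
            src, pix = _ray_through_pixel(g, iv, iu, angle=30.0)
            # independent slab clip of the segment inside the cube
            t0, t1 = 0.0, 1.0
            r = pix - src
            for ax in range(3):
                lo, hi = ph.origin[ax], ph.origin[ax] + 16.0
                if r[ax] == 0:
                    if not lo <= src[ax] <= hi:
                        t0, t1 = 1.0, 0.0
                    continue
                ta, tb = (lo - src[ax]) / r[ax], (hi - src[ax]) / r[ax]
                ta, tb = min(ta, tb), max(ta, tb)
                t0, t1 = max(t0, ta), min(t1, tb)
            expect_cm = max(0.0, t1 - t0) * np.linalg.norm(r) / 10
            assert paths.total()[iv, iu] == pytest.approx(expect_cm, rel=1e-6,
                                                          abs=1e-9)

    def test_against_dense_sampling_oracle(self, desk_geometry):
        ph = _sphere_phantom(8.0, voxel=0.5, n=48)
        g = desk_geometry
        angle = 72.0
        paths = siddon_raypaths(ph, g, angle)
        rng = np.random.default_rng(1)
        step = 0.01  # mm
        for _ in range(5):
            iv = int(rng.integers(20, 44))
            iu = int(rng.integers(20, 44))
            src, pix = _ray_through_pixel(g, iv, iu, angle=angle)
            r = pix - src
            length = np.linalg.norm(r)
            n_steps = int(length / step)
            ts = (np.arange(n_steps) + 0.5) / n_steps
            pts = src[None, :] + ts[:, None] * r[None, :]
            idx = np.floor((pts - np.array(ph.origin)) / 0.5).astype(int)
            ok = np.all((idx >= 0) & (idx < 48), axis=1)
            labels = np.zeros(n_steps, dtype=int)
            labels[ok] = ph.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            dense_cm = (labels == 1).sum() * (length / n_steps) / 10
            if dense_cm < 0.05:
                continue
            assert paths.lengths[iv, iu, 1] == pytest.approx(dense_cm, rel=0.005)

    def test_ray_missing_grid_is_zero(self, desk_geometry):
        ph = _sphere_phantom(4.0, voxel=0.2, n=32)
        paths = siddon_raypaths(ph, desk_geometry, 0.0)
        assert paths.lengths[0, 0].sum() == 0.0  # corner ray misses the grid


class TestFloodField:
    def test_mono_ideal_unity(self):
        s = P.mono_spectrum(35.0)
        assert flood_field(s, P.DetectorModel("ideal-photon-counting")) == 1.0

    def test_linearity_in_weights(self):
        s = P.imaging_spectrum()
        double = P.Spectrum(s.grid, 2 * s.weights)
        det = P.DetectorModel()
        assert flood_field(double, det) == pytest.approx(
            2 * flood_field(s, det), rel=1e-12)

    def test_matches_hand_summation(self, db):
        s = P.imaging_spectrum()
        det = P.DetectorModel()
        d = P.detector_response(s.grid, det, db)
        expect = sum(float(w) * float(di) for w, di in zip(s.weights, d))
        assert flood_field(s, det, db) == pytest.approx(expect, rel=1e-12)


class TestProjection:
    def test_empty_phantom_projects_zero(self, desk_geometry):
        labels = np.zeros((16, 16, 16), dtype=np.int16)
        ph = VoxelPhantom(labels, (0.5,) * 3, (-4.0,) * 3, {0: P.tissue("air")})
        pm = project_mono(ph, desk_geometry, 35.0, [0.0, 90.0])
        # only the ~4e-4/cm attenuation of <1 cm of air remains
        assert np.all(pm.images < 1e-3)

    def test_mono_beer_lambert_central_ray(self, desk_geometry, water_cylinder,
                                           db):
        pm = project_mono(water_cylinder, desk_geometry, 35.0, [0.0])
        g = desk_geometry
        iu = iv = g.n_u // 2
        src, pix = _ray_through_pixel(g, iv, iu)
        d = (pix - src) / np.linalg.norm(pix - src)
        b = np.linalg.norm(np.cross(-src, d))
        chord_cm = 2 * np.sqrt(25.0 - b * b) / 10
        mu = P.material_mu(P.tissue("water"), [35.0], db)[0]
        assert pm.images[0, iv, iu] == pytest.approx(mu * chord_cm, rel=0.02)

    def test_slab_additivity(self, desk_geometry):
        """Projection of two stacked slabs equals the sum of each alone."""
        def slab(i0, i1):
            labels = np.zeros((32, 32, 32), dtype=np.int16)
            labels[i0:i1] = 1
            return VoxelPhantom(labels, (0.5,) * 3, (-8.0,) * 3,
                                {0: P.tissue("air"), 1: P.tissue("water")})

        both = project_mono(slab(4, 20), desk_geometry, 35.0, [0.0])
        lower = project_mono(slab(4, 12), desk_geometry, 35.0, [0.0])
        upper = project_mono(slab(12, 20), desk_geometry, 35.0, [0.0])
        # each single-slab projection carries the air background once, so
        # their sum carries it twice; subtract one all-air projection
        air = project_mono(slab(0, 0), desk_geometry, 35.0, [0.0])
        np.testing.assert_allclose(
            both.images, lower.images + upper.images - air.images,
            rtol=1e-4, atol=2e-6)

    def test_single_bin_poly_equals_mono(self, desk_geometry, water_cylinder):
        s = P.mono_spectrum(35.0)
        pp = project_poly(water_cylinder, desk_geometry, s,
                          P.DetectorModel("ideal-photon-counting"), [0.0, 45.0])
        pm = project_mono(water_cylinder, desk_geometry, 35.0, [0.0, 45.0])
        np.testing.assert_allclose(pp.images, pm.images, rtol=1e-5, atol=1e-6)

    def test_beam_hardening_on_water_slabs(self, desk_geometry, db):
        """Effective attenuation p/L strictly decreases with water thickness,
        matching a direct spectral-summation oracle."""
        s = P.imaging_spectrum()
        det = P.DetectorModel()
        d = P.detector_response(s.grid, det, db)
        wd = s.weights * d
        mu_w = P.material_mu(P.tissue("water"), s.grid, db)
        mu_air = P.material_mu(P.tissue("air"), s.grid, db)
        n, voxel = 60, 1.5  # grid long enough for 8 cm of water
        g = desk_geometry
        iu = iv = g.n_u // 2
        ratios = []
        for t_cm in range(1, 9):
            labels = np.zeros((n, n, n), dtype=np.int16)
            k = int(t_cm * 10 / voxel)
            labels[:k] = 1
            half = n * voxel / 2
            ph = VoxelPhantom(labels, (voxel,) * 3, (-half,) * 3,
                              {0: P.tissue("air"), 1: P.tissue("water")})
            pp = project_poly(ph, g, s, det, [0.0])
            p = pp.images[0, iv, iu]
            # oracle: direct spectral sum with the exact Siddon paths
            # (water and the in-grid air background)
            lengths = siddon_raypaths(ph, g, 0.0).lengths[iv, iu]
            atten = mu_air * lengths[0] + mu_w * lengths[1]
            expect = -np.log(np.sum(wd * np.exp(-atten)) / np.sum(wd))
            assert p == pytest.approx(expect, rel=1e-5)
            ratios.append(p / lengths[1])
        assert np.all(np.diff(ratios) < 0)

    def test_conservation_p_nonnegative(self, cylinder_poly_scan):
        assert cylinder_poly_scan.images.min() > -1e-5

    def test_poisson_noise_deterministic_and_off_by_default(
            self, desk_geometry, water_cylinder):
        s = P.imaging_spectrum()
        a = project_poly(water_cylinder, desk_geometry, s, angles=[0.0],
                         noise_photons=1e4, seed=3)
        b = project_poly(water_cylinder, desk_geometry, s, angles=[0.0],
                         noise_photons=1e4, seed=3)
        clean = project_poly(water_cylinder, desk_geometry, s, angles=[0.0])
        np.testing.assert_array_equal(a.images, b.images)
        assert np.any(a.images != clean.images)
        assert np.std(a.images - clean.images) > 0


class TestSimulatePair:
    def test_pair_deterministic_and_consistent(self, desk_geometry):
        specs = make_dataset(1, 1, 1, seed=4)
        s = P.imaging_spectrum()
        for spec in specs:
            p1, m1 = simulate_pair(spec, desk_geometry, s)
            p2, m2 = simulate_pair(spec, desk_geometry, s)
            np.testing.assert_array_equal(p1.images, p2.images)
            np.testing.assert_array_equal(m1.images, m2.images)
            assert p1.kind == "poly" and m1.kind == "mono"
            assert p1.angles[0] == m1.angles[0] == spec.angle
            # poly differs from mono where the object is thick
            thick = m1.images > 0.5
            if thick.any():
                assert np.abs(p1.images[thick] - m1.images[thick]).mean() > 0.01
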