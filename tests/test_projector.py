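import numpy as np
import pytest

from bctsim.fixtures import FixtureSpec, make_cylinder_fixture, \
    make_uniform_cube
from bctsim.physics_data import Spectrum, make_spectrum, mu_lookup, \
    uniform_spectrum
from bctsim.projector import (ProjectionImage, ScanGeometry,
                              ThicknessProjection, mono_project,
                              poly_project, poly_project_per_bin,
                              relative_error_map, siddon_trace,
                              thickness_project)
from bctsim.volume import LabelVolume


class TestSiddon:
    def test_axis_aligned_chord_is_exact(self):
        cube = make_uniform_cube(n=8, voxel_mm=1.0)
        lengths = siddon_trace(cube, [-20.0, 0.0, 0.0], [20.0, 0.0, 0.0])
        assert lengths[1] == pytest.approx(8.0, abs=1e-9)
        assert lengths[0] == 0.0  # nothing traced outside the grid

    def test_main_diagonal_of_cube(self):
        cube = make_uniform_cube(n=10, voxel_mm=1.0)
        c = 10.0
        lengths = siddon_trace(cube, [-c, -c, -c], [c, c, c])
        assert lengths[1] == pytest.approx(10.0 * np.sqrt(3.0), abs=1e-9)

    def test_miss_returns_zero(self):
        cube = make_uniform_cube(n=8, voxel_mm=1.0)
        lengths = siddon_trace(cube, [-20, 30, 0], [20, 30, 0])
        assert np.all(lengths == 0)

    def test_degenerate_ray_rejected(self):
        cube = make_uniform_cube(n=4)
        with pytest.raises(ValueError):
            siddon_trace(cube, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_dense_sampling_oracle(self, rng):
        """Per-label lengths agree with brute-force uniform ray sampling."""
        labels = rng.integers(0, 4, size=(8, 8, 8)).astype(np.uint8)
        vol = LabelVolume(labels, 1.0, origin_mm=-3.5 * np.ones(3))
        n_steps = 10_000
        for _ in range(100):
            src = rng.uniform(-15, -9, 3) * rng.choice([-1, 1], 3)
            dst = rng.uniform(-4, 4, 3)
            end = src + 2.5 * (dst - src)  # pass fully through
            exact = siddon_trace(vol, src, end)
            ts = (np.arange(n_steps) + 0.5) / n_steps
            pts = src + ts[:, None] * (end - src)
            seg = np.linalg.norm(end - src) / n_steps
            idx = np.round((pts - vol.origin_mm) / vol.voxel_mm).astype(int)
            inside = np.all((idx >= 0) & (idx < 8), axis=1)
            approx = np.zeros(4)
            lab = labels[idx[inside, 0], idx[inside, 1], idx[inside, 2]]
            np.add.at(approx, lab, seg)
            total = np.linalg.norm(end - src)
            assert np.all(np.abs(exact - approx) <= 0.005 * total)


class TestThicknessProjection:
    def test_empty_volume_gives_zero_maps(self):
        vol = LabelVolume(np.zeros((8, 8, 8), np.uint8), 1.0,
                          origin_mm=-3.5 * np.ones(3))
        geom = ScanGeometry(n_rows=4, n_cols=8, pixel_mm=2.0,
                            angles_deg=np.array([0.0]))
        t = thickness_project(vol, geom, 0.0)
        assert t.lengths_mm == {}
        assert np.all(t.total() == 0)
        assert t.shape == (4, 8)

    def test_material_maps_partition_support_trace(self):
        vol = make_cylinder_fixture()
        geom = ScanGeometry(n_rows=1, n_cols=64, pixel_mm=2.4,
                            angles_deg=np.array([30.0]))
        t = thickness_project(vol, geom, 30.0, central_row_only=True)
        support = vol.copy()
        support.data[support.data > 0] = 1
        support.legend = {1: "water"}
        t_support = thickness_project(support, geom, 30.0,
                                      central_row_only=True)
        assert np.allclose(t.total(), t_support.total(), atol=1e-9)

    def test_cylinder_chord_profile_analytic(self):
        spec = FixtureSpec(inserts=[])
        vol = make_cylinder_fixture(spec)
        geom = ScanGeometry(sdd_mm=700, sad_mm=500, n_rows=1, n_cols=128,
                            pixel_mm=1.2, angles_deg=np.array([0.0]))
        t = thickness_project(vol, geom, 0.0, central_row_only=True)
        prof = t.lengths_mm["water"][0]
        gamma = np.arctan(geom.u_coords() / geom.sdd_mm)
        d = geom.sad_mm * np.sin(gamma)  # ray-to-axis distance
        r = spec.host_radius_mm
        expected = np.where(np.abs(d) < r, 2 * np.sqrt(
            np.clip(r ** 2 - d ** 2, 0, None)), 0.0)
        assert np.max(np.abs(prof - expected)) <= 2 * spec.voxel_mm

    def test_sum_bounded_by_bounding_box_chord(self):
        vol = make_cylinder_fixture()
        geom = ScanGeometry(n_rows=8, n_cols=32, pixel_mm=4.0,
                            angles_deg=np.array([45.0]))
        t = thickness_project(vol, geom, 45.0)
        bbox_diag = np.linalg.norm(np.array(vol.shape) * vol.voxel_mm)
        assert np.all(t.total() <= bbox_diag + 1e-9)


class TestPolyProjection:
    def _slab(self, thickness_mm, material="water"):
        return ThicknessProjection({material: np.atleast_2d(thickness_mm)})

    def test_open_field_value_exact(self):
        s = make_spectrum(60.0)
        img = poly_project(self._slab(np.zeros((3, 3))), s)
        expected = float((s.fluence * s.energies_kev)[s.fluence > 0].sum())
        assert np.allclose(img.data, expected, rtol=1e-12)
        assert img.open_field == pytest.approx(expected, rel=1e-12)

    def test_single_bin_reduces_to_beers_law(self):
        e = np.arange(10.0, 101.0)
        phi = np.zeros_like(e)
        phi[25] = 1.0  # 35 keV
        s = Spectrum(e, phi, 60.0)
        t = self._slab(np.array([[10.0, 30.0]]))
        poly = poly_project(t, s)
        mono = mono_project(t, 35.0)
        assert np.allclose(poly.data, mono.data, rtol=1e-12)

    def test_doubling_thickness_squares_transmission(self):
        t1 = mono_project(self._slab(np.array([[25.0]])), 40.0)
        t2 = mono_project(self._slab(np.array([[50.0]])), 40.0)
        assert (t2.data / t2.open_field) == pytest.approx(
            (t1.data / t1.open_field) ** 2, rel=1e-10)

    def test_more_material_never_raises_signal(self, rng):
        s = make_spectrum(70.0)
        base = rng.uniform(0, 40, size=(5, 5))
        p1 = poly_project(self._slab(base), s)
        p2 = poly_project(self._slab(base + 5.0), s)
        assert np.all(p2.data < p1.data)

    def test_fluence_scaling_cancels_in_normalization(self):
        s = make_spectrum(60.0)
        s10 = Spectrum(s.energies_kev, 10.0 * s.fluence, s.kvp)
        t = self._slab(np.array([[12.0, 48.0]]))
        a = poly_project(t, s)
        b = poly_project(t, s10)
        assert np.allclose(b.data, 10.0 * a.data, rtol=1e-12)
        assert np.allclose(b.normalized(), a.normalized(), rtol=1e-12)

    def test_factorization_matches_per_bin_retrace(self):
        """Thickness-projection poly equals the per-bin re-trace oracle."""
        rng = np.random.default_rng(21)
        labels = rng.integers(0, 4, size=(16, 16, 16)).astype(np.uint8)
        vol = LabelVolume(labels, 1.0, origin_mm=-7.5 * np.ones(3),
                          legend={1: "adipose", 2: "glandular", 3: "skin"})
        geom = ScanGeometry(n_rows=4, n_cols=16, pixel_mm=2.0,
                            angles_deg=np.array([17.0]))
        s = make_spectrum(60.0)
        fast = poly_project(thickness_project(vol, geom, 17.0), s)
        slow = poly_project_per_bin(vol, geom, 17.0, s)
        assert np.max(np.abs(fast.data - slow.data) / slow.data) < 1e-10

    def test_unassigned_label_raises(self):
        vol = LabelVolume(np.ones((4, 4, 4), np.uint8), 1.0, legend={})
        geom = ScanGeometry(n_rows=1, n_cols=4, pixel_mm=4.0,
                            angles_deg=np.array([0.0]))
        with pytest.raises(KeyError):
            thickness_project(vol, geom, 0.0)


class TestBeamHardening:
    def test_effective_mu_falls_with_depth_only_for_poly(self):
        thick = np.linspace(5.0, 120.0, 12)[None, :]
        t = ThicknessProjection({"water": thick})
        poly = poly_project(t, make_spectrum(60.0))
        mono = mono_project(t, 35.0)
        mu_eff_poly = -np.log(poly.normalized()) / thick
        mu_eff_mono = -np.log(mono.normalized()) / thick
        assert np.all(np.diff(mu_eff_poly[0]) < 0)
        assert np.allclose(mu_eff_mono, mu_lookup("water", 35.0), rtol=1e-9)


class TestRelativeErrorMap:
    def _pair(self, poly, mono, open_p=1.0, open_m=1.0):
        return (ProjectionImage(np.asarray(poly, float), open_p, "poly"),
                ProjectionImage(np.asarray(mono, float), open_m, "mono"))

    def test_identical_images_give_zero(self):
        p, m = self._pair([[0.5, 0.2]], [[0.5, 0.2]])
        for domain in ("intensity", "log"):
            err = relative_error_map(p, m, domain=domain)
            assert np.allclose(err[~np.isnan(err)], 0.0)

    def test_linear_scaling_gives_uniform_percentage(self):
        poly = np.array([[0.9, 0.5, 0.1]])
        p, m = self._pair(poly, 0.8 * poly)
        err = relative_error_map(p, m, domain="intensity")
        assert np.allclose(err, 20.0)

    def test_log_domain_flags_open_field_as_nan(self):
        p, m = self._pair([[1.0, 0.5]], [[1.0, 0.4]])
        err = relative_error_map(p, m, domain="log")
        assert np.isnan(err[0, 0]) and np.isfinite(err[0, 1])

    def test_shape_mismatch_rejected(self):
        p, _ = self._pair([[1.0]], [[1.0]])
        _, m = self._pair([[1.0, 1.0]], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            relative_error_map(p, m)


def test_geometry_validation():
    with pytest.raises(ValueError):
        ScanGeometry(sdd_mm=400.0, sad_mm=500.0)
    with pytest.raises(ValueError):
        ScanGeometry(pixel_mm=0.0)
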