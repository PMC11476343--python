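"""AFM topography: leveling, step heights, pores, particles, densities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memquant.afm import (Topograph, attribute_density, detect_particles,
                          detect_pores, level, step_from_profile, step_height)
from memquant.synthetic import simulate_topograph


def _masks_left_right(shape):
    left = np.zeros(shape, dtype=bool)
    left[:, : shape[1] // 2] = True
    return left, ~left


class TestLevel:
    def test_tilted_plane_flattens_to_zero(self):
        topo, _ = simulate_topograph(shape=(100, 100), pixel_size_nm=5.0,
                                     roughness_rms_nm=0.0,
                                     tilt_nm_per_um=(2.0, -1.0), rng_seed=0)
        leveled = level(topo, order=1)
        assert np.abs(leveled.heights_nm).max() < 1e-9

    def test_idempotent(self):
        topo, _ = simulate_topograph(shape=(80, 80), pixel_size_nm=5.0,
                                     roughness_rms_nm=0.2,
                                     tilt_nm_per_um=(1.0, 0.5), rng_seed=1)
        once = level(topo, order=1)
        twice = level(once, order=1)
        np.testing.assert_allclose(twice.heights_nm, once.heights_nm,
                                   atol=1e-9)

    @given(st.floats(min_value=-50.0, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_commutes_with_constant_offset(self, offset):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 0.2, (40, 40)) + np.linspace(0, 3, 40)
        a = level(Topograph(z, 5.0), order=1)
        b = level(Topograph(z + offset, 5.0), order=1)
        np.testing.assert_allclose(a.heights_nm, b.heights_nm, atol=1e-8)

    def test_masked_leveling_preserves_feature_heights(self):
        topo, truth = simulate_topograph(
            shape=(300, 300), pixel_size_nm=2.0, membrane_height_nm=0.0,
            n_particles=10, roughness_rms_nm=0.0,
            tilt_nm_per_um=(3.0, 0.0), rng_seed=3)
        leveled = level(topo, order=1,
                        exclusion_mask=topo.heights_nm
                        - np.min(topo.heights_nm) > 2.0)
        for p in truth.particles:
            iy, ix = int(p["y_px"]), int(p["x_px"])
            measured = leveled.heights_nm[iy - 2: iy + 3, ix - 2: ix + 3].max()
            assert measured == pytest.approx(p["height_nm"], abs=0.15)

    def test_over_excluded_fit_rejected(self):
        topo = Topograph(np.zeros((50, 50)), 5.0)
        with pytest.raises(ValueError, match="90%"):
            level(topo, exclusion_mask=np.ones((50, 50), dtype=bool))


class TestStepHeight:
    def _template_scene(self, mesa, roughness, seed):
        shape = (200, 400)
        topo, _ = simulate_topograph(
            shape=shape, pixel_size_nm=5.0, template="left-half",
            mesa_height_nm=mesa, roughness_rms_nm=roughness,
            tilt_nm_per_um=(0.05, 0.05), rng_seed=seed)
        upper, lower = _masks_left_right(shape)
        leveled = level(topo, order=1, exclusion_mask=upper)
        return leveled, lower, upper

    def test_empty_template_step(self):
        leveled, lower, upper = self._template_scene(4.81, 0.1, 4)
        step = step_height(leveled, lower, upper)
        assert step.step_height_nm == pytest.approx(4.81, abs=0.05)

    def test_backfilled_residual_step_resolved_at_sub_angstrom(self):
        leveled, lower, upper = self._template_scene(0.19, 0.1, 5)
        step = step_height(leveled, lower, upper)
        assert step.step_height_nm == pytest.approx(0.19, abs=0.02)

    def test_zero_step_measures_zero(self):
        leveled, lower, upper = self._template_scene(0.0, 0.1, 6)
        step = step_height(leveled, lower, upper)
        assert step.step_height_nm == pytest.approx(0.0, abs=0.02)

    def test_antisymmetry(self):
        leveled, lower, upper = self._template_scene(4.81, 0.1, 7)
        ab = step_height(leveled, lower, upper)
        ba = step_height(leveled, upper, lower)
        assert ab.step_height_nm == pytest.approx(-ba.step_height_nm)

    def test_profile_mode_recovers_step(self):
        leveled, _, _ = self._template_scene(4.81, 0.1, 8)
        step = step_from_profile(leveled, (100, 50), (100, 350))
        assert abs(step.step_height_nm) == pytest.approx(4.81, abs=0.1)

    def test_profile_mode_rejects_unseparable_plateaus(self):
        leveled, _, _ = self._template_scene(0.0, 0.1, 9)
        with pytest.raises(ValueError, match="not separable"):
            step_from_profile(leveled, (100, 50), (100, 350))

    def test_small_plateaus_rejected(self):
        topo = Topograph(np.zeros((10, 10)), 5.0, leveled=True)
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :5] = True
        with pytest.raises(ValueError, match="pixels"):
            step_height(topo, mask, ~mask)


class TestDetectPores:
    def test_defect_free_membrane_yields_empty_poreset(self):
        topo, _ = simulate_topograph(shape=(500, 500), pixel_size_nm=2.0,
                                     membrane_height_nm=4.62,
                                     roughness_rms_nm=0.15, rng_seed=10)
        pores = detect_pores(level(topo, order=1))
        assert len(pores) == 0
        assert pores.pore_area_fraction == 0.0

    def test_planted_pores_recovered(self):
        topo, truth = simulate_topograph(
            shape=(1000, 1000), pixel_size_nm=2.0, membrane_height_nm=4.62,
            n_pores=12, pore_depth_nm=4.45, pore_diameter_nm=100.0,
            roughness_rms_nm=0.15, rng_seed=11)
        pores = detect_pores(level(topo, order=1))
        assert len(pores) == 12
        assert pores.mean_depth_nm == pytest.approx(4.45, rel=0.05)
        assert pores.mean_diameter_nm == pytest.approx(100.0, rel=0.05)

    def test_ten_percent_area_fraction_recovered(self):
        topo, truth = simulate_topograph(
            shape=(1000, 1000), pixel_size_nm=2.0, membrane_height_nm=4.62,
            n_pores=50, pore_depth_nm=4.45, pore_diameter_nm=100.0,
            roughness_rms_nm=0.15, rng_seed=12)
        # 50 pores of 50 nm radius on a 2 x 2 um field => ~9.8% of area
        planted_fraction = 50 * np.pi * 50.0 ** 2 / 2000.0 ** 2
        pores = detect_pores(level(topo, order=1))
        assert pores.pore_area_fraction == pytest.approx(planted_fraction,
                                                         rel=0.1)

    def test_depth_invariant_under_tilt(self):
        kwargs = dict(shape=(600, 600), pixel_size_nm=2.0,
                      membrane_height_nm=4.62, n_pores=6,
                      pore_depth_nm=4.45, pore_diameter_nm=100.0,
                      roughness_rms_nm=0.1, rng_seed=13)
        flat, _ = simulate_topograph(**kwargs)
        tilted, _ = simulate_topograph(**{**kwargs,
                                          "tilt_nm_per_um": (2.0, 1.0)})
        d_flat = detect_pores(level(flat, order=1)).mean_depth_nm
        d_tilt = detect_pores(level(tilted, order=1)).mean_depth_nm
        assert abs(d_flat - d_tilt) < 0.05


class TestDetectParticles:
    def _scene(self, n, seed, shape=(500, 500)):
        topo, truth = simulate_topograph(
            shape=shape, pixel_size_nm=2.0, membrane_height_nm=0.0,
            n_particles=n, roughness_rms_nm=0.15, rng_seed=seed)
        leveled = level(topo, order=1,
                        exclusion_mask=topo.heights_nm > 1.0)
        return detect_particles(leveled), truth

    def test_hybrid_membrane_density_recovered(self):
        # 77 planted on ~1 um^2 of analyzed membrane
        particles, truth = self._scene(77, 14)
        planted_density = len(truth.particles) / particles.analyzed_area_um2
        assert particles.density_per_um2 == pytest.approx(
            planted_density, abs=2 * np.sqrt(planted_density))

    def test_control_membrane_density_recovered(self):
        particles, truth = self._scene(10, 15)
        assert abs(len(particles.gated) - 10) <= 2

    def test_precision_and_recall_above_95_percent(self):
        particles, truth = self._scene(60, 16)
        planted = np.array([[p["y_px"], p["x_px"]] for p in truth.particles])
        detected = np.array([p.centroid_px for p in particles.particles])
        # oracle: planted coordinate list; match within one base radius
        d2 = ((planted[:, None, :] - detected[None, :, :]) ** 2).sum(-1)
        matched_planted = (d2.min(axis=1) < 8 ** 2).sum()
        matched_detected = (d2.min(axis=0) < 8 ** 2).sum()
        recall = matched_planted / len(planted)
        precision = matched_detected / len(detected)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_low_particles_not_gated(self):
        topo, _ = simulate_topograph(
            shape=(400, 400), pixel_size_nm=2.0, membrane_height_nm=0.0,
            n_particles=20, particle_height_nm=3.0,
            particle_diameter_nm=15.0, roughness_rms_nm=0.1, rng_seed=17)
        leveled = level(topo, order=1,
                        exclusion_mask=topo.heights_nm > 1.0)
        particles = detect_particles(leveled)
        assert len(particles.gated) == 0

    def test_class_bands_are_height_tertiles(self):
        particles, _ = self._scene(50, 18)
        for p in particles.gated:
            expected = ("P1" if p.height_nm < 5 + 5 / 3 else
                        "P2" if p.height_nm < 5 + 10 / 3 else "P3")
            assert p.class_label == expected

    def test_coarse_pixels_rejected(self):
        topo = Topograph(np.zeros((50, 50)), 10.0, leveled=True)
        with pytest.raises(ValueError, match="pixel"):
            detect_particles(topo)


class TestAttributeDensity:
    def _set_with_density(self, density, area=1.0):
        from memquant.afm import Particle, ParticleSet
        n = int(round(density * area))
        parts = [Particle((0, 0), 7.0, 15.0, True, "P2") for _ in range(n)]
        return ParticleSet(parts, analyzed_area_um2=area)

    def test_equal_densities_give_zero_attribution(self):
        s = self._set_with_density(50)
        fraction, density = attribute_density(s, s)
        assert fraction == 0.0 and density == 0.0

    def test_hybrid_vs_control_arithmetic(self):
        test = self._set_with_density(77.0, area=10.0)
        ctrl = self._set_with_density(9.7, area=10.0)
        fraction, density = attribute_density(test, ctrl)
        assert density == pytest.approx(67.3)
        assert fraction == pytest.approx(67.3 / 77.0)

    def test_empty_control_gives_full_attribution(self):
        test = self._set_with_density(50)
        ctrl = self._set_with_density(0)
        fraction, density = attribute_density(test, ctrl)
        assert fraction == 1.0 and density == 50.0

    def test_excess_control_flagged_negative(self):
        test = self._set_with_density(10)
        ctrl = self._set_with_density(20)
        with pytest.warns(UserWarning, match="control"):
            fraction, _ = attribute_density(test, ctrl)
        assert fraction < 0


class TestTopographIO:
    def test_tiff_roundtrip(self, tmp_path):
        topo, _ = simulate_topograph(shape=(64, 64), pixel_size_nm=2.0,
                                     roughness_rms_nm=0.1, rng_seed=19)
        path = tmp_path / "topo.tif"
        topo.to_tiff(path)
        loaded = Topograph.from_tiff(path)
        np.testing.assert_allclose(loaded.heights_nm, topo.heights_nm,
                                   atol=1e-6)
        assert loaded.pixel_size_nm == 2.0

    def test_txt_roundtrip(self, tmp_path):
        topo, _ = simulate_topograph(shape=(32, 32), pixel_size_nm=5.0,
                                     roughness_rms_nm=0.1, rng_seed=20)
        path = tmp_path / "topo.txt"
        topo.to_txt(path)
        loaded = Topograph.from_txt(path)
        np.testing.assert_allclose(loaded.heights_nm, topo.heights_nm,
                                   atol=1e-5)
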