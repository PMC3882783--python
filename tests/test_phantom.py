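"""Phantom: slice planning, activation envelope, deformation map, truth."""

import dataclasses

import numpy as np
import pytest

from cinedense.phantom import (
    Phantom,
    PhantomConfig,
    PhantomConfigError,
    activation,
    plan_slices,
)


def identity_config(**kwargs):
    base = dict(circ_stretch_endo=1.0, circ_stretch_epi=1.0, long_stretch=1.0,
                twist_base_peak=0.0, twist_apex_peak=0.0)
    base.update(kwargs)
    return PhantomConfig(**base)


class TestPlanSlices:
    @pytest.mark.parametrize("length, expected", [
        (8.0, {"basal": 5.6, "mid": 4.0, "apical": 2.4}),
        (10.0, {"basal": 7.0, "mid": 5.0, "apical": 3.0}),
    ])
    def test_fifty_twenty_rule(self, length, expected):
        got = plan_slices(length)
        for k, v in expected.items():
            assert got[k] == pytest.approx(v)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(PhantomConfigError):
            plan_slices(0.0)


class TestActivation:
    def test_zero_at_onset_and_peak_at_end_systole(self):
        assert activation(12.0, delay=12.0, period=130.0, systole=45.0) == 0.0
        assert activation(57.0, delay=12.0, period=130.0, systole=45.0) == 1.0

    def test_delay_shifts_peak_time_exactly(self):
        t = np.linspace(0, 130, 13001)
        peak0 = t[np.argmax(activation(t, 0.0, 130.0))]
        peak10 = t[np.argmax(activation(t, 10.0, 130.0))]
        assert peak10 - peak0 == pytest.approx(10.0, abs=0.02)

    def test_continuous_and_bounded(self):
        t = np.linspace(0, 130, 2000)
        a = activation(t, 5.0, 130.0)
        assert np.all((a >= 0) & (a <= 1))
        assert np.max(np.abs(np.diff(a))) < 0.01


class TestMaterialMap:
    def test_identity_for_undeformed_config(self):
        ph = Phantom(identity_config())
        z = ph.slice_z["mid"]
        X = np.array([[1.8, 0.3], [-1.5, 1.0], [0.0, -2.0]])
        for t in (0.0, 30.0, 60.0, 100.0):
            np.testing.assert_allclose(ph.material_map(X, z, t), X, atol=1e-12)

    def test_endocardial_point_scaled_by_prescribed_stretch(self):
        cfg = PhantomConfig(circ_stretch_endo=0.9, circ_stretch_epi=0.95,
                            twist_apex_peak=0.0, long_stretch=1.0)
        ph = Phantom(cfg)
        z = ph.slice_z["mid"]
        r_endo = float(ph.rho_endo(z))
        x = ph.material_map(np.array([[r_endo, 0.0]]), z, t=cfg.systole_ms)
        assert np.hypot(*x[0]) == pytest.approx(0.9 * r_endo, rel=1e-9)

    def test_twist_rotates_apical_slice_about_centroid(self):
        cfg = identity_config(twist_apex_peak=8.8)
        ph = Phantom(cfg)
        z = ph.slice_z["apical"]
        X = np.array([[1.5, 0.0]])
        x = ph.material_map(X, z, t=cfg.systole_ms)
        ang = np.degrees(np.arctan2(x[0, 1], x[0, 0]))
        assert ang == pytest.approx(8.8, abs=1e-9)
        assert np.hypot(*x[0]) == pytest.approx(1.5, rel=1e-12)

    def test_point_outside_annulus_rejected(self):
        ph = Phantom(identity_config())
        with pytest.raises(PhantomConfigError, match="annulus"):
            ph.material_map(np.array([[0.1, 0.0]]), ph.slice_z["mid"], 20.0)


class TestGroundTruth:
    def test_prescribed_stretch_gives_layer_strains(self, lowfat_phantom):
        gt = lowfat_phantom.ground_truth()
        assert gt.peak_strain["ecc"]["endo"] == pytest.approx(-17.0)
        assert gt.peak_strain["ecc"]["epi"] == pytest.approx(-9.4)
        assert gt.peak_strain["ell"]["endo"] == pytest.approx(-12.0)

    def test_torsion_is_twist_difference_over_length(self, lowfat_phantom):
        gt = lowfat_phantom.ground_truth()
        assert gt.peak_torsion == pytest.approx(8.8)  # 8.8 deg over 1.0 cm

    def test_torsion_invariant_to_constant_rotation_of_both_slices(
            self, lowfat_config):
        shifted = dataclasses.replace(lowfat_config, twist_base_peak=3.0,
                                      twist_apex_peak=11.8)
        assert Phantom(shifted).ground_truth().peak_torsion == pytest.approx(8.8)

    def test_zero_delay_gives_perfect_synchrony(self, lowfat_phantom):
        gt = lowfat_phantom.ground_truth()
        assert gt.cure == pytest.approx(1.0, abs=1e-12)
        assert gt.rure == pytest.approx(1.0, abs=1e-12)

    def test_ef_consistent_with_volumes(self, lowfat_phantom):
        gt = lowfat_phantom.ground_truth()
        assert gt.ef == pytest.approx(100 * (gt.edv - gt.esv) / gt.edv)

    def test_strains_match_finite_difference_of_material_map(
            self, lowfat_phantom):
        """Brute-force oracle: FD deformation gradient on a refined radial
        grid reproduces the analytic circumferential/radial strains."""
        ph = lowfat_phantom
        cfg = ph.config
        z = ph.slice_z["mid"]
        rho_e, rho_p = float(ph.rho_endo(z)), float(ph.rho_epi(z))
        t = cfg.systole_ms  # peak activation
        h = 1e-5
        depths = np.linspace(0.05, 0.95, 10)
        for d in depths:
            R = rho_e + d * (rho_p - rho_e)
            lam_true = (cfg.circ_stretch_endo
                        + (cfg.circ_stretch_epi - cfg.circ_stretch_endo) * d)
            # circumferential: arclength ratio via angular FD
            X0 = np.array([[R, 0.0]])
            dth = 1e-5
            X1 = R * np.array([[np.cos(dth), np.sin(dth)]])
            x0 = ph.material_map(X0, z, t)
            x1 = ph.material_map(X1, z, t)
            lam_c = np.linalg.norm(x1 - x0) / (R * dth)
            assert 100 * (lam_c - 1) == pytest.approx(
                100 * (lam_true - 1), abs=0.1)
            # radial: d|x|/dR by central FD
            xp = ph.material_map(np.array([[R + h, 0.0]]), z, t)
            xm = ph.material_map(np.array([[R - h, 0.0]]), z, t)
            lam_r = (np.hypot(*xp[0]) - np.hypot(*xm[0])) / (2 * h)
            alpha, beta, *_ = ph._lambda_coeffs(z)
            assert 100 * (lam_r - 1) == pytest.approx(
                100 * (alpha + 2 * beta * R - 1), abs=0.1)


class TestRenderStudy:
    def test_frame_count_matches_protocol(self, lowfat_study):
        study, _ = lowfat_study
        assert study.slices["mid"].n_frames == 18  # floor(60000/457/7.1)
        assert 15 <= study.slices["mid"].n_frames <= 20

    def test_zero_deformation_zero_noise_gives_zero_phase(self):
        study, _ = Phantom(identity_config()).render_study()
        for sl in study.slices.values():
            assert np.all(sl.phase_x == 0)
            assert np.all(sl.phase_y == 0)

    def test_rendering_is_deterministic(self):
        cfg = PhantomConfig(phase_noise_sd=0.05, random_seed=7)
        s1, _ = Phantom(cfg).render_study()
        s2, _ = Phantom(cfg).render_study()
        for label in s1.slices:
            np.testing.assert_array_equal(s1.slices[label].phase_x,
                                          s2.slices[label].phase_x)
            np.testing.assert_array_equal(s1.slices[label].magnitude,
                                          s2.slices[label].magnitude)

    @pytest.mark.parametrize("heart_rate, tr", [
        (60.0, 7.1),     # 140 frames: too many
        (500.0, 80.0),   # 1 frame: too few
    ])
    def test_frame_count_out_of_range_rejected(self, heart_rate, tr):
        with pytest.raises(PhantomConfigError, match="frame count"):
            Phantom(PhantomConfig(heart_rate=heart_rate, repetition_time=tr))

    def test_invalid_stretch_rejected(self):
        with pytest.raises(PhantomConfigError):
            PhantomConfig(circ_stretch_endo=1.4)
        with pytest.raises(PhantomConfigError):
            PhantomConfig(endo_radius_ed=2.5, epi_radius_ed=2.0)
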