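"""Tracking, deformation-gradient estimation, strain projection, layers."""

import dataclasses

import numpy as np
import pytest

from cinedense import kinematics as kin
from cinedense.model import ContourSet
from cinedense.phantom import Phantom, PhantomConfig


def rotation_field(angle_deg_per_frame, center):
    def u_of(x, f):
        ang = np.radians(angle_deg_per_frame * f)
        c, s = np.cos(-ang), np.sin(-ang)
        rel = x - center
        X = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                             s * rel[:, 0] + c * rel[:, 1]]) + center
        return x - X

    return u_of


def simple_point_set(transform, n_frames=3, spacing=0.3):
    xs = np.arange(-2.0, 2.01, spacing)
    gx, gy = np.meshgrid(xs, xs)
    X = np.column_stack([gx.ravel() + 8.0, gy.ravel() + 8.0])
    traj = np.stack([transform(X, f) for f in range(n_frames)])
    return kin.MaterialPointSet(
        reference=X, trajectories=traj,
        valid=np.ones((n_frames, len(X)), dtype=bool))


class TestTracking:
    def test_zero_displacement_keeps_points_fixed(self, annulus_field_factory):
        fld, _ = annulus_field_factory(lambda x, f: np.zeros_like(x))
        pts = kin.track_points(fld)
        np.testing.assert_allclose(pts.trajectories[2], pts.reference,
                                   atol=1e-9)
        assert pts.valid.all()

    def test_rigid_translation_offsets_every_trajectory(
            self, annulus_field_factory):
        shift = np.array([0.3, 0.0])
        fld, _ = annulus_field_factory(
            lambda x, f: np.tile(shift * (f > 0), (len(x), 1)))
        pts = kin.track_points(fld)
        np.testing.assert_allclose(pts.trajectories[1],
                                   pts.reference + shift, atol=1e-9)

    def test_phantom_rotation_matches_analytic_map(self):
        cfg = PhantomConfig(circ_stretch_endo=1.0, circ_stretch_epi=1.0,
                            long_stretch=1.0, twist_base_peak=0.0,
                            twist_apex_peak=8.8)
        ph = Phantom(cfg)
        study, _ = ph.render_study()
        from cinedense.phase import compute_displacement_field

        sl = study.slices["apical"]
        pts = kin.track_points(compute_displacement_field(sl))
        center = cfg.field_of_view / 2
        z = ph.slice_z["apical"]
        for f in (4, 6, 9):
            truth = ph.material_map(pts.reference - center, z,
                                    sl.meta.frame_times[f]) + center
            err = np.linalg.norm(pts.trajectories[f] - truth, axis=1)
            assert err[pts.valid[f]].max() < 0.05

    def test_invalid_flags_are_monotone(self, lowfat_study):
        from cinedense.phase import compute_displacement_field

        pts = kin.track_points(
            compute_displacement_field(lowfat_study[0].slices["apical"]))
        lost = ~pts.valid
        assert np.all(lost[:-1] <= lost[1:])


class TestDeformationGradient:
    def test_uniform_scaling_recovered_exactly(self):
        pts = simple_point_set(
            lambda X, f: 8.0 + (X - 8.0) * (1.0 + 0.05 * f))
        F = kin.fit_deformation_gradient(pts, index=40, frame=2, radius=1.0)
        np.testing.assert_allclose(F, 1.1 * np.eye(2), atol=1e-10)

    def test_rigid_rotation_gives_orthogonal_gradient(self):
        ang = np.radians(30.0)
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])

        def transform(X, f):
            return (X - 8.0) @ (R.T if f == 2 else np.eye(2)) + 8.0

        pts = simple_point_set(transform)
        F = kin.fit_deformation_gradient(pts, index=40, frame=2, radius=1.0)
        np.testing.assert_allclose(F, R, atol=1e-10)
        np.testing.assert_allclose(F.T @ F, np.eye(2), atol=1e-10)

    def test_phantom_gradient_matches_analytic_interior(self, lowfat_phantom):
        """Oracle: analytic F of the deformation map, on exact trajectories."""
        ph = lowfat_phantom
        cfg = ph.config
        z = ph.slice_z["mid"]
        ps = cfg.field_of_view / cfg.matrix_size
        rho_e, rho_p = float(ph.rho_endo(z)), float(ph.rho_epi(z))
        rng = np.random.default_rng(0)
        R = rng.uniform(rho_e, rho_p, 4000)
        th = rng.uniform(0, 2 * np.pi, 4000)
        X = np.column_stack([R * np.cos(th), R * np.sin(th)])
        times = np.array(cfg.frame_times)
        traj = np.stack([np.atleast_2d(ph.material_map(X, z, t))
                         for t in times])
        pts = kin.MaterialPointSet(reference=X, trajectories=traj,
                                   valid=np.ones((len(times), len(X)), bool))
        F, ok = kin.deformation_gradients(pts, radius=2.0 * ps, order=3,
                                          min_neighbors=20)
        f = 6
        a = float(ph.act(times[f]))
        phi = np.radians(ph.twist_deg(z, times[f]))
        Q = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        alpha, beta, *_ = ph._lambda_coeffs(z)
        interior = ok & (R > rho_e + 2 * ps) & (R < rho_p - 2 * ps)
        idx = np.flatnonzero(interior)[:200]
        for i in idx:
            g = 1.0 + (alpha + beta * R[i] - 1.0) * a
            outer = np.outer(X[i], X[i]) / R[i]
            F_true = Q @ (g * np.eye(2) + beta * a * outer)
            assert np.linalg.norm(F[f, i] - F_true) < 1e-3

    def test_insufficient_neighbourhood_flagged(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        pts = kin.MaterialPointSet(
            reference=X, trajectories=np.stack([X, X]),
            valid=np.ones((2, 4), bool))
        F = kin.fit_deformation_gradient(pts, index=0, frame=1, radius=5.0)
        assert np.isnan(F).all()


class TestProjectStrain:
    def test_zero_tensor(self):
        err, ecc = kin.project_strain(np.zeros((2, 2)), np.array([1.0, 0.0]),
                                      np.array([0.0, 0.0]))
        assert err == 0.0 and ecc == 0.0

    def test_uniform_scale_ten_percent(self):
        F = 1.1 * np.eye(2)
        E = kin.green_lagrange(F)
        err, ecc = kin.project_strain(E, np.array([2.0, 1.0]),
                                      np.array([0.0, 0.0]))
        assert err == pytest.approx(10.0, abs=1e-9)
        assert ecc == pytest.approx(10.0, abs=1e-9)

    def test_centroid_coincides_with_point_rejected(self):
        with pytest.raises(ValueError):
            kin.project_strain(np.zeros((2, 2)), np.array([1.0, 1.0]),
                               np.array([1.0, 1.0]))

    def test_green_to_engineering_inverse_relation(self):
        lam = np.array([0.8, 0.9, 1.0, 1.2])
        E_dd = 0.5 * (lam**2 - 1.0)
        np.testing.assert_allclose(kin.engineering_from_green(E_dd),
                                   100 * (lam - 1), atol=1e-12)


class TestLayersSegments:
    def _setup(self, label, n=600):
        th = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        ring = np.column_stack([np.cos(th), np.sin(th)])
        cs = ContourSet(endocardium=8.0 + 1.5 * ring,
                        epicardium=8.0 + 3.0 * ring)
        rng = np.random.default_rng(1)
        R = rng.uniform(1.5, 3.0, n)
        ang = rng.uniform(0, 2 * np.pi, n)
        X = 8.0 + np.column_stack([R * np.cos(ang), R * np.sin(ang)])
        pts = kin.MaterialPointSet(reference=X, trajectories=X[None],
                                   valid=np.ones((1, n), bool))
        return pts, cs

    def test_depth_zero_on_endocardium_and_half_midway(self):
        pts, cs = self._setup("mid")
        probe = np.array([[8.0 + 1.5, 8.0], [8.0 + 2.25, 8.0],
                          [8.0 + 3.0, 8.0]])
        p = kin.MaterialPointSet(reference=probe, trajectories=probe[None],
                                 valid=np.ones((1, 3), bool))
        depth, _, _, excluded = kin.assign_layers_segments(p, cs, "mid")
        assert depth == pytest.approx([0.0, 0.5, 1.0], abs=1e-6)
        assert not excluded.any()
        assert list(kin.layer_of_depth(depth)) == ["endo", "mid", "epi"]

    @pytest.mark.parametrize("label, expected_ids", [
        ("basal", set(range(1, 7))),
        ("mid", set(range(7, 13))),
        ("apical", set(range(13, 17))),
    ])
    def test_segment_counts_per_slice(self, label, expected_ids):
        pts, cs = self._setup(label)
        _, _, seg, excluded = kin.assign_layers_segments(pts, cs, label)
        assert set(seg[~excluded]) == expected_ids

    def test_point_outside_annulus_excluded(self):
        pts, cs = self._setup("mid")
        probe = np.array([[8.0 + 0.2, 8.0]])
        p = kin.MaterialPointSet(reference=probe, trajectories=probe[None],
                                 valid=np.ones((1, 1), bool))
        _, _, _, excluded = kin.assign_layers_segments(p, cs, "mid")
        assert excluded.all()


class TestPeakStrain:
    @pytest.mark.parametrize("curve, direction, expected", [
        ([0, -5, -17, -10], "circumferential", -17),
        ([0, 10, 36, 20], "radial", 36),
        ([0, 0, 0], "circumferential", 0),
    ])
    def test_peak_rule(self, curve, direction, expected):
        assert kin.peak_strain(curve, direction) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            kin.peak_strain([], "radial")


class TestRigidMotionInvariance:
    def test_rigid_motion_yields_zero_strain(self, annulus_field_factory):
        """Translation + rotation through the full chain: |strain| < 0.1%."""
        center_val = 8.0
        shift = np.array([0.2, -0.15])

        def u_of(x, f):
            if f == 0:
                return np.zeros_like(x)
            ang = np.radians(4.0 * f)
            c, s = np.cos(-ang), np.sin(-ang)
            rel = (x - shift * f) - center_val
            X = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                                 s * rel[:, 0] + c * rel[:, 1]]) + center_val
            return x - X

        fld, center = annulus_field_factory(u_of)
        pts = kin.track_points(fld)
        F, ok = kin.deformation_gradients(pts, radius=3.0 * fld.pixel_spacing)
        v = pts.reference - center
        e_r = v / np.linalg.norm(v, axis=1, keepdims=True)
        e_c = np.column_stack([-e_r[:, 1], e_r[:, 0]])
        for direction in (e_r, e_c):
            strain = kin.directional_strains(F, direction)
            assert np.nanmax(np.abs(strain[:, ok])) < 0.1

    def test_frame_zero_strain_is_zero(self, lowfat_analysis):
        for sl in lowfat_analysis.short_axis.values():
            for direction in ("ecc", "err"):
                for curve in sl.layer[direction].values():
                    assert abs(curve[0]) < 1e-9


class TestTransmuralPattern:
    def test_endocardial_shortening_exceeds_epicardial(self, lowfat_analysis):
        m = lowfat_analysis.metrics
        assert abs(m["ecc_endo"]) > abs(m["ecc_epi"])
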