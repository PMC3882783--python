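"""Analytic left-ventricular deformation phantom.

Generates complete :class:`~cinedense.model.DenseStudy` objects from a
closed-form, time-resolved LV model with exactly known strains, twist,
torsion, synchrony, volumes, and mass, so that every stage of the analysis
pipeline can be verified without scanner data.

Model
-----
The reference (end-diastolic) geometry is a pair of confocal-style
half-ellipsoids of revolution about the long (z) axis: the epicardial apex
sits at z = 0 and the flat base plane at z = L (``long_axis_length_ed``);
the endocardial apex sits one apical wall thickness above the epicardial one.
Three short-axis imaging planes are prescribed at 30%/50%/70% of the
*end-systolic* long-axis length above the apex, and two long-axis planes
(two-chamber: x–z, four-chamber: y–z) complete the five-view study.

In-plane deformation at a slice multiplies the reference radius R by a
circumferential stretch that interpolates linearly in wall depth between the
prescribed endocardial and epicardial peak stretches, scaled by a smooth
raised-cosine activation envelope; a per-slice rigid rotation (twist, linear
in z between the basal and apical slice planes) and a longitudinal scaling
z -> lambda_l(t) * z complete the map.  Radial strain is therefore emergent
(dr/dR), not independently prescribable.  Regional dyssynchrony is modelled
as a smooth septal-to-lateral gradient of activation delays.

Displacement-encoded images are rendered by inverting the map at every pixel
centre: the phase channels are wrap(2*pi*ke*u) plus optional Gaussian phase
noise, and the magnitude channel is a bright annulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .model import (
    LONG_AXIS_LABELS,
    MYOCARDIAL_DENSITY_MG_PER_UL,
    SHORT_AXIS_LABELS,
    AcquisitionMeta,
    ContourSet,
    DenseSlice,
    DenseStudy,
)

#: angular position (radians, CCW from +x in image mm coordinates) of the
#: earliest-activating wall for the septal-to-lateral delay gradient; the
#: default bisects the septum (180 deg) and anterior wall (90 deg).
DEFAULT_EARLY_ANGLE_DEG = 135.0

_BACKGROUND_MAGNITUDE = 0.05


class PhantomConfigError(ValueError):
    pass


def plan_slices(long_axis_length_es: float) -> dict:
    """Short-axis slice positions (mm above the apex) from the ES length.

    The mid-ventricular plane sits at 50% of the end-systolic long-axis
    length above the apex; the basal and apical planes are 20% of that
    length above and below the mid-ventricle.
    """
    if not long_axis_length_es > 0:
        raise PhantomConfigError("long-axis length must be positive")
    L = float(long_axis_length_es)
    return {"basal": 0.7 * L, "mid": 0.5 * L, "apical": 0.3 * L}


def activation(t, delay: float, period: float, systole: float = 45.0):
    """Smooth raised-cosine activation envelope in [0, 1].

    Zero at t <= delay, rises to a peak of 1 at t = delay + systole, and
    relaxes back to 0 at t = period.  Continuous in t; vectorized.
    """
    if not period > 0:
        raise PhantomConfigError("period must be positive")
    scalar = np.isscalar(t) and np.isscalar(delay)
    t, delay = np.broadcast_arrays(np.asarray(t, dtype=float),
                                   np.asarray(delay, dtype=float))
    a = np.zeros(t.shape, dtype=float)
    rise = (t > delay) & (t <= delay + systole)
    a[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - delay[rise]) / systole))
    fall = (t > delay + systole) & (t < period)
    tail = np.maximum(period - delay - systole, 1e-9)
    a[fall] = 0.5 * (1.0 + np.cos(
        np.pi * (t[fall] - delay[fall] - systole) / tail[fall]))
    return float(a) if scalar else a


@dataclass
class PhantomConfig:
    """Full ground-truth specification of one synthetic subject.

    Radii are mid-ventricular end-diastolic values in mm; stretches are peak
    (end-systolic) values, dimensionless (0.83 = -17% engineering strain);
    twist angles are the peak values at the basal/apical slice planes in
    degrees (counter-clockwise viewed from the apex positive).
    """

    endo_radius_ed: float = 1.41
    epi_radius_ed: float = 2.26
    long_axis_length_ed: float = 10.0
    circ_stretch_endo: float = 0.83
    circ_stretch_epi: float = 0.906
    long_stretch: float = 0.88
    twist_base_peak: float = 0.0
    twist_apex_peak: float = 8.8
    activation_delay: Optional[dict] = None
    heart_rate: float = 457.0
    systole_ms: float = 45.0
    apex_wall_thickness: float = 0.8
    encoding_frequency: float = 0.9
    field_of_view: float = 32.0
    matrix_size: int = 128
    repetition_time: float = 7.1
    phase_noise_sd: float = 0.0
    random_seed: int = 0

    def __post_init__(self):
        if not (0 < self.circ_stretch_endo <= 1 and 0 < self.circ_stretch_epi <= 1):
            raise PhantomConfigError("circumferential stretches must be in (0, 1]")
        if not (self.epi_radius_ed > self.endo_radius_ed > 0):
            raise PhantomConfigError("need epi_radius_ed > endo_radius_ed > 0")
        if self.phase_noise_sd < 0:
            raise PhantomConfigError("phase_noise_sd must be >= 0")
        if not (0 < self.long_stretch <= 1.2):
            raise PhantomConfigError("long_stretch out of range")

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    @property
    def n_frames(self) -> int:
        return int(math.floor(60000.0 / self.heart_rate / self.repetition_time))

    @property
    def frame_times(self) -> tuple:
        tr = self.repetition_time
        return tuple(i * tr for i in range(self.n_frames))

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            encoding_frequency=self.encoding_frequency,
            pixel_spacing=self.field_of_view / self.matrix_size,
            repetition_time=self.repetition_time,
            frame_times=self.frame_times,
            field_of_view=self.field_of_view,
            matrix_size=self.matrix_size,
        )


@dataclass
class GroundTruth:
    """Analytic per-subject truth mirroring the pipeline's summary metrics.

    ``peak_strain[direction][layer]`` holds engineering strain in percent at
    the endocardial surface / mid-wall / epicardial surface (radial values
    averaged over the three short-axis planes); twist in degrees, torsion in
    degrees/cm, volumes in uL, mass in mg, ef in percent.
    """

    peak_strain: dict
    peak_torsion: float
    peak_twist: dict
    cure: float
    rure: float
    edv: float
    esv: float
    mass: float
    ef: float

    def __post_init__(self):
        expected = 100.0 * (self.edv - self.esv) / self.edv
        assert abs(self.ef - expected) < 1e-9


class Phantom:
    """Deformation model and image renderer for one :class:`PhantomConfig`."""

    def __init__(self, config: PhantomConfig):
        self.config = c = config
        n = c.n_frames
        if not (2 <= n <= 100):
            raise PhantomConfigError(
                f"frame count {n} outside [2, 100]; check heart_rate/TR"
            )
        self.period = 60000.0 / c.heart_rate
        self.L = c.long_axis_length_ed
        self.Le = self.L - c.apex_wall_thickness
        if self.Le <= 0:
            raise PhantomConfigError("apex wall thicker than the ventricle")
        L_es = c.long_stretch * self.L
        self.slice_z = plan_slices(L_es)
        # equatorial radii from the prescribed mid-ventricular values
        z_mid = self.slice_z["mid"]
        self.Re = c.endo_radius_ed / self._ellipse_factor(z_mid, self.Le)
        self.Rp = c.epi_radius_ed / self._ellipse_factor(z_mid, self.L)
        if self.rho_endo(z_mid) >= self.rho_epi(z_mid):
            raise PhantomConfigError("endo/epi surfaces cross at mid-ventricle")

    # ---------------------------------------------------------------- geometry

    def _ellipse_factor(self, z, semi_length):
        arg = 1.0 - ((self.L - np.asarray(z, float)) / semi_length) ** 2
        return np.sqrt(np.clip(arg, 0.0, None))

    def rho_endo(self, z):
        """Reference endocardial radius at height z (0 below the endo apex)."""
        z = np.asarray(z, dtype=float)
        rho = self.Re * self._ellipse_factor(z, self.Le)
        return np.where(z >= self.config.apex_wall_thickness, rho, 0.0)

    def rho_epi(self, z):
        z = np.asarray(z, dtype=float)
        return np.where(z >= 0, self.Rp * self._ellipse_factor(z, self.L), 0.0)

    # ---------------------------------------------------------------- temporal

    def delay_of(self, theta):
        """Activation delay (ms) at reference circumferential angle theta."""
        spec = self.config.activation_delay
        theta = np.asarray(theta, dtype=float)
        if not spec or spec.get("mode") in (None, "none"):
            return np.zeros_like(theta)
        if spec.get("mode") == "septal_lateral":
            d = float(spec["max_delay_ms"])
            early = math.radians(spec.get("early_angle_deg", DEFAULT_EARLY_ANGLE_DEG))
            return 0.5 * d * (1.0 - np.cos(theta - early))
        if "sectors" in spec:
            deg = np.degrees(theta) % 360.0
            out = np.zeros_like(theta)
            for sector in spec["sectors"]:
                lo, hi = sector["start_deg"] % 360.0, sector["end_deg"]
                hi = hi if hi > lo else hi + 360.0
                inside = ((deg - lo) % 360.0) < (hi - lo)
                out[inside] = sector["delay_ms"]
            return out
        raise PhantomConfigError(f"unrecognised activation_delay: {spec!r}")

    def act(self, t, delay=0.0):
        return activation(t, delay, self.period, self.config.systole_ms)

    def long_scale(self, t):
        """Longitudinal stretch factor at time t (global activation)."""
        return 1.0 + (self.config.long_stretch - 1.0) * self.act(np.asarray(t, float))

    def twist_deg(self, z, t):
        """Slice twist angle (degrees) at height z and time t."""
        zb, za = self.slice_z["basal"], self.slice_z["apical"]
        tb, ta = self.config.twist_base_peak, self.config.twist_apex_peak
        peak = tb + (ta - tb) * (zb - np.asarray(z, float)) / (zb - za)
        return peak * self.act(np.asarray(t, float))

    def _lambda_coeffs(self, z):
        """(alpha, beta) of the transmural stretch lambda_c(R) = alpha+beta*R."""
        rho_e = self.rho_endo(z)
        rho_p = self.rho_epi(z)
        le, lp = self.config.circ_stretch_endo, self.config.circ_stretch_epi
        beta = (lp - le) / (rho_p - rho_e)
        alpha = le - beta * rho_e
        return alpha, beta, rho_e, rho_p

    # ------------------------------------------------------------ deformation

    def material_map(self, X, z: float, t: float):
        """Deformed in-plane position of reference point(s) X at slice z.

        X is an (N, 2) array (or single point) of positions in mm relative to
        the long axis.  Raises for points outside the end-diastolic annulus.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        R = np.hypot(X[:, 0], X[:, 1])
        theta = np.arctan2(X[:, 1], X[:, 0])
        alpha, beta, rho_e, rho_p = self._lambda_coeffs(z)
        if np.any(R < rho_e - 1e-6) or np.any(R > rho_p + 1e-6):
            raise PhantomConfigError("reference point outside the annulus")
        lam = alpha + beta * R
        a = self.act(np.full_like(R, t), self.delay_of(theta))
        r = R * (1.0 + (lam - 1.0) * a)
        phi = math.radians(self.twist_deg(z, t))
        th = theta + phi
        out = np.column_stack([r * np.cos(th), r * np.sin(th)])
        return out[0] if out.shape[0] == 1 and np.asarray(X).ndim == 1 else out

    def inverse_inplane(self, xy, z: float, t: float, rho_e=None, rho_p=None,
                        alpha=None, beta=None, cap=False):
        """Invert the in-plane map at deformed positions ``xy`` (N, 2).

        Returns (X, inside) where X are reference positions and ``inside``
        flags pixels whose reference radius falls within the annulus (or, if
        ``cap``, within the solid apex cap of radius rho_p).
        """
        if alpha is None:
            alpha, beta, rho_e, rho_p = self._lambda_coeffs(z)
        xy = np.asarray(xy, dtype=float)
        phi = math.radians(self.twist_deg(z, t))
        cosp, sinp = math.cos(phi), math.sin(phi)
        # un-rotate the twist (rotation by -phi)
        x1 = cosp * xy[:, 0] + sinp * xy[:, 1]
        y1 = -sinp * xy[:, 0] + cosp * xy[:, 1]
        r = np.hypot(x1, y1)
        theta = np.arctan2(y1, x1)
        a = self.act(np.full_like(r, t), self.delay_of(theta))
        b = 1.0 + (alpha - 1.0) * a
        q = a * beta
        with np.errstate(invalid="ignore", divide="ignore"):
            R_quad = (-b + np.sqrt(b * b + 4.0 * q * r)) / (2.0 * q)
        R = np.where(np.abs(q) > 1e-12, R_quad, r / b)
        lo = -1e-9 if cap else rho_e - 1e-9
        inside = (R >= lo) & (R <= rho_p + 1e-9) & (r > 0)
        scale = np.where(r > 0, R / np.maximum(r, 1e-300), 0.0)
        X = scale[:, None] * np.column_stack([x1, y1])
        return X, inside

    # --------------------------------------------------------------- rendering

    def _pixel_coords(self):
        n = self.config.matrix_size
        ps = self.config.field_of_view / n
        centers = (np.arange(n) + 0.5) * ps
        cx, cy = np.meshgrid(centers, centers)  # cx varies along columns
        return cx, cy

    def _render_short_axis(self, label: str, rng) -> np.ndarray:
        """Displacement images (u_x, u_y in mm; NaN background) per frame."""
        z = self.slice_z[label]
        cx, cy = self._pixel_coords()
        center = self.config.field_of_view / 2.0
        xy = np.column_stack([(cx - center).ravel(), (cy - center).ravel()])
        n_frames = self.config.n_frames
        ux = np.full((n_frames,) + cx.shape, np.nan)
        uy = np.full_like(ux, np.nan)
        for f, t in enumerate(self.config.frame_times):
            X, inside = self.inverse_inplane(xy, z, t)
            u = xy - X
            ux[f].ravel()[inside] = u[inside, 0]
            uy[f].ravel()[inside] = u[inside, 1]
        return ux, uy

    def _la_axis_offsets(self):
        """Image-coordinate placement of the long axis for long-axis views."""
        cx0 = self.config.field_of_view / 2.0
        cy0 = (self.config.field_of_view + self.L) / 2.0  # apex row position
        return cx0, cy0

    def la_to_image(self, xi, z):
        cx0, cy0 = self._la_axis_offsets()
        return cx0 + np.asarray(xi, float), cy0 - np.asarray(z, float)

    def _render_long_axis(self, label: str, rng):
        """Long-axis views: horizontal = lateral offset, vertical = -z.

        Rendered without the twist component (through-plane motion is outside
        the phantom's scope); the longitudinal scaling uses the global
        activation envelope.
        """
        theta_pos = 0.0 if label == "two_chamber" else 0.5 * math.pi
        cx, cy = self._pixel_coords()
        cx0, cy0 = self._la_axis_offsets()
        xi = (cx - cx0).ravel()
        z_lab = (cy0 - cy).ravel()
        n_frames = self.config.n_frames
        ux = np.full((n_frames,) + cx.shape, np.nan)
        uy = np.full_like(ux, np.nan)
        c = self.config
        for f, t in enumerate(c.frame_times):
            sl = float(self.long_scale(t))
            Z = z_lab / sl
            valid = (Z >= 0.0) & (Z <= self.L)
            rho_e = self.rho_endo(np.clip(Z, 0, self.L))
            rho_p = self.rho_epi(np.clip(Z, 0, self.L))
            wall = np.maximum(rho_p - rho_e, 1e-9)
            le, lp = c.circ_stretch_endo, c.circ_stretch_epi
            beta = (lp - le) / wall
            alpha = le - beta * rho_e
            r = np.abs(xi)
            theta = np.where(xi >= 0, theta_pos, theta_pos + math.pi)
            a = self.act(np.full_like(r, t), self.delay_of(theta))
            b = 1.0 + (alpha - 1.0) * a
            q = a * beta
            with np.errstate(invalid="ignore", divide="ignore"):
                R_quad = (-b + np.sqrt(b * b + 4.0 * q * r)) / (2.0 * q)
            R = np.where(np.abs(q) > 1e-12, R_quad, r / b)
            inside = valid & (R >= rho_e - 1e-9) & (R <= rho_p + 1e-9)
            u_xi = xi - np.sign(xi) * R
            u_z = z_lab - Z
            ux[f].ravel()[inside] = u_xi[inside]
            # image vertical axis points opposite to z
            uy[f].ravel()[inside] = -u_z[inside]
        return ux, uy

    def _displacement_to_slice(self, label, ux, uy, rng) -> DenseSlice:
        c = self.config
        ke = c.encoding_frequency
        mask = np.isfinite(ux)
        magnitude = np.where(mask, 1.0, _BACKGROUND_MAGNITUDE)
        phase_x = np.zeros_like(ux)
        phase_y = np.zeros_like(uy)
        phase_x[mask] = 2.0 * np.pi * ke * ux[mask]
        phase_y[mask] = 2.0 * np.pi * ke * uy[mask]
        if c.phase_noise_sd > 0:
            phase_x[mask] += rng.normal(0.0, c.phase_noise_sd, mask.sum())
            phase_y[mask] += rng.normal(0.0, c.phase_noise_sd, mask.sum())
        from .phase import wrap

        return DenseSlice(
            label=label,
            magnitude=magnitude,
            phase_x=wrap(phase_x),
            phase_y=wrap(phase_y),
            meta=c.meta,
        )

    # ---------------------------------------------------------------- contours

    def short_axis_contour(self, label: str, n_vertices: int = 96) -> ContourSet:
        z = self.slice_z[label]
        center = self.config.field_of_view / 2.0
        th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        ring = np.column_stack([np.cos(th), np.sin(th)])
        return ContourSet(
            endocardium=center + float(self.rho_endo(z)) * ring,
            epicardium=center + float(self.rho_epi(z)) * ring,
            frame_index=0,
        )

    def long_axis_contour(self, n_z: int = 48) -> ContourSet:
        ta = self.config.apex_wall_thickness
        z_endo = np.linspace(ta + 0.02 * self.Le, self.L, n_z)
        z_epi = np.linspace(0.003 * self.L, self.L, n_z)
        endo_r = self.rho_endo(z_endo)
        epi_r = self.rho_epi(z_epi)

        def _u_shape(zs, rs):
            right = np.column_stack(self.la_to_image(rs, zs))
            left = np.column_stack(self.la_to_image(-rs[::-1], zs[::-1]))
            return np.vstack([right, left])

        return ContourSet(
            endocardium=_u_shape(z_endo, endo_r),
            epicardium=_u_shape(z_epi, epi_r),
            frame_index=0,
        )

    def deformed_sa_boundary(self, label: str, which: str, t: float,
                             n_vertices: int = 96) -> np.ndarray:
        """Analytic deformed endo/epi boundary of a short-axis slice (mm)."""
        z = self.slice_z[label]
        rho = float(self.rho_endo(z) if which == "endo" else self.rho_epi(z))
        lam = (self.config.circ_stretch_endo if which == "endo"
               else self.config.circ_stretch_epi)
        th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        a = self.act(np.full_like(th, t), self.delay_of(th))
        r = rho * (1.0 + (lam - 1.0) * a)
        phi = math.radians(self.twist_deg(z, t))
        center = self.config.field_of_view / 2.0
        return np.column_stack([center + r * np.cos(th + phi),
                                center + r * np.sin(th + phi)])

    # ------------------------------------------------------------ ground truth

    def sector_strain_curves(self, direction: str, n_sectors: int = 24):
        """Analytic per-sector wall-averaged strain curves (T, N) in percent."""
        th = (np.arange(n_sectors) + 0.5) * 2 * np.pi / n_sectors
        delays = self.delay_of(th)
        t = np.asarray(self.config.frame_times)
        a = np.stack([self.act(t, d) for d in delays], axis=1)  # (T, N)
        if direction == "circumferential":
            amp = 100.0 * ((self.config.circ_stretch_endo
                            + self.config.circ_stretch_epi) / 2.0 - 1.0)
            return amp * a
        if direction == "radial":
            amps = []
            for label in SHORT_AXIS_LABELS:
                z = self.slice_z[label]
                alpha, beta, rho_e, rho_p = self._lambda_coeffs(z)
                # wall-averaged d(r)/dR - 1 at full activation
                Rm = 0.5 * (rho_e + rho_p)
                amps.append(100.0 * (alpha + beta * Rm + beta * Rm - 1.0))
            return float(np.mean(amps)) * a
        raise ValueError(direction)

    def _radial_truth(self, depth: float) -> float:
        """Peak-activation radial engineering strain (%) at a wall depth,
        averaged over the three short-axis planes."""
        vals = []
        for label in SHORT_AXIS_LABELS:
            alpha, beta, rho_e, rho_p = self._lambda_coeffs(self.slice_z[label])
            R = rho_e + depth * (rho_p - rho_e)
            vals.append(100.0 * (alpha + 2.0 * beta * R - 1.0))
        return float(np.mean(vals))

    def analytic_volumes(self):
        edv = (2.0 / 3.0) * np.pi * self.Re**2 * self.Le
        epi_vol = (2.0 / 3.0) * np.pi * self.Rp**2 * self.L
        esv = self.config.circ_stretch_endo**2 * self.config.long_stretch * edv
        mass = MYOCARDIAL_DENSITY_MG_PER_UL * (epi_vol - edv)
        return float(edv), float(esv), float(mass)

    def ground_truth(self) -> GroundTruth:
        from .globalfn import uniformity_index

        c = self.config
        le, lp = c.circ_stretch_endo, c.circ_stretch_epi
        ecc = {"endo": 100.0 * (le - 1.0),
               "mid": 100.0 * ((le + lp) / 2.0 - 1.0),
               "epi": 100.0 * (lp - 1.0)}
        err = {layer: self._radial_truth(d)
               for layer, d in (("endo", 0.0), ("mid", 0.5), ("epi", 1.0))}
        ell_val = 100.0 * (c.long_stretch - 1.0)
        ell = {"endo": ell_val, "mid": ell_val, "epi": ell_val}
        # a strain-free (degenerate) phantom is perfectly synchronous
        from .globalfn import UndefinedIndexError

        try:
            cure = uniformity_index(
                self.sector_strain_curves("circumferential")).index
        except UndefinedIndexError:
            cure = 1.0
        try:
            rure = uniformity_index(self.sector_strain_curves("radial")).index
        except UndefinedIndexError:
            rure = 1.0
        edv, esv, mass = self.analytic_volumes()
        torsion = (c.twist_apex_peak - c.twist_base_peak) / (c.long_axis_length_ed / 10.0)
        twist = {"basal": c.twist_base_peak,
                 "mid": 0.5 * (c.twist_base_peak + c.twist_apex_peak),
                 "apical": c.twist_apex_peak}
        return GroundTruth(
            peak_strain={"ecc": ecc, "err": err, "ell": ell},
            peak_torsion=torsion,
            peak_twist=twist,
            cure=cure,
            rure=rure,
            edv=edv,
            esv=esv,
            mass=mass,
            ef=100.0 * (edv - esv) / edv,
        )

    # ------------------------------------------------------------------ study

    def render_study(self, subject_id: str = "phantom",
                     group_label: Optional[str] = None):
        """Render the five-view study and its ground truth.

        Deterministic given (config, random_seed).
        """
        rng = np.random.default_rng(self.config.random_seed)
        slices = {}
        contours = {}
        for label in SHORT_AXIS_LABELS:
            ux, uy = self._render_short_axis(label, rng)
            slices[label] = self._displacement_to_slice(label, ux, uy, rng)
            contours[label] = self.short_axis_contour(label)
        la_contour = self.long_axis_contour()
        for label in LONG_AXIS_LABELS:
            ux, uy = self._render_long_axis(label, rng)
            slices[label] = self._displacement_to_slice(label, ux, uy, rng)
            contours[label] = ContourSet(
                endocardium=la_contour.endocardium.copy(),
                epicardium=la_contour.epicardium.copy(),
                frame_index=0,
            )
        study = DenseStudy(slices=slices, ed_contours=contours,
                           subject_id=subject_id, group_label=group_label)
        return study, self.ground_truth()


def material_map(config: PhantomConfig, X, z: float, t: float):
    """Deformed position (mm) of reference point(s) X at slice height z."""
    return Phantom(config).material_map(X, z, t)


def ground_truth(config: PhantomConfig) -> GroundTruth:
    return Phantom(config).ground_truth()


def render_study(config: PhantomConfig, subject_id: str = "phantom",
                 group_label: Optional[str] = None):
    return Phantom(config).render_study(subject_id, group_label)
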