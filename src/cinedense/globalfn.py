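"""Twist, torsion, and the CURE/RURE synchrony indices.

Torsion is the basal-to-apical twist-angle difference normalised by the
end-diastolic epicardial long-axis length (degrees/cm).  The uniformity
ratio estimate is a Fourier-harmonic index of the spatial strain profile
around the ventricle: with per-frame DFT coefficients c_k of the sector
strain profile, index = sum_t P0(t) / sum_t (P0(t) + P1(t)) where
P0 = |c_0|^2 and P1 = |c_1|^2 + |c_{N-1}|^2.  The index lies in (0, 1] and
equals 1 exactly when the profile has no first spatial harmonic at any
frame (perfectly synchronous, uniform contraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import MaterialPointSet


class GlobalFunctionError(ValueError):
    pass


class UndefinedIndexError(GlobalFunctionError):
    pass


def twist_angle(points: MaterialPointSet, centroid) -> np.ndarray:
    """Mean rotation angle (degrees) of the tracked points about the
    centroid, per frame; counter-clockwise positive, 0 at frame 0."""
    centroid = np.asarray(centroid, dtype=float)
    use = points.always_valid
    if use.sum() < 10:
        raise GlobalFunctionError(
            f"only {int(use.sum())} valid points; need at least 10 for twist"
        )
    v0 = points.reference[use] - centroid
    out = np.empty(points.n_frames)
    for f in range(points.n_frames):
        vt = points.trajectories[f][use] - centroid
        ang = np.arctan2(v0[:, 0] * vt[:, 1] - v0[:, 1] * vt[:, 0],
                         (v0 * vt).sum(axis=1))
        out[f] = np.degrees(np.mean(ang))
    return out


@dataclass
class TorsionResult:
    twist_base: np.ndarray     # degrees per frame
    twist_apex: np.ndarray
    normalization_length: float  # cm
    torsion_curve: np.ndarray  # degrees/cm per frame
    peak_torsion: float        # signed value of maximal magnitude

    @property
    def peak_torsion_deg_per_mm(self) -> float:
        return self.peak_torsion / 10.0


def torsion(twist_base, twist_apex, length_cm: float) -> TorsionResult:
    """Torsion curve and signed peak from per-slice twist curves."""
    twist_base = np.asarray(twist_base, dtype=float)
    twist_apex = np.asarray(twist_apex, dtype=float)
    if twist_base.shape != twist_apex.shape:
        raise GlobalFunctionError("twist curves differ in length")
    if not length_cm > 0:
        raise GlobalFunctionError("normalization length must be positive")
    curve = (twist_apex - twist_base) / length_cm
    peak = float(curve[np.argmax(np.abs(curve))])
    return TorsionResult(twist_base=twist_base, twist_apex=twist_apex,
                         normalization_length=length_cm, torsion_curve=curve,
                         peak_torsion=peak)


@dataclass
class SynchronyResult:
    index: float
    p0: np.ndarray   # zeroth-harmonic power per frame
    p1: np.ndarray   # first-harmonic power per frame


def uniformity_index(sector_strain: np.ndarray) -> SynchronyResult:
    """Uniformity ratio estimate from (n_frames, n_sectors) strain curves.

    CURE uses circumferential sector strains, RURE radial ones.
    """
    s = np.asarray(sector_strain, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise GlobalFunctionError("need a (n_frames >= 2, n_sectors) array")
    n = s.shape[1]
    if n < 8:
        raise GlobalFunctionError(f"need >= 8 sectors, got {n}")
    if np.isnan(s).any():
        raise GlobalFunctionError("sector strain profile contains NaN")
    c = np.fft.fft(s, axis=1) / n
    p0 = np.abs(c[:, 0]) ** 2
    p1 = np.abs(c[:, 1]) ** 2 + np.abs(c[:, n - 1]) ** 2
    total = float(np.sum(p0 + p1))
    if total == 0.0:
        raise UndefinedIndexError("all-zero sector profiles: index undefined")
    return SynchronyResult(index=float(np.sum(p0) / total), p0=p0, p1=p1)
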