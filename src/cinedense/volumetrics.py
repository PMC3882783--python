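"""Left-ventricular volumetry from the five-slice geometry.

The endo/epicardial surfaces are reconstructed as smooth bodies of
revolution-like shapes: per angular ray about the long axis, a cubic radial
profile (fitted to the squared radii of the three short-axis contours and
pinned to zero at the apex) is integrated from the apex to the base plane.
EDV/ESV are endocardial cavity volumes, mass is 1.05 mg/uL times the
end-diastolic wall volume, and EF = 100*(EDV-ESV)/EDV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MYOCARDIAL_DENSITY_MG_PER_UL


class GeometryError(ValueError):
    pass


@dataclass
class Surface:
    """Ray-wise radial reconstruction of one cardiac surface.

    ``radius_sq_poly`` holds, per angular ray, cubic coefficients (highest
    power first) of squared radius versus height z (mm above the apex).
    """

    apex_z: float
    base_z: float
    radius_sq_poly: np.ndarray   # (n_rays, 4)

    def radius_profile(self, z: np.ndarray) -> np.ndarray:
        """(n_rays, len(z)) radii, clipped to >= 0."""
        vals = np.stack([np.polyval(p, z) for p in self.radius_sq_poly])
        return np.sqrt(np.clip(vals, 0.0, None))

    def volume(self, n_z: int = 400) -> float:
        """Enclosed volume in uL (= mm^3)."""
        z = np.linspace(self.apex_z, self.base_z, n_z)
        r_sq = np.clip(
            np.stack([np.polyval(p, z) for p in self.radius_sq_poly]),
            0.0, None)
        return float(np.pi * np.trapezoid(r_sq.mean(axis=0), z))


def _ray_radii(contour: np.ndarray, center: np.ndarray,
               ray_angles: np.ndarray) -> np.ndarray:
    d = contour - center
    theta = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    theta, rad = theta[order], rad[order]
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad, rad])
    return np.interp(np.mod(ray_angles + np.pi, 2 * np.pi) - np.pi,
                     theta_ext, rad_ext)


def reconstruct_surface(contours_mm: dict, slice_z: dict, apex_z: float,
                        base_z: float, n_rays: int = 72) -> Surface:
    """Reconstruct a surface from the three short-axis contours.

    Parameters
    ----------
    contours_mm : dict
        ``{"basal"|"mid"|"apical": (V, 2) polygon}`` in image mm coordinates.
    slice_z : dict
        Height of each slice plane in mm above the apex.
    apex_z, base_z : float
        Long-axis extent (from the long-axis views); the radial profile is
        pinned to zero at ``apex_z`` and capped at the ``base_z`` plane.
    """
    zs = np.array([slice_z[l] for l in ("apical", "mid", "basal")])
    if not (apex_z < zs[0] < zs[1] < zs[2] <= base_z + 1e-9):
        raise GeometryError(
            f"slice planes {zs} out of order along the long axis "
            f"(apex {apex_z}, base {base_z})"
        )
    ray_angles = np.arange(n_rays) * 2 * np.pi / n_rays
    rows = []
    for label in ("apical", "mid", "basal"):
        poly = np.asarray(contours_mm[label], dtype=float)
        center = poly.mean(axis=0)
        rows.append(_ray_radii(poly, center, ray_angles))
    radii = np.stack(rows)                       # (3, n_rays)
    # cubic through (apex, 0) + three squared radii, per ray
    z_nodes = np.concatenate([[apex_z], zs])
    V = np.vander(z_nodes, 4)                    # (4, 4), highest power first
    targets = np.vstack([np.zeros(n_rays), radii**2])   # (4, n_rays)
    coeffs = np.linalg.solve(V, targets).T       # (n_rays, 4)
    return Surface(apex_z=apex_z, base_z=base_z, radius_sq_poly=coeffs)


@dataclass
class VolumetryResult:
    edv: float           # uL
    esv: float
    ef: float            # %
    mass: float          # mg
    mass_to_edv: float   # mg/uL

    def __post_init__(self):
        assert abs(self.ef - 100.0 * (self.edv - self.esv) / self.edv) < 1e-6
        assert abs(self.mass_to_edv - self.mass / self.edv) < 1e-6


def ejection_fraction(edv: float, esv: float) -> float:
    """EF (%) from end-diastolic and end-systolic volumes."""
    if not edv > 0:
        raise GeometryError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def compute_volumetry(endo_ed: Surface, endo_es: Surface,
                      epi_ed: Surface) -> VolumetryResult:
    """Volumes, mass, and EF from reconstructed surfaces."""
    z = np.linspace(max(endo_ed.apex_z, epi_ed.apex_z), min(endo_ed.base_z,
                                                            epi_ed.base_z), 100)
    if np.any(epi_ed.radius_profile(z) + 1e-6 < endo_ed.radius_profile(z)):
        raise GeometryError("endocardial surface crosses the epicardial one")
    edv = endo_ed.volume()
    esv = endo_es.volume()
    if esv >= edv:
        warnings.warn("ESV >= EDV: check end-systolic frame selection")
    wall = epi_ed.volume() - edv
    mass = MYOCARDIAL_DENSITY_MG_PER_UL * wall
    return VolumetryResult(edv=edv, esv=esv, ef=ejection_fraction(edv, esv),
                           mass=mass, mass_to_edv=mass / edv)
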