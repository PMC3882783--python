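"""Tissue tracking and Lagrangian strain estimation.

Material points seeded at end-diastole are followed through the cycle by
inverting the Eulerian displacement field; the local deformation gradient F
is estimated per point by a weighted least-squares polynomial fit of current
positions against reference offsets over a reference-frame neighbourhood,
and the Green-Lagrange tensor E = (F^T F - I)/2 is projected onto the
radial/circumferential (or longitudinal) directions.  Strain is reported as
engineering percent length change, 100*(sqrt(2*E_dd + 1) - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .interp import mls_interp, pixel_center_coords
from .model import ContourSet
from .phase import DisplacementField

LAYERS = ("endo", "mid", "epi")
#: evaluation depth of each reported layer when using the transmural fit
LAYER_EVAL_DEPTH = {"endo": 0.0, "mid": 0.5, "epi": 1.0}
#: wall-depth thirds used for band membership
LAYER_BANDS = {"endo": (0.0, 1 / 3), "mid": (1 / 3, 2 / 3), "epi": (2 / 3, 1.0001)}

SEGMENT_COUNTS = {"basal": 6, "mid": 6, "apical": 4}
SEGMENT_OFFSETS = {"basal": 0, "mid": 6, "apical": 12}


class TrackingError(RuntimeError):
    pass


@dataclass
class MaterialPointSet:
    """Trajectories of myocardial material points defined at end-diastole."""

    reference: np.ndarray      # (N, 2) mm
    trajectories: np.ndarray   # (F, N, 2) mm
    valid: np.ndarray          # (F, N) bool, monotone non-increasing in F

    def __post_init__(self):
        assert self.trajectories.shape[1:] == (len(self.reference), 2)
        assert np.allclose(self.trajectories[0], self.reference)

    @property
    def n_points(self) -> int:
        return len(self.reference)

    @property
    def n_frames(self) -> int:
        return self.trajectories.shape[0]

    @property
    def always_valid(self) -> np.ndarray:
        return self.valid.all(axis=0)


def seed_points(ed_mask: np.ndarray, pixel_spacing: float,
                upsample: int = 1) -> np.ndarray:
    """Material-point seeds: one per end-diastolic myocardial pixel centre,
    or an upsample x upsample subgrid of each masked pixel."""
    cx, cy = pixel_center_coords(ed_mask.shape, pixel_spacing)
    base = np.column_stack([cx[ed_mask], cy[ed_mask]])
    if upsample <= 1:
        return base
    offs = (np.arange(upsample) + 0.5) / upsample - 0.5
    ox, oy = np.meshgrid(offs, offs)
    shifts = np.column_stack([ox.ravel(), oy.ravel()]) * pixel_spacing
    return (base[:, None, :] + shifts[None, :, :]).reshape(-1, 2)


def track_points(field: DisplacementField, ed_mask: np.ndarray = None,
                 upsample: int = 1, residual_tol_px: float = 0.1,
                 min_valid_frac: float = 0.5, mls_k: int = 20,
                 mls_order: int = 2) -> MaterialPointSet:
    """Track material points through the cycle by inverse interpolation.

    For each frame t the position x(t) of the point with reference position X
    is found by scattered interpolation of the forward map sampled at the
    myocardial pixels (X_i = x_i - u_i -> x_i), then checked against the
    consistency residual ||x - u(x, t) - X||; points whose residual exceeds
    ``residual_tol_px`` pixels are flagged invalid (and stay invalid).
    """
    if ed_mask is None:
        ed_mask = field.mask[0]
    ps = field.pixel_spacing
    X = seed_points(ed_mask, ps, upsample)
    n_pts, n_frames = len(X), field.n_frames
    traj = np.empty((n_frames, n_pts, 2))
    traj[0] = X
    valid = np.ones((n_frames, n_pts), dtype=bool)
    tol = residual_tol_px * ps
    for f in range(1, n_frames):
        X_i, x_i = field.reference_scatter(f)
        if len(X_i) < 4:
            raise TrackingError(f"frame {f}: empty displacement field")
        x_pred = mls_interp(X_i, x_i, X, k=mls_k, order=mls_order)
        x_scatter, u_scatter = field.scatter(f)
        u_at_pred = mls_interp(x_scatter, u_scatter, x_pred, k=mls_k,
                               order=mls_order)
        residual = np.linalg.norm(x_pred - u_at_pred - X, axis=1)
        valid[f] = valid[f - 1] & (residual < tol) & np.isfinite(residual)
        traj[f] = x_pred
        frac = valid[f].mean()
        if frac < min_valid_frac:
            raise TrackingError(
                f"tracking failure: only {100 * frac:.0f}% of points valid at "
                f"frame {f}"
            )
    return MaterialPointSet(reference=X, trajectories=traj, valid=valid)


# --------------------------------------------------------------------- strain


def _design_matrix(dX: np.ndarray, order: int) -> np.ndarray:
    x, y = dX[:, 0], dX[:, 1]
    cols = [np.ones(len(dX)), x, y]
    if order >= 2:
        cols += [x * x, x * y, y * y]
    if order >= 3:
        cols += [x**3, x * x * y, x * y * y, y**3]
    return np.column_stack(cols)


def deformation_gradients(points: MaterialPointSet, radius: float,
                          order: int = 1, min_neighbors: int = 6):
    """Deformation gradient F for every point and frame.

    A polynomial (affine for ``order=1``) model of current position against
    reference offsets is fitted by least squares over all always-valid
    neighbours within ``radius`` mm of each reference position; F is the
    linear part evaluated at the point.  Exact for affine motions.

    Returns
    -------
    F : (n_frames, n_points, 2, 2) array, NaN where the fit is invalid
    ok : (n_points,) bool, False where the neighbourhood was insufficient
    """
    n_coef = {1: 3, 2: 6, 3: 10}[order]
    need = max(min_neighbors, n_coef)
    usable = points.always_valid
    ref = points.reference
    pool = ref[usable]
    pool_idx = np.flatnonzero(usable)
    tree = cKDTree(pool)
    n_frames, n_pts = points.n_frames, points.n_points
    F = np.full((n_frames, n_pts, 2, 2), np.nan)
    ok = np.zeros(n_pts, dtype=bool)
    traj = points.trajectories
    for i in range(n_pts):
        nb = tree.query_ball_point(ref[i], radius)
        if len(nb) < need:
            continue
        gidx = pool_idx[nb]
        dX = pool[nb] - ref[i]
        A = _design_matrix(dX, order)
        # guard against rank deficiency (e.g. collinear neighbourhoods)
        if np.linalg.matrix_rank(A.T @ A) < A.shape[1]:
            continue
        P = np.linalg.pinv(A)
        targets = traj[:, gidx, :]             # (F, k, 2)
        coef = np.einsum("ck,fkm->fcm", P, targets)
        F[:, i, :, :] = np.transpose(coef[:, 1:3, :], (0, 2, 1))
        ok[i] = True
    return F, ok


def fit_deformation_gradient(points: MaterialPointSet, index: int, frame: int,
                             radius: float, order: int = 1) -> np.ndarray:
    """F for a single point/frame (NaN matrix if the fit is invalid)."""
    sub = MaterialPointSet(
        reference=points.reference,
        trajectories=points.trajectories[: frame + 1],
        valid=points.valid[: frame + 1],
    )
    F, ok = deformation_gradients(sub, radius, order=order)
    return F[frame, index]


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """E = (F^T F - I)/2 for an (..., 2, 2) stack."""
    C = np.einsum("...ji,...jk->...ik", F, F)
    return 0.5 * (C - np.eye(2))


def engineering_from_green(E_dd: np.ndarray) -> np.ndarray:
    """Engineering strain (%) along a direction from its Green strain."""
    return 100.0 * (np.sqrt(np.clip(2.0 * E_dd + 1.0, 0.0, None)) - 1.0)


def project_strain(E: np.ndarray, reference_position: np.ndarray,
                   centroid: np.ndarray):
    """Radial/circumferential engineering strains (%) of one strain tensor.

    The radial unit vector points from the (fixed, end-diastolic) centroid to
    the point's reference position; the circumferential unit vector is its
    90-degree counter-clockwise rotation.
    """
    v = np.asarray(reference_position, float) - np.asarray(centroid, float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("reference position coincides with centroid")
    e_r = v / norm
    e_c = np.array([-e_r[1], e_r[0]])
    err = engineering_from_green(e_r @ E @ e_r)
    ecc = engineering_from_green(e_c @ E @ e_c)
    return err, ecc


def directional_strains(F: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Engineering strain (%) of an (F, N, 2, 2) gradient stack along
    per-point unit directions (N, 2)."""
    E = green_lagrange(F)
    E_dd = np.einsum("ni,fnij,nj->fn", directions, E, directions)
    return engineering_from_green(E_dd)


# ------------------------------------------------------- layers and segments


def _radius_lookup(contour: np.ndarray, centroid: np.ndarray):
    """Radius-versus-angle interpolator for a star-shaped contour."""
    d = contour - centroid
    theta = np.arctan2(d[:, 1], d[:, 0])
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    theta, rad = theta[order], rad[order]
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    rad_ext = np.concatenate([rad, rad, rad])

    def lookup(query):
        return np.interp(query, theta_ext, rad_ext)

    return lookup


def wall_centroid(contours: ContourSet) -> np.ndarray:
    """Area centroid of the end-diastolic epicardial contour."""
    c = Polygon(contours.epicardium).centroid
    return np.array([c.x, c.y])


def assign_layers_segments(points: MaterialPointSet, contours: ContourSet,
                           slice_label: str, origin_angle_deg: float = 90.0):
    """Wall depth, circumferential angle, and 16-segment id per point.

    Depth is the normalised endo-to-epi distance along the centroid ray
    (0 = endocardium, 1 = epicardium); segments split the angle into 6/6/4
    equal sectors for basal/mid/apical slices, counted counter-clockwise from
    ``origin_angle_deg``.  Points outside the annulus (beyond a 10% margin)
    are flagged excluded.
    """
    centroid = wall_centroid(contours)
    v = points.reference - centroid
    theta = np.arctan2(v[:, 1], v[:, 0])
    rho = np.hypot(v[:, 0], v[:, 1])
    r_endo = _radius_lookup(contours.endocardium, centroid)(theta)
    r_epi = _radius_lookup(contours.epicardium, centroid)(theta)
    wall = np.maximum(r_epi - r_endo, 1e-9)
    depth = (rho - r_endo) / wall
    excluded = (depth < -0.1) | (depth > 1.1)
    depth = np.clip(depth, 0.0, 1.0)
    n_seg = SEGMENT_COUNTS[slice_label]
    width = 2 * np.pi / n_seg
    rel = np.mod(theta - np.radians(origin_angle_deg), 2 * np.pi)
    segment_id = SEGMENT_OFFSETS[slice_label] + 1 + (rel // width).astype(int)
    return depth, theta, segment_id, excluded


def layer_of_depth(depth: np.ndarray) -> np.ndarray:
    """Layer label per point from transmural thirds."""
    out = np.empty(len(depth), dtype=object)
    for name, (lo, hi) in LAYER_BANDS.items():
        out[(depth >= lo) & (depth < hi)] = name
    out[depth >= 1.0] = "epi"
    return out


# ------------------------------------------------------------------- curves


def layer_curves(strain: np.ndarray, depth: np.ndarray, use: np.ndarray,
                 method: str = "transmural_fit") -> dict:
    """Per-layer strain curves from per-point curves.

    ``transmural_fit`` (default) fits strain linearly against wall depth at
    every frame and evaluates the fit at depth 0 / 0.5 / 1, so the reported
    subendocardial and subepicardial values refer to the wall surfaces;
    ``band_mean`` averages points within each transmural third.
    """
    strain = np.asarray(strain)
    curves = {}
    if method == "transmural_fit":
        d = depth[use]
        A = np.column_stack([np.ones(d.size), d])
        coef, *_ = np.linalg.lstsq(A, strain[:, use].T, rcond=None)
        for name, d_eval in LAYER_EVAL_DEPTH.items():
            curves[name] = coef[0] + coef[1] * d_eval
    elif method == "band_mean":
        layers = layer_of_depth(depth)
        for name in LAYERS:
            sel = use & (layers == name)
            curves[name] = strain[:, sel].mean(axis=1)
    else:
        raise ValueError(f"unknown layer method {method!r}")
    return curves


def segment_curves(strain: np.ndarray, segment_id: np.ndarray,
                   use: np.ndarray) -> dict:
    out = {}
    for seg in np.unique(segment_id[use]):
        sel = use & (segment_id == seg)
        out[int(seg)] = strain[:, sel].mean(axis=1)
    return out


def sector_curves(strain: np.ndarray, theta: np.ndarray, use: np.ndarray,
                  n_sectors: int = 24, origin_angle_deg: float = 90.0):
    """(n_frames, n_sectors) mean strain per equal angular sector."""
    rel = np.mod(theta - np.radians(origin_angle_deg), 2 * np.pi)
    sector = (rel // (2 * np.pi / n_sectors)).astype(int)
    out = np.full((strain.shape[0], n_sectors), np.nan)
    for j in range(n_sectors):
        sel = use & (sector == j)
        if sel.any():
            out[:, j] = strain[:, sel].mean(axis=1)
    return out


def peak_strain(curve, direction: str) -> float:
    """Peak of a strain-versus-time curve: the minimum for circumferential
    and longitudinal strain (maximum shortening), the maximum for radial."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty strain curve")
    if direction in ("circumferential", "longitudinal", "ecc", "ell"):
        return float(np.nanmin(curve))
    if direction in ("radial", "err"):
        return float(np.nanmax(curve))
    raise ValueError(f"unknown direction {direction!r}")
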