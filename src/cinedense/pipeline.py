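"""End-to-end study analysis.

Runs the full chain for one five-view study: magnitude masking, phase
unwrapping and decoding, tissue tracking, strain tensor estimation, layer
and 16-segment aggregation, twist/torsion, CURE/RURE, and volumetrics,
producing the per-subject scalar metrics that feed the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from . import kinematics as kin
from .globalfn import torsion, twist_angle, uniformity_index
from .interp import mls_interp
from .model import LONG_AXIS_LABELS, SHORT_AXIS_LABELS, DenseStudy
from .phantom import plan_slices
from .phase import compute_displacement_field, propagate_contours
from .volumetrics import compute_volumetry, reconstruct_surface


@dataclass
class AnalysisSettings:
    """Tunable parameters of the analysis chain.

    ``upsample`` seeds an n x n subgrid of material points per end-diastolic
    myocardial pixel; ``fit_order`` > 1 uses a local polynomial displacement
    model (its linear part at the point gives F), which removes the boundary
    and wall-curvature bias of a plain affine fit on the few-pixel-thick
    mouse wall.
    """

    upsample: int = 2
    fit_radius_px: float = 2.0
    fit_order: int = 3
    min_neighbors: int = 20
    n_sectors: int = 24
    layer_method: str = "transmural_fit"
    origin_angle_deg: float = 90.0
    apical_exclusion_frac: float = 0.3
    volumetry: bool = True


@dataclass
class SliceAnalysis:
    label: str
    times: np.ndarray
    points: "kin.MaterialPointSet"
    centroid: np.ndarray
    depth: np.ndarray
    theta: np.ndarray
    segment_id: np.ndarray
    use: np.ndarray
    strains: dict          # direction -> (n_frames, n_points) percent
    layer: dict            # direction -> layer -> curve
    segment: dict          # direction -> segment id -> curve
    sector: dict = field(default_factory=dict)   # direction -> (F, n_sectors)
    twist: np.ndarray = None


@dataclass
class LongAxisAnalysis:
    label: str
    times: np.ndarray
    axis_length_ed: float   # epicardial long-axis length, mm
    layer: dict             # layer -> ell curve (%)


@dataclass
class StudyAnalysis:
    subject_id: str
    group_label: str
    times: np.ndarray
    short_axis: dict
    long_axis: dict
    metrics: dict

    def metrics_row(self) -> dict:
        row = {"subject_id": self.subject_id, "group": self.group_label}
        row.update(self.metrics)
        return row


def _polygon_distances(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    boundary = shapely.LinearRing(polygon)
    return shapely.distance(shapely.points(points), boundary)


def _long_axis_frame(epicardium: np.ndarray):
    """(apex point, unit axis apex->base, length) of a long-axis epi contour.

    Orientation convention of the study container: the apex is rendered at
    the bottom of long-axis images (larger image y).
    """
    verts = np.asarray(epicardium, dtype=float)
    center = verts.mean(axis=0)
    u, s, vt = np.linalg.svd(verts - center, full_matrices=False)
    axis = vt[0]
    proj = (verts - center) @ axis
    length = float(proj.max() - proj.min())
    p_lo = center + proj.min() * axis
    p_hi = center + proj.max() * axis
    apex, base = (p_lo, p_hi) if p_lo[1] > p_hi[1] else (p_hi, p_lo)
    return apex, (base - apex) / length, length


def analyze_short_axis_slice(study: DenseStudy, label: str,
                             settings: AnalysisSettings,
                             fld=None) -> SliceAnalysis:
    sl = study.slices[label]
    ps = sl.meta.pixel_spacing
    if fld is None:
        fld = compute_displacement_field(sl)
    pts = kin.track_points(fld, upsample=settings.upsample)
    contours = study.ed_contours[label]
    centroid = kin.wall_centroid(contours)
    depth, theta, segment_id, excluded = kin.assign_layers_segments(
        pts, contours, label, settings.origin_angle_deg)
    F, ok = kin.deformation_gradients(
        pts, radius=settings.fit_radius_px * ps, order=settings.fit_order,
        min_neighbors=settings.min_neighbors)
    use = ok & ~excluded & pts.always_valid
    v = pts.reference - centroid
    e_r = v / np.linalg.norm(v, axis=1, keepdims=True)
    e_c = np.column_stack([-e_r[:, 1], e_r[:, 0]])
    strains = {"ecc": kin.directional_strains(F, e_c),
               "err": kin.directional_strains(F, e_r)}
    layer = {d: kin.layer_curves(s, depth, use, settings.layer_method)
             for d, s in strains.items()}
    segment = {d: kin.segment_curves(s, segment_id, use)
               for d, s in strains.items()}
    sector = {d: kin.sector_curves(s, theta, use, settings.n_sectors,
                                   settings.origin_angle_deg)
              for d, s in strains.items()}
    twist = twist_angle(pts, centroid)
    return SliceAnalysis(
        label=label, times=np.asarray(sl.meta.frame_times), points=pts,
        centroid=centroid, depth=depth, theta=theta, segment_id=segment_id,
        use=use, strains=strains, layer=layer, segment=segment, sector=sector,
        twist=twist)


def analyze_long_axis_slice(study: DenseStudy, label: str,
                            settings: AnalysisSettings,
                            fld=None) -> LongAxisAnalysis:
    sl = study.slices[label]
    ps = sl.meta.pixel_spacing
    if fld is None:
        fld = compute_displacement_field(sl)
    pts = kin.track_points(fld, upsample=settings.upsample)
    contours = study.ed_contours[label]
    d_endo = _polygon_distances(pts.reference, contours.endocardium)
    d_epi = _polygon_distances(pts.reference, contours.epicardium)
    depth = np.clip(d_endo / np.maximum(d_endo + d_epi, 1e-9), 0.0, 1.0)
    apex, axis, length = _long_axis_frame(contours.epicardium)
    s_axis = (pts.reference - apex) @ axis
    apical = s_axis < settings.apical_exclusion_frac * length
    # wall tangent = perpendicular of the local transmural (depth-gradient)
    # direction, estimated by a local linear fit of depth
    grad = _local_gradient(pts.reference, depth)
    gnorm = np.linalg.norm(grad, axis=1)
    e_t = grad / np.maximum(gnorm, 1e-12)[:, None]
    e_l = np.column_stack([-e_t[:, 1], e_t[:, 0]])
    F, ok = kin.deformation_gradients(
        pts, radius=settings.fit_radius_px * ps, order=settings.fit_order,
        min_neighbors=settings.min_neighbors)
    use = ok & ~apical & pts.always_valid & (gnorm > 1e-6)
    ell = kin.directional_strains(F, e_l)
    layer = kin.layer_curves(ell, depth, use, settings.layer_method)
    return LongAxisAnalysis(label=label, times=np.asarray(sl.meta.frame_times),
                            axis_length_ed=length, layer=layer)


def _local_gradient(points: np.ndarray, values: np.ndarray,
                    k: int = 16) -> np.ndarray:
    """Per-point gradient of a scattered scalar field by local linear fits."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    k = min(k, len(points))
    dist, idx = tree.query(points, k=k)
    nb = points[idx] - points[:, None, :]
    ones = np.ones(nb.shape[:2] + (1,))
    A = np.concatenate([ones, nb], axis=2)
    G = np.einsum("nki,nkj->nij", A, A) + 1e-9 * np.eye(3)
    rhs = np.einsum("nki,nk->ni", A, values[idx])
    coef = np.linalg.solve(G, rhs[..., None])[..., 0]
    return coef[:, 1:]


def longitudinal_strain(two_chamber: LongAxisAnalysis,
                        four_chamber: LongAxisAnalysis) -> dict:
    """Average longitudinal layer curves of the two long-axis views."""
    if two_chamber is None or four_chamber is None:
        raise ValueError("both long-axis views are required")
    return {layer: 0.5 * (two_chamber.layer[layer] + four_chamber.layer[layer])
            for layer in two_chamber.layer}


def _volumetry(study: DenseStudy, sa_fields: dict, la_fields: dict):
    """Cavity-volume curve, volumetry result, and ES frame index."""
    prop = {}
    for label in SHORT_AXIS_LABELS:
        prop[label] = propagate_contours(study.ed_contours[label],
                                         sa_fields[label])
    la_prop = {}
    for label in LONG_AXIS_LABELS:
        la_prop[label] = propagate_contours(study.ed_contours[label],
                                            la_fields[label])
    n_frames = sa_fields["mid"].n_frames
    # per-frame long-axis extents, averaged over the two views, measured
    # along each view's fixed end-diastolic axis
    frames_geom = []
    for f in range(n_frames):
        epi_len, endo_apex, base = [], [], []
        for label in LONG_AXIS_LABELS:
            apex0, axis, _ = _long_axis_frame(study.ed_contours[label].epicardium)
            cs = la_prop[label][f]
            p_epi = (cs.epicardium - apex0) @ axis
            p_endo = (cs.endocardium - apex0) @ axis
            epi_len.append(p_epi.max() - p_epi.min())
            endo_apex.append(p_endo.min() - p_epi.min())
            base.append(p_epi.max() - p_epi.min())
        frames_geom.append({"epi_len": np.mean(epi_len),
                            "endo_apex": np.mean(endo_apex),
                            "base": np.mean(base)})
    l_es = min(g["epi_len"] for g in frames_geom)
    slice_z = plan_slices(l_es)
    volumes = np.empty(n_frames)
    endo_surfaces = []
    for f in range(n_frames):
        g = frames_geom[f]
        surf = reconstruct_surface(
            {l: prop[l][f].endocardium for l in SHORT_AXIS_LABELS},
            slice_z, apex_z=g["endo_apex"], base_z=g["base"])
        endo_surfaces.append(surf)
        volumes[f] = surf.volume()
    es_frame = int(np.argmin(volumes))
    epi_ed = reconstruct_surface(
        {l: study.ed_contours[l].epicardium for l in SHORT_AXIS_LABELS},
        slice_z, apex_z=0.0, base_z=frames_geom[0]["base"])
    result = compute_volumetry(endo_surfaces[0], endo_surfaces[es_frame], epi_ed)
    return volumes, result, es_frame


def analyze_study(study: DenseStudy,
                  settings: AnalysisSettings = None) -> StudyAnalysis:
    """Run the full analysis chain on one study."""
    settings = settings or AnalysisSettings()
    fields = {label: compute_displacement_field(study.slices[label])
              for label in study.slices}
    sa = {label: analyze_short_axis_slice(study, label, settings, fields[label])
          for label in SHORT_AXIS_LABELS}
    la = {label: analyze_long_axis_slice(study, label, settings, fields[label])
          for label in LONG_AXIS_LABELS}
    times = sa["mid"].times

    metrics = {}
    for direction, key in (("ecc", "ecc"), ("err", "err")):
        for layer in kin.LAYERS:
            curve = np.mean([sa[l].layer[direction][layer]
                             for l in SHORT_AXIS_LABELS], axis=0)
            metrics[f"{key}_{layer}"] = kin.peak_strain(curve, direction)
    ell_layers = longitudinal_strain(la["two_chamber"], la["four_chamber"])
    for layer, curve in ell_layers.items():
        metrics[f"ell_{layer}"] = kin.peak_strain(curve, "ell")

    length_cm = np.mean([la[l].axis_length_ed for l in LONG_AXIS_LABELS]) / 10.0
    tors = torsion(sa["basal"].twist, sa["apical"].twist, length_cm)
    metrics["peak_torsion_deg_per_cm"] = tors.peak_torsion
    for label in SHORT_AXIS_LABELS:
        metrics[f"peak_twist_{label}"] = float(
            sa[label].twist[np.argmax(np.abs(sa[label].twist))])

    metrics["cure"] = float(np.mean(
        [uniformity_index(sa[l].sector["ecc"]).index for l in SHORT_AXIS_LABELS]))
    metrics["rure"] = float(np.mean(
        [uniformity_index(sa[l].sector["err"]).index for l in SHORT_AXIS_LABELS]))

    meta = study.slices["mid"].meta
    metrics["heart_rate_bpm"] = 60000.0 / (meta.n_frames * meta.repetition_time)

    if settings.volumetry:
        volumes, volumetry, es_frame = _volumetry(
            study, {l: fields[l] for l in SHORT_AXIS_LABELS},
            {l: fields[l] for l in LONG_AXIS_LABELS})
        metrics.update(edv_ul=volumetry.edv, esv_ul=volumetry.esv,
                       ef_pct=volumetry.ef, mass_mg=volumetry.mass,
                       mass_to_edv=volumetry.mass_to_edv)
        metrics["es_frame"] = es_frame

    return StudyAnalysis(subject_id=study.subject_id,
                         group_label=study.group_label, times=times,
                         short_axis=sa, long_axis=la, metrics=metrics)


def strain_curves_frame(analysis: StudyAnalysis) -> pd.DataFrame:
    """Tidy per-segment and per-layer strain curves for export."""
    rows = []
    for label, sl in analysis.short_axis.items():
        for direction in ("ecc", "err"):
            for layer, curve in sl.layer[direction].items():
                for t, v in zip(sl.times, curve):
                    rows.append((label, "layer", layer, direction, t, v))
            for seg, curve in sl.segment[direction].items():
                for t, v in zip(sl.times, curve):
                    rows.append((label, "segment", str(seg), direction, t, v))
    for label, view in analysis.long_axis.items():
        for layer, curve in view.layer.items():
            for t, v in zip(view.times, curve):
                rows.append((label, "layer", layer, "ell", t, v))
    return pd.DataFrame(rows, columns=["slice", "kind", "name", "direction",
                                       "frame_time_ms", "strain_percent"])
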