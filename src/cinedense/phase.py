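"""Displacement-phase processing.

Turns wrapped displacement-encoded phase images into physical displacement
fields (mm) and propagates end-diastolic contours through the cardiac cycle
(motion-guided segmentation).  The DENSE phase of a pixel encodes the
displacement of the tissue currently at that pixel relative to its
end-diastolic position: u = phi / (2 * pi * ke).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .interp import mls_interp, pixel_center_coords
from .model import ContourSet, DenseSlice


class PhaseProcessingError(ValueError):
    pass


class ContourPropagationError(PhaseProcessingError):
    pass


def wrap(phase):
    """Wrap phase (radians) into the half-open interval (-pi, pi].

    The boundary maps to +pi, so wrap(pi) == wrap(-pi) == pi.
    """
    scalar = np.isscalar(phase)
    w = np.mod(np.asarray(phase, dtype=float), 2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    return float(w) if scalar else w


def decode(unwrapped_phase, ke: float):
    """Convert unwrapped phase (radians) to displacement (mm)."""
    if not ke > 0:
        raise PhaseProcessingError(f"encoding frequency must be > 0, got {ke}")
    return np.asarray(unwrapped_phase, dtype=float) / (2.0 * np.pi * ke)


def _phase_quality(wrapped: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel quality = negative variance of wrapped gradients to the
    4-neighbours inside the mask (higher is smoother)."""
    ny, nx = wrapped.shape
    quality = np.full((ny, nx), -np.inf)
    idx = np.argwhere(mask)
    for r, c in idx:
        grads = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
                grads.append(wrap(wrapped[rr, cc] - wrapped[r, c]))
        if grads:
            quality[r, c] = -float(np.var(grads))
    return quality


def unwrap_masked(wrapped: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Quality-guided region-growing phase unwrapping over a connected mask.

    Growth starts from the highest-quality pixel and proceeds through a
    max-heap of mask pixels adjacent to the unwrapped region; each pixel is
    unwrapped against the mean of its already-unwrapped 4-neighbours.  Ties
    in quality are broken by row-major pixel index, making the result fully
    deterministic.  The output equals the true smooth field up to a single
    global multiple of 2*pi.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    labels, n_comp = ndimage.label(mask)
    if n_comp != 1:
        raise PhaseProcessingError(f"{n_comp} connected components in mask")
    quality = _phase_quality(wrapped, mask)
    out = np.array(wrapped, copy=True)
    done = np.zeros_like(mask)
    ny, nx = mask.shape

    seed_flat = int(np.argmax(np.where(mask, quality, -np.inf)))
    sr, sc = divmod(seed_flat, nx)
    done[sr, sc] = True
    heap = []

    def push_neighbours(r, c):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc] and not done[rr, cc]:
                heapq.heappush(heap, (-quality[rr, cc], rr * nx + cc))

    push_neighbours(sr, sc)
    while heap:
        _, flat = heapq.heappop(heap)
        r, c = divmod(flat, nx)
        if done[r, c]:
            continue
        refs = [out[r + dr, c + dc]
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                if 0 <= r + dr < ny and 0 <= c + dc < nx and done[r + dr, c + dc]]
        ref = float(np.mean(refs))
        out[r, c] = ref + wrap(wrapped[r, c] - ref)
        done[r, c] = True
        push_neighbours(r, c)
    return out


@dataclass
class DisplacementField:
    """Per-frame displacement of the tissue at each myocardial pixel,
    relative to its end-diastolic position.

    ``u_x``/``u_y`` are (n_frames, ny, nx) arrays in mm, NaN outside the
    per-frame myocardial mask.
    """

    u_x: np.ndarray
    u_y: np.ndarray
    mask: np.ndarray
    pixel_spacing: float

    @property
    def n_frames(self) -> int:
        return self.u_x.shape[0]

    def scatter(self, frame: int):
        """(current positions x_i, displacements u_i) of masked pixels (mm)."""
        cx, cy = pixel_center_coords(self.u_x.shape[1:], self.pixel_spacing)
        m = self.mask[frame]
        x = np.column_stack([cx[m], cy[m]])
        u = np.column_stack([self.u_x[frame][m], self.u_y[frame][m]])
        return x, u

    def reference_scatter(self, frame: int):
        """(reference positions X_i = x_i - u_i, current positions x_i)."""
        x, u = self.scatter(frame)
        return x - u, x


def magnitude_masks(dense_slice: DenseSlice, threshold: float = 0.5) -> np.ndarray:
    """Per-frame myocardial mask from the magnitude images (bright annulus)."""
    mag = dense_slice.magnitude
    cut = threshold * mag.max()
    return mag > cut


def compute_displacement_field(dense_slice: DenseSlice,
                               masks: np.ndarray = None) -> DisplacementField:
    """Unwrap, temporally anchor, and decode one slice into displacements.

    Spatial unwrapping leaves an unknown global multiple of 2*pi per frame;
    it is resolved by frame-to-frame consistency anchored at frame 0, where
    displacement is identically zero by the end-diastolic reference.
    """
    if masks is None:
        masks = magnitude_masks(dense_slice)
    ke = dense_slice.meta.encoding_frequency
    n = dense_slice.n_frames
    shape = dense_slice.shape
    u = {"x": np.full((n,) + shape, np.nan), "y": np.full((n,) + shape, np.nan)}
    prev = {"x": None, "y": None}
    prev_mask = None
    for f in range(n):
        m = masks[f]
        for comp, stack in (("x", dense_slice.phase_x), ("y", dense_slice.phase_y)):
            phi = unwrap_masked(stack[f], m)
            if f == 0:
                # displacement is zero at end-diastole: remove any global cycle
                k = np.round(np.median(phi[m]) / (2 * np.pi))
            else:
                overlap = m & prev_mask
                if overlap.sum() < 4:
                    overlap = m
                    ref = 0.0
                else:
                    ref = np.median(prev[comp][overlap])
                k = np.round((np.median(phi[overlap]) - ref) / (2 * np.pi))
            phi = phi - 2 * np.pi * k
            u[comp][f][m] = decode(phi[m], ke)
            prev[comp] = np.where(m, phi, 0.0)
        prev_mask = m
    return DisplacementField(u_x=u["x"], u_y=u["y"], mask=np.asarray(masks),
                             pixel_spacing=dense_slice.meta.pixel_spacing)


def propagate_contours(ed_contours: ContourSet, field: DisplacementField,
                       max_fail_frac: float = 0.1) -> list:
    """Propagate end-diastolic contours to every frame.

    Each end-diastolic vertex V is mapped to the frame-t position x solving
    x - u(x, t) = V by scattered interpolation of the forward map sampled at
    the myocardial pixels (reference position X_i = x_i - u_i -> x_i).
    Vertices farther than 2 pixels from any sampled reference position are
    flagged as failures; more than ``max_fail_frac`` failures on a contour
    raises.
    """
    out = []
    reach = 2.0 * field.pixel_spacing
    for f in range(field.n_frames):
        if f == 0:
            out.append(ContourSet(ed_contours.endocardium.copy(),
                                  ed_contours.epicardium.copy(), frame_index=0))
            continue
        X_i, x_i = field.reference_scatter(f)
        if len(X_i) < 4:
            raise ContourPropagationError(f"frame {f}: empty displacement field")
        from scipy.spatial import cKDTree

        tree = cKDTree(X_i)
        polys = {}
        for name, verts in (("endocardium", ed_contours.endocardium),
                            ("epicardium", ed_contours.epicardium)):
            d, _ = tree.query(verts)
            failed = d > reach
            if failed.mean() > max_fail_frac:
                raise ContourPropagationError(
                    f"frame {f}: {failed.sum()}/{len(verts)} {name} vertices "
                    f"unreachable"
                )
            moved = mls_interp(X_i, x_i, verts)
            # keep failed vertices consistent with their neighbours rather
            # than extrapolating from far-away tissue
            if failed.any():
                ok = ~failed
                moved[failed] = verts[failed] + np.mean(
                    moved[ok] - verts[ok], axis=0)
            if not Polygon(moved).is_valid:
                raise ContourPropagationError(
                    f"frame {f}: propagated {name} is not simple")
            polys[name] = moved
        polys["endocardium"] = _clamp_inside(polys["endocardium"],
                                             polys["epicardium"])
        out.append(ContourSet(polys["endocardium"], polys["epicardium"],
                              frame_index=f))
    return out


def _clamp_inside(endo: np.ndarray, epi: np.ndarray,
                  margin: float = 1e-3) -> np.ndarray:
    """Nudge endocardial vertices that interpolation pushed (marginally)
    outside the epicardium back just inside it."""
    import shapely

    epi_poly = Polygon(epi)
    outside = ~shapely.covers(epi_poly, shapely.points(endo))
    if not outside.any():
        return endo
    out = endo.copy()
    boundary = epi_poly.exterior
    centroid = np.array([epi_poly.centroid.x, epi_poly.centroid.y])
    for i in np.flatnonzero(outside):
        nearest = boundary.interpolate(boundary.project(shapely.points(out[i])))
        p = np.array([nearest.x, nearest.y])
        step = centroid - p
        out[i] = p + margin * step / max(np.linalg.norm(step), 1e-9)
    return out
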