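"""Scattered-data helpers shared by tracking and contour propagation."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def pixel_center_coords(shape: tuple, pixel_spacing: float):
    """Physical (x, y) mm coordinates of pixel centers for an image shape.

    Row r, column c maps to x = (c + 1/2) * spacing, y = (r + 1/2) * spacing
    (origin at the image corner).
    """
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * pixel_spacing
    ys = (np.arange(ny) + 0.5) * pixel_spacing
    cx, cy = np.meshgrid(xs, ys)
    return cx, cy


def mls_interp(points: np.ndarray, values: np.ndarray, queries: np.ndarray,
               k: int = 12, ridge: float = 1e-9, order: int = 1) -> np.ndarray:
    """Moving-least-squares (locally polynomial) scattered interpolation.

    Fits a weighted linear (``order=1``) or quadratic (``order=2``) model
    over the ``k`` nearest data points of each query and evaluates it at the
    query.  Exact for globally affine (resp. quadratic) fields, well-behaved
    at the edges of non-convex (annular) point clouds, and deterministic.

    Parameters
    ----------
    points : (M, 2) data locations
    values : (M,) or (M, m) data values
    queries : (N, 2) evaluation locations

    Returns
    -------
    (N,) or (N, m) interpolated values.
    """
    points = np.asarray(points, dtype=float)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    k = min(k, len(points))
    tree = cKDTree(points)
    dist, idx = tree.query(queries, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    nb = points[idx] - queries[:, None, :]          # (N, k, 2)
    scale = np.maximum(dist.mean(axis=1, keepdims=True), 1e-9)
    w = np.exp(-((dist / scale) ** 2))
    ones = np.ones(nb.shape[:2] + (1,))
    terms = [ones, nb]
    if order >= 2:
        terms.append(np.stack([nb[..., 0] ** 2, nb[..., 0] * nb[..., 1],
                               nb[..., 1] ** 2], axis=2))
    A = np.concatenate(terms, axis=2)               # (N, k, p)
    p = A.shape[2]
    Aw = A * w[..., None]
    G = np.einsum("nki,nkj->nij", Aw, A)
    G = G + ridge * np.eye(p)
    rhs = np.einsum("nki,nkm->nim", Aw, values[idx])
    coef = np.linalg.solve(G, rhs)                  # (N, p, m)
    out = coef[:, 0, :]
    return out[:, 0] if squeeze else out
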