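"""Shared geometry for the scene generators: smooth star-shaped cell
outlines and raster distance fields."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import distance_transform_edt
from skimage.draw import polygon as draw_polygon


def star_polygon(
    center: tuple[float, float],
    mean_radius: float,
    rng: np.random.Generator,
    *,
    n_control: int = 10,
    radial_sd_frac: float = 0.10,
    n_vertices: int = 200,
) -> np.ndarray:
    """Smooth, closed, non-self-intersecting outline around ``center``.

    The radius is a periodic cubic spline through ``n_control`` jittered
    control radii, so the curve is star-shaped about the center (a radius
    function of angle can never self-intersect). Returned as an (n, 2)
    open vertex list in the same coordinate convention as ``center``.
    """
    if n_control < 3:
        raise ValueError("need at least 3 control points")
    ang = np.linspace(0.0, 2 * np.pi, n_control, endpoint=False)
    radii = mean_radius * (1.0 + radial_sd_frac * rng.standard_normal(n_control))
    radii = np.clip(radii, 0.55 * mean_radius, 1.45 * mean_radius)
    spline = CubicSpline(
        np.append(ang, 2 * np.pi), np.append(radii, radii[0]), bc_type="periodic"
    )
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = spline(theta)
    offs = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return np.asarray(center, dtype=float) + offs


def rasterize_interior(poly_rc: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean interior mask of a (row, col) polygon on a raster."""
    rr, cc = draw_polygon(poly_rc[:, 0], poly_rc[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def boundary_distance_field(interior: np.ndarray) -> np.ndarray:
    """Approximate unsigned pixel distance to the interior/exterior
    interface, valid on both sides.

    Uses two Euclidean distance transforms; the half-pixel offset of the
    digitized interface is split symmetrically.
    """
    d_in = distance_transform_edt(interior)
    d_out = distance_transform_edt(~interior)
    return np.where(interior, d_in, d_out) - 0.5


def polyline_arclength_samples(
    poly: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_samples`` points drawn uniformly by arc length on a closed
    polygon (vertex list open, closure implied)."""
    closed = np.vstack([poly, poly[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = rng.uniform(0.0, cum[-1], size=n_samples)
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return closed[idx] + frac[:, None] * seg[idx]


def perimeter(poly: np.ndarray) -> float:
    closed = np.vstack([poly, poly[:1]])
    seg = np.diff(closed, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def stamp_gaussian(
    image: np.ndarray,
    center_rc: tuple[float, float],
    sigma_px: float,
    amplitude: float,
    *,
    truncate: float = 4.0,
) -> None:
    """Add a 2-D Gaussian spot in place, on a bounded local window only.

    Bounding the stamp keeps far-away pixels at *exactly* their previous
    value, which downstream exact-zero contracts rely on.
    """
    r0, c0 = center_rc
    half = int(np.ceil(truncate * sigma_px))
    rlo = max(int(np.floor(r0)) - half, 0)
    rhi = min(int(np.floor(r0)) + half + 1, image.shape[0])
    clo = max(int(np.floor(c0)) - half, 0)
    chi = min(int(np.floor(c0)) + half + 1, image.shape[1])
    if rlo >= rhi or clo >= chi:
        return
    rr = np.arange(rlo, rhi, dtype=float)[:, None]
    cc = np.arange(clo, chi, dtype=float)[None, :]
    image[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2)
    )
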