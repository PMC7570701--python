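"""Deformable ventral fish silhouette: parameters, contour synthesis, rasterization.

The silhouette is controlled by an eight-component parameter set: snout-tip
image position (``sx``, ``sy``), spine arc length ``l``, head angle ``alpha``
relative to the image x axis, a global spine bending angle ``theta_b``, a
widths vector ``w`` (ordered head to tail, first element is the maximum body
width), and a terminal caudal segment of length ``lp`` and slope ``sp`` that
closes the outline at the tail.

Image coordinates follow the usual raster convention: origin at the top-left
pixel, x rightward (columns), y downward (rows), angles in degrees measured
from the +x axis towards +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "TunaModelParams",
    "InvalidModelError",
    "spine_points",
    "silhouette_polygon",
    "contour_points",
    "render_silhouette",
    "model_fei",
]

#: spine samples used when synthesizing the outline polygon
N_SPINE = 48

#: fraction of the spine where the first (maximum) width node sits
_W_FIRST_STATION = 0.2


class InvalidModelError(ValueError):
    """Raised for silhouette parameters that cannot describe a fish."""


@dataclass
class TunaModelParams:
    """Parameter vector of the deformable ventral silhouette model."""

    sx: float
    sy: float
    l: float
    alpha_deg: float
    theta_b_deg: float
    w: np.ndarray
    lp: float
    sp: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.isfinite(self.l) or self.l <= 0:
            raise InvalidModelError(f"spine length must be positive, got {self.l}")
        if self.w.ndim != 1 or self.w.size == 0:
            raise InvalidModelError("widths vector must be a non-empty 1-D array")
        if np.any(~np.isfinite(self.w)) or np.any(self.w <= 0):
            raise InvalidModelError("all widths must be positive and finite")
        if self.w[0] < self.w.max() - 1e-9:
            raise InvalidModelError("w[0] must be the maximum width")
        if self.lp < 0:
            raise InvalidModelError("caudal segment length must be non-negative")

    def scaled(self, factor: float) -> "TunaModelParams":
        """Return a copy with all length-like parameters scaled by ``factor``."""
        return TunaModelParams(
            sx=self.sx,
            sy=self.sy,
            l=self.l * factor,
            alpha_deg=self.alpha_deg,
            theta_b_deg=self.theta_b_deg,
            w=self.w * factor,
            lp=self.lp * factor,
            sp=self.sp,
        )


def spine_points(params: TunaModelParams, n: int = N_SPINE):
    """Sample the spine as a circular arc.

    The tangent angle varies linearly with arc length from
    ``alpha - theta_b/2`` at the snout to ``alpha + theta_b/2`` at the tail,
    so ``alpha`` is the chord direction and ``theta_b`` the total turning.

    Returns ``(points, tangent_angles_rad)`` where ``points`` is ``(n, 2)``
    in (x, y) pixels.
    """
    t = np.linspace(0.0, 1.0, n)
    a = np.radians(params.alpha_deg)
    k = np.radians(params.theta_b_deg)
    phi = a + k * (t - 0.5)
    if abs(k) < 1e-9:
        x = params.sx + params.l * t * np.cos(a)
        y = params.sy + params.l * t * np.sin(a)
    else:
        phi0 = a - 0.5 * k
        x = params.sx + params.l * (np.sin(phi) - np.sin(phi0)) / k
        y = params.sy - params.l * (np.cos(phi) - np.cos(phi0)) / k
    return np.column_stack([x, y]), phi


def _pchip_slopes(h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Shape-preserving (Fritsch-Carlson) node derivatives."""
    n = h.size + 1
    m = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = 2.0 * h[1:] + h[:-1]
        w2 = h[1:] + 2.0 * h[:-1]
        hm = (w1 + w2) / (w1 / d[:-1] + w2 / d[1:])
    keep = (np.sign(d[:-1]) * np.sign(d[1:])) > 0
    m[1:-1] = np.where(keep, np.nan_to_num(hm), 0.0)

    def edge(h0, h1, d0, d1):
        s = ((2.0 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if np.sign(s) != np.sign(d0):
            return 0.0
        if np.sign(d0) != np.sign(d1) and abs(s) > 3.0 * abs(d0):
            return 3.0 * d0
        return s

    m[0] = edge(h[0], h[1], d[0], d[1]) if n > 2 else d[0]
    m[-1] = edge(h[-1], h[-2], d[-1], d[-2]) if n > 2 else d[-1]
    return m


def _pchip_eval(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Monotone cubic Hermite interpolation (vectorized, no object churn)."""
    h = np.diff(x)
    d = np.diff(y) / h
    m = _pchip_slopes(h, d)
    i = np.clip(np.searchsorted(x, xq, side="right") - 1, 0, x.size - 2)
    t = (xq - x[i]) / h[i]
    t2 = t * t
    t3 = t2 * t
    h00 = 2 * t3 - 3 * t2 + 1
    h10 = t3 - 2 * t2 + t
    h01 = -2 * t3 + 3 * t2
    h11 = t3 - t2
    return (h00 * y[i] + h10 * h[i] * m[i]
            + h01 * y[i + 1] + h11 * h[i] * m[i + 1])


def _half_widths(params: TunaModelParams, t: np.ndarray) -> np.ndarray:
    """Half-width profile along the spine (zero at the snout tip).

    Width nodes sit at fixed fractional stations from ``_W_FIRST_STATION``
    to 1.0; the profile is interpolated with a shape-preserving cubic.
    """
    m = params.w.size
    if m == 1:
        nodes_t = np.array([0.0, _W_FIRST_STATION, 1.0])
        nodes_w = np.array([0.0, params.w[0], params.w[0]]) / 2.0
    else:
        nodes_t = np.concatenate([[0.0], np.linspace(_W_FIRST_STATION, 1.0, m)])
        nodes_w = np.concatenate([[0.0], params.w]) / 2.0
    return _pchip_eval(nodes_t, nodes_w, np.asarray(t, dtype=float))


def silhouette_polygon(params: TunaModelParams, n_spine: int = N_SPINE) -> np.ndarray:
    """Closed outline polygon of the silhouette, ``(k, 2)`` in (x, y) pixels.

    Sides run perpendicular to the spine at the local half-width; the tail is
    closed by a straight segment of length ``lp`` centered on the spine end,
    rotated by ``atan(sp)`` away from the spine normal.
    """
    pts, phi = spine_points(params, n_spine)
    t = np.linspace(0.0, 1.0, n_spine)
    hw = _half_widths(params, t)
    normal = np.column_stack([-np.sin(phi), np.cos(phi)])
    left = pts + normal * hw[:, None]
    right = pts - normal * hw[:, None]
    seg_ang = phi[-1] + np.pi / 2.0 + np.arctan(params.sp)
    u = np.array([np.cos(seg_ang), np.sin(seg_ang)])
    e1 = pts[-1] + u * params.lp / 2.0
    e2 = pts[-1] - u * params.lp / 2.0
    return np.vstack([left, e1, e2, right[::-1]])


def contour_points(params: TunaModelParams, n: int = 100,
                   n_spine: int = N_SPINE) -> np.ndarray:
    """Resample the outline polygon to ``n`` points uniform in arc length."""
    poly = silhouette_polygon(params, n_spine)
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise InvalidModelError("degenerate outline with zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def render_silhouette(params: TunaModelParams, image_size: tuple[int, int],
                      n_spine: int = N_SPINE):
    """Rasterize the filled silhouette.

    Parameters
    ----------
    image_size:
        (height, width) of the output binary image.

    Returns
    -------
    (mask, clipped):
        boolean image and a flag set when the outline extends beyond the
        image bounds (the rendered mask is then clipped).
    """
    poly = silhouette_polygon(params, n_spine)
    h, w = image_size
    clipped = bool(
        poly[:, 0].min() < 0 or poly[:, 1].min() < 0
        or poly[:, 0].max() > w - 1 or poly[:, 1].max() > h - 1
    )
    rr, cc = _draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask, clipped


def model_fei(params: TunaModelParams, edges: np.ndarray,
              n_contour: int = 100, tree: cKDTree | None = None) -> float:
    """Fitting error index: mean squared distance from model contour points
    to their nearest edge point, normalized by the squared spine length."""
    edges = np.asarray(edges, dtype=float)
    if edges.size == 0:
        raise ValueError("empty edge point list")
    if tree is None:
        tree = cKDTree(edges)
    pts = contour_points(params, n_contour)
    d, _ = tree.query(pts)
    return float(np.mean(d ** 2) / params.l ** 2)
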