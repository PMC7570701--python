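"""Frame segmentation, deformable silhouette fitting and visual tracking.

Fish are dark targets on a bright uniform background (a back panel). Each
frame is segmented with local thresholding, candidate blobs are filtered by
shape, density and size, blob boundaries are traced, and the eight-parameter
ventral silhouette model is fitted to the boundary by a deterministic
derivative-free local search started from the blob's principal axis (two
starts to resolve the head/tail ambiguity). Fits are associated across
frames into tracks by bounding-box overlap and length/direction similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from skimage.filters import threshold_local
from skimage.measure import find_contours
from skimage.measure import label as _sk_label, regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import opening as _opening

from .geometry import (
    InvalidModelError,
    TunaModelParams,
    contour_points,
    model_fei,
    silhouette_polygon,
)

__all__ = [
    "SegmentConfig",
    "BlobFilterConfig",
    "FitConfig",
    "TrackConfig",
    "Blob",
    "ModelFit",
    "Track",
    "segment_frame",
    "extract_blobs",
    "filter_blobs",
    "detect_edges",
    "fit_tuna_model",
    "compute_fei",
    "track_fish",
    "measure_in_image",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentConfig:
    block_size: int = 51      # local-threshold neighborhood (odd)
    offset: float = 25.0      # gray levels below local mean to call foreground
    dark_foreground: bool = True


@dataclass
class BlobFilterConfig:
    min_aspect_ratio: float = 1.6
    max_aspect_ratio: float = 12.0
    min_density: float = 0.12   # bbox fill fraction; low for diagonal fish
    max_density: float = 0.95
    min_length_px: float = 30.0
    max_length_px: float = 2000.0
    min_width_px: float = 6.0
    max_width_px: float = 500.0


@dataclass
class FitConfig:
    n_widths: int = 6
    n_contour: int = 100
    min_edge_points: int = 20
    max_fei: float = 0.002
    stage1_maxfev: int = 250
    stage2_maxfev: int = 900


@dataclass
class TrackConfig:
    max_gap: int = 2          # frames a track may skip and still be linked
    min_iou: float = 0.05
    len_tol: float = 0.10     # relative length difference
    dir_tol_deg: float = 20.0


@dataclass
class Blob:
    pixels: np.ndarray        # (k, 2) of (row, col)
    bbox: tuple               # (min_row, min_col, max_row, max_col) exclusive
    aspect_ratio: float
    pixel_density: float
    length_px: float
    width_px: float


@dataclass
class ModelFit:
    params: TunaModelParams
    fei: float
    frame_index: int
    accepted: bool
    t_s: float = np.nan       # frame timestamp, set by the pipeline

    @property
    def bbox_xyxy(self) -> tuple[float, float, float, float]:
        poly = silhouette_polygon(self.params)
        return (poly[:, 0].min(), poly[:, 1].min(),
                poly[:, 0].max(), poly[:, 1].max())

    @property
    def heading_deg(self) -> float:
        """Snout-to-tail chord direction, degrees in (-180, 180]."""
        a = self.params.alpha_deg % 360.0
        if a > 180.0:
            a -= 360.0
        return a


@dataclass
class Track:
    track_id: int
    fits: list = field(default_factory=list)

    @property
    def lengths_px(self) -> np.ndarray:
        return np.array([f.params.l for f in self.fits])

    @property
    def directions_deg(self) -> np.ndarray:
        return np.array([f.heading_deg for f in self.fits])


def segment_frame(frame: np.ndarray, cfg: SegmentConfig = SegmentConfig()) -> np.ndarray:
    """Local-threshold segmentation followed by opening and closing.

    The per-pixel threshold is the mean over a sliding ``block_size``
    neighborhood shifted by ``offset``; with ``dark_foreground`` pixels
    darker than that become foreground (set the flag to False for
    inverted-contrast input).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single-channel image")
    local_mean = threshold_local(img, cfg.block_size, method="mean")
    if cfg.dark_foreground:
        fg = img < local_mean - cfg.offset
    else:
        fg = img > local_mean + cfg.offset
    fg = _opening(fg, _SQUARE3)
    fg = _closing(fg, _SQUARE3)
    return fg.astype(bool)


def extract_blobs(b: np.ndarray) -> list[Blob]:
    """Connected components of a binary image with geometric features."""
    lab = _sk_label(np.asarray(b, dtype=bool), connectivity=2)
    blobs = []
    for rp in regionprops(lab):
        r0, c0, r1, c1 = rp.bbox
        h, w = r1 - r0, c1 - c0
        # rotation-invariant elongation from the principal axes
        minor = max(rp.axis_minor_length, 1.0)
        blobs.append(
            Blob(
                pixels=rp.coords,
                bbox=rp.bbox,
                aspect_ratio=max(rp.axis_major_length, 1.0) / minor,
                pixel_density=rp.area / (h * w),
                length_px=float(max(h, w)),
                width_px=float(min(h, w)),
            )
        )
    return blobs


def filter_blobs(blobs: list[Blob], cfg: BlobFilterConfig = BlobFilterConfig()) -> list[Blob]:
    """Conjunction of aspect-ratio, density and dimensional criteria."""
    return [
        b
        for b in blobs
        if cfg.min_aspect_ratio <= b.aspect_ratio <= cfg.max_aspect_ratio
        and cfg.min_density <= b.pixel_density <= cfg.max_density
        and cfg.min_length_px <= b.length_px <= cfg.max_length_px
        and cfg.min_width_px <= b.width_px <= cfg.max_width_px
    ]


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def detect_edges(b: np.ndarray, blob: Blob, subpixel: bool = False):
    """Ordered boundary points of a blob.

    Returns ``(edges, truncated)`` where ``edges`` is ``(k, 2)`` in (x, y)
    pixel coordinates ordered along the contour and ``truncated`` flags a
    blob touching the image border. By default the points are the boundary
    pixel centers (Moore-neighbor tracing); with ``subpixel`` the half-level
    marching-squares contour is returned instead, which removes the ~0.5 px
    inward bias of pixel centers and is preferred for model fitting.
    """
    if blob.pixels.size == 0:
        raise ValueError("empty blob")
    h, w = np.asarray(b).shape
    r0, c0, r1, c1 = blob.bbox
    truncated = r0 == 0 or c0 == 0 or r1 == h or c1 == w

    mask = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    mask[blob.pixels[:, 0] - r0 + 1, blob.pixels[:, 1] - c0 + 1] = True

    if subpixel:
        contours = find_contours(mask.astype(float), 0.5)
        contour = max(contours, key=len)
        pts = np.column_stack([contour[:, 1] - 1 + c0, contour[:, 0] - 1 + r0])
        return pts, truncated

    # start: topmost of the leftmost foreground pixels
    cols = np.nonzero(mask.any(axis=0))[0]
    start_c = cols[0]
    start_r = np.nonzero(mask[:, start_c])[0][0]
    start = (start_r, start_c)

    boundary = [start]
    if blob.pixels.shape[0] > 1:
        cur = start
        d = 7  # background guaranteed west of start; scan clockwise from NW
        seen_states = set()
        while True:
            step = None
            for k in range(8):
                dd = (d + k) % 8
                nr, nc = cur[0] + _MOORE[dd][0], cur[1] + _MOORE[dd][1]
                if mask[nr, nc]:
                    step = (nr, nc, dd)
                    break
            if step is None:  # isolated pixel
                break
            cur = (step[0], step[1])
            d = (step[2] + 6) % 8  # restart scan two steps back (clockwise)
            state = (cur, d)
            if state in seen_states:
                break
            seen_states.add(state)
            boundary.append(cur)

    seen = set()
    pts = []
    for r, c in boundary:
        if (r, c) not in seen:
            seen.add((r, c))
            pts.append((c - 1 + c0, r - 1 + r0))  # (x, y) in image coords
    return np.array(pts, dtype=float), truncated


def compute_fei(params: TunaModelParams, edges: np.ndarray,
                n_contour: int = 100) -> float:
    """Mean squared distance from model contour points to the nearest edge
    point, normalized by the squared spine length (scale-free)."""
    return model_fei(params, edges, n_contour=n_contour)


# --- fitting ---------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _unpack(x: np.ndarray, n_widths: int) -> TunaModelParams:
    sx, sy, l, alpha, theta_b, w0 = x[:6]
    ratios = _sigmoid(x[6:6 + n_widths - 1])
    w = abs(w0) * np.concatenate([[1.0], np.cumprod(ratios)])
    return TunaModelParams(
        sx=sx, sy=sy, l=abs(l), alpha_deg=alpha, theta_b_deg=theta_b,
        w=np.maximum(w, 1e-6), lp=abs(x[-2]), sp=x[-1],
    )


def _pack(p: TunaModelParams) -> np.ndarray:
    ratios = np.clip(p.w[1:] / p.w[:-1], 1e-4, 1 - 1e-4)
    r = np.log(ratios / (1.0 - ratios))
    return np.concatenate([[p.sx, p.sy, p.l, p.alpha_deg, p.theta_b_deg, p.w[0]],
                           r, [p.lp, p.sp]])


def _objective(x, tree, edge_sub, n_widths, n_contour):
    """Symmetrized quadratic contour distance.

    The reported fitting error index is one-directional (model contour to
    edges); the search objective adds the reverse direction so a model that
    leaves part of the target outline uncovered (e.g. a shortened spine
    with a compensating caudal segment) is penalized too.
    """
    if abs(x[2]) < 1.0 or abs(x[5]) < 0.5:
        return 1e6
    try:
        params = _unpack(x, n_widths)
        pts = contour_points(params, n_contour)
    except (InvalidModelError, ValueError):
        return 1e6
    d, _ = tree.query(pts)
    d_rev, _ = cKDTree(pts).query(edge_sub)
    return float((np.mean(d ** 2) + np.mean(d_rev ** 2)) / params.l ** 2)


def _principal_axis_inits(edges: np.ndarray, cfg: FitConfig) -> list[TunaModelParams]:
    c = edges.mean(axis=0)
    centered = edges - c
    cov = centered.T @ centered / len(edges)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    minor_extent = 2.0 * np.sqrt(max(evals.min(), 0.0)) * 1.6
    if minor_extent < 1.0:
        raise InvalidModelError("edge points are (near-)collinear")
    proj = centered @ v
    extent = proj.max() - proj.min()
    l0 = 0.80 * extent
    w0 = max(0.95 * minor_extent, 1.0)
    ratios = np.array([0.85, 0.80, 0.74, 0.66, 0.55])[: cfg.n_widths - 1]
    w = w0 * np.concatenate([[1.0], np.cumprod(ratios)])
    inits = []
    for sign in (1.0, -1.0):
        d = v * sign
        snout = edges[np.argmin(centered @ d)]
        alpha = np.degrees(np.arctan2(d[1], d[0]))
        inits.append(
            TunaModelParams(
                sx=float(snout[0]), sy=float(snout[1]), l=float(l0),
                alpha_deg=float(alpha), theta_b_deg=0.0, w=w,
                lp=float(0.4 * w0), sp=0.0,
            )
        )
    return inits


def _simplex(x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += steps[i]
    return simplex


def _nm(fun, x0, steps, maxfev):
    res = minimize(
        fun, x0, method="Nelder-Mead",
        options={
            "initial_simplex": _simplex(x0, steps),
            "maxfev": maxfev,
            "xatol": 1e-3,
            "fatol": 1e-10,
        },
    )
    return res.x, res.fun, res.success


def fit_tuna_model(edges: np.ndarray, init: TunaModelParams | None = None,
                   cfg: FitConfig = FitConfig(), frame_index: int = 0) -> ModelFit:
    """Fit the silhouette model to an ordered (or unordered) edge point list.

    A pose-only stage (snout position, spine length, head angle) precedes
    the full search. The procedure is deterministic for fixed inputs.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 2 or edges.shape[0] < cfg.min_edge_points:
        raise ValueError(
            f"need at least {cfg.min_edge_points} edge points, got {len(edges)}"
        )
    tree = cKDTree(edges)
    stride = max(1, len(edges) // 120)
    edge_sub = edges[::stride]
    inits = [init] if init is not None else _principal_axis_inits(edges, cfg)

    def full_obj(x):
        return _objective(x, tree, edge_sub, cfg.n_widths, cfg.n_contour)

    # stage 1: pose-only search from each start (resolves head/tail)
    staged = []
    for p0 in inits:
        x0 = _pack(p0)
        scale = max(p0.l, 20.0)
        pose_steps = np.array([0.05 * scale, 0.05 * scale, 0.06 * scale, 5.0])

        def pose_obj(xp, base=x0.copy()):
            x = base.copy()
            x[:4] = xp
            return full_obj(x)

        xp, fp, _ = _nm(pose_obj, x0[:4], pose_steps, cfg.stage1_maxfev)
        x1 = x0.copy()
        x1[:4] = xp
        staged.append((fp, x1, p0, scale))

    # stage 2: full search from the best pose only
    staged.sort(key=lambda s: s[0])
    _, x1, p0, scale = staged[0]
    steps = np.concatenate([
        [0.02 * scale, 0.02 * scale, 0.03 * scale, 2.5, 5.0, 0.08 * max(p0.w[0], 4.0)],
        np.full(cfg.n_widths - 1, 0.5),
        [0.15 * max(p0.lp, 2.0), 0.15],
    ])
    best_x, _, _ = _nm(full_obj, x1, steps, cfg.stage2_maxfev)

    params = _unpack(best_x, cfg.n_widths)
    fei = compute_fei(params, edges, n_contour=cfg.n_contour)
    return ModelFit(params=params, fei=fei, frame_index=frame_index,
                    accepted=fei <= cfg.max_fei)


# --- tracking --------------------------------------------------------------

def _iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    if inter <= 0:
        return 0.0
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    return inter / (area_a + area_b - inter)


def _angdiff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def track_fish(fits: list[ModelFit], cfg: TrackConfig = TrackConfig()) -> list[Track]:
    """Greedy frame-to-frame association of accepted fits into tracks.

    A fit links to the track whose latest fit (within ``max_gap`` frames)
    has the highest bounding-box IoU, provided IoU, relative length
    difference and heading difference pass the configured tolerances.
    Every accepted fit ends up in exactly one track.
    """
    accepted = sorted((f for f in fits if f.accepted),
                      key=lambda f: f.frame_index)
    tracks: list[Track] = []
    next_id = 0
    frames = sorted({f.frame_index for f in accepted})
    by_frame = {k: [f for f in accepted if f.frame_index == k] for k in frames}
    for k in frames:
        candidates = [
            t for t in tracks
            if 0 < k - t.fits[-1].frame_index <= cfg.max_gap
        ]
        scored = []
        for fi, f in enumerate(by_frame[k]):
            for t in candidates:
                last = t.fits[-1]
                iou = _iou(f.bbox_xyxy, last.bbox_xyxy)
                if iou < cfg.min_iou:
                    continue
                if abs(f.params.l - last.params.l) / last.params.l > cfg.len_tol:
                    continue
                if _angdiff(f.heading_deg, last.heading_deg) > cfg.dir_tol_deg:
                    continue
                scored.append((iou, fi, t.track_id, f, t))
        scored.sort(key=lambda s: (-s[0], s[1], s[2]))
        used_fits, used_tracks = set(), set()
        for iou, fi, tid, f, t in scored:
            if fi in used_fits or tid in used_tracks:
                continue
            t.fits.append(f)
            used_fits.add(fi)
            used_tracks.add(tid)
        for fi, f in enumerate(by_frame[k]):
            if fi not in used_fits:
                tracks.append(Track(track_id=next_id, fits=[f]))
                next_id += 1
    return tracks


def measure_in_image(fit: ModelFit) -> tuple[float, float]:
    """(spine length, maximum width) in pixels of an accepted fit."""
    if not fit.accepted:
        raise ValueError("cannot measure an unaccepted fit")
    p = fit.params
    if p.w[0] < p.w.max() - 1e-9:
        raise InvalidModelError("widths vector violates w[0] = max(w)")
    return float(p.l), float(p.w[0])
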