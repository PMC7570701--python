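"""Acoustic-optical correspondence and metric 3D sizing.

Image-plane sizes are converted to meters through the pinhole relation
``Y = y * Z / f`` using the acoustic range at the frame's ping, and the
per-fish estimate is a symmetric trimmed mean over the fish's tracked
measurements. The model length is converted to snout-fork length with a
fixed linear relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .echogram import Trace, range_at_ping
from .geometry import silhouette_polygon, spine_points
from .vision import ModelFit, Track

__all__ = [
    "CameraIntrinsics",
    "BeamProjectionModel",
    "MeasurementSeries",
    "SFLRelation",
    "SizingResult",
    "FusionConfig",
    "AmbiguousCorrespondenceError",
    "NoMeasurementError",
    "temporal_window",
    "project_beam",
    "check_spatial_correspondence",
    "rectify_size",
    "undistort_point",
    "map_to_3d",
    "trimmed_mean_size",
    "ml_to_sfl",
    "size_fish",
]


class AmbiguousCorrespondenceError(RuntimeError):
    """Two or more tracks intersect the beam in one temporal window."""


class NoMeasurementError(RuntimeError):
    """No frame of the track passes the spatio-temporal correspondence."""


@dataclass
class CameraIntrinsics:
    f_px: float
    cx: float
    cy: float
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if self.f_px <= 0:
            raise ValueError("focal length must be positive")
        self.distortion = np.asarray(self.distortion, dtype=float)


@dataclass
class BeamProjectionModel:
    """Projection of the acoustic beam onto the image.

    The beam-axis image point for a given range is linearly interpolated
    from calibration points; the projected radius is the beam cone's
    angular radius through the pinhole, optionally narrowed.
    """

    half_angle_deg: float = 3.5
    axis_ranges_m: np.ndarray = field(default_factory=lambda: np.array([1.0, 8.0]))
    axis_points_px: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [0.0, 0.0]]))
    narrowing_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.half_angle_deg <= 0:
            raise ValueError("half_angle_deg must be positive")
        if not 0 < self.narrowing_factor <= 1:
            raise ValueError("narrowing_factor must be in (0, 1]")
        self.axis_ranges_m = np.asarray(self.axis_ranges_m, dtype=float)
        self.axis_points_px = np.asarray(self.axis_points_px, dtype=float)


@dataclass
class MeasurementSeries:
    """Per-frame (size, range) pairs entering the trimmed mean."""

    entries: list  # of (y_px, z_m, frame_index, ping_index)
    p: int = 0

    @property
    def n(self) -> int:
        return len(self.entries)


@dataclass
class SFLRelation:
    """Linear model-length to snout-fork-length conversion (meters)."""

    slope: float = 1.0312
    intercept_m: float = 0.065641


@dataclass
class FusionConfig:
    trim_fraction: float = 0.1      # p = floor(trim_fraction * n) per tail
    sfl_relation: SFLRelation = field(default_factory=SFLRelation)

    def trim_count(self, n: int) -> int:
        p = int(np.floor(self.trim_fraction * n))
        return min(p, (n - 1) // 2)


@dataclass
class SizingResult:
    track_id: int
    trace_id: int
    ml_m: float
    sfl_m: float
    width_m: float
    n_measurements: int
    tilt_class: str = "kept"
    provenance: dict = field(default_factory=dict)


def temporal_window(trace: Trace) -> tuple[float, float]:
    """1000 ms window centered on the trace's time center."""
    return trace.t_center_s - 0.5, trace.t_center_s + 0.5


def project_beam(bpm: BeamProjectionModel, intr: CameraIntrinsics,
                 range_m: float) -> tuple[np.ndarray, float]:
    """Beam-disk center (px) and radius (px) at a given range."""
    if range_m <= 0:
        raise ValueError("range must be positive")
    r = bpm.axis_ranges_m
    if not r[0] <= range_m <= r[-1]:
        warnings.warn(f"range {range_m} m outside calibrated span, extrapolating",
                      stacklevel=2)
    cx = np.interp(range_m, r, bpm.axis_points_px[:, 0])
    cy = np.interp(range_m, r, bpm.axis_points_px[:, 1])
    radius = bpm.narrowing_factor * intr.f_px * np.tan(
        np.radians(bpm.half_angle_deg))
    return np.array([cx, cy]), float(radius)


def check_spatial_correspondence(fit: ModelFit,
                                 beam: tuple[np.ndarray, float]) -> bool:
    """True iff the fitted silhouette intersects the beam disk."""
    center, radius = beam
    poly = Polygon(silhouette_polygon(fit.params))
    return poly.distance(Point(center)) <= radius


def undistort_point(pt: np.ndarray, intr: CameraIntrinsics,
                    n_iter: int = 8) -> np.ndarray:
    """Invert the radial distortion model x_d = x_u (1 + k1 r^2 + k2 r^4).

    Coordinates are normalized by the focal length around the principal
    point; the inverse is found by fixed-point iteration.
    """
    k = intr.distortion
    if k.size == 0 or not np.any(k):
        return np.asarray(pt, dtype=float)
    xd = (np.asarray(pt, dtype=float) - [intr.cx, intr.cy]) / intr.f_px
    xu = xd.copy()
    for _ in range(n_iter):
        r2 = np.sum(xu ** 2)
        factor = 1.0 + k[0] * r2 + (k[1] * r2 ** 2 if k.size > 1 else 0.0)
        xu = xd / factor
    return xu * intr.f_px + [intr.cx, intr.cy]


def rectify_size(y_px: float, intr: CameraIntrinsics,
                 endpoints_px: np.ndarray | None = None) -> float:
    """Undistort a segment's endpoints and return their distance.

    With zero distortion (or without endpoints) this is the identity on
    ``y_px``.
    """
    if endpoints_px is None or not np.any(intr.distortion):
        return float(y_px)
    e = np.asarray(endpoints_px, dtype=float)
    a = undistort_point(e[0], intr)
    b = undistort_point(e[1], intr)
    return float(np.linalg.norm(a - b))


def map_to_3d(y_px: float, intr: CameraIntrinsics, z_m: float) -> float:
    """Pinhole conversion of an image-plane size to meters."""
    if z_m <= 0:
        raise ValueError("range must be positive")
    return float(y_px * z_m / intr.f_px)


def trimmed_mean_size(series: MeasurementSeries,
                      intr: CameraIntrinsics) -> float:
    """Symmetric trimmed mean of the per-entry 3D sizes.

    Each entry's metric size ``y * Z / f`` is computed, the values are
    sorted ascending, ``p`` smallest and ``p`` largest are dropped, and the
    mean of the remainder is returned.
    """
    n, p = series.n, series.p
    if n - 2 * p < 1:
        raise ValueError(f"n - 2p must be >= 1 (n={n}, p={p})")
    vals = np.sort([map_to_3d(y, intr, z) for y, z, *_ in series.entries])
    if p > 0:
        vals = vals[p:-p]
    return float(np.mean(vals))


def ml_to_sfl(ml_m: float, rel: SFLRelation | None = None) -> float:
    """Linear conversion from model length to snout-fork length (meters)."""
    rel = rel or SFLRelation()
    return rel.slope * ml_m + rel.intercept_m


def _measurement_endpoints(fit: ModelFit):
    """Length (snout to spine end) and max-width segment endpoints."""
    pts, phi = spine_points(fit.params, 33)
    length_eps = np.array([pts[0], pts[-1]])
    # max width sits at the first width node (fractional station 0.2)
    i = 33 // 5
    normal = np.array([-np.sin(phi[i]), np.cos(phi[i])])
    half = fit.params.w[0] / 2.0
    width_eps = np.array([pts[i] + normal * half, pts[i] - normal * half])
    return length_eps, width_eps


def size_fish(track: Track, trace: Trace, intr: CameraIntrinsics,
              bpm: BeamProjectionModel, cfg: FusionConfig | None = None,
              competing_tracks: tuple = ()) -> SizingResult:
    """Fuse one track with one trace into a 3D sizing result.

    For each accepted fit inside the trace's temporal window, the nearest
    ping supplies the range through the trace's fitted line; fits whose
    silhouette misses the projected beam disk are dropped. If any competing
    track also intersects the beam inside the window the correspondence is
    ambiguous and the sample is discarded.
    """
    cfg = cfg or FusionConfig()
    t0, t1 = temporal_window(trace)

    def window_hits(tr: Track):
        hits = []
        for f in tr.fits:
            if not (f.accepted and t0 <= f.t_s <= t1):
                continue
            ping = trace.ping_index_at_time(f.t_s)
            z = range_at_ping(trace, ping)
            if z <= 0:
                continue
            beam = project_beam(bpm, intr, z)
            if check_spatial_correspondence(f, beam):
                hits.append((f, ping, z))
        return hits

    for other in competing_tracks:
        if other is track:
            continue
        if window_hits(other):
            raise AmbiguousCorrespondenceError(
                f"trace {trace.trace_id}: multiple tracks intersect the beam")

    hits = window_hits(track)
    if not hits:
        raise NoMeasurementError(
            f"trace {trace.trace_id}: no corresponding frames")

    len_entries, wid_entries = [], []
    for f, ping, z in hits:
        length_eps, width_eps = _measurement_endpoints(f)
        y_len = rectify_size(f.params.l, intr, length_eps)
        y_wid = rectify_size(f.params.w[0], intr, width_eps)
        len_entries.append((y_len, z, f.frame_index, ping))
        wid_entries.append((y_wid, z, f.frame_index, ping))

    p = cfg.trim_count(len(len_entries))
    ml = trimmed_mean_size(MeasurementSeries(len_entries, p), intr)
    width = trimmed_mean_size(MeasurementSeries(wid_entries, p), intr)
    return SizingResult(
        track_id=track.track_id,
        trace_id=trace.trace_id,
        ml_m=ml,
        sfl_m=ml_to_sfl(ml, cfg.sfl_relation),
        width_m=width,
        n_measurements=len(len_entries),
    )
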