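"""Synthetic paired echogram + video scenes with full ground truth.

Each simulated fish crosses the sensor's field of view along a straight
image-plane line at constant speed. Its range trajectory is shared between
the two channels: the video projection uses Z(t) and the echogram trace's
per-ping maximum-backscatter range follows the same line, so the acoustic
range fit is consistent with the optical geometry by construction. The
range line's slope is ``sti_gain * speed * tan(tilt)`` per second (the
physical coupling for a fish whose body axis is inclined by the swimming
tilt angle while it transits the beam; ``sti_gain`` defaults to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .echogram import Echogram
from .fusion import BeamProjectionModel, CameraIntrinsics, SFLRelation
from .geometry import TunaModelParams, render_silhouette

__all__ = [
    "GroundTruthFish",
    "SceneConfig",
    "SyntheticScene",
    "FrameSequence",
    "render_tuna_silhouette",
    "generate_swim_sequence",
    "generate_echogram",
    "generate_paired_scene",
    "sample_truth",
    "fish_model_at_time",
]

#: relative width profile along the widths vector (head -> tail), max first
_WIDTH_PROFILE = np.array([1.0, 0.85, 0.68, 0.50, 0.33, 0.18])

_BG_LEVEL = 220.0
_FISH_LEVEL = 30.0


@dataclass
class GroundTruthFish:
    fish_id: int
    sfl_m: float
    width_m: float
    tilt_deg: float            # positive = ascending (range decreasing)
    range_at_center_m: float
    crossing_time_s: float
    speed_px_per_frame: float  # image-plane speed at the center range
    heading_deg: float         # in-image swimming direction

    def __post_init__(self) -> None:
        if not 0.3 <= self.sfl_m <= 1.5:
            raise ValueError(f"sfl_m out of [0.3, 1.5]: {self.sfl_m}")
        if self.range_at_center_m <= 0:
            raise ValueError("range_at_center_m must be positive")
        if abs(self.tilt_deg) > 60:
            raise ValueError("|tilt_deg| must be <= 60")

    def ml_m(self, rel: SFLRelation | None = None) -> float:
        """Spine (model) length implied by the SFL via the linear relation."""
        rel = rel or SFLRelation()
        return (self.sfl_m - rel.intercept_m) / rel.slope


@dataclass
class SceneConfig:
    n_fish: int = 5
    ping_rate_hz: float = 20.0
    frame_rate_hz: float = 35.0
    duration_s: float = 12.0
    image_size_px: tuple[int, int] = (480, 640)
    noise_db: float = -90.0
    seed: int = 0
    # echogram geometry
    max_range_m: float = 8.0
    sample_spacing_m: float = 0.01
    # tight noise keeps the global threshold's between-class variance for the
    # signal/noise cut above that of any split inside the noise bulk, even in
    # sparse scenes (few signal cells)
    noise_db_sigma: float = 1.0
    signal_db: float = -32.0
    range_jitter_m: float = 0.005
    sti_gain: float = 1.0
    trace_duration_scale: float = 1.6  # margin over the nominal beam transit
    # optics
    f_px: float = 700.0
    frame_noise_sigma: float = 4.0
    beam_half_angle_deg: float = 3.5
    # fish sampling
    tilt_range_deg: tuple[float, float] = (-10.0, 10.0)
    sfl_range_m: tuple[float, float] = (0.5, 1.0)
    range_span_m: tuple[float, float] = (2.0, 6.0)
    speed_range_m_s: tuple[float, float] = (1.0, 1.8)
    spacing_s: float = 2.5

    def __post_init__(self) -> None:
        if self.ping_rate_hz <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("ping and frame rates must be positive")

    def intrinsics(self) -> CameraIntrinsics:
        h, w = self.image_size_px
        return CameraIntrinsics(f_px=self.f_px, cx=(w - 1) / 2.0,
                                cy=(h - 1) / 2.0)

    def beam_model(self) -> BeamProjectionModel:
        intr = self.intrinsics()
        return BeamProjectionModel(
            half_angle_deg=self.beam_half_angle_deg,
            axis_ranges_m=np.array([0.5, self.max_range_m]),
            axis_points_px=np.array([[intr.cx, intr.cy], [intr.cx, intr.cy]]),
        )


def render_tuna_silhouette(params: TunaModelParams,
                           image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize the filled silhouette; clipping at image bounds is allowed
    (a warning-level flag is available through the geometry layer)."""
    mask, _ = render_silhouette(params, image_size)
    return mask


def _speed_m_s(fish: GroundTruthFish, cfg: SceneConfig) -> float:
    """In-plane swimming speed implied by the image-plane speed at center range."""
    return (fish.speed_px_per_frame * fish.range_at_center_m
            * cfg.frame_rate_hz / cfg.f_px)


def range_at_time(fish: GroundTruthFish, cfg: SceneConfig, t_s) -> np.ndarray:
    """Shared range trajectory Z(t): linear around the crossing instant.

    Positive tilt (ascending, towards an upward-looking sensor) decreases
    the range over time.
    """
    v = _speed_m_s(fish, cfg)
    dzdt = -cfg.sti_gain * v * np.tan(np.radians(fish.tilt_deg))
    return fish.range_at_center_m + dzdt * (np.asarray(t_s) - fish.crossing_time_s)


def transit_duration_s(fish: GroundTruthFish, cfg: SceneConfig) -> float:
    """Time the fish spends inside the beam: diameter at range over speed."""
    diameter = 2.0 * fish.range_at_center_m * np.tan(
        np.radians(cfg.beam_half_angle_deg))
    return cfg.trace_duration_scale * diameter / _speed_m_s(fish, cfg)


def fish_model_at_time(fish: GroundTruthFish, cfg: SceneConfig,
                       t_s: float) -> TunaModelParams | None:
    """Silhouette parameters projecting the fish at time ``t_s``.

    The spine length maps the model length (SFL through the inverse linear
    relation) foreshortened by cos(tilt) through the pinhole model; the
    width is not foreshortened (the lateral axis stays in-plane).
    Returns None when the fish is entirely outside the image.
    """
    z = float(range_at_time(fish, cfg, t_s))
    if z <= 0.1:
        return None
    intr = cfg.intrinsics()
    f = intr.f_px
    l_px = fish.ml_m() * np.cos(np.radians(fish.tilt_deg)) * f / z
    w_px = fish.width_m * f / z
    heading = np.radians(fish.heading_deg)
    # straight line through the principal point at the crossing instant
    dt_frames = (t_s - fish.crossing_time_s) * cfg.frame_rate_hz
    center = np.array([intr.cx, intr.cy]) + fish.speed_px_per_frame * dt_frames \
        * np.array([np.cos(heading), np.sin(heading)])
    snout = center + 0.5 * l_px * np.array([np.cos(heading), np.sin(heading)])
    # snout leads: spine runs from the snout backwards against the heading
    params = TunaModelParams(
        sx=float(snout[0]), sy=float(snout[1]), l=float(l_px),
        alpha_deg=float((fish.heading_deg + 180.0) % 360.0),
        theta_b_deg=0.0, w=w_px * _WIDTH_PROFILE,
        lp=float(0.45 * w_px), sp=0.0,
    )
    h, w_img = cfg.image_size_px
    if (params.sx < -l_px or params.sx > w_img + l_px
            or params.sy < -l_px or params.sy > h + l_px):
        return None
    return params


class FrameSequence:
    """Lazy, deterministic timestamped frame sequence.

    Frames are rendered on demand; the pixel noise of frame ``i`` is drawn
    from a child seed of ``(seed, "frame", i)`` so any access pattern
    produces byte-identical images.
    """

    def __init__(self, cfg: SceneConfig, truth: list[GroundTruthFish]):
        self.cfg = cfg
        self.truth = truth
        n = int(np.floor(cfg.duration_s * cfg.frame_rate_hz)) + 1
        self.timestamps_s = np.arange(n) / cfg.frame_rate_hz

    def __len__(self) -> int:
        return len(self.timestamps_s)

    def get_frame(self, i: int) -> np.ndarray:
        cfg = self.cfg
        t = self.timestamps_s[i]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, i]))
        img = np.full(cfg.image_size_px, _BG_LEVEL, dtype=float)
        img += rng.normal(0.0, cfg.frame_noise_sigma, size=cfg.image_size_px)
        for fish in self.truth:
            params = fish_model_at_time(fish, cfg, t)
            if params is None:
                continue
            mask = render_tuna_silhouette(params, cfg.image_size_px)
            img[mask] = _FISH_LEVEL
        return np.clip(img, 0, 255).astype(np.uint8)

    def __iter__(self):
        for i in range(len(self)):
            yield self.timestamps_s[i], self.get_frame(i)


@dataclass
class SyntheticScene:
    echogram: Echogram
    frames: FrameSequence
    truth: list[GroundTruthFish]
    intrinsics: CameraIntrinsics
    beam: BeamProjectionModel
    config: SceneConfig = None


def generate_swim_sequence(fish: GroundTruthFish, cfg: SceneConfig,
                           intrinsics: CameraIntrinsics | None = None) -> FrameSequence:
    """Frame sequence containing a single fish (background plus noise).

    Emits a warning and an empty sequence when the fish never intersects
    the image.
    """
    seq = FrameSequence(cfg, [fish])
    visible = [
        t for t in seq.timestamps_s
        if fish_model_at_time(fish, cfg, t) is not None
    ]
    if not visible:
        import warnings

        warnings.warn("fish never intersects the image", stacklevel=2)
        seq.timestamps_s = np.array([])
    return seq


def generate_echogram(truth: list[GroundTruthFish], cfg: SceneConfig) -> Echogram:
    """Echogram with one elongated trace per fish over background noise.

    For each ping during a fish's transit, a short vertical band of signal
    cells is placed around the range line, its per-ping maximum exactly on
    the line (plus jitter), reproducing elongated blob-like traces whose
    fitted slope tracks tan(tilt).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_pings = int(np.floor(cfg.duration_s * cfg.ping_rate_hz)) + 1
    ping_times = np.arange(n_pings) / cfg.ping_rate_hz
    ranges = np.arange(cfg.sample_spacing_m, cfg.max_range_m,
                       cfg.sample_spacing_m)
    values = rng.normal(cfg.noise_db, cfg.noise_db_sigma,
                        size=(n_pings, ranges.size))
    for fish in truth:
        if not 0.0 <= fish.crossing_time_s <= cfg.duration_s:
            raise ValueError(
                f"crossing time {fish.crossing_time_s} outside scene duration")
        half = transit_duration_s(fish, cfg) / 2.0
        in_transit = np.abs(ping_times - fish.crossing_time_s) <= half
        p_idx = np.nonzero(in_transit)[0]
        for p in p_idx:
            r = float(range_at_time(fish, cfg, ping_times[p]))
            r += rng.normal(0.0, cfg.range_jitter_m)
            s = int(round((r - ranges[0]) / cfg.sample_spacing_m))
            if not 0 <= s < ranges.size:
                continue
            # vertical band: strongest at the line, weaker flanks
            for ds in range(-3, 4):
                sj = s + ds
                if 0 <= sj < ranges.size:
                    level = cfg.signal_db - 2.5 * abs(ds)
                    values[p, sj] = max(values[p, sj], level)
    return Echogram(values_db=values, ping_times_s=ping_times,
                    sample_ranges_m=ranges)


def sample_truth(cfg: SceneConfig) -> list[GroundTruthFish]:
    """Draw fish with evenly spaced crossing times and randomized geometry."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    fish = []
    t0 = cfg.spacing_s / 2.0 + 0.6
    for i in range(cfg.n_fish):
        sfl = rng.uniform(*cfg.sfl_range_m)
        z = rng.uniform(*cfg.range_span_m)
        tilt = rng.uniform(*cfg.tilt_range_deg)
        speed = rng.uniform(*cfg.speed_range_m_s)
        heading = rng.uniform(0.0, 360.0)
        fish.append(
            GroundTruthFish(
                fish_id=i,
                sfl_m=float(sfl),
                width_m=float(0.20 * sfl),
                tilt_deg=float(tilt),
                range_at_center_m=float(z),
                crossing_time_s=float(t0 + i * cfg.spacing_s),
                speed_px_per_frame=float(speed * cfg.f_px
                                         / (z * cfg.frame_rate_hz)),
                heading_deg=float(heading),
            )
        )
    return fish


def generate_paired_scene(cfg: SceneConfig,
                          truth: list[GroundTruthFish] | None = None) -> SyntheticScene:
    """Echogram plus frames plus truth, consistent per fish and
    deterministic under a fixed seed."""
    if truth is None:
        truth = sample_truth(cfg)
        needed = (max(f.crossing_time_s for f in truth) + cfg.spacing_s / 2.0
                  if truth else cfg.duration_s)
        if needed > cfg.duration_s:
            cfg = replace(cfg, duration_s=float(needed))
    eg = generate_echogram(truth, cfg)
    frames = FrameSequence(cfg, truth)
    return SyntheticScene(
        echogram=eg, frames=frames, truth=truth,
        intrinsics=cfg.intrinsics(), beam=cfg.beam_model(), config=cfg,
    )
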