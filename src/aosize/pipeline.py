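"""End-to-end orchestration: echogram -> windows -> vision -> fusion.

The acoustic channel acts as a trigger: by default only video frames inside
the 1000 ms temporal windows of surviving traces are segmented and fitted,
which is equivalent to (but much cheaper than) processing every frame.
Per-stage sample accounting is conserved:

    total traces = discarded(isolation) + discarded(features)
                 + discarded(tilt) + discarded(ambiguous)
                 + discarded(no measurement) + sized
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import echogram as eg_mod
from . import vision
from .echogram import Echogram, TraceFilterConfig
from .fusion import (
    AmbiguousCorrespondenceError,
    BeamProjectionModel,
    CameraIntrinsics,
    FusionConfig,
    NoMeasurementError,
    SizingResult,
    size_fish,
    temporal_window,
)
from .tiltfilter import NON_TILTED, TiltFilterConfig, classify_by_sti

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_sizing"]


def _config_hash(cfg) -> str:
    from .io import config_hash

    return config_hash(cfg)


@dataclass
class PipelineConfig:
    trace_filter: TraceFilterConfig = field(default_factory=TraceFilterConfig)
    tilt_filter: TiltFilterConfig | None = field(default_factory=TiltFilterConfig)
    segment: vision.SegmentConfig = field(default_factory=vision.SegmentConfig)
    blob_filter: vision.BlobFilterConfig = field(default_factory=vision.BlobFilterConfig)
    fit: vision.FitConfig = field(default_factory=vision.FitConfig)
    track: vision.TrackConfig = field(default_factory=vision.TrackConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    windowed_frames: bool = True  # trigger design: vision only inside windows


@dataclass
class PipelineResult:
    results: list[SizingResult]
    counts: dict
    traces: list
    tracks_by_trace: dict

    def assert_conserved(self) -> None:
        c = self.counts
        total = (c["discarded_isolation"] + c["discarded_features"]
                 + c["discarded_tilt"] + c["discarded_ambiguous"]
                 + c["discarded_no_measurement"] + c["sized"])
        if total != c["traces_total"]:
            raise AssertionError(f"accounting leak: {c}")


def _fit_frames(frames, frame_indices, cfg: PipelineConfig):
    """Segment and fit every requested frame; returns accepted fits."""
    fits = []
    for i in frame_indices:
        img = frames.get_frame(i)
        fg = vision.segment_frame(img, cfg.segment)
        blobs = vision.filter_blobs(vision.extract_blobs(fg), cfg.blob_filter)
        for blob in blobs:
            edges, truncated = vision.detect_edges(fg, blob, subpixel=True)
            if truncated or len(edges) < cfg.fit.min_edge_points:
                continue
            try:
                fit = vision.fit_tuna_model(edges, cfg=cfg.fit, frame_index=i)
            except (ValueError, vision.InvalidModelError):
                continue
            fit.t_s = float(frames.timestamps_s[i])
            if fit.accepted:
                fits.append(fit)
    return fits


def run_sizing(eg: Echogram, frames, intr: CameraIntrinsics,
               bpm: BeamProjectionModel,
               cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run the full sizing chain on one scene."""
    cfg = cfg or PipelineConfig()
    counts: dict = {}

    binary = eg_mod.binarize_echogram(eg)
    cleaned = eg_mod.morphological_cleanup(binary)
    traces = eg_mod.extract_traces(cleaned, eg)
    counts["traces_total"] = len(traces)

    isolated = eg_mod.filter_isolated(traces, cfg.trace_filter)
    counts["discarded_isolation"] = len(traces) - len(isolated)

    good = eg_mod.filter_traces(isolated, cfg.trace_filter)
    counts["discarded_features"] = len(isolated) - len(good)

    if cfg.tilt_filter is not None:
        kept = [t for t in good
                if t.has_sti and classify_by_sti(t, cfg.tilt_filter) == NON_TILTED]
    else:
        kept = list(good)
    counts["discarded_tilt"] = len(good) - len(kept)

    # vision: frames inside kept traces' windows (or every frame)
    timestamps = frames.timestamps_s
    if cfg.windowed_frames:
        wanted: set[int] = set()
        for t in kept:
            t0, t1 = temporal_window(t)
            wanted.update(np.nonzero((timestamps >= t0) & (timestamps <= t1))[0])
        frame_indices = sorted(wanted)
    else:
        frame_indices = list(range(len(timestamps)))
    counts["frames_processed"] = len(frame_indices)

    fits = _fit_frames(frames, frame_indices, cfg)
    tracks = vision.track_fish(fits, cfg.track)
    counts["fits_accepted"] = len(fits)
    counts["tracks"] = len(tracks)

    results: list[SizingResult] = []
    tracks_by_trace: dict = {}
    n_ambiguous = n_nomeas = 0
    for trace in kept:
        t0, t1 = temporal_window(trace)
        in_window = [
            tr for tr in tracks
            if any(t0 <= f.t_s <= t1 and f.accepted for f in tr.fits)
        ]
        tracks_by_trace[trace.trace_id] = in_window
        if not in_window:
            n_nomeas += 1
            continue
        # candidate = track with most accepted fits inside the window
        in_window.sort(key=lambda tr: -sum(1 for f in tr.fits
                                           if t0 <= f.t_s <= t1))
        candidate, competitors = in_window[0], in_window[1:]
        try:
            res = size_fish(candidate, trace, intr, bpm, cfg.fusion,
                            competing_tracks=tuple(competitors))
        except AmbiguousCorrespondenceError:
            n_ambiguous += 1
            log.info("trace %d discarded: ambiguous correspondence",
                     trace.trace_id)
            continue
        except NoMeasurementError:
            n_nomeas += 1
            continue
        res.tilt_class = "kept"
        res.provenance = {"config_hash": _config_hash(cfg)}
        results.append(res)
    counts["discarded_ambiguous"] = n_ambiguous
    counts["discarded_no_measurement"] = n_nomeas
    counts["sized"] = len(results)

    out = PipelineResult(results=results, counts=counts, traces=traces,
                         tracks_by_trace=tracks_by_trace)
    out.assert_conserved()
    return out
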