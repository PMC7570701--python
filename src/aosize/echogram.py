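"""Echogram trace detection, characterization and the swimming tilt indicator.

The processing chain mirrors a classic image pipeline applied to the
ping x range backscatter matrix: global (Otsu) binarization, morphological
cleanup, 8-connected component labelling, geometric/acoustic feature
filters, a time-and-space isolation filter, and a per-trace linear fit of
the per-ping maximum-backscatter ranges whose slope is the swimming tilt
indicator (STI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.morphology import closing as _closing
from skimage.morphology import dilation as _dilation
from skimage.morphology import opening as _opening

__all__ = [
    "Echogram",
    "Trace",
    "TraceFilterConfig",
    "UndefinedSTIError",
    "otsu_threshold",
    "binarize_echogram",
    "morphological_cleanup",
    "extract_traces",
    "characterize_trace",
    "filter_isolated",
    "filter_traces",
    "compute_sti",
    "range_at_ping",
]

_CROSS3 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE3 = np.ones((3, 3), dtype=bool)


class UndefinedSTIError(ValueError):
    """Raised when a trace has too few pings for the tilt-indicator fit."""


@dataclass
class Echogram:
    """Backscatter matrix, oriented pings (time) x samples (range)."""

    values_db: np.ndarray        # [n_pings, n_samples]
    ping_times_s: np.ndarray     # strictly increasing, seconds
    sample_ranges_m: np.ndarray  # strictly increasing, meters

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=float)
        self.ping_times_s = np.asarray(self.ping_times_s, dtype=float)
        self.sample_ranges_m = np.asarray(self.sample_ranges_m, dtype=float)
        if self.values_db.ndim != 2:
            raise ValueError("values_db must be 2-D [n_pings, n_samples]")
        n_pings, n_samples = self.values_db.shape
        if self.ping_times_s.shape != (n_pings,):
            raise ValueError("ping_times_s length must match n_pings")
        if self.sample_ranges_m.shape != (n_samples,):
            raise ValueError("sample_ranges_m length must match n_samples")
        if np.any(np.diff(self.ping_times_s) <= 0):
            raise ValueError("ping_times_s must be strictly increasing")
        if np.any(np.diff(self.sample_ranges_m) <= 0):
            raise ValueError("sample_ranges_m must be strictly increasing")
        if not np.all(np.isfinite(self.values_db)):
            raise ValueError("values_db must be finite")

    @property
    def n_pings(self) -> int:
        return self.values_db.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values_db.shape[1]


@dataclass
class Trace:
    """One connected echogram component with its features."""

    trace_id: int
    cells: np.ndarray                 # (k, 2) of (ping_index, sample_index)
    t_center_s: float = 0.0
    per_ping_max: np.ndarray = field(default=None)  # (m, 3): ping, max_db, range_m
    ping_times: np.ndarray = field(default=None)    # (m,) times of those pings
    area_cells: int = 0
    solidity: float = 1.0
    max_ts_db: float = 0.0
    min_ts_db: float = 0.0
    mean_range_m: float = 0.0
    n_pings: int = 0
    t_min_s: float = 0.0
    t_max_s: float = 0.0
    range_min_m: float = 0.0
    range_max_m: float = 0.0
    sti: float = np.nan               # m per ping
    sti_intercept_m: float = np.nan   # range at ping index 0
    sti_per_s: float = np.nan         # m per second

    @property
    def has_sti(self) -> bool:
        return np.isfinite(self.sti)

    def ping_index_at_time(self, t_s: float) -> int:
        """Nearest ping index for a timestamp, extrapolating with the local
        ping rate outside the trace's own ping span."""
        p = self.per_ping_max[:, 0]
        times = self.ping_times
        if times.size == 1:
            return int(p[0])
        rate = (p[-1] - p[0]) / (times[-1] - times[0])
        return int(round(p[0] + (t_s - times[0]) * rate))


@dataclass
class TraceFilterConfig:
    """Thresholds for the geometric/acoustic filters and the isolation test."""

    min_area_cells: int = 20
    min_solidity: float = 0.5
    ts_min_db: float = -np.inf
    ts_max_db: float = np.inf
    range_min_m: float = 0.0
    range_max_m: float = np.inf
    min_pings: int = 4
    window_time_ms: float = 1000.0
    window_range_m: float = 8.0

    def __post_init__(self) -> None:
        if self.window_time_ms <= 0:
            raise ValueError("window_time_ms must be positive")
        if self.window_range_m <= 0:
            raise ValueError("window_range_m must be positive")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over an nbins histogram."""
    return float(threshold_otsu(np.asarray(values, dtype=float), nbins=nbins))


def binarize_echogram(eg: Echogram, nbins: int = 256) -> np.ndarray:
    """Threshold the dB matrix with Otsu's method.

    The threshold maximizes the between-class variance of a ``nbins``-bin
    histogram over the data range; cells at or above the threshold are
    foreground. A constant matrix yields an all-background result with a
    warning.
    """
    vals = eg.values_db
    if np.ptp(vals) == 0:
        warnings.warn("constant echogram: no foreground", stacklevel=2)
        return np.zeros_like(vals, dtype=bool)
    return vals >= otsu_threshold(vals, nbins=nbins)


def morphological_cleanup(
    b: np.ndarray,
    thicken_footprint: np.ndarray = _CROSS3,
    open_footprint: np.ndarray = _SQUARE3,
    close_footprint: np.ndarray = _SQUARE3,
) -> np.ndarray:
    """Thicken (dilation), open (remove protrusions and weak connections),
    then close (smooth contours, fill small holes)."""
    b = np.asarray(b, dtype=bool)
    out = _dilation(b, thicken_footprint)
    out = _opening(out, open_footprint)
    out = _closing(out, close_footprint)
    return out.astype(bool)


def _hull_area_of_cells(cells: np.ndarray) -> float:
    """Area of the convex hull of the union of unit-square cells."""
    p = cells[:, 0]
    s = cells[:, 1]
    corners = np.concatenate(
        [
            np.column_stack([p, s]),
            np.column_stack([p + 1, s]),
            np.column_stack([p, s + 1]),
            np.column_stack([p + 1, s + 1]),
        ]
    ).astype(float)
    try:
        return float(ConvexHull(corners).volume)
    except QhullError:  # pragma: no cover - corners of >=1 cell always span 2-D
        return float(len(cells))


def characterize_trace(trace: Trace, eg: Echogram) -> Trace:
    """Populate geometric and acoustic features of a trace in place."""
    cells = trace.cells
    pings = cells[:, 0]
    samples = cells[:, 1]
    vals = eg.values_db[pings, samples]

    trace.area_cells = len(cells)
    hull_area = _hull_area_of_cells(cells)
    trace.solidity = min(1.0, trace.area_cells / hull_area)
    trace.max_ts_db = float(vals.max())
    trace.min_ts_db = float(vals.min())

    uniq = np.unique(pings)
    per_ping = np.empty((uniq.size, 3))
    for i, p in enumerate(uniq):
        m = pings == p
        j = np.argmax(vals[m])
        s_best = samples[m][j]
        per_ping[i] = (p, vals[m][j], eg.sample_ranges_m[s_best])
    trace.per_ping_max = per_ping
    trace.ping_times = eg.ping_times_s[uniq]
    trace.n_pings = uniq.size
    trace.mean_range_m = float(per_ping[:, 2].mean())
    trace.t_min_s = float(eg.ping_times_s[uniq[0]])
    trace.t_max_s = float(eg.ping_times_s[uniq[-1]])
    trace.t_center_s = 0.5 * (trace.t_min_s + trace.t_max_s)
    trace.range_min_m = float(eg.sample_ranges_m[samples.min()])
    trace.range_max_m = float(eg.sample_ranges_m[samples.max()])

    if trace.n_pings >= 2:
        sti, intercept = compute_sti(trace)
        trace.sti = sti
        trace.sti_intercept_m = intercept
        dt = trace.ping_times[-1] - trace.ping_times[0]
        dp = per_ping[-1, 0] - per_ping[0, 0]
        trace.sti_per_s = sti * dp / dt if dt > 0 else np.nan
    return trace


def extract_traces(b: np.ndarray, eg: Echogram) -> list[Trace]:
    """8-connected components of the cleaned binary matrix as traces."""
    lab = _sk_label(np.asarray(b, dtype=bool), connectivity=2)
    traces = []
    for k in range(1, lab.max() + 1):
        cells = np.argwhere(lab == k)
        traces.append(characterize_trace(Trace(trace_id=k, cells=cells), eg))
    return traces


def filter_isolated(traces: list[Trace], cfg: TraceFilterConfig) -> list[Trace]:
    """Keep only traces whose isolation rectangle contains no other trace.

    The rectangle is ``window_time_ms`` wide centered on the trace's time
    center and ``window_range_m`` tall centered on its mean range. A
    collision discards both parties; the result does not depend on input
    order.
    """
    half_t = cfg.window_time_ms / 2000.0
    half_r = cfg.window_range_m / 2.0
    kept = []
    for t in traces:
        lone = True
        for o in traces:
            if o is t:
                continue
            overlaps_time = (o.t_max_s >= t.t_center_s - half_t
                             and o.t_min_s <= t.t_center_s + half_t)
            overlaps_range = (o.range_max_m >= t.mean_range_m - half_r
                              and o.range_min_m <= t.mean_range_m + half_r)
            if overlaps_time and overlaps_range:
                lone = False
                break
        if lone:
            kept.append(t)
    return kept


def filter_traces(traces: list[Trace], cfg: TraceFilterConfig) -> list[Trace]:
    """Conjunction of area, solidity, TS, range and ping-count criteria."""
    out = []
    for t in traces:
        if (
            t.area_cells >= cfg.min_area_cells
            and t.solidity >= cfg.min_solidity
            and cfg.ts_min_db <= t.max_ts_db <= cfg.ts_max_db
            and t.min_ts_db >= cfg.ts_min_db
            and cfg.range_min_m <= t.mean_range_m <= cfg.range_max_m
            and t.n_pings >= cfg.min_pings
        ):
            out.append(t)
    return out


def compute_sti(trace: Trace) -> tuple[float, float]:
    """Ordinary least squares of per-ping max range against ping index.

    Returns (slope in m per ping, intercept in m at ping index 0).
    """
    if trace.per_ping_max is None or trace.per_ping_max.shape[0] < 2:
        raise UndefinedSTIError("STI needs at least 2 pings")
    x = trace.per_ping_max[:, 0]
    y = trace.per_ping_max[:, 2]
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def range_at_ping(trace: Trace, ping_index: float) -> float:
    """Evaluate the fitted range line at a ping index (extrapolation allowed)."""
    if not trace.has_sti:
        raise UndefinedSTIError("trace has no fitted STI line")
    return float(trace.sti_intercept_m + trace.sti * ping_index)
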