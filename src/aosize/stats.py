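"""Measurement comparison, relative errors and stock summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "relative_error",
    "error_by_tilt_bins",
    "summarize",
    "frequency_histogram",
]


def relative_error(ao_value: float, ref_value: float) -> float:
    """Relative error in percent: (ao - ref) / ref * 100."""
    if ref_value == 0:
        raise ValueError("reference value must be nonzero")
    return (ao_value - ref_value) / ref_value * 100.0


def error_by_tilt_bins(table: pd.DataFrame, bins: np.ndarray) -> pd.DataFrame:
    """Percentile summary of relative errors per |tilt| bin.

    ``table`` needs columns ``er_percent`` and ``tilt_deg``. Percentiles
    use linear interpolation between order statistics. Empty bins yield
    NaN rows rather than errors.
    """
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (table["tilt_deg"].abs() >= lo) & (table["tilt_deg"].abs() < hi)
        er = table.loc[m, "er_percent"].to_numpy()
        if er.size == 0:
            rows.append({"bin_lo_deg": lo, "bin_hi_deg": hi, "n": 0,
                         "p5": np.nan, "p25": np.nan, "median": np.nan,
                         "p75": np.nan, "p95": np.nan})
            continue
        p5, p25, p50, p75, p95 = np.percentile(er, [5, 25, 50, 75, 95])
        rows.append({"bin_lo_deg": lo, "bin_hi_deg": hi, "n": int(er.size),
                     "p5": p5, "p25": p25, "median": p50, "p75": p75, "p95": p95})
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame,
              value_cols: tuple = ("sfl_m", "width_m")) -> pd.DataFrame:
    """Population mean, standard deviation and variance per dimension per
    source (divisor n)."""
    if table.empty:
        raise ValueError("empty measurement table")
    rows = []
    groups = table.groupby("source") if "source" in table else [("all", table)]
    for source, g in groups:
        for col in value_cols:
            if col not in g:
                continue
            v = g[col].to_numpy(dtype=float)
            mean = float(np.mean(v))
            var = float(np.var(v))  # population variance, divisor n
            rows.append({"source": source, "dimension": col, "n": v.size,
                         "mean": mean, "sd": float(np.sqrt(var)),
                         "variance": var})
    return pd.DataFrame(rows)


def frequency_histogram(values, bin_width_m: float,
                        start: float | None = None) -> pd.DataFrame:
    """Counts per half-open bin [edge, edge + width).

    Edges are generated as ``start + k * width``; enough bins are created
    that the maximum value falls strictly inside the last bin, so counts
    always sum to ``len(values)``.
    """
    if bin_width_m <= 0:
        raise ValueError("bin width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return pd.DataFrame({"bin_left_m": [], "bin_right_m": [], "count": []})
    if start is None:
        start = np.floor(v.min() / bin_width_m) * bin_width_m
    k = 1
    while start + k * bin_width_m <= v.max():
        k += 1
    edges = start + bin_width_m * np.arange(k + 1)
    counts, _ = np.histogram(v, bins=edges)
    return pd.DataFrame({"bin_left_m": edges[:-1], "bin_right_m": edges[1:],
                         "count": counts})
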