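"""Swimming-tilt classification of traces from acoustic information alone.

Traces are called non-tilted when their swimming tilt indicator falls in a
closed interval, tilted otherwise. A pluggable classifier interface allows
alternative methods (e.g. image-based classifiers trained on trace
thumbnails); only the STI interval rule ships here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
import pandas as pd

from .echogram import Trace

__all__ = [
    "TILT_BOUNDARY_DEG",
    "TiltLabel",
    "TiltFilterConfig",
    "TraceClassifier",
    "classify_by_sti",
    "sti_classifier",
    "classification_report",
]

#: ground-truth boundary between the tilted and non-tilted classes
TILT_BOUNDARY_DEG = 10.0

TILTED = "tilted"
NON_TILTED = "non-tilted"


@dataclass
class TiltLabel:
    trace_id: int
    true_tilt_deg: float
    predicted_class: str
    method: str = "sti"

    @property
    def true_class(self) -> str:
        return TILTED if abs(self.true_tilt_deg) > TILT_BOUNDARY_DEG else NON_TILTED


@dataclass
class TiltFilterConfig:
    sti_low: float = -0.3
    sti_high: float = 0.3
    #: classify on the slope per second (speed-scaled) rather than per ping
    per_second: bool = True

    def __post_init__(self) -> None:
        if not self.sti_low < self.sti_high:
            raise ValueError("sti_low must be < sti_high")


class TraceClassifier(Protocol):
    """Anything mapping a trace to a predicted tilt class."""

    def __call__(self, trace: Trace) -> str: ...


def classify_by_sti(trace: Trace, cfg: TiltFilterConfig) -> str:
    """Non-tilted iff the STI lies in the closed configured interval."""
    sti = trace.sti_per_s if cfg.per_second else trace.sti
    if not np.isfinite(sti):
        raise ValueError(f"trace {trace.trace_id} has no defined STI")
    return NON_TILTED if cfg.sti_low <= sti <= cfg.sti_high else TILTED


def sti_classifier(cfg: TiltFilterConfig) -> Callable[[Trace], str]:
    """Bind an interval config into a ``TraceClassifier``."""
    return lambda trace: classify_by_sti(trace, cfg)


def classification_report(labels: list[TiltLabel]) -> pd.DataFrame:
    """Confusion summary per class.

    One row per true class with true/false positive counts and rates; the
    kept sizing dataset consists of the non-tilted predictions (true
    positives of the non-tilted class plus false positives from the tilted
    class).
    """
    rows = []
    for cls in (TILTED, NON_TILTED):
        members = [l for l in labels if l.true_class == cls]
        n = len(members)
        tp = sum(1 for l in members if l.predicted_class == cls)
        rows.append(
            {
                "true_class": cls,
                "n": n,
                "true_positives": tp,
                "false_positives": n - tp,
                "tp_rate": tp / n if n else np.nan,
                "fp_rate": (n - tp) / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
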