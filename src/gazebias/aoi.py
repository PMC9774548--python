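"""Per-trial AOI gaze metrics.

For every trial the detector runs on the mean-binocular stream and each
fixation is assigned to *every* AOI that contains at least one of its
member samples (whole-fixation accrual).  A fixation straddling an AOI
border therefore contributes its full duration to both AOIs — which is why
combined AOI fixation time can exceed the slide duration, the situation the
5500 ms curation criterion screens for.  Exported per AOI: number of
fixations, total fixation time, and the durations of the first, second and
third fixation assigned to that AOI in time order; plus the number of
retained sample measurements for the whole trial (approximately 300 for a
5 s slide at 60 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .config import AOI, DetectorConfig, validate_aois
from .detection import Fixation, detect_fixations
from .io import METRIC_COLUMNS, TrialRecording

__all__ = ["AOIStats", "TrialMetrics", "assign_fixation_aois", "compute_trial_metrics",
           "metrics_to_frame", "AOIMetrics"]


@dataclass
class AOIStats:
    n_fixations: int = 0
    fixation_time_ms: float = 0.0
    first_fixation_ms: float = math.nan
    second_fixation_ms: float = math.nan
    third_fixation_ms: float = math.nan


@dataclass
class TrialMetrics:
    participant_id: str
    slide_id: str
    n_sample_measurements: int
    per_aoi: dict[str, AOIStats] = field(default_factory=dict)


def assign_fixation_aois(fixation: Fixation, aois: Sequence[AOI], x, y) -> set[str]:
    """Names of all AOIs containing at least one member sample of the fixation.

    ``x, y`` are the retained-sample coordinate arrays the detector ran on.
    Samples lying in no AOI contribute no assignment; a fixation entirely in
    the dead zone between AOIs yields the empty set.
    """
    sl = slice(fixation.start_index, fixation.end_index + 1)
    xs, ys = np.asarray(x)[sl], np.asarray(y)[sl]
    return {a.name for a in aois if bool(a.contains(xs, ys).any())}


def compute_trial_metrics(rec: TrialRecording, aois: Sequence[AOI],
                          detector: DetectorConfig | None = None) -> TrialMetrics:
    """Detect fixations on the mean-binocular stream and tally them per AOI."""
    validate_aois(aois)
    detector = detector or DetectorConfig()
    t, x, y = rec.retained()
    fixations = detect_fixations(t, x, y, detector)

    stats = {a.name: AOIStats() for a in aois}
    ordinal_fields = ("first_fixation_ms", "second_fixation_ms", "third_fixation_ms")
    # AOIs are validated disjoint, so each sample belongs to at most one;
    # coding every sample once keeps the per-fixation lookup cheap.
    codes = np.full(x.shape, -1, dtype=np.int8)
    names = []
    for k, a in enumerate(aois):
        codes[np.asarray(a.contains(x, y))] = k
        names.append(a.name)
    for fx in fixations:
        touched = np.unique(codes[fx.start_index:fx.end_index + 1])
        for name in (names[c] for c in touched if c >= 0):
            s = stats[name]
            if s.n_fixations < 3:
                setattr(s, ordinal_fields[s.n_fixations], fx.duration_ms)
            s.n_fixations += 1
            s.fixation_time_ms += fx.duration_ms
    return TrialMetrics(rec.participant_id, rec.slide_id, int(t.size), stats)


def metrics_to_frame(metrics: Iterable[TrialMetrics]) -> pd.DataFrame:
    """Tidy table: one row per participant x slide x AOI (stable column order)."""
    rows = []
    for m in metrics:
        for name, s in m.per_aoi.items():
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "slide_id": m.slide_id,
                    "aoi": name,
                    "n_fixations": s.n_fixations,
                    "fixation_time_ms": s.fixation_time_ms,
                    "first_fixation_ms": s.first_fixation_ms,
                    "second_fixation_ms": s.second_fixation_ms,
                    "third_fixation_ms": s.third_fixation_ms,
                    "n_sample_measurements": m.n_sample_measurements,
                }
            )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


class AOIMetrics:
    """Sklearn-style transformer: trial recordings -> tidy AOI metrics table."""

    def __init__(self, aois: Sequence[AOI] | None = None,
                 detector: DetectorConfig | None = None):
        self.aois = aois
        self.detector = detector

    def get_params(self, deep: bool = True) -> dict:
        return {"aois": self.aois, "detector": self.detector}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        from .config import default_aois

        self.aois_ = list(self.aois) if self.aois is not None else default_aois()
        validate_aois(self.aois_)
        self.detector_ = self.detector or DetectorConfig()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "aois_"):
            self.fit()
        recs = X if isinstance(X, (list, tuple)) else [X]
        return metrics_to_frame(compute_trial_metrics(r, self.aois_, self.detector_) for r in recs)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
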