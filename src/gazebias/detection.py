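"""Lead-sample dispersion fixation detection.

A fixation is a maximal run of consecutive retained samples that all lie
within ``dispersion_px`` (Euclidean, inclusive) of the run's *lead* sample.
The first sample of the stream is a lead; every sample that falls outside
the current lead's dispersion circle becomes the next lead.  Runs shorter
than ``min_samples`` are discarded (their samples are not revisited), so at
60 Hz with the default minimum of 3 samples the shortest fixation lasts
50 ms.  Fixation duration is defined as ``n_samples`` times the nominal
sampling interval, not as a timestamp difference: three samples at 60 Hz
make a 50 ms fixation.

This is deliberately not classical I-DT: membership is judged against the
lead sample, not against the running pairwise dispersion of the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DetectorConfig

__all__ = ["Fixation", "detect_fixations", "fixation_sequence_summary", "FixationDetector"]


@dataclass(frozen=True)
class Fixation:
    """One detected fixation.

    Indices refer to positions in the retained-sample arrays handed to the
    detector.  ``lead_index`` always equals ``start_index`` under the greedy
    lead rule; both are kept so downstream code never has to assume it.
    """

    lead_index: int
    start_index: int
    end_index: int  # inclusive
    start_t: float
    end_t: float
    n_samples: int
    duration_ms: float
    centroid_xy: tuple[float, float]

    @property
    def member_indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


def detect_fixations(t, x, y, config: DetectorConfig | None = None) -> list[Fixation]:
    """Segment a retained (gap-free-of-NaN) sample stream into fixations.

    Parameters
    ----------
    t, x, y
        Equal-length 1-D arrays: timestamps in ms (strictly increasing) and
        screen coordinates in px of the retained samples.
    config
        Detector parameters; defaults are 37 px, 3 samples, 60 Hz.

    Returns
    -------
    list of Fixation, time-ordered and non-overlapping.
    """
    config = config or DetectorConfig()
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (t.shape == x.shape == y.shape) or t.ndim != 1:
        raise ValueError("t, x, y must be 1-D arrays of equal length")
    n = t.size
    if n == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing samples must be removed before detection")

    interval = config.sample_interval_ms
    # Gap rule: a run closes when consecutive retained samples are more than
    # gap_tolerance_intervals nominal intervals apart.  The gap is rounded
    # to whole intervals first so that a single dropped sample (exactly two
    # intervals) never splits a run just because timestamps jitter around
    # the boundary.
    tol_intervals = config.gap_tolerance_intervals
    disp2 = config.dispersion_px * config.dispersion_px

    fixations: list[Fixation] = []
    lead = 0
    run_start = 0
    # precomputed helpers keep the per-sample loop cheap
    gap_breaks = (np.rint(np.diff(t) / interval) > tol_intervals).tolist()
    xs, ys, ts = x.tolist(), y.tolist(), t.tolist()
    cum_x = np.concatenate([[0.0], np.cumsum(x)])
    cum_y = np.concatenate([[0.0], np.cumsum(y)])

    def close(run_end: int) -> None:
        m = run_end - run_start + 1
        if m >= config.min_samples:
            fixations.append(
                Fixation(
                    lead_index=lead,
                    start_index=run_start,
                    end_index=run_end,
                    start_t=ts[run_start],
                    end_t=ts[run_end],
                    n_samples=m,
                    duration_ms=m * interval,
                    centroid_xy=(
                        (cum_x[run_end + 1] - cum_x[run_start]) / m,
                        (cum_y[run_end + 1] - cum_y[run_start]) / m,
                    ),
                )
            )

    lx, ly = xs[0], ys[0]
    for i in range(1, n):
        dx = xs[i] - lx
        dy = ys[i] - ly
        if gap_breaks[i - 1] or dx * dx + dy * dy > disp2:
            close(i - 1)
            lead = i
            run_start = i
            lx, ly = xs[i], ys[i]
    close(n - 1)
    return fixations


def fixation_sequence_summary(fixations: list[Fixation]) -> dict:
    """Count, total duration, and durations of the first three fixations.

    Absent ordinal fixations are reported as NaN.
    """
    durations = [f.duration_ms for f in fixations]
    ordinals = durations[:3] + [math.nan] * (3 - min(len(durations), 3))
    return {
        "n_fixations": len(fixations),
        "total_duration_ms": float(sum(durations)),
        "first_fixation_ms": ordinals[0],
        "second_fixation_ms": ordinals[1],
        "third_fixation_ms": ordinals[2],
    }


def fixations_to_frame(fixations, participant_id=None, slide_id=None) -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "slide_id": slide_id,
            "fix_index": i,
            "start_ms": f.start_t,
            "n_samples": f.n_samples,
            "duration_ms": f.duration_ms,
            "cx": f.centroid_xy[0],
            "cy": f.centroid_xy[1],
        }
        for i, f in enumerate(fixations)
    ]
    cols = ["participant_id", "slide_id", "fix_index", "start_ms", "n_samples", "duration_ms", "cx", "cy"]
    return pd.DataFrame(rows, columns=cols)


class FixationDetector:
    """Stateless sklearn-style transformer wrapping :func:`detect_fixations`.

    ``transform`` accepts a single trial recording or an iterable of them
    (anything with ``participant_id``, ``slide_id`` and a ``retained()``
    method returning ``(t, x, y)``) and returns one tidy fixation table.
    """

    def __init__(self, dispersion_px: float = 37.0, min_samples: int = 3,
                 sampling_rate_hz: float = 60.0, gap_tolerance_intervals: float = 2.0):
        self.dispersion_px = dispersion_px
        self.min_samples = min_samples
        self.sampling_rate_hz = sampling_rate_hz
        self.gap_tolerance_intervals = gap_tolerance_intervals

    def _config(self) -> DetectorConfig:
        return DetectorConfig(
            dispersion_px=self.dispersion_px,
            min_samples=self.min_samples,
            sampling_rate_hz=self.sampling_rate_hz,
            gap_tolerance_intervals=self.gap_tolerance_intervals,
        )

    def get_params(self, deep: bool = True) -> dict:
        return {
            "dispersion_px": self.dispersion_px,
            "min_samples": self.min_samples,
            "sampling_rate_hz": self.sampling_rate_hz,
            "gap_tolerance_intervals": self.gap_tolerance_intervals,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> pd.DataFrame:
        cfg = self._config()
        recs = X if isinstance(X, (list, tuple)) else [X]
        frames = []
        for rec in recs:
            t, x, y = rec.retained()
            fx = detect_fixations(t, x, y, cfg)
            frames.append(fixations_to_frame(fx, rec.participant_id, rec.slide_id))
        if not frames:
            return fixations_to_frame([])
        return pd.concat(frames, ignore_index=True)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
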