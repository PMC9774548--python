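"""Data model and readers/writers for gaze logs, rosters and metric tables.

The neutral interchange formats are plain delimited text (CSV, or TSV
autodetected by the sniffer):

* gaze log — ``participant_id, slide_id, t_ms, lx, ly, rx, ry`` with blank
  cells for missing eyes; one row per sample.  A ``t_s`` column (seconds)
  is accepted instead of ``t_ms`` and converted on read.
* roster — ``participant_id, nationality, gender, age``.
* metrics table — tidy, one row per participant x slide x AOI (see
  :func:`write_metrics_table`).

The mean binocular position is the coordinate-wise average of the two eyes;
when only one eye was tracked it falls back to that eye, and a sample with
neither eye is retained as a missing sample (it contributes to no fixation
but keeps the record of track loss).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ScreenConfig

NATIONALITIES = ("somali", "czech")
GENDERS = ("woman", "man")

GAZE_COLUMNS = ["participant_id", "slide_id", "t_ms", "lx", "ly", "rx", "ry"]
METRIC_COLUMNS = [
    "participant_id",
    "slide_id",
    "aoi",
    "n_fixations",
    "fixation_time_ms",
    "first_fixation_ms",
    "second_fixation_ms",
    "third_fixation_ms",
    "n_sample_measurements",
]


@dataclass(frozen=True)
class GazeSample:
    """One time-stamped binocular measurement (times in ms from slide onset)."""

    t: float
    left_xy: tuple[float, float] | None = None
    right_xy: tuple[float, float] | None = None

    @property
    def mean_xy(self) -> tuple[float, float] | None:
        if self.left_xy is not None and self.right_xy is not None:
            return (
                (self.left_xy[0] + self.right_xy[0]) / 2.0,
                (self.left_xy[1] + self.right_xy[1]) / 2.0,
            )
        return self.left_xy if self.left_xy is not None else self.right_xy


@dataclass
class Participant:
    participant_id: str
    nationality: str
    gender: str
    age: float

    def __post_init__(self) -> None:
        if self.nationality not in NATIONALITIES:
            raise ValueError(f"unknown nationality {self.nationality!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")


@dataclass
class TrialRecording:
    """All samples of one participant viewing one slide.

    ``samples`` holds columns ``t, lx, ly, rx, ry, mx, my`` sorted by ``t``;
    ``mx, my`` are the mean binocular coordinates (NaN when both eyes are
    missing).
    """

    participant_id: str
    slide_id: str
    samples: pd.DataFrame
    pair_type: str | None = None
    orientation: str | None = None

    def retained(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Timestamps and mean-binocular coordinates of non-missing samples."""
        vals = self.samples[["t", "mx", "my"]].to_numpy(dtype=float)
        good = ~np.isnan(vals[:, 1])
        vals = vals[good]
        return vals[:, 0], vals[:, 1], vals[:, 2]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _mean_binocular(df: pd.DataFrame) -> pd.DataFrame:
    """Add mx/my columns: average of both eyes, or the single available eye."""
    both = df["lx"].notna() & df["rx"].notna()
    mx = np.where(both, (df["lx"] + df["rx"]) / 2.0, df["lx"].fillna(df["rx"]))
    my = np.where(both, (df["ly"] + df["ry"]) / 2.0, df["ly"].fillna(df["ry"]))
    out = df.copy()
    out["mx"] = mx
    out["my"] = my
    return out


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_gaze_table(path, screen: ScreenConfig | None = None,
                    known_slides: Iterable[str] | None = None) -> list[TrialRecording]:
    """Read a delimited gaze log into one TrialRecording per participant x slide.

    Rows with no eye data are retained as missing samples.  Rows are sorted
    by timestamp within each trial.  Malformed rows (non-numeric timestamp
    or half-specified eye coordinates) raise a ValueError naming the row;
    with ``known_slides`` given, unknown slide ids raise too.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype={"participant_id": str, "slide_id": str})
    if "t_s" in df.columns and "t_ms" not in df.columns:
        df["t_ms"] = df.pop("t_s") * 1000.0
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze table lacks columns: {missing}")
    for c in ["t_ms", "lx", "ly", "rx", "ry"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad_t = df["t_ms"].isna() | (df["t_ms"] < 0)
    if bad_t.any():
        raise ValueError(f"malformed timestamp in row {int(np.flatnonzero(bad_t)[0]) + 2} of {path.name}")
    half = (df["lx"].isna() != df["ly"].isna()) | (df["rx"].isna() != df["ry"].isna())
    if half.any():
        raise ValueError(f"half-specified eye coordinates in row {int(np.flatnonzero(half)[0]) + 2} of {path.name}")
    if known_slides is not None:
        unknown = set(df["slide_id"]) - set(known_slides)
        if unknown:
            raise ValueError(f"unknown slide ids: {sorted(unknown)}")

    df = _mean_binocular(df.rename(columns={"t_ms": "t"}))
    recordings = []
    for (pid, sid), g in df.groupby(["participant_id", "slide_id"], sort=True):
        g = g.sort_values("t", kind="stable").reset_index(drop=True)
        recordings.append(
            TrialRecording(pid, sid, g[["t", "lx", "ly", "rx", "ry", "mx", "my"]])
        )
    return recordings


def write_gaze_table(recordings: Iterable[TrialRecording], path) -> None:
    frames = []
    for rec in recordings:
        g = rec.samples[["t", "lx", "ly", "rx", "ry"]].rename(columns={"t": "t_ms"}).copy()
        g.insert(0, "slide_id", rec.slide_id)
        g.insert(0, "participant_id", rec.participant_id)
        frames.append(g)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def validate_recording(rec: TrialRecording, screen: ScreenConfig | None = None,
                       nominal_duration_ms: float = 5000.0) -> list[str]:
    """Report (never fix) data-quality issues in one recording."""
    screen = screen or ScreenConfig()
    issues: list[str] = []
    t = rec.samples["t"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        issues.append("non-monotone timestamps")
    for col, bound in (("mx", screen.width_px), ("my", screen.height_px)):
        v = rec.samples[col].to_numpy(dtype=float)
        bad = np.flatnonzero((v < 0) | (v >= bound))
        for i in bad:
            issues.append(f"out-of-bounds {col}={v[i]:.1f} at sample {int(i)}")
    if t.size:
        span = t[-1] - t[0]
        slack = 2.0 * 1000.0 / screen.sampling_rate_hz
        if span > nominal_duration_ms + slack:
            issues.append(f"duration {span:.0f} ms exceeds nominal {nominal_duration_ms:.0f} ms")
    expected = nominal_duration_ms / 1000.0 * screen.sampling_rate_hz
    if rec.n_samples > expected * 1.2:
        issues.append(f"{rec.n_samples} samples where about {expected:.0f} were expected")
    return issues


def write_metrics_table(metrics: pd.DataFrame, path) -> None:
    """Write the tidy per participant x slide x AOI metrics table.

    Column order is stable and the table round-trips losslessly through
    :func:`read_metrics_table`.
    """
    out = pd.DataFrame(metrics, columns=METRIC_COLUMNS) if len(metrics) else pd.DataFrame(columns=METRIC_COLUMNS)
    out = out[METRIC_COLUMNS]
    out.to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "slide_id": str, "aoi": str})
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    return df[METRIC_COLUMNS]


def read_roster(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    need = ["participant_id", "nationality", "gender", "age"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"roster lacks columns: {missing}")
    for _, row in df.iterrows():
        Participant(row["participant_id"], row["nationality"], row["gender"], row["age"])
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant ids in roster")
    return df[need]


def write_roster(roster: pd.DataFrame, path) -> None:
    roster[["participant_id", "nationality", "gender", "age"]].to_csv(path, index=False)
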