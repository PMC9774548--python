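"""Screen, detector and AOI configuration.

Coordinates are screen pixels with the origin in the top-left corner,
x increasing rightward and y downward.  All defaults describe a
1920 x 1080 display sampled at 60 Hz where 37 px subtend 1 degree of
visual angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class ScreenConfig:
    """Display geometry and nominal sampling rate of the eye tracker."""

    width_px: int = 1920
    height_px: int = 1080
    sampling_rate_hz: float = 60.0
    px_per_degree: float = 37.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the lead-sample dispersion fixation detector.

    dispersion_px
        Maximal Euclidean distance (inclusive) of a member sample from the
        lead sample of its fixation; default 37 px = 1 degree.
    min_samples
        Minimal run length for a run to count as a fixation (3 samples at
        60 Hz, i.e. a minimal fixation duration of 50 ms).
    gap_tolerance_intervals
        A run is closed whenever the time between two consecutive retained
        samples exceeds this many nominal sampling intervals (missing
        samples are dropped upstream; short dropouts do not break a run).
    """

    dispersion_px: float = 37.0
    min_samples: int = 3
    sampling_rate_hz: float = 60.0
    gap_tolerance_intervals: float = 2.0

    def __post_init__(self) -> None:
        if self.dispersion_px <= 0:
            raise ValueError("dispersion_px must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def sample_interval_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class AOI:
    """Rectangular area of interest, half-open: x0 <= x < x1, y0 <= y < y1."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"AOI {self.name!r} has empty extent")

    def contains(self, x, y):
        """Vectorised membership test (NaN-safe: NaN is outside)."""
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def overlaps(self, other: "AOI") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


def default_aois(screen: ScreenConfig | None = None) -> list[AOI]:
    """Three disjoint AOIs: left stimulus, right stimulus, fixation cross.

    The study design only fixes the roles (left / right / cross) and that
    the rectangles never overlap; the pixel bounds below are this package's
    declared defaults and are fully configurable.
    """
    screen = screen or ScreenConfig()
    w, h = screen.width_px, screen.height_px
    return [
        AOI("left", 0, 0, 860 * w / 1920, h),
        AOI("right", 1060 * w / 1920, 0, w, h),
        AOI("cross", 860 * w / 1920, 440 * h / 1080, 1060 * w / 1920, 640 * h / 1080),
    ]


def validate_aois(aois: Sequence[AOI], screen: ScreenConfig | None = None) -> None:
    """Raise ValueError on overlapping or out-of-screen AOIs."""
    names = [a.name for a in aois]
    if len(set(names)) != len(names):
        raise ValueError("duplicate AOI names")
    for i, a in enumerate(aois):
        for b in aois[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"AOIs {a.name!r} and {b.name!r} overlap")
    if screen is not None:
        for a in aois:
            if a.x0 < 0 or a.y0 < 0 or a.x1 > screen.width_px or a.y1 > screen.height_px:
                raise ValueError(f"AOI {a.name!r} exceeds screen bounds")


@dataclass
class AnalysisConfig:
    """One bundle for everything the pipeline needs besides the data."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    aois: list[AOI] = field(default_factory=default_aois)
    max_combined_fixation_ms: float = 5500.0

    def __post_init__(self) -> None:
        validate_aois(self.aois, self.screen)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a JSON file.

    Recognised keys: ``screen``, ``detector``, ``aois`` (list of
    ``{name, x0, y0, x1, y1}``), ``max_combined_fixation_ms``.  Missing keys
    fall back to the defaults above.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a JSON object")
    screen = ScreenConfig(**raw.get("screen", {}))
    det = dict(raw.get("detector", {}))
    det.setdefault("sampling_rate_hz", screen.sampling_rate_hz)
    detector = DetectorConfig(**det)
    if "aois" in raw:
        aois = [AOI(**a) for a in raw["aois"]]
    else:
        aois = default_aois(screen)
    return AnalysisConfig(
        screen=screen,
        detector=detector,
        aois=aois,
        max_combined_fixation_ms=raw.get("max_combined_fixation_ms", 5500.0),
    )


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    payload = {
        "screen": asdict(cfg.screen),
        "detector": asdict(cfg.detector),
        "aois": [asdict(a) for a in cfg.aois],
        "max_combined_fixation_ms": cfg.max_combined_fixation_ms,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
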