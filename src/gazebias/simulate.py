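"""Synthetic gaze cohorts with exported ground truth.

The generator emulates the study conditions: binocular 60 Hz sampling over
5 s slides on a 1920 x 1080 screen, 36 paired-stimulus slides per
participant (3 pair types x 6 base pairs x 2 mirror orientations, shown in
an interlaced pseudo-random order, reversed for half the cohort), a
132-strong two-nationality roster, track loss, and attentional bias that
depends on pair type, nationality and gender.

Bias is planted directly: for every trial the generator draws latent
fixation-time and fixation-count differences from the configured cell mean
plus a participant random intercept and a nationality-scaled residual, then
assembles the sample stream so the planted allocation is exactly what the
detection/AOI/curation pipeline measures (fixations are jittered well
inside the dispersion radius and separated by blank saccade gaps longer
than the detector's gap tolerance; planted sample budgets are inflated by
1/(1 - track-loss rate) so the configured values are expectations of the
*measured* metrics).  This makes the configured cell means exact ground
truth for parameter-recovery and coverage tests.

The default cell means are the study's reported attentional-bias estimates;
they, the cohort composition and the exclusion-injection rates together
define the default simulated experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import AOI, DetectorConfig, ScreenConfig, default_aois
from .io import TrialRecording
from .schedule import (build_pairs, default_image_set, make_schedule,
                       mirror_pairs, reverse_schedule)

__all__ = ["GeneratorConfig", "GroundTruth", "simulate_trial", "simulate_cohort",
           "score_recovery", "GazeCohortSimulator",
           "DEFAULT_TIME_DIFF_MS", "DEFAULT_COUNT_DIFF"]

PAIR_TYPES = ("spider-grasshopper", "scorpion-grasshopper", "spider-scorpion")

# Default planted attentional-bias cell means, keyed by
# (pair_type, nationality, gender): expected fixation-time difference (ms)
# and fixation-count difference, first-named animal minus second
# (scorpion minus spider for spider-scorpion pairs).
DEFAULT_TIME_DIFF_MS: dict[tuple[str, str, str], float] = {
    ("spider-grasshopper", "somali", "woman"): 414.54,
    ("scorpion-grasshopper", "somali", "woman"): 741.86,
    ("spider-scorpion", "somali", "woman"): 322.81,
    ("spider-grasshopper", "czech", "woman"): 92.39,
    ("scorpion-grasshopper", "czech", "woman"): 419.71,
    ("spider-scorpion", "czech", "woman"): 0.66,
    ("spider-grasshopper", "somali", "man"): 709.93,
    ("scorpion-grasshopper", "somali", "man"): 1037.25,
    ("spider-scorpion", "somali", "man"): 618.20,
    ("spider-grasshopper", "czech", "man"): 387.77,
    ("scorpion-grasshopper", "czech", "man"): 715.09,
    ("spider-scorpion", "czech", "man"): 296.04,
}

DEFAULT_COUNT_DIFF: dict[tuple[str, str, str], float] = {
    ("spider-grasshopper", "somali", "woman"): 1.23,
    ("scorpion-grasshopper", "somali", "woman"): 3.40,
    ("spider-scorpion", "somali", "woman"): 1.28,
    ("spider-grasshopper", "czech", "woman"): 0.23,
    ("scorpion-grasshopper", "czech", "woman"): 2.39,
    ("spider-scorpion", "czech", "woman"): 0.28,
    ("spider-grasshopper", "somali", "man"): 2.49,
    ("scorpion-grasshopper", "somali", "man"): 4.65,
    ("spider-scorpion", "somali", "man"): 2.54,
    ("spider-grasshopper", "czech", "man"): 1.48,
    ("scorpion-grasshopper", "czech", "man"): 3.65,
    ("spider-scorpion", "czech", "man"): 1.53,
}

DEFAULT_COHORT: dict[tuple[str, str], int] = {
    ("somali", "woman"): 24,
    ("somali", "man"): 41,
    ("czech", "woman"): 35,
    ("czech", "man"): 32,
}


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator.

    Cell-mean dictionaries may be partial; missing cells fall back to the
    defaults.  SDs are on the trial level: after mirror averaging an
    observation of weight w has residual variance
    ``resid_sd**2 * multiplier**2 / (2 w)``, exactly the structure the
    mixed models assume.
    """

    n_participants: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT))
    time_diff_ms: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TIME_DIFF_MS))
    count_diff: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COUNT_DIFF))
    participant_sd_ms: float = 400.0
    participant_sd_count: float = 2.0
    resid_sd_ms: float = 1200.0
    resid_sd_count: float = 3.5
    nat_sd_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"somali": 1.0, "czech": 1.0})
    position_effect_ms: float | Mapping[str, float] = 0.0  # added to the LEFT stimulus
    # gaze-stream mechanics
    mean_total_fixations: float = 14.0
    sd_total_fixations: float = 2.0
    fix_median_ms: float = 250.0
    fix_log_sd: float = 0.4
    jitter_sd_px: float = 3.0
    eye_offset_px: float = 15.0
    saccade_gap_samples: int = 2
    cross_dwell_mean_samples: float = 24.0
    cross_dwell_participant_sd: float = 5.0
    track_loss_p: float = 0.02
    single_eye_loss_p: float = 0.01
    border_straddle_p: float = 0.005
    # curation-violation injection (per-trial probabilities)
    invalid_a_rate: float = 19.0 / 4752.0
    invalid_b_rate: float = 346.0 / 4752.0
    slide_ms: float = 5000.0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    aois: list[AOI] = field(default_factory=default_aois)
    schedule_seed: int | None = None  # derived from the cohort seed when None

    def __post_init__(self) -> None:
        for p in (self.track_loss_p, self.single_eye_loss_p, self.border_straddle_p,
                  self.invalid_a_rate, self.invalid_b_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (self.participant_sd_ms, self.participant_sd_count,
                  self.resid_sd_ms, self.resid_sd_count, self.jitter_sd_px):
            if s < 0:
                raise ValueError("SDs must be nonnegative")

    def cell_time_diff(self, pair_type, nationality, gender) -> float:
        key = (pair_type, nationality, gender)
        return self.time_diff_ms.get(key, DEFAULT_TIME_DIFF_MS.get(key, 0.0))

    def cell_count_diff(self, pair_type, nationality, gender) -> float:
        key = (pair_type, nationality, gender)
        return self.count_diff.get(key, DEFAULT_COUNT_DIFF.get(key, 0.0))

    def position_shift(self, pair_type) -> float:
        if isinstance(self.position_effect_ms, Mapping):
            return float(self.position_effect_ms.get(pair_type, 0.0))
        return float(self.position_effect_ms)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    time_diff_ms: dict
    count_diff: dict
    participant_sd_ms: float
    participant_sd_count: float
    resid_sd_ms: float
    resid_sd_count: float
    nat_sd_multiplier: dict
    trials: pd.DataFrame  # per-trial latent allocation and injection flags
    participant_effects: pd.DataFrame
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "time_diff_ms": {"|".join(k): v for k, v in self.time_diff_ms.items()},
            "count_diff": {"|".join(k): v for k, v in self.count_diff.items()},
            "participant_sd_ms": self.participant_sd_ms,
            "participant_sd_count": self.participant_sd_count,
            "resid_sd_ms": self.resid_sd_ms,
            "resid_sd_count": self.resid_sd_count,
            "nat_sd_multiplier": dict(self.nat_sd_multiplier),
            "seed": self.seed,
            "trials": self.trials.to_dict(orient="list"),
            "participant_effects": self.participant_effects.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _partition_duration(total: int, n: int, cfg: GeneratorConfig, rng) -> np.ndarray:
    """Split ``total`` samples into ``n`` integer fixation durations >= 3."""
    if n == 0:
        return np.zeros(0, dtype=int)
    base = 3 * n
    if total < base:
        raise ValueError("total too small for the requested fixation count")
    shares = rng.lognormal(np.log(cfg.fix_median_ms), cfg.fix_log_sd, size=n)
    shares /= shares.sum()
    extra = total - base
    alloc = np.floor(shares * extra).astype(int)
    rem = extra - alloc.sum()
    order = np.argsort(shares * extra - alloc)[::-1]
    alloc[order[:rem]] += 1
    return alloc + 3


def _anchor(aoi: AOI, cfg: GeneratorConfig, rng) -> np.ndarray:
    m = 5.0 * cfg.jitter_sd_px + cfg.eye_offset_px + 2.0
    return np.array([
        rng.uniform(aoi.x0 + m, aoi.x1 - m),
        rng.uniform(aoi.y0 + m, aoi.y1 - m),
    ])


def _border_anchor(side_aoi: AOI, cross: AOI, rng) -> np.ndarray:
    """Anchor sitting exactly on the border between a stimulus AOI and the cross."""
    x = cross.x0 if side_aoi.x1 <= cross.x0 + 1e-9 else cross.x1
    y = rng.uniform(cross.y0 + 20, cross.y1 - 20)
    return np.array([float(x), float(y)])


def simulate_trial(cfg: GeneratorConfig, rng, participant: dict, slide: dict,
                   latent: dict) -> tuple[TrialRecording, dict]:
    """Assemble one 300-sample trial realising a planted allocation.

    ``latent`` carries the trial's latent differences (``d_time_ms``,
    ``d_count``) and the injection flag (``None``, ``'a'`` or ``'b'``).
    Returns the recording plus the realised plan for the ground-truth log.
    """
    dt = cfg.screen.sample_interval_ms
    n_rows = int(round(cfg.slide_ms / dt))
    aois = {a.name: a for a in cfg.aois}
    left_aoi, right_aoi, cross_aoi = aois["left"], aois["right"], aois["cross"]

    focal_side = "left" if slide["left_category"] == latent["focal_animal"] else "right"
    inject = latent.get("inject")

    # planted counts
    n_total = int(np.clip(np.round(rng.normal(cfg.mean_total_fixations, cfg.sd_total_fixations)), 1, 24))
    if inject == "b" or n_total == 1:
        n_f, n_o = n_total, 0
    else:
        n_f = int(np.clip(np.round((n_total + latent["d_count"]) / 2.0), 1, n_total - 1))
        n_o = n_total - n_f

    # sample budget
    g = cfg.saccade_gap_samples
    base = participant["cross_base"]
    cross_dwell = int(np.clip(np.round(rng.normal(base, 2.0)),
                              max(0.0, base - 10.0), base + 16.0))
    S = n_rows - cross_dwell - g * n_total
    while S < 3 * n_total + 2 and n_total > 2:
        n_total -= 1
        n_f = min(n_f, max(n_total - (0 if inject == "b" else 1), 1))
        n_o = n_total - n_f
        S = n_rows - cross_dwell - g * n_total

    # planted times (inflated so the post-track-loss expectation hits target)
    comp = 1.0 / (1.0 - cfg.track_loss_p) if cfg.track_loss_p < 1 else 1.0
    d_samples = int(np.round(latent["d_time_ms"] / dt * comp))
    if inject == "b" or n_o == 0:
        T_f, T_o = S, 0
    else:
        T_f = int(np.clip(np.round((S + d_samples) / 2.0), 3 * n_f, S - 3 * n_o))
        T_o = S - T_f

    dur_f = _partition_duration(T_f, n_f, cfg, rng)
    dur_o = _partition_duration(T_o, n_o, cfg, rng)
    other_side = "right" if focal_side == "left" else "left"
    fixations = [(focal_side, int(d)) for d in dur_f] + [(other_side, int(d)) for d in dur_o]
    rng.shuffle(fixations)

    # coordinates
    side_aoi = {"left": left_aoi, "right": right_aoi}
    xy = np.full((n_rows, 2), np.nan)
    jitter = rng.normal(0, cfg.jitter_sd_px, (n_rows, 2))
    pos = 0
    cross_anchor = np.array([(cross_aoi.x0 + cross_aoi.x1) / 2.0,
                             (cross_aoi.y0 + cross_aoi.y1) / 2.0])
    xy[pos:pos + cross_dwell] = cross_anchor + jitter[pos:pos + cross_dwell]
    pos += cross_dwell
    for side, dur in fixations:
        pos += g  # blank saccade gap: longer than the detector's gap tolerance
        if inject == "a" or (cfg.border_straddle_p > 0 and rng.random() < cfg.border_straddle_p):
            anchor = _border_anchor(side_aoi[side], cross_aoi, rng)
        else:
            anchor = _anchor(side_aoi[side], cfg, rng)
        xy[pos:pos + dur] = anchor + jitter[pos:pos + dur]
        pos += dur
    # any remaining rows stay blank (possible after budget shrinking)

    t = np.arange(n_rows) * dt + rng.normal(0.0, 0.3, n_rows)
    t = np.maximum.accumulate(t)  # temporal jitter, kept monotone
    t += np.arange(n_rows) * 1e-6
    if t[0] < 0.0:
        t -= t[0]

    off = np.array([cfg.eye_offset_px, 0.0])
    noise = lambda: rng.normal(0, 0.8, (n_rows, 2))
    left_eye = xy - off + noise()
    right_eye = xy + off + noise()
    lost = rng.random(n_rows) < cfg.track_loss_p
    left_eye[lost] = np.nan
    right_eye[lost] = np.nan
    one_eye = rng.random(n_rows) < cfg.single_eye_loss_p
    which = rng.random(n_rows) < 0.5
    left_eye[one_eye & which] = np.nan
    right_eye[one_eye & ~which] = np.nan

    both = ~np.isnan(left_eye[:, 0]) & ~np.isnan(right_eye[:, 0])
    mx = np.where(both, (left_eye[:, 0] + right_eye[:, 0]) / 2.0,
                  np.where(np.isnan(left_eye[:, 0]), right_eye[:, 0], left_eye[:, 0]))
    my = np.where(both, (left_eye[:, 1] + right_eye[:, 1]) / 2.0,
                  np.where(np.isnan(left_eye[:, 1]), right_eye[:, 1], left_eye[:, 1]))

    samples = pd.DataFrame({
        "t": t,
        "lx": left_eye[:, 0], "ly": left_eye[:, 1],
        "rx": right_eye[:, 0], "ry": right_eye[:, 1],
        "mx": mx, "my": my,
    })
    rec = TrialRecording(participant["participant_id"], slide["slide_id"], samples,
                         pair_type=slide["pair_type"], orientation=slide["orientation"])
    plan = {
        "participant_id": participant["participant_id"],
        "slide_id": slide["slide_id"],
        "base_pair_id": slide["base_pair_id"],
        "pair_type": slide["pair_type"],
        "focal_side": focal_side,
        "inject": inject or "",
        "d_time_latent_ms": latent["d_time_ms"],
        "d_count_latent": latent["d_count"],
        "n_f": n_f, "n_o": n_o,
        "T_f_ms": T_f * dt, "T_o_ms": T_o * dt,
    }
    return rec, plan


def simulate_cohort(cfg: GeneratorConfig | None = None, seed: int = 0
                    ) -> tuple[list[TrialRecording], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full cohort: recordings, roster, schedule and ground truth.

    Deterministic given ``seed``; all randomness flows from one
    ``numpy.random.default_rng(seed)`` stream.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)

    # roster
    rows = []
    k = 0
    age_mean = {"somali": 22.2, "czech": 24.3}
    for (nat, gen), n in cfg.n_participants.items():
        for _ in range(n):
            k += 1
            age = float(np.clip(np.round(rng.gamma(4.0, 1.5) + age_mean[nat] - 6.0), 18, 44))
            rows.append({"participant_id": f"p{k:03d}", "nationality": nat,
                         "gender": gen, "age": age})
    roster = pd.DataFrame(rows)

    # stimuli and schedule (one order + its reverse for half the cohort)
    sched_seed = cfg.schedule_seed if cfg.schedule_seed is not None else int(rng.integers(2**31 - 1))
    slides = mirror_pairs(build_pairs(default_image_set()))
    forward = make_schedule(slides, seed=sched_seed)
    backward = reverse_schedule(forward)
    schedule_df = forward.to_frame()

    # participant-level effects
    n_part = len(roster)
    eff = pd.DataFrame({
        "participant_id": roster["participant_id"],
        "b_time_ms": rng.normal(0, cfg.participant_sd_ms, n_part),
        "b_count": rng.normal(0, cfg.participant_sd_count, n_part),
        "cross_base": np.clip(
            rng.normal(cfg.cross_dwell_mean_samples, cfg.cross_dwell_participant_sd, n_part),
            max(0.0, cfg.cross_dwell_mean_samples - 2.0 * cfg.cross_dwell_participant_sd),
            cfg.cross_dwell_mean_samples + 2.0 * cfg.cross_dwell_participant_sd),
    })

    recordings: list[TrialRecording] = []
    plans = []
    from .analysis import PAIR_DIFFERENCE

    for i, prow in roster.iterrows():
        part = {**prow.to_dict(), **eff.iloc[i][["b_time_ms", "b_count", "cross_base"]].to_dict()}
        order = forward if i % 2 == 0 else backward
        mult = float(cfg.nat_sd_multiplier.get(prow["nationality"], 1.0))
        for sl in order.slides:
            slide = {
                "slide_id": sl.pair_id, "base_pair_id": sl.base_pair_id,
                "pair_type": sl.pair_type, "orientation": sl.orientation,
                "left_category": sl.left_category, "right_category": sl.right_category,
            }
            focal, _ = PAIR_DIFFERENCE[sl.pair_type]
            mu_t = cfg.cell_time_diff(sl.pair_type, prow["nationality"], prow["gender"])
            mu_c = cfg.cell_count_diff(sl.pair_type, prow["nationality"], prow["gender"])
            pos_shift = cfg.position_shift(sl.pair_type)
            side_sign = 1.0 if sl.left_category == focal else -1.0
            d_time = (mu_t + part["b_time_ms"] + rng.normal(0, cfg.resid_sd_ms) * mult
                      + pos_shift * side_sign)
            d_count = mu_c + part["b_count"] + rng.normal(0, cfg.resid_sd_count) * mult
            u = rng.random()
            inject = "a" if u < cfg.invalid_a_rate else (
                "b" if u < cfg.invalid_a_rate + cfg.invalid_b_rate else None)
            latent = {"d_time_ms": d_time, "d_count": d_count,
                      "focal_animal": focal, "inject": inject}
            rec, plan = simulate_trial(cfg, rng, part, slide, latent)
            recordings.append(rec)
            plans.append(plan)

    truth = GroundTruth(
        time_diff_ms={k: cfg.cell_time_diff(*k)
                      for k in _all_cells(cfg)},
        count_diff={k: cfg.cell_count_diff(*k)
                    for k in _all_cells(cfg)},
        participant_sd_ms=cfg.participant_sd_ms,
        participant_sd_count=cfg.participant_sd_count,
        resid_sd_ms=cfg.resid_sd_ms,
        resid_sd_count=cfg.resid_sd_count,
        nat_sd_multiplier=dict(cfg.nat_sd_multiplier),
        trials=pd.DataFrame(plans),
        participant_effects=eff,
        seed=seed,
    )
    return recordings, roster, schedule_df, truth


def _all_cells(cfg: GeneratorConfig):
    nats = sorted({n for n, _ in cfg.n_participants})
    gens = sorted({g for _, g in cfg.n_participants})
    return [(pt, n, g) for pt in PAIR_TYPES for n in nats for g in gens]


def score_recovery(truth: GroundTruth, reports: list[pd.DataFrame],
                   value: str = "time") -> pd.DataFrame:
    """Per-cell bias, RMSE and CI coverage of model reports against truth.

    ``reports`` is a list (one per analysed cohort) of cell-estimate tables
    as returned by :func:`analysis.test_differences_against_zero` (columns
    ``pair_type, nationality, gender, estimate, ci_low, ci_high``).
    """
    truths = truth.time_diff_ms if value == "time" else truth.count_diff
    rows = []
    for key, tv in truths.items():
        ests, covered = [], []
        for rep in reports:
            m = rep
            for col, val in zip(("pair_type", "nationality", "gender"), key):
                m = m[m[col] == val]
            if len(m) != 1:
                raise ValueError(f"report does not have exactly one row for cell {key}")
            r = m.iloc[0]
            ests.append(r["estimate"])
            covered.append(bool(r["ci_low"] <= tv <= r["ci_high"]))
        ests = np.asarray(ests)
        rows.append({
            "pair_type": key[0], "nationality": key[1], "gender": key[2],
            "truth": tv, "mean_estimate": float(ests.mean()),
            "bias": float(ests.mean() - tv),
            "rmse": float(np.sqrt(np.mean((ests - tv) ** 2))),
            "coverage": float(np.mean(covered)),
            "n_reports": len(reports),
        })
    return pd.DataFrame(rows)


class GazeCohortSimulator:
    """Sklearn-style wrapper: ``sample(seed)`` returns a simulated cohort."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def sample(self, seed: int = 0):
        cfg = self.config or GeneratorConfig()
        return simulate_cohort(cfg, seed=seed)
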