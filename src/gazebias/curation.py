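"""Trial exclusion rules and mirror-pair averaging with observation weights.

A trial (one participant viewing one slide) is excluded when

(a) its combined fixation time over all AOIs exceeds 5500 ms — the signature
    of failed measurements and of border-gazing, where whole-fixation
    accrual books the same fixation to several AOIs; or
(b) the left or the right AOI received zero fixations — gaze glued to a
    single stimulus measures either disinterest or extreme emotion, neither
    of which the paradigm wants.  The criterion never applies to the cross.

Kept slides are then collapsed over mirror pairs: the two slides showing
the same base pair in both left/right arrangements are averaged *per animal
category* (the schedule resolves which screen side held which animal), so
side preferences cancel.  A full mirror pair yields an observation of
weight 1.0; when only one of the two slides survived curation its values
are kept with weight 0.5, and the weight later scales the residual variance
in the mixed models.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["apply_exclusions", "count_cohort_measurements", "average_mirror_pairs",
           "curation_report", "TrialCurator", "MirrorPairAverager"]

CURATED_COLUMNS = ["participant_id", "base_pair_id", "pair_type", "animal",
                   "n_fixations", "fixation_time_ms", "count_sum", "n_slides", "weight"]


def _trial_flags(metrics: pd.DataFrame, max_combined_ms: float) -> pd.DataFrame:
    """Per-trial exclusion flags from the tidy metrics table."""
    total = metrics.groupby(["participant_id", "slide_id"])["fixation_time_ms"].sum()
    side = metrics[metrics["aoi"].isin(["left", "right"])]
    zero_side = side.groupby(["participant_id", "slide_id"])["n_fixations"].min() == 0
    flags = pd.DataFrame({"combined_ms": total})
    flags["criterion_a"] = flags["combined_ms"] > max_combined_ms  # strictly over
    flags["criterion_b"] = zero_side.reindex(flags.index, fill_value=True)
    return flags.reset_index()


def apply_exclusions(metrics: pd.DataFrame, max_combined_ms: float = 5500.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the tidy metrics table into kept rows and excluded trials.

    Returns ``(kept, excluded)``: ``kept`` holds the surviving tidy rows;
    ``excluded`` has one row per removed trial with a ``reason`` of
    ``'a'``, ``'b'`` or ``'ab'`` and the offending combined time.
    """
    if metrics.empty:
        return metrics.copy(), pd.DataFrame(
            columns=["participant_id", "slide_id", "reason", "combined_ms"])
    flags = _trial_flags(metrics, max_combined_ms)
    flags["reason"] = flags["criterion_a"].map({True: "a", False: ""}) + \
        flags["criterion_b"].map({True: "b", False: ""})
    excluded = flags[flags["reason"] != ""][
        ["participant_id", "slide_id", "reason", "combined_ms"]].reset_index(drop=True)
    bad = set(zip(excluded["participant_id"], excluded["slide_id"]))
    keep_mask = [
        (p, s) not in bad
        for p, s in zip(metrics["participant_id"], metrics["slide_id"])
    ]
    kept = metrics[keep_mask].reset_index(drop=True)
    return kept, excluded


def count_cohort_measurements(participants, schedule) -> int:
    """Number of trials the cohort contributes: valid participants x slides.

    ``participants`` may be a roster DataFrame, an iterable, or an int;
    ``schedule`` a PresentationSchedule, a schedule DataFrame, or an int.
    """
    if hasattr(participants, "participant_id"):
        n_part = participants["participant_id"].nunique()
    elif isinstance(participants, int):
        n_part = participants
    else:
        n_part = len(list(participants))
    if hasattr(schedule, "slides"):
        n_slides = len(schedule.slides)
    elif hasattr(schedule, "slide_id"):
        n_slides = schedule["slide_id"].nunique()
    elif isinstance(schedule, int):
        n_slides = schedule
    else:
        n_slides = len(list(schedule))
    return n_part * n_slides


def average_mirror_pairs(kept: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Collapse kept left/right AOI metrics over mirror pairs, per animal.

    Parameters
    ----------
    kept
        Tidy metrics rows that survived :func:`apply_exclusions`.
    schedule
        Schedule table with ``slide_id, base_pair_id, pair_type,
        left_category, right_category`` (maps screen side to animal).

    Returns
    -------
    One row per participant x base pair x animal with the mirror-mean
    ``n_fixations`` and ``fixation_time_ms``, the integer ``count_sum`` over
    the contributing slides, ``n_slides`` (1 or 2) and the observation
    ``weight`` (1.0 for a full pair, 0.5 for a lone slide).
    """
    sched = schedule.set_index("slide_id")
    unknown = set(kept["slide_id"]) - set(sched.index)
    if unknown:
        raise ValueError(f"slides missing from schedule: {sorted(unknown)}")

    side = kept[kept["aoi"].isin(["left", "right"])].copy()
    side["base_pair_id"] = sched["base_pair_id"].reindex(side["slide_id"]).to_numpy()
    side["pair_type"] = sched["pair_type"].reindex(side["slide_id"]).to_numpy()
    cat = {
        "left": sched["left_category"].reindex(side["slide_id"]).to_numpy(),
        "right": sched["right_category"].reindex(side["slide_id"]).to_numpy(),
    }
    side["animal"] = [cat[a][i] for i, a in enumerate(side["aoi"])]

    grp = side.groupby(["participant_id", "base_pair_id", "pair_type", "animal"], sort=True)
    out = grp.agg(
        n_fixations=("n_fixations", "mean"),
        fixation_time_ms=("fixation_time_ms", "mean"),
        count_sum=("n_fixations", "sum"),
        n_slides=("slide_id", "nunique"),
    ).reset_index()
    out["weight"] = out["n_slides"].map({2: 1.0, 1: 0.5})
    if out["weight"].isna().any():
        raise ValueError("a base pair contributed more than two slides")
    out["count_sum"] = out["count_sum"].astype(int)
    return out[CURATED_COLUMNS]


def curation_report(metrics: pd.DataFrame, excluded: pd.DataFrame,
                    curated: pd.DataFrame) -> dict:
    """Bookkeeping summary of both curation paths.

    ``n_trials_total`` / ``n_trials_excluded`` describe slide-level
    curation; ``n_halfpair_observations`` and ``n_slides_in_half_pairs``
    describe the second path, where the count model additionally drops
    every observation that lost its mirror mate.  Both denominators are
    reported side by side and deliberately left unreconciled.
    """
    n_total = metrics.groupby(["participant_id", "slide_id"]).ngroups
    pair_level = curated.drop_duplicates(["participant_id", "base_pair_id"])
    n_half = int((pair_level["weight"] == 0.5).sum())
    return {
        "n_trials_total": int(n_total),
        "n_trials_excluded": int(len(excluded)),
        "n_excluded_a": int(excluded["reason"].str.contains("a").sum()) if len(excluded) else 0,
        "n_excluded_b": int(excluded["reason"].str.contains("b").sum()) if len(excluded) else 0,
        "n_trials_kept": int(n_total - len(excluded)),
        "n_pair_observations": int(len(pair_level)),
        "n_halfpair_observations": n_half,
        "n_slides_in_half_pairs": n_half,  # each half pair keeps exactly one slide
    }


class TrialCurator:
    """Sklearn-style transformer applying the (a)/(b) exclusion rules."""

    def __init__(self, max_combined_ms: float = 5500.0):
        self.max_combined_ms = max_combined_ms

    def get_params(self, deep: bool = True) -> dict:
        return {"max_combined_ms": self.max_combined_ms}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept, excluded = apply_exclusions(X, self.max_combined_ms)
        self.excluded_ = excluded
        return kept

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class MirrorPairAverager:
    """Sklearn-style transformer collapsing metrics over mirror pairs."""

    def __init__(self, schedule: pd.DataFrame | None = None):
        self.schedule = schedule

    def get_params(self, deep: bool = True) -> dict:
        return {"schedule": self.schedule}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        if self.schedule is None:
            raise ValueError("MirrorPairAverager needs a schedule table")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return average_mirror_pairs(X, self.schedule)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
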