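"""Exclusion rules, cohort bookkeeping and mirror-pair averaging."""

import numpy as np
import pandas as pd
import pytest

from gazebias import GeneratorConfig, simulate_cohort
from gazebias.curation import (MirrorPairAverager, TrialCurator, apply_exclusions,
                               average_mirror_pairs, count_cohort_measurements,
                               curation_report)
from gazebias.pipeline import compute_metrics
from gazebias.schedule import build_pairs, default_image_set, make_schedule, mirror_pairs


def _trial_rows(pid, sid, left, right, cross):
    rows = []
    for aoi, (n, ms) in {"left": left, "right": right, "cross": cross}.items():
        rows.append({"participant_id": pid, "slide_id": sid, "aoi": aoi,
                     "n_fixations": n, "fixation_time_ms": ms,
                     "first_fixation_ms": np.nan, "second_fixation_ms": np.nan,
                     "third_fixation_ms": np.nan, "n_sample_measurements": 300})
    return rows


def test_exclusion_worked_examples():
    m = pd.DataFrame(
        _trial_rows("p1", "s1", (3, 2600.0), (3, 2600.0), (1, 400.0))    # (a): 5600 > 5500
        + _trial_rows("p1", "s2", (3, 2000.0), (0, 0.0), (1, 400.0))     # (b): zero right
        + _trial_rows("p1", "s3", (3, 2600.0), (0, 3000.0), (1, 400.0))  # both
        + _trial_rows("p1", "s4", (3, 2500.0), (3, 2500.0), (1, 500.0))  # exactly 5500: kept
        + _trial_rows("p1", "s5", (2, 2000.0), (2, 2000.0), (0, 0.0))    # zero cross: kept
    )
    kept, excluded = apply_exclusions(m)
    reasons = excluded.set_index("slide_id")["reason"].to_dict()
    assert reasons == {"s1": "a", "s2": "b", "s3": "ab"}
    assert set(kept["slide_id"]) == {"s4", "s5"}
    # partition: kept rows + excluded trials cover the input exactly
    assert len(kept) + 3 * len(excluded) == len(m)


def test_exclusion_idempotent_and_threshold_monotone(small_metrics):
    kept1, ex1 = apply_exclusions(small_metrics)
    kept2, ex2 = apply_exclusions(kept1)
    assert ex2.empty
    pd.testing.assert_frame_equal(kept1, kept2)
    shuffled = small_metrics.sample(frac=1.0, random_state=0)
    kept3, ex3 = apply_exclusions(shuffled)
    assert set(zip(ex3.participant_id, ex3.slide_id)) == set(zip(ex1.participant_id, ex1.slide_id))
    prev = -1
    for thr in (5000.0, 5500.0, 6000.0, 1e12):
        kept, _ = apply_exclusions(small_metrics, max_combined_ms=thr)
        assert len(kept) >= prev
        prev = len(kept)


def test_planted_violations_recovered_exactly():
    """Deterministic bookkeeping: the excluded set equals the injected set."""
    cfg = GeneratorConfig(
        n_participants={("somali", "man"): 5, ("czech", "woman"): 5},
        track_loss_p=0.0, single_eye_loss_p=0.0, border_straddle_p=0.0,
        invalid_a_rate=0.02, invalid_b_rate=0.08)
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=9)
    metrics = compute_metrics(recs)
    kept, excluded = apply_exclusions(metrics)
    injected = truth.trials[truth.trials["inject"] != ""]
    assert set(zip(excluded.participant_id, excluded.slide_id)) == \
        set(zip(injected.participant_id, injected.slide_id))
    by_reason = excluded["reason"].value_counts().to_dict()
    planted = injected["inject"].value_counts().to_dict()
    assert by_reason.get("a", 0) == planted.get("a", 0)
    assert by_reason.get("b", 0) == planted.get("b", 0)
    # independent oracle recount of the filter itself
    wide = metrics.pivot_table(index=["participant_id", "slide_id"], columns="aoi",
                               values=["fixation_time_ms", "n_fixations"])
    total = wide["fixation_time_ms"].sum(axis=1)
    zero = (wide["n_fixations"]["left"] == 0) | (wide["n_fixations"]["right"] == 0)
    assert int(((total > 5500) | zero).sum()) == len(excluded)


def test_count_cohort_measurements():
    schedule = make_schedule(mirror_pairs(build_pairs(default_image_set())), seed=0)
    roster = pd.DataFrame({"participant_id": [f"p{i}" for i in range(132)]})
    assert count_cohort_measurements(roster, schedule) == 4752
    assert count_cohort_measurements(1, 36) == 36
    assert count_cohort_measurements(0, schedule.to_frame()) == 0


def _schedule_two_slides():
    return pd.DataFrame({
        "position": [0, 1], "slide_id": ["SS1_o", "SS1_m"], "base_pair_id": ["SS1"] * 2,
        "pair_type": ["spider-scorpion"] * 2, "orientation": ["original", "mirrored"],
        "left_image": ["sp", "sc"], "right_image": ["sc", "sp"],
        "left_category": ["spider", "scorpion"], "right_category": ["scorpion", "spider"],
    })


def test_mirror_average_resolves_sides_to_animals():
    # spider is left on the original slide and right on the mirror
    m = pd.DataFrame(
        _trial_rows("p1", "SS1_o", (4, 2000.0), (6, 2600.0), (1, 200.0))
        + _trial_rows("p1", "SS1_m", (5, 2200.0), (2, 2400.0), (1, 200.0)))
    cur = average_mirror_pairs(m, _schedule_two_slides())
    spider = cur[cur.animal == "spider"].iloc[0]
    scorpion = cur[cur.animal == "scorpion"].iloc[0]
    assert spider.fixation_time_ms == pytest.approx((2000.0 + 2400.0) / 2)  # left_o + right_m
    assert scorpion.fixation_time_ms == pytest.approx((2600.0 + 2200.0) / 2)
    assert spider.weight == 1.0 and spider.n_slides == 2
    assert spider.count_sum == 4 + 2 and scorpion.count_sum == 6 + 5


def test_lone_slide_keeps_values_with_half_weight():
    m = pd.DataFrame(_trial_rows("p1", "SS1_o", (4, 2000.0), (6, 2400.0), (1, 200.0)))
    cur = average_mirror_pairs(m, _schedule_two_slides())
    assert set(cur.weight) == {0.5}
    assert cur[cur.animal == "spider"].fixation_time_ms.iloc[0] == 2000.0


def test_unknown_slide_errors():
    m = pd.DataFrame(_trial_rows("p1", "mystery", (1, 100.0), (1, 100.0), (0, 0.0)))
    with pytest.raises(ValueError, match="mystery"):
        average_mirror_pairs(m, _schedule_two_slides())


def test_weighted_mean_conserves_slide_means(small_cohort, small_metrics):
    """Curated per-animal means equal the plain mean over contributing kept
    slides, participant x base pair by participant x base pair."""
    kept, _ = apply_exclusions(small_metrics)
    cur = average_mirror_pairs(kept, small_cohort["schedule"])
    sched = small_cohort["schedule"].set_index("slide_id")
    side = kept[kept.aoi.isin(["left", "right"])].copy()
    side["base"] = sched["base_pair_id"].reindex(side.slide_id).to_numpy()
    lc = sched["left_category"].reindex(side.slide_id).to_numpy()
    rc = sched["right_category"].reindex(side.slide_id).to_numpy()
    side["animal"] = np.where(side.aoi == "left", lc, rc)
    manual = side.groupby(["participant_id", "base", "animal"]).fixation_time_ms.mean()
    merged = cur.set_index(["participant_id", "base_pair_id", "animal"])
    assert np.allclose(
        merged["fixation_time_ms"].sort_index().to_numpy(),
        manual.sort_index().to_numpy())


def test_curation_report_counts(small_cohort, small_metrics):
    kept, excluded = apply_exclusions(small_metrics)
    cur = average_mirror_pairs(kept, small_cohort["schedule"])
    rep = curation_report(small_metrics, excluded, cur)
    assert rep["n_trials_total"] == 16 * 36
    assert rep["n_trials_kept"] + rep["n_trials_excluded"] == rep["n_trials_total"]
    assert rep["n_halfpair_observations"] == rep["n_slides_in_half_pairs"]


def test_transformers_compose(small_cohort, small_metrics):
    curator = TrialCurator()
    kept = curator.fit_transform(small_metrics)
    assert len(curator.excluded_) > 0
    averager = MirrorPairAverager(schedule=small_cohort["schedule"])
    cur = averager.fit_transform(kept)
    assert set(cur.columns) >= {"participant_id", "base_pair_id", "animal", "weight"}
    with pytest.raises(ValueError, match="schedule"):
        MirrorPairAverager().fit()
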