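"""Synthetic cohort generator: determinism, closed-loop recovery, truth export."""

import numpy as np
import pandas as pd
import pytest

from gazebias import GeneratorConfig, simulate_cohort
from gazebias.analysis import compute_differences
from gazebias.config import DetectorConfig
from gazebias.curation import apply_exclusions, average_mirror_pairs, count_cohort_measurements
from gazebias.detection import detect_fixations
from gazebias.pipeline import compute_metrics
from gazebias.simulate import GazeCohortSimulator, score_recovery, simulate_trial

SMALL = {("somali", "woman"): 3, ("somali", "man"): 3,
         ("czech", "woman"): 3, ("czech", "man"): 3}


def test_same_seed_gives_identical_cohorts():
    cfg = GeneratorConfig(n_participants=dict(SMALL))
    recs1, roster1, sched1, truth1 = simulate_cohort(cfg, seed=7)
    recs2, roster2, sched2, truth2 = simulate_cohort(cfg, seed=7)
    pd.testing.assert_frame_equal(roster1, roster2)
    pd.testing.assert_frame_equal(sched1, sched2)
    pd.testing.assert_frame_equal(truth1.trials, truth2.trials)
    assert len(recs1) == len(recs2) == 12 * 36
    for a, b in zip(recs1[:20], recs2[:20]):
        pd.testing.assert_frame_equal(a.samples, b.samples)
    recs3, *_ = simulate_cohort(cfg, seed=8)
    assert not recs1[0].samples.equals(recs3[0].samples)


def test_default_trial_has_300_rows_at_60hz():
    cfg = GeneratorConfig(n_participants={("somali", "man"): 1})
    recs, *_ = simulate_cohort(cfg, seed=0)
    assert all(r.n_samples == 300 for r in recs)
    t, x, y = recs[0].retained()
    # retained sample count: 300 minus track loss and blank saccade gaps
    assert 200 <= len(t) <= 300


def test_single_fixation_closed_loop():
    """Jitter 0, loss 0, one planted 5-s fixation: the detector returns
    exactly one fixation spanning all 300 samples."""
    cfg = GeneratorConfig(
        n_participants={("somali", "man"): 1},
        mean_total_fixations=1.0, sd_total_fixations=0.0,
        cross_dwell_mean_samples=0.0, cross_dwell_participant_sd=0.0,
        saccade_gap_samples=0, jitter_sd_px=0.0,
        track_loss_p=0.0, single_eye_loss_p=0.0, border_straddle_p=0.0,
        invalid_a_rate=0.0, invalid_b_rate=0.0)
    rng = np.random.default_rng(0)
    participant = {"participant_id": "p1", "cross_base": 0.0}
    slide = {"slide_id": "SS1_o", "base_pair_id": "SS1", "pair_type": "spider-scorpion",
             "orientation": "original", "left_category": "spider", "right_category": "scorpion"}
    latent = {"d_time_ms": 0.0, "d_count": 0.0, "focal_animal": "scorpion", "inject": None}
    rec, plan = simulate_trial(cfg, rng, participant, slide, latent)
    t, x, y = rec.retained()
    fx = detect_fixations(t, x, y, DetectorConfig())
    assert len(fx) == 1
    assert fx[0].n_samples == 300
    assert fx[0].duration_ms == pytest.approx(5000.0)


def test_planted_segmentation_recovered_without_noise():
    """With jitter well inside the dispersion radius and loss off, the
    detector recovers the planted fixation counts exactly, trial by trial."""
    cfg = GeneratorConfig(
        n_participants=dict(SMALL), track_loss_p=0.0, single_eye_loss_p=0.0,
        border_straddle_p=0.0, invalid_a_rate=0.0, invalid_b_rate=0.0)
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=3)
    plans = truth.trials.set_index(["participant_id", "slide_id"])
    for rec in recs[:200]:
        t, x, y = rec.retained()
        fx = detect_fixations(t, x, y, DetectorConfig())
        plan = plans.loc[(rec.participant_id, rec.slide_id)]
        planted = int(plan.n_f + plan.n_o) + 1  # + initial cross dwell
        assert len(fx) == planted


def test_measured_metrics_equal_planted_allocation_without_noise():
    cfg = GeneratorConfig(
        n_participants=dict(SMALL), track_loss_p=0.0, single_eye_loss_p=0.0,
        border_straddle_p=0.0, invalid_a_rate=0.0, invalid_b_rate=0.0)
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=4)
    metrics = compute_metrics(recs)
    kept, excluded = apply_exclusions(metrics)
    assert excluded.empty
    side = kept[kept.aoi.isin(["left", "right"])]
    tot = side.groupby(["participant_id", "slide_id"]).fixation_time_ms.sum()
    plans = truth.trials.set_index(["participant_id", "slide_id"])
    planted_tot = plans["T_f_ms"] + plans["T_o_ms"]
    merged = pd.concat([tot, planted_tot.rename("planted")], axis=1)
    assert np.allclose(merged.fixation_time_ms, merged.planted)


def test_cell_means_converge_to_configured_truth():
    """Law of large numbers: a 500-participant cohort's empirical cell means
    sit within 3 SE of the configured truths."""
    n = {("somali", "woman"): 125, ("somali", "man"): 125,
         ("czech", "woman"): 125, ("czech", "man"): 125}
    cfg = GeneratorConfig(n_participants=n)
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=5)
    kept, _ = apply_exclusions(compute_metrics(recs))
    cur = average_mirror_pairs(kept, schedule)
    d = compute_differences(cur, roster)
    g = d.groupby(["pair_type", "nationality", "gender"])
    for key, grp in g:
        est = np.average(grp.d_fix_time_ms, weights=grp.weight)
        se = grp.d_fix_time_ms.std(ddof=1) / np.sqrt(grp.participant_id.nunique())
        assert abs(est - truth.time_diff_ms[key]) < 3 * se, key
        estc = np.average(grp.d_fix_count, weights=grp.weight)
        sec = grp.d_fix_count.std(ddof=1) / np.sqrt(grp.participant_id.nunique())
        assert abs(estc - truth.count_diff[key]) < 3 * sec, key


def test_cohort_size_formula_consistency():
    n = {("somali", "woman"): 24, ("somali", "man"): 41,
         ("czech", "woman"): 35, ("czech", "man"): 32}
    cfg = GeneratorConfig(n_participants=n)
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=6)
    assert count_cohort_measurements(roster, schedule) == 4752 == len(recs)
    assert roster.nationality.value_counts().to_dict() == {"czech": 67, "somali": 65}


def test_score_recovery_trivial_cases():
    cfg = GeneratorConfig(n_participants=dict(SMALL))
    _, _, _, truth = simulate_cohort(cfg, seed=1)
    perfect = pd.DataFrame([
        {"pair_type": pt, "nationality": nat, "gender": gen,
         "estimate": v, "ci_low": v - 1.0, "ci_high": v + 1.0}
        for (pt, nat, gen), v in truth.time_diff_ms.items()])
    rep = score_recovery(truth, [perfect, perfect])
    assert np.allclose(rep.bias, 0.0) and np.allclose(rep.rmse, 0.0)
    assert (rep.coverage == 1.0).all()
    shifted = perfect.assign(estimate=perfect.estimate + 50.0)
    rep2 = score_recovery(truth, [shifted])
    assert np.allclose(rep2.bias, 50.0)
    with pytest.raises(ValueError, match="exactly one row"):
        score_recovery(truth, [perfect.iloc[:3]])


def test_config_validation_errors():
    with pytest.raises(ValueError, match="probabilities"):
        GeneratorConfig(track_loss_p=1.5)
    with pytest.raises(ValueError, match="SDs"):
        GeneratorConfig(resid_sd_ms=-1.0)


def test_simulator_wrapper_params():
    sim = GazeCohortSimulator()
    assert sim.get_params() == {"config": None}
    cfg = GeneratorConfig(n_participants={("somali", "man"): 1})
    sim.set_params(config=cfg)
    recs, roster, *_ = sim.sample(seed=2)
    assert len(recs) == 36 and len(roster) == 1
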