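"""Difference statistics, mixed-model estimators, reduction and post hocs."""

import numpy as np
import pandas as pd
import pytest

from gazebias.analysis import (MixedLMEstimator, anova_table, compute_differences,
                               emmeans, fit_count_model, position_effect_check,
                               posthoc_contrasts, reduce_model)
from gazebias.analysis import test_differences_against_zero as cells_against_zero
from gazebias.curation import apply_exclusions
from gazebias.simulate import DEFAULT_TIME_DIFF_MS


def _curated_row(pid, base, ptype, animal, n_fix, t_ms, w=1.0):
    return {"participant_id": pid, "base_pair_id": base, "pair_type": ptype,
            "animal": animal, "n_fixations": n_fix, "fixation_time_ms": t_ms,
            "count_sum": int(2 * n_fix), "n_slides": 2 if w == 1.0 else 1, "weight": w}


def test_compute_differences_sign_convention():
    cur = pd.DataFrame([
        _curated_row("p1", "SS1", "spider-scorpion", "scorpion", 6, 2400.0),
        _curated_row("p1", "SS1", "spider-scorpion", "spider", 5, 2000.0),
        _curated_row("p1", "SG1", "spider-grasshopper", "spider", 4, 1800.0),
        _curated_row("p1", "SG1", "spider-grasshopper", "grasshopper", 4, 1800.0),
    ])
    d = compute_differences(cur).set_index("base_pair_id")
    # scorpion minus spider for spider-scorpion pairs
    assert d.loc["SS1", "d_fix_time_ms"] == pytest.approx(400.0)
    assert d.loc["SS1", "d_fix_count"] == pytest.approx(1.0)
    # equal attention -> zero difference
    assert d.loc["SG1", "d_fix_time_ms"] == 0.0
    flipped = compute_differences(cur, sign=-1).set_index("base_pair_id")
    assert np.allclose(flipped["d_fix_time_ms"], -d["d_fix_time_ms"])


def test_compute_differences_missing_animal_errors():
    cur = pd.DataFrame([_curated_row("p1", "SS1", "spider-scorpion", "scorpion", 6, 2400.0)])
    with pytest.raises(ValueError, match="missing"):
        compute_differences(cur)


def _difference_data(rng, nper, cells, part_sd=400.0, resid_sd=849.0,
                     nat_mult=None, half_rate=0.15):
    nat_mult = nat_mult or {"somali": 1.0, "czech": 1.0}
    rows, pid = [], 0
    for (nat, gen), n in nper.items():
        for _ in range(n):
            pid += 1
            b = rng.normal(0, part_sd)
            for pt in ("spider-grasshopper", "scorpion-grasshopper", "spider-scorpion"):
                for k in range(6):
                    w = 0.5 if rng.random() < half_rate else 1.0
                    eps = rng.normal(0, resid_sd * nat_mult[nat] / np.sqrt(w))
                    rows.append({"participant_id": f"p{pid}", "base_pair_id": f"{pt}-{k}",
                                 "pair_type": pt, "nationality": nat, "gender": gen,
                                 "weight": w, "d_fix_time_ms": cells[(pt, nat, gen)] + b + eps})
    return pd.DataFrame(rows)


NPER = {("somali", "woman"): 8, ("somali", "man"): 8,
        ("czech", "woman"): 8, ("czech", "man"): 8}


def test_contrasts_equal_emmean_differences():
    rng = np.random.default_rng(0)
    data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS)
    est = MixedLMEstimator("d_fix_time_ms").fit(data)
    em = emmeans(est, "pair_type", by="nationality")
    con = posthoc_contrasts(est, "pair_type", by="nationality")
    assert len(con) == 6  # C(3,2) contrasts x 2 strata
    for _, row in con.iterrows():
        a, b = row["contrast"].split(" - ")
        sub = em[em.by_level == row.by_level].set_index("level")
        assert row["estimate"] == pytest.approx(
            sub.loc[a, "estimate"] - sub.loc[b, "estimate"], abs=1e-8)
    assert ((con["p_adj"] >= 0) & (con["p_adj"] <= 1)).all()


def test_anova_detects_planted_structure():
    rng = np.random.default_rng(1)
    data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS)
    est = MixedLMEstimator("d_fix_time_ms").fit(data)
    a = anova_table(est).set_index("term")
    assert a.loc["pair_type", "p"] < 0.001  # strong pair-type effect planted
    assert a.loc["pair_type", "df"] == 2


def test_estimates_shift_equivariantly_under_constant_offset():
    rng = np.random.default_rng(2)
    data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS)
    shifted = data.assign(d_fix_time_ms=data.d_fix_time_ms + 500.0)
    c1 = cells_against_zero(MixedLMEstimator("d_fix_time_ms").fit(data))
    c2 = cells_against_zero(MixedLMEstimator("d_fix_time_ms").fit(shifted))
    assert np.allclose(c2.estimate - c1.estimate, 500.0, atol=1e-6)


def test_reduction_drops_absent_interactions_keeps_real_ones():
    rng = np.random.default_rng(3)
    drop3 = keep2 = 0
    R = 12
    for r in range(R):
        data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS)
        est = MixedLMEstimator("d_fix_time_ms").fit(data)
        final, steps = reduce_model(est, data)
        if ("pair_type", "nationality", "gender") not in final.terms_:
            drop3 += 1
    # additive truth: the three-way interaction should essentially always go
    assert drop3 >= R - 2

    # planted strong pair_type x nationality interaction is retained
    cells = dict(DEFAULT_TIME_DIFF_MS)
    for pt in ("spider-grasshopper", "scorpion-grasshopper", "spider-scorpion"):
        for gen in ("woman", "man"):
            cells[(pt, "somali", gen)] += {"spider-grasshopper": -700,
                                           "scorpion-grasshopper": 0,
                                           "spider-scorpion": 700}[pt]
    for r in range(R):
        data = _difference_data(rng, NPER, cells)
        est = MixedLMEstimator("d_fix_time_ms").fit(data)
        final, _ = reduce_model(est, data)
        if ("pair_type", "nationality") in final.terms_:
            keep2 += 1
    assert keep2 >= R - 2


def test_reduction_returns_minimal_model_unchanged():
    rng = np.random.default_rng(4)
    data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS)
    est = MixedLMEstimator("d_fix_time_ms", terms=[("pair_type",)]).fit(data)
    final, steps = reduce_model(est, data)
    assert final.terms_ == [("pair_type",)]
    assert all(not s.removed for s in steps)


def test_single_observation_cell_has_wide_ci_and_no_crash():
    rng = np.random.default_rng(5)
    nper = {("somali", "woman"): 1, ("somali", "man"): 4,
            ("czech", "woman"): 4, ("czech", "man"): 4}
    data = _difference_data(rng, nper, DEFAULT_TIME_DIFF_MS)
    est = MixedLMEstimator("d_fix_time_ms").fit(data)
    cells = cells_against_zero(est).set_index(
        ["pair_type", "nationality", "gender"])
    lone = cells.loc[("spider-scorpion", "somali", "woman")]
    typical = cells.loc[("spider-scorpion", "czech", "man")]
    assert lone.se > 1.5 * typical.se
    assert np.isfinite(lone.ci_low) and lone.ci_low < lone.estimate < lone.ci_high


def test_heteroscedastic_ratio_recovery_direct():
    """A 2x nationality residual-SD ratio is recovered by the delta estimate."""
    rng = np.random.default_rng(6)
    ratios = []
    for r in range(15):
        data = _difference_data(rng, NPER, DEFAULT_TIME_DIFF_MS,
                                nat_mult={"somali": 1.0, "czech": 2.0})
        est = MixedLMEstimator("d_fix_time_ms").fit(data)
        ratios.append(1.0 / est.result_.deltas["somali"])  # czech is reference
    m, se = np.mean(ratios), np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert m - 2.5 * se <= 2.0 <= m + 2.5 * se


def test_factor_with_one_level_errors():
    rng = np.random.default_rng(7)
    data = _difference_data(rng, {("somali", "man"): 8, ("czech", "man"): 8},
                            DEFAULT_TIME_DIFF_MS)
    with pytest.raises(ValueError, match="gender"):
        MixedLMEstimator("d_fix_time_ms").fit(data)


def test_count_model_uses_full_pairs_and_requires_integers():
    rng = np.random.default_rng(8)
    rows, pid = [], 0
    for (nat, gen), n in NPER.items():
        for _ in range(n):
            pid += 1
            b = rng.normal(0, 0.3)
            for pt, (a1, a2) in {"spider-grasshopper": ("spider", "grasshopper"),
                                 "scorpion-grasshopper": ("scorpion", "grasshopper"),
                                 "spider-scorpion": ("spider", "scorpion")}.items():
                for k in range(6):
                    w = 0.5 if rng.random() < 0.2 else 1.0
                    for animal in (a1, a2):
                        lam = np.exp(2.0 + (0.25 if animal == "scorpion" else 0.0) + b)
                        rows.append({"participant_id": f"p{pid}", "base_pair_id": f"{pt}{k}",
                                     "pair_type": pt, "animal": animal,
                                     "nationality": nat, "gender": gen, "weight": w,
                                     "count_sum": int(rng.poisson(lam))})
    data = pd.DataFrame(rows)
    fit = fit_count_model(data, reduce=False)
    assert fit.result_.nobs == int((data.weight == 1.0).sum())
    a = anova_table(fit).set_index("term")
    assert a.loc["animal", "p"] < 0.01  # planted scorpion rate excess
    bad = data.copy()
    bad["count_sum"] = bad["count_sum"].astype(float)
    bad.loc[0, "count_sum"] = 1.5
    with pytest.raises(ValueError, match="integer"):
        fit_count_model(bad, reduce=False)


def test_position_effect_check_null_and_planted(small_cohort, small_metrics):
    kept, _ = apply_exclusions(small_metrics)
    est = position_effect_check(kept, small_cohort["schedule"])
    a = est.anova_.set_index("term")
    assert {"position", "pair_type", "position:pair_type"} <= set(a.index)
    # the generator plants no position effect in this cohort
    assert a.loc["position:pair_type", "p"] > 0.001

    lone = kept[kept.participant_id == kept.participant_id.iloc[0]]
    with pytest.raises(ValueError, match="participants"):
        position_effect_check(lone, small_cohort["schedule"])


def test_position_effect_power_when_planted():
    """A strong planted position x pair-type interaction is detected."""
    from gazebias import GeneratorConfig, simulate_cohort
    from gazebias.pipeline import compute_metrics

    hits = 0
    for s in range(5):
        cfg = GeneratorConfig(
            n_participants={("somali", "man"): 8, ("czech", "woman"): 8},
            position_effect_ms={"spider-grasshopper": 800.0,
                                "scorpion-grasshopper": -800.0,
                                "spider-scorpion": 0.0})
        recs, roster, schedule, truth = simulate_cohort(cfg, seed=60 + s)
        kept, _ = apply_exclusions(compute_metrics(recs))
        est = position_effect_check(kept, schedule)
        a = est.anova_.set_index("term")
        hits += a.loc["position:pair_type", "p"] < 0.05
    assert hits >= 4
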