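"""End-to-end orchestration: recordings -> metrics -> curation -> models.

`run_pipeline` is what the command-line `gazebias run` and the acceptance
script call; each stage is also usable on its own.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .analysis import (anova_table, compute_differences, emmeans, fit_count_model,
                       fit_difference_model, fit_total_metric_model,
                       position_effect_check, posthoc_contrasts,
                       test_differences_against_zero)
from .aoi import compute_trial_metrics, metrics_to_frame
from .config import AnalysisConfig
from .curation import apply_exclusions, average_mirror_pairs, curation_report
from .io import TrialRecording


def compute_metrics(recordings: Iterable[TrialRecording], cfg: AnalysisConfig | None = None
                    ) -> pd.DataFrame:
    cfg = cfg or AnalysisConfig()
    return metrics_to_frame(
        compute_trial_metrics(rec, cfg.aois, cfg.detector) for rec in recordings
    )


def run_pipeline(recordings: Sequence[TrialRecording], roster: pd.DataFrame,
                 schedule: pd.DataFrame, cfg: AnalysisConfig | None = None,
                 models: Sequence[str] = ("time_diff", "count_diff"),
                 check_position: bool = True, reduce: bool = True) -> dict:
    """Run the full analysis and return all intermediate and final products.

    ``models`` may contain ``time_diff``, ``count_diff`` (difference LMMs,
    the context-specific analysis), ``total_time`` (per-animal total
    fixation time LMM with Tukey post hocs) and ``count_poisson`` (the
    Poisson GLMM on full-pair sums).
    """
    cfg = cfg or AnalysisConfig()
    out: dict = {}
    metrics = compute_metrics(recordings, cfg)
    out["metrics"] = metrics
    kept, excluded = apply_exclusions(metrics, cfg.max_combined_fixation_ms)
    out["kept"], out["excluded"] = kept, excluded
    curated = average_mirror_pairs(kept, schedule)
    out["curated"] = curated
    out["curation_report"] = curation_report(metrics, excluded, curated)
    if check_position:
        out["position_check"] = position_effect_check(kept, schedule)

    curated_roster = curated.merge(
        roster[["participant_id", "nationality", "gender"]], on="participant_id",
        how="left", validate="many_to_one")
    differences = compute_differences(curated, roster)
    out["differences"] = differences

    if "time_diff" in models:
        fit = fit_difference_model(differences, "d_fix_time_ms", reduce=reduce)
        out["time_diff_fit"] = fit
        out["time_diff_anova"] = anova_table(fit)
        out["time_diff_cells"] = test_differences_against_zero(
            fit, ("pair_type", "nationality", "gender"))
    if "count_diff" in models:
        fit = fit_difference_model(differences, "d_fix_count", reduce=reduce)
        out["count_diff_fit"] = fit
        out["count_diff_anova"] = anova_table(fit)
        out["count_diff_cells"] = test_differences_against_zero(
            fit, ("pair_type", "nationality", "gender"))
    if "total_time" in models:
        fit = fit_total_metric_model(curated_roster, reduce=reduce)
        out["total_time_fit"] = fit
        out["total_time_anova"] = anova_table(fit)
        out["total_time_emm_nat"] = emmeans(fit, "animal", by="nationality")
        out["total_time_emm_gender"] = emmeans(fit, "animal", by="gender")
        out["total_time_contrasts_nat"] = posthoc_contrasts(fit, "animal", by="nationality")
        out["total_time_contrasts_gender"] = posthoc_contrasts(fit, "animal", by="gender")
    if "count_poisson" in models:
        fit = fit_count_model(curated_roster, reduce=reduce)
        out["count_poisson_fit"] = fit
        out["count_poisson_anova"] = anova_table(fit)
    return out


def write_reports(result: dict, out_dir) -> None:
    """Persist the pipeline products as CSV/JSON under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("metrics", "kept", "excluded", "curated", "differences",
                "time_diff_cells", "count_diff_cells", "time_diff_anova",
                "count_diff_anova", "total_time_anova",
                "total_time_emm_nat", "total_time_emm_gender",
                "total_time_contrasts_nat", "total_time_contrasts_gender",
                "count_poisson_anova"):
        if key in result:
            result[key].to_csv(out_dir / f"{key}.csv", index=False)
    summary: dict = {"curation": result.get("curation_report", {})}
    for key in ("time_diff_fit", "count_diff_fit", "total_time_fit", "count_poisson_fit"):
        if key in result:
            fit = result[key]
            res = fit.result_
            summary[key] = {
                "formula": fit.formula_,
                "terms": [list(t) for t in fit.terms_],
                "coefficients": dict(zip(res.names, map(float, res.beta))),
                "loglik": res.loglik,
                "aic": res.aic,
                "re_var": res.re_var,
                "deltas": getattr(res, "deltas", {}),
            }
    if "position_check" in result:
        summary["position_check"] = result["position_check"].anova_.to_dict(orient="records")
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out_dir / "tables.txt").write_text(format_tables(result))


def _cells_block(cells: pd.DataFrame, title: str, unit: str) -> list[str]:
    lines = [title, "-" * len(title)]
    for gender in sorted(cells["gender"].unique()):
        lines.append(f"{gender}:")
        for _, r in cells[cells.gender == gender].iterrows():
            stars = "***" if r.p < 0.001 else "**" if r.p < 0.01 else "*" if r.p < 0.05 else "n.s."
            lines.append(
                f"  {r.pair_type:22s} {r.nationality:7s} "
                f"{r.estimate:9.2f} {unit} [{r.ci_low:9.2f}, {r.ci_high:9.2f}]  "
                f"t = {r.t:6.2f}  p = {r.p:.3f} {stars}")
    lines.append("")
    return lines


def format_tables(result: dict) -> str:
    """Human-readable text rendering of the fitted tables.

    Estimated marginal means with Tukey contrasts for the total-time model,
    and per-cell difference estimates tested against zero for the two
    difference models.
    """
    lines: list[str] = []
    if "total_time_emm_nat" in result:
        lines += ["Total fixation time (ms): estimated marginal means",
                  "---------------------------------------------------"]
        for key in ("total_time_emm_nat", "total_time_emm_gender"):
            for _, r in result[key].iterrows():
                lines.append(f"  {r.by_level:7s} {r.level:12s} "
                             f"{r.estimate:7.0f} [{r.ci_low:7.0f}, {r.ci_high:7.0f}]")
        lines.append("")
        lines += ["Pairwise animal contrasts (Tukey-adjusted)",
                  "-------------------------------------------"]
        for key in ("total_time_contrasts_nat", "total_time_contrasts_gender"):
            if key in result:
                for _, r in result[key].iterrows():
                    lines.append(f"  {r.by_level:7s} {r.contrast:26s} "
                                 f"{r.estimate:7.0f}  t = {r.t_ratio:6.2f}  p = {r.p_adj:.3f}")
        lines.append("")
    if "time_diff_cells" in result:
        lines += _cells_block(result["time_diff_cells"],
                              "Fixation-time difference vs zero", "ms")
    if "count_diff_cells" in result:
        lines += _cells_block(result["count_diff_cells"],
                              "Fixation-count difference vs zero", "   ")
    return "\n".join(lines) + "\n"
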