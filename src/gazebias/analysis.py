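"""Attentional-bias statistics: difference responses and mixed-effects models.

The analysis chain mirrors the study's statistical procedure:

1. a position-effect pre-check (side x pair-type interaction) justifying the
   collapse over mirror pairs;
2. per-animal difference responses — fixation-time and fixation-count
   differences with the sign convention spider-grasshopper,
   scorpion-grasshopper, scorpion-spider (first-named minus second);
3. Gaussian mixed models with a participant random intercept and the
   combined residual-variance structure (per-nationality multiplier x
   inverse observation weight) for total fixation time and for both
   difference responses;
4. a Poisson log-link GLMM for fixation counts, fitted on full-pair sums
   only (no variance structure is available for this model class, so the
   half-weight observations are dropped instead);
5. backward model reduction by likelihood-ratio test and AIC, respecting
   marginality, with a final REML refit;
6. Tukey-adjusted pairwise contrasts of estimated marginal means, and cell
   means tested against zero for the difference models.

Fixed-effect factors are coded with sum-to-zero contrasts so per-term Wald
F statistics are marginal (Type-III-style); denominator degrees of freedom
use the residual count, which is immaterial at the sample sizes involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.stats import studentized_range

from .mixedlm import fit_gaussian_lmm, fit_poisson_glmm

__all__ = [
    "PAIR_DIFFERENCE", "compute_differences", "MixedLMEstimator", "PoissonGLMMEstimator",
    "reduce_model", "posthoc_contrasts", "test_differences_against_zero",
    "fit_total_metric_model", "fit_count_model", "fit_difference_model",
    "position_effect_check", "anova_table",
]

# first-named minus second-named animal, per pair type
PAIR_DIFFERENCE = {
    "spider-grasshopper": ("spider", "grasshopper"),
    "scorpion-grasshopper": ("scorpion", "grasshopper"),
    "spider-scorpion": ("scorpion", "spider"),
}


def compute_differences(curated: pd.DataFrame, roster: pd.DataFrame | None = None,
                        sign: int = 1) -> pd.DataFrame:
    """Per participant x base pair difference records from curated metrics.

    ``d_fix_count`` and ``d_fix_time_ms`` are the first-named minus the
    second-named animal of the pair type (see :data:`PAIR_DIFFERENCE`);
    observation weights are carried through.  ``sign=-1`` flips the
    convention (used by the property tests).
    """
    wide = curated.pivot_table(
        index=["participant_id", "base_pair_id", "pair_type", "weight"],
        columns="animal", values=["n_fixations", "fixation_time_ms"],
    )
    rows = []
    for (pid, base, ptype, w), r in wide.iterrows():
        focal, other = PAIR_DIFFERENCE[ptype]
        for metric in ("n_fixations", "fixation_time_ms"):
            for animal in (focal, other):
                if (metric, animal) not in r.index or pd.isna(r[(metric, animal)]):
                    raise ValueError(
                        f"missing {metric} for animal {animal!r} in pair {base!r}")
        rows.append(
            {
                "participant_id": pid,
                "base_pair_id": base,
                "pair_type": ptype,
                "d_fix_count": sign * (r[("n_fixations", focal)] - r[("n_fixations", other)]),
                "d_fix_time_ms": sign * (r[("fixation_time_ms", focal)] - r[("fixation_time_ms", other)]),
                "weight": w,
            }
        )
    out = pd.DataFrame(rows)
    if roster is not None:
        out = out.merge(roster[["participant_id", "nationality", "gender"]],
                        on="participant_id", how="left", validate="many_to_one")
        if out["nationality"].isna().any():
            raise ValueError("participants missing from roster")
    return out


# ---------------------------------------------------------------------------
# formula machinery


def _full_factorial(factors: Sequence[str]) -> list[tuple[str, ...]]:
    terms = []
    for k in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, k))
    return terms


def _terms_to_formula(response: str, terms: Sequence[tuple[str, ...]]) -> str:
    if not terms:
        return f"{response} ~ 1"
    parts = [":".join(f"C({v}, Sum)" for v in t) for t in terms]
    return f"{response} ~ " + " + ".join(parts)


def _term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


class _BaseMixedEstimator:
    """Shared sklearn-style surface of the two mixed-model estimators."""

    _param_names: tuple[str, ...] = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")

    # design helpers -------------------------------------------------------
    def _build_design(self, data: pd.DataFrame):
        terms = list(self.terms) if self.terms is not None else _full_factorial(self.factors)
        formula = _terms_to_formula(self.response, terms)
        ymat, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return terms, formula, np.asarray(ymat).ravel(), X

    def _term_slices(self, X) -> dict[str, slice]:
        info = X.design_info
        out = {}
        for name, sl in info.term_name_slices.items():
            if name == "Intercept":
                out["Intercept"] = sl
                continue
            plain = tuple(p.split("C(")[1].split(",")[0] for p in name.split(":"))
            out[_term_label(plain)] = sl
        return out


class MixedLMEstimator(_BaseMixedEstimator):
    """Gaussian mixed model with random intercept and variance structure.

    Parameters
    ----------
    response
        Name of the response column.
    factors
        Categorical fixed-effect factors; ``terms=None`` means their full
        factorial.
    terms
        Explicit list of term tuples, e.g. ``[("animal",), ("animal",
        "gender")]``.
    groups
        Column holding the random-intercept grouping (participant id).
    variance_by
        Column defining the per-stratum residual-SD multipliers
        (``None`` disables the varIdent part).
    weight_col
        Observation-weight column; residual variance scales as 1/weight
        (``None`` disables the varFixed part).
    reml
        REML for reported estimates; set False for ML fits used in
        likelihood-ratio comparisons.
    """

    _param_names = ("response", "factors", "terms", "groups", "variance_by",
                    "weight_col", "reml")

    def __init__(self, response: str, factors: Sequence[str] = ("pair_type", "nationality", "gender"),
                 terms: Sequence[tuple[str, ...]] | None = None, groups: str = "participant_id",
                 variance_by: str | None = "nationality", weight_col: str | None = "weight",
                 reml: bool = True):
        self.response = response
        self.factors = tuple(factors)
        self.terms = list(terms) if terms is not None else None
        self.groups = groups
        self.variance_by = variance_by
        self.weight_col = weight_col
        self.reml = reml

    family = "gaussian"

    def fit(self, data: pd.DataFrame, y=None):
        for f in self.factors:
            if data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} needs at least 2 observed levels")
        terms, formula, yv, X = self._build_design(data)
        strata = data[self.variance_by].to_numpy() if self.variance_by else None
        if strata is not None and len(set(strata)) < 2:
            import warnings

            warnings.warn("fewer than 2 variance strata; dropping the varIdent structure")
            strata = None
        w = data[self.weight_col].to_numpy(dtype=float) if self.weight_col else None
        self.result_ = fit_gaussian_lmm(
            yv, np.asarray(X), data[self.groups].to_numpy(), var_strata=strata,
            weights=w, reml=self.reml, names=list(X.columns),
        )
        self.terms_ = terms
        self.formula_ = formula
        self.design_info_ = X.design_info
        self.term_slices_ = self._term_slices(X)
        self.data_ = data
        self.factor_levels_ = {f: sorted(data[f].unique()) for f in self.factors}
        self.params_ = pd.Series(self.result_.beta, index=self.result_.names)
        return self

    def clone_with_terms(self, terms, reml=None):
        est = MixedLMEstimator(
            self.response, self.factors, terms, self.groups,
            self.variance_by, self.weight_col, self.reml if reml is None else reml,
        )
        return est

    @property
    def loglik_(self):
        return self.result_.loglik

    @property
    def aic_(self):
        return self.result_.aic


class PoissonGLMMEstimator(_BaseMixedEstimator):
    """Poisson log-link GLMM with a participant random intercept.

    Fitted by adaptive Gauss-Hermite quadrature and always by maximum
    likelihood.  No residual-variance structure exists for this model
    class; callers restrict the data to full-pair sums instead.
    """

    _param_names = ("response", "factors", "terms", "groups", "n_quad")

    def __init__(self, response: str, factors: Sequence[str] = ("animal", "nationality", "gender"),
                 terms: Sequence[tuple[str, ...]] | None = None, groups: str = "participant_id",
                 n_quad: int = 15):
        self.response = response
        self.factors = tuple(factors)
        self.terms = list(terms) if terms is not None else None
        self.groups = groups
        self.n_quad = n_quad

    family = "poisson"

    def fit(self, data: pd.DataFrame, y=None):
        for f in self.factors:
            if data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} needs at least 2 observed levels")
        terms, formula, yv, X = self._build_design(data)
        self.result_ = fit_poisson_glmm(
            yv, np.asarray(X), data[self.groups].to_numpy(), n_quad=self.n_quad,
            names=list(X.columns),
        )
        self.terms_ = terms
        self.formula_ = formula
        self.design_info_ = X.design_info
        self.term_slices_ = self._term_slices(X)
        self.data_ = data
        self.factor_levels_ = {f: sorted(data[f].unique()) for f in self.factors}
        self.params_ = pd.Series(self.result_.beta, index=self.result_.names)
        return self

    def clone_with_terms(self, terms, reml=None):
        return PoissonGLMMEstimator(self.response, self.factors, terms, self.groups, self.n_quad)

    @property
    def loglik_(self):
        return self.result_.loglik

    @property
    def aic_(self):
        return self.result_.aic


# ---------------------------------------------------------------------------
# inference on a fitted estimator


def anova_table(est) -> pd.DataFrame:
    """Marginal (Type-III-style) Wald tests for every fixed-effect term."""
    est._check_fitted()
    res = est.result_
    rows = []
    for label, sl in est.term_slices_.items():
        if label == "Intercept":
            continue
        b = res.beta[sl]
        V = res.cov_beta[sl, sl]
        q = b.size
        fstat = float(b @ np.linalg.solve(V, b) / q)
        if est.family == "gaussian":
            p = float(stats.f.sf(fstat, q, res.df_resid))
        else:
            p = float(stats.chi2.sf(fstat * q, q))
        rows.append({"term": label, "df": q, "F": fstat, "p": p})
    return pd.DataFrame(rows)


def _reference_grid(est, factors=None) -> pd.DataFrame:
    factors = list(factors or est.factors)
    levels = [est.factor_levels_[f] for f in factors]
    grid = pd.DataFrame(list(itertools.product(*levels)), columns=factors)
    return grid


def _grid_design(est, grid: pd.DataFrame) -> np.ndarray:
    (mat,) = patsy.build_design_matrices([est.design_info_], grid)
    return np.asarray(mat)


def _estimate(est, L: np.ndarray) -> tuple[float, float, float]:
    """Contrast estimate, SE and denominator df.

    Gaussian fits carry a Satterthwaite df for scalar contrasts (essential
    when participant-level variance dominates and cells are small); the
    Poisson GLMM uses the large-sample normal reference.
    """
    res = est.result_
    estv = float(L @ res.beta)
    se = float(np.sqrt(L @ res.cov_beta @ L))
    if est.family == "gaussian" and hasattr(res, "contrast_df"):
        df = res.contrast_df(L)
    else:
        df = np.inf
    return estv, se, df


def emmeans(est, factor: str, by: str | None = None) -> pd.DataFrame:
    """Estimated marginal means of ``factor`` (optionally within ``by``),
    averaging the reference grid with equal cell weights."""
    est._check_fitted()
    grid = _reference_grid(est)
    M = _grid_design(est, grid)
    rows = []
    by_levels = est.factor_levels_[by] if by else [None]
    for bl in by_levels:
        for lev in est.factor_levels_[factor]:
            mask = (grid[factor] == lev).to_numpy()
            if bl is not None:
                mask &= (grid[by] == bl).to_numpy()
            L = M[mask].mean(axis=0)
            estv, se, df = _estimate(est, L)
            tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
            rows.append({
                "factor": factor, "level": lev, "by": by, "by_level": bl,
                "estimate": estv, "se": se, "df": df,
                "ci_low": estv - tcrit * se, "ci_high": estv + tcrit * se,
            })
    return pd.DataFrame(rows)


def posthoc_contrasts(est, factor: str, by: str | None = None) -> pd.DataFrame:
    """All pairwise Tukey-adjusted contrasts of ``factor`` within ``by``.

    The adjusted p uses the studentized range over the factor's k levels;
    confidence intervals are Tukey simultaneous intervals.
    """
    est._check_fitted()
    if factor not in est.factors:
        raise ValueError(f"factor {factor!r} is not in the model")
    grid = _reference_grid(est)
    M = _grid_design(est, grid)
    levels = est.factor_levels_[factor]
    k = len(levels)
    rows = []
    by_levels = est.factor_levels_[by] if by else [None]
    for bl in by_levels:
        for la, lb in itertools.combinations(levels, 2):
            mask_a = (grid[factor] == la).to_numpy()
            mask_b = (grid[factor] == lb).to_numpy()
            if bl is not None:
                inby = (grid[by] == bl).to_numpy()
                mask_a, mask_b = mask_a & inby, mask_b & inby
            L = M[mask_a].mean(axis=0) - M[mask_b].mean(axis=0)
            estv, se, df = _estimate(est, L)
            df_use = df if np.isfinite(df) else 1e6
            tval = estv / se
            p = float(studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df_use))
            qcrit = studentized_range.ppf(0.95, k, df_use) / np.sqrt(2.0)
            rows.append({
                "contrast": f"{la} - {lb}", "by": by, "by_level": bl,
                "estimate": estv, "se": se, "df": df, "t_ratio": tval,
                "p_adj": min(p, 1.0),
                "ci_low": estv - qcrit * se, "ci_high": estv + qcrit * se,
            })
    return pd.DataFrame(rows)


def test_differences_against_zero(est, factors: Sequence[str] | None = None) -> pd.DataFrame:
    """Estimated cell means on the full factor grid, each t-tested against 0."""
    est._check_fitted()
    grid = _reference_grid(est, factors)
    M = _grid_design(est, grid)
    rows = []
    for i in range(len(grid)):
        estv, se, df = _estimate(est, M[i])
        df_use = df if np.isfinite(df) else 1e6
        tval = estv / se if se > 0 else np.nan
        tcrit = stats.t.ppf(0.975, df_use)
        rows.append({
            **grid.iloc[i].to_dict(),
            "estimate": estv, "se": se, "df": df, "t": tval,
            "p": float(2.0 * stats.t.sf(abs(tval), df_use)),
            "ci_low": estv - tcrit * se, "ci_high": estv + tcrit * se,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward reduction


@dataclass
class ReductionStep:
    term: str
    lrt: float
    df: int
    p: float
    aic_before: float
    aic_after: float
    removed: bool


def reduce_model(est, data: pd.DataFrame, alpha: float = 0.05):
    """Backward-eliminate fixed effects by LRT and AIC, marginality-respecting.

    Starting from the fitted estimator's terms, repeatedly consider every
    maximal term (one not contained in any other retained term); drop the
    least significant candidate iff its likelihood-ratio p >= alpha *and*
    dropping it does not worsen (increase) the ML AIC.  Candidate
    comparisons use ML fits; the returned final model is refitted by REML
    for Gaussian models.  Returns ``(final_estimator, steps)``.
    """
    terms = list(est.terms_ if hasattr(est, "terms_") else
                 (est.terms or _full_factorial(est.factors)))
    use_reml_final = getattr(est, "reml", False)
    current = est.clone_with_terms(terms, reml=False).fit(data)
    steps: list[ReductionStep] = []
    while True:
        maximal = [t for t in terms
                   if not any(set(t) < set(u) for u in terms)]
        best = None
        for cand in maximal:
            reduced_terms = [t for t in terms if t != cand]
            try:
                red = current.clone_with_terms(reduced_terms, reml=False).fit(data)
            except ValueError:
                continue
            lrt = 2.0 * (current.loglik_ - red.loglik_)
            df = current.result_.rank - red.result_.rank
            p = float(stats.chi2.sf(max(lrt, 0.0), df)) if df > 0 else 1.0
            if best is None or p > best[2]:
                best = (cand, red, p, lrt, df)
        if best is None:
            break
        cand, red, p, lrt, df = best
        ok = p >= alpha and red.aic_ <= current.aic_
        steps.append(ReductionStep(_term_label(cand), lrt, df, p,
                                   current.aic_, red.aic_, ok))
        if not ok:
            break
        terms = [t for t in terms if t != cand]
        current = red
        if not terms:
            break
    final = est.clone_with_terms(terms, reml=use_reml_final).fit(data)
    final.reduction_steps_ = steps
    final.ml_loglik_ = current.loglik_
    return final, steps


# ---------------------------------------------------------------------------
# the named model fits


def fit_difference_model(differences: pd.DataFrame, response: str = "d_fix_time_ms",
                         reduce: bool = True, alpha: float = 0.05) -> MixedLMEstimator:
    """Mixed model for a difference response (time or count difference).

    Full factorial of pair type, nationality and gender; participant random
    intercept; per-nationality x inverse-weight residual variance; backward
    reduction unless ``reduce=False``.
    """
    est = MixedLMEstimator(response, factors=("pair_type", "nationality", "gender")).fit(differences)
    if not reduce:
        return est
    final, _ = reduce_model(est, differences, alpha=alpha)
    return final

def fit_total_metric_model(curated_with_roster: pd.DataFrame,
                           response: str = "fixation_time_ms",
                           reduce: bool = True, alpha: float = 0.05) -> MixedLMEstimator:
    """Mixed model for a per-animal total metric (total fixation time).

    One row per participant x base pair x animal; fixed factors animal,
    nationality, gender and their interactions; participant random
    intercept; combined variance structure.
    """
    est = MixedLMEstimator(response, factors=("animal", "nationality", "gender")).fit(curated_with_roster)
    if not reduce:
        return est
    final, _ = reduce_model(est, curated_with_roster, alpha=alpha)
    return final


def fit_count_model(curated_with_roster: pd.DataFrame, reduce: bool = True,
                    alpha: float = 0.05, n_quad: int = 15) -> PoissonGLMMEstimator:
    """Poisson GLMM for fixation counts on full-pair sums only.

    Rows with weight < 1 (lone mirror slides) are excluded because the
    weight-based variance structure is unavailable for this model class;
    the response is the integer sum of fixations over the two mirror
    slides.
    """
    data = curated_with_roster[curated_with_roster["weight"] == 1.0].copy()
    y = data["count_sum"].to_numpy()
    if np.any(y != np.round(y)):
        raise ValueError("count responses must be integers")
    est = PoissonGLMMEstimator("count_sum", factors=("animal", "nationality", "gender"),
                               n_quad=n_quad).fit(data)
    if not reduce:
        return est
    final, _ = reduce_model(est, data, alpha=alpha)
    return final


def position_effect_check(kept_metrics: pd.DataFrame, schedule: pd.DataFrame,
                          response: str = "fixation_time_ms") -> MixedLMEstimator:
    """Pre-check: does stimulus position (left/right) interact with pair type?

    Fits the per-slide difference response on position-of-focal x pair type
    with a participant random intercept (homoscedastic, unit weights) and
    returns the fitted estimator; its ``anova_`` attribute holds the term
    tests used to justify collapsing mirror pairs.
    """
    if kept_metrics["participant_id"].nunique() < 2:
        raise ValueError("position-effect check needs at least 2 participants")
    sched = schedule.set_index("slide_id")
    side = kept_metrics[kept_metrics["aoi"].isin(["left", "right"])].copy()
    side["pair_type"] = sched["pair_type"].reindex(side["slide_id"]).to_numpy()
    cat = {
        "left": sched["left_category"].reindex(side["slide_id"]).to_numpy(),
        "right": sched["right_category"].reindex(side["slide_id"]).to_numpy(),
    }
    side["animal"] = [cat[a][i] for i, a in enumerate(side["aoi"])]
    rows = []
    for (pid, sid), g in side.groupby(["participant_id", "slide_id"]):
        ptype = g["pair_type"].iloc[0]
        focal, other = PAIR_DIFFERENCE[ptype]
        vals = g.set_index("animal")[response]
        pos = g.set_index("animal")["aoi"]
        if focal not in vals.index or other not in vals.index:
            continue
        rows.append({
            "participant_id": pid,
            "pair_type": ptype,
            "position": pos[focal],
            "d": vals[focal] - vals[other],
        })
    data = pd.DataFrame(rows)
    est = MixedLMEstimator("d", factors=("position", "pair_type"),
                           variance_by=None, weight_col=None).fit(data)
    est.anova_ = anova_table(est)
    return est
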