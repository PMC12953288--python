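"""Concordance statistics: discordance rates, group tests, logistic models.

Implements the full battery run on a graded cohort table: the discordance
rate with its cross-tabulation, concordant-vs-discordant group comparisons
(optionally stratified by histology grade), univariable and multivariable
logistic modelling of discordance with an explicit entry rule and
collinearity screen, Spearman/Pearson correlations, per-grade paired
Wilcoxon tests, quadratic composition-curve fits, and the precision-based
sample-size formula for a proportion.

Modelling conventions: odds ratios are per unit of the predictor (per % for
area variables, per year for age); confidence intervals are Wald,
exp(beta +/- z * SE).  No multiple-testing correction is applied; p-values
are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LogitResult",
    "CorrelationResult",
    "QuadFitResult",
    "GroupComparison",
    "DiscordanceSummary",
    "SeparationError",
    "discordance_summary",
    "compare_groups",
    "stratified_comparison",
    "univariable_logit",
    "multivariable_logit",
    "discordance_model_table",
    "correlate",
    "wilcoxon_paired_by_grade",
    "quad_fit",
    "required_sample_size",
]

#: Derived-sum variables and their components: if a sum and any of its
#: components both enter a multivariable model, the sum is dropped.
SUM_COMPONENTS: dict[str, tuple[str, ...]] = {
    "total_pct": ("tiny_pct", "small_pct", "large_pct"),
}


class SeparationError(RuntimeError):
    """Logistic fit is degenerate (complete or quasi-complete separation)."""


@dataclass
class LogitResult:
    """A fitted logistic model of discordance.

    ``table`` has one row per predictor with columns
    odds_ratio / ci_low / ci_high / p_value.
    """

    table: pd.DataFrame
    n_used: int
    predictors_entered: list[str]
    predictors_excluded_collinear: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # 'spearman' or 'pearson'
    coefficient: float
    p_value: float
    n: int


@dataclass(frozen=True)
class QuadFitResult:
    """Least-squares quadratic y = a*x^2 + b*x + c."""

    coefficients: tuple[float, float, float]
    r_squared: float
    concavity: str  # 'up', 'down' or 'none'


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str
    statistic: float
    p_value: float
    n_groups: tuple[int, int]
    group_means: tuple[float, float] | None = None


@dataclass
class DiscordanceSummary:
    n: int
    n_discordant: int
    rate: float
    rate_ci: tuple[float, float]  # 95% Wilson binomial CI
    counts_by_magnitude: pd.Series
    counts_by_direction: pd.Series
    crosstab: pd.DataFrame  # histology grades (rows) x PDFF grades (columns)


# --------------------------------------------------------------------------
# endpoint rates

def discordance_summary(cohort: pd.DataFrame) -> DiscordanceSummary:
    """Discordance rate, magnitude/direction counts and the 4x4 cross-tab.

    Requires ``hist_grade`` and ``pdff_grade`` columns (see
    :func:`steatodia.grading.add_grading_columns`).
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    hist = cohort["hist_grade"].to_numpy(dtype=int)
    pdff = cohort["pdff_grade"].to_numpy(dtype=int)
    diff = pdff - hist
    n = len(cohort)
    n_disc = int((diff != 0).sum())
    lo, hi = proportion_confint(n_disc, n, alpha=0.05, method="wilson")
    magnitude = pd.Series(np.abs(diff)).value_counts().sort_index()
    magnitude = magnitude[magnitude.index >= 1]
    direction = pd.Series(
        np.select([diff > 0, diff < 0], ["mri_over", "mri_under"], "concordant")
    ).value_counts()
    grades = [0, 1, 2, 3]
    crosstab = (
        pd.crosstab(pd.Series(hist, name="hist_grade"), pd.Series(pdff, name="pdff_grade"))
        .reindex(index=grades, columns=grades, fill_value=0)
    )
    return DiscordanceSummary(
        n=n,
        n_discordant=n_disc,
        rate=n_disc / n,
        rate_ci=(float(lo), float(hi)),
        counts_by_magnitude=magnitude,
        counts_by_direction=direction.reindex(
            ["concordant", "mri_over", "mri_under"], fill_value=0
        ),
        crosstab=crosstab,
    )


# --------------------------------------------------------------------------
# group comparisons

def _shapiro_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if len(x) < 3:
        return True
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    cohort: pd.DataFrame,
    grouping: str,
    variable: str,
    test: str = "auto",
) -> GroupComparison:
    """Two-group comparison of ``variable`` split by binary ``grouping``.

    ``test`` is one of 't', 'mannwhitney', 'chi2', 'fisher' or 'auto';
    'auto' uses Welch's t when both groups pass a Shapiro normality check
    (alpha 0.05) and Mann-Whitney otherwise for continuous variables, and
    Fisher's exact test (chi-square when all expected counts >= 5) for
    binary variables.
    """
    g = cohort[grouping]
    levels = sorted(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly two levels")
    x0 = cohort.loc[g == levels[0], variable].dropna()
    x1 = cohort.loc[g == levels[1], variable].dropna()
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("one of the groups is empty")

    values = pd.concat([x0, x1])
    binary = set(pd.unique(values)) <= {0, 1, True, False}
    if test == "auto":
        if binary:
            table = np.array(
                [[(x0 == 0).sum(), (x0 == 1).sum()], [(x1 == 0).sum(), (x1 == 1).sum()]]
            )
            expected = stats.contingency.expected_freq(table)
            test = "chi2" if (expected >= 5).all() else "fisher"
        else:
            x0n, x1n = x0.to_numpy(float), x1.to_numpy(float)
            test = "t" if _shapiro_normal(x0n) and _shapiro_normal(x1n) else "mannwhitney"

    if test == "t":
        if len(x0) < 2 or len(x1) < 2:
            raise ValueError("t-test needs at least 2 observations per group")
        res = stats.ttest_ind(x0, x1, equal_var=False)
        stat, p = res.statistic, res.pvalue
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    elif test in ("chi2", "fisher"):
        table = np.array(
            [[(x0 == 0).sum(), (x0 == 1).sum()], [(x1 == 0).sum(), (x1 == 1).sum()]]
        )
        if test == "chi2":
            stat, p = stats.chi2_contingency(table)[:2]
        else:
            stat, p = stats.fisher_exact(table)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        variable=variable,
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        n_groups=(len(x0), len(x1)),
        group_means=(float(np.mean(x0)), float(np.mean(x1))),
    )


def stratified_comparison(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    grouping: str = "discordant",
    strata: str = "hist_grade",
    test: str = "auto",
) -> pd.DataFrame:
    """Concordant-vs-discordant comparisons within each histology grade.

    Returns a tidy table (stratum, variable, group means +/- sd, test, p);
    strata where a group is empty are reported with NaN p and test
    'not_computed'.
    """
    rows = []
    for stratum, sub in cohort.groupby(strata, sort=True):
        for var in variables:
            counts = sub.groupby(grouping)[var].count()
            if len(counts) < 2 or (counts < 2).any():
                rows.append(
                    dict(stratum=stratum, variable=var, test="not_computed",
                         statistic=np.nan, p_value=np.nan,
                         mean_g0=np.nan, sd_g0=np.nan, mean_g1=np.nan, sd_g1=np.nan)
                )
                continue
            cmp_res = compare_groups(sub, grouping, var, test=test)
            stats_by = sub.groupby(grouping)[var].agg(["mean", "std"])
            rows.append(
                dict(
                    stratum=stratum,
                    variable=var,
                    test=cmp_res.test_used,
                    statistic=cmp_res.statistic,
                    p_value=cmp_res.p_value,
                    mean_g0=stats_by["mean"].iloc[0],
                    sd_g0=stats_by["std"].iloc[0],
                    mean_g1=stats_by["mean"].iloc[1],
                    sd_g1=stats_by["std"].iloc[1],
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# logistic modelling

def _design_column(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric design column; 'sex' is coded male=1 (OR reported for male)."""
    col = cohort[name]
    if col.dtype == object or str(col.dtype) == "category":
        levels = set(pd.unique(col.dropna()))
        if levels <= {"female", "male"}:
            return (col == "male").to_numpy(dtype=float)
        raise ValueError(f"cannot encode non-numeric column {name!r}: {levels}")
    return col.to_numpy(dtype=float)


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]) -> pd.DataFrame:
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (separation?)")
    beta = fit.params[1:]
    se = fit.bse[1:]
    if np.any(np.abs(beta) > 15) or np.any(~np.isfinite(se)):
        raise SeparationError("degenerate coefficients; data likely separated")
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p_value": fit.pvalues[1:],
        },
        index=pd.Index(names, name="predictor"),
    )


def univariable_logit(
    cohort: pd.DataFrame, predictor: str, outcome: str = "discordant"
) -> LogitResult:
    """Logistic fit of a binary outcome on one predictor.

    The odds ratio is per unit of the predictor with a Wald 95% CI.
    Complete separation raises :class:`SeparationError` rather than
    returning a degenerate table.
    """
    sub = cohort[[outcome, predictor]].dropna() if predictor != outcome else None
    if sub is None:
        raise ValueError("predictor must differ from outcome")
    y = sub[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes")
    X = _design_column(sub, predictor).reshape(-1, 1)
    table = _fit_logit(y, X, [predictor])
    return LogitResult(table=table, n_used=len(sub), predictors_entered=[predictor])


def multivariable_logit(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "discordant",
    forced: Sequence[str] = ("age", "sex"),
    entry_alpha: float = 0.05,
    collinearity_r: float = 0.9,
    interactions: Iterable[tuple[str, str]] = (),
) -> LogitResult:
    """Multivariable logistic model with univariable entry and collinearity screen.

    Entry rule: a candidate enters iff its univariable p-value is below
    ``entry_alpha``; ``forced`` covariates (age and sex by default) always
    enter, so a screen where nothing passes yields a forced-only model.  Collinearity screen on the entered candidates: (a) a derived-sum
    variable (e.g. total area) is dropped whenever one of its components is
    also entered; (b) of any remaining pair with |Pearson r| above
    ``collinearity_r``, the one with the larger univariable p is dropped.
    Optional ``interactions`` adds product terms of entered/forced columns.
    """
    candidates = list(candidates)
    interactions = list(interactions)
    interaction_cols = {c for pair in interactions for c in pair}
    use_cols = sorted(set(candidates) | set(forced) | interaction_cols | {outcome})
    data = cohort[use_cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes")

    uni_p: dict[str, float] = {}
    for cand in candidates:
        uni_p[cand] = float(
            univariable_logit(data, cand, outcome=outcome).table["p_value"].iloc[0]
        )
    # when no candidate passes the entry rule the model is forced-only
    entered = [c for c in candidates if uni_p[c] < entry_alpha]
    excluded: list[str] = []

    # (a) sum-variable rule
    for sum_var, components in SUM_COMPONENTS.items():
        if sum_var in entered and any(c in entered for c in components):
            entered.remove(sum_var)
            excluded.append(sum_var)

    # (b) pairwise screen, worst pair first; keep the smaller univariable p
    def _corr(a: str, b: str) -> float:
        return abs(float(np.corrcoef(_design_column(data, a), _design_column(data, b))[0, 1]))

    changed = True
    while changed:
        changed = False
        pairs = [
            (a, b) for i, a in enumerate(entered) for b in entered[i + 1:]
        ]
        pairs = [(a, b, _corr(a, b)) for a, b in pairs]
        pairs = [p for p in pairs if p[2] > collinearity_r]
        if pairs:
            a, b, _ = max(pairs, key=lambda p: p[2])
            drop = a if uni_p[a] >= uni_p[b] else b
            entered.remove(drop)
            excluded.append(drop)
            changed = True

    model_terms = [f for f in forced if f not in entered] + entered
    columns = {t: _design_column(data, t) for t in model_terms}
    names = list(model_terms)
    for a, b in interactions:
        names.append(f"{a}:{b}")
        columns[f"{a}:{b}"] = _design_column(data, a) * _design_column(data, b)
    X = np.column_stack([columns[nm] for nm in names])
    table = _fit_logit(y, X, names)
    return LogitResult(
        table=table,
        n_used=len(data),
        predictors_entered=names,
        predictors_excluded_collinear=excluded,
    )


def discordance_model_table(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "discordant",
    **multi_kwargs,
) -> pd.DataFrame:
    """Tidy univariable + multivariable OR table (one row per predictor/stage)."""
    rows = []
    for cand in candidates:
        res = univariable_logit(cohort, cand, outcome=outcome)
        row = res.table.iloc[0]
        rows.append(
            dict(predictor=cand, stage="univariable", odds_ratio=row["odds_ratio"],
                 ci_low=row["ci_low"], ci_high=row["ci_high"], p_value=row["p_value"],
                 n_used=res.n_used)
        )
    multi = multivariable_logit(cohort, candidates, outcome=outcome, **multi_kwargs)
    for pred, row in multi.table.iterrows():
        rows.append(
            dict(predictor=pred, stage="multivariable", odds_ratio=row["odds_ratio"],
                 ci_low=row["ci_low"], ci_high=row["ci_high"], p_value=row["p_value"],
                 n_used=multi.n_used)
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded_collinear"] = multi.predictors_excluded_collinear
    return out


# --------------------------------------------------------------------------
# correlations, paired tests, curve fits

def correlate(cohort: pd.DataFrame, x: str, y: str, method: str) -> CorrelationResult:
    """Spearman (midranks for ties) or Pearson correlation with two-sided p."""
    sub = cohort[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired observations")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, coefficient=float(r), p_value=float(p), n=len(sub))


def wilcoxon_paired_by_grade(
    cohort: pd.DataFrame,
    a: str = "pdff_pct",
    b: str = "total_pct",
    strata: str = "hist_grade",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test of paired columns within each grade stratum.

    Strata with fewer than ``min_pairs`` pairs are flagged ``too_small``;
    strata whose differences are all zero are flagged ``degenerate`` with
    p recorded as 1 (the test statistic is undefined there).  The exact
    null distribution is used for fewer than 25 pairs, the normal
    approximation with continuity correction otherwise.
    """
    rows = []
    for stratum, sub in cohort.groupby(strata, sort=True):
        diff = (sub[a] - sub[b]).dropna().to_numpy(dtype=float)
        n = len(diff)
        if n < min_pairs:
            rows.append(dict(stratum=stratum, n=n, statistic=np.nan,
                             p_value=np.nan, status="too_small"))
            continue
        if np.all(diff == 0):
            rows.append(dict(stratum=stratum, n=n, statistic=np.nan,
                             p_value=1.0, status="degenerate"))
            continue
        mode = "exact" if n < 25 else "approx"
        res = stats.wilcoxon(diff, alternative="two-sided", mode=mode, correction=True)
        rows.append(dict(stratum=stratum, n=n, statistic=float(res.statistic),
                         p_value=float(res.pvalue), status="ok"))
    return pd.DataFrame(rows)


def quad_fit(x, y, concavity_tol: float = 1e-9) -> QuadFitResult:
    """Least-squares quadratic fit with R^2 against the mean-only model.

    Concavity is the sign of the leading coefficient beyond
    ``concavity_tol`` ('none' within it).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(xv) < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if len(np.unique(xv)) < 3:
        raise ValueError("x is rank-deficient for a quadratic")
    a, b, c = np.polyfit(xv, yv, 2)
    resid = yv - (a * xv**2 + b * xv + c)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if a > concavity_tol:
        concavity = "up"
    elif a < -concavity_tol:
        concavity = "down"
    else:
        concavity = "none"
    return QuadFitResult(coefficients=(float(a), float(b), float(c)),
                         r_squared=r2, concavity=concavity)


def required_sample_size(prevalence: float, precision_d: float, alpha: float = 0.05) -> int:
    """Sample size to estimate a proportion to absolute precision d.

    n = ceil(z^2 * p * (1 - p) / d^2) with z the two-sided standard-normal
    quantile at ``alpha``.  E.g. prevalence 0.60, d 0.05, alpha 0.05 -> 369.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    if not 0 < precision_d < 1:
        raise ValueError("precision_d must lie strictly in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return math.ceil(z**2 * prevalence * (1.0 - prevalence) / precision_d**2)
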