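"""Two-stage exposure statistics: univariate screen, Bonferroni-corrected
multivariate models, and ADR incidence analyses.

The strategy mirrors standard candidate-gene PK practice: pharmacokinetic
parameters are dose/weight-normalised where appropriate and natural-log
transformed; categorical covariates are screened one at a time (t test for
two levels, one-way ANOVA with Bonferroni-adjusted pairwise post-hocs for
three or more); only covariates with univariate p < 0.05 enter a linear (or,
for ADRs, logistic) regression whose significance threshold is 0.05 divided
by the number of covariates entered.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: reference level per analysis column; contrasts are against these
REFERENCE_LEVELS = {
    "sex": "F",
    "race": "Caucasian",
    "trial_arm": "A",
    "ezetimibe": False,
    "slco1b1_phenotype": "NF",
    "slco1b1_df_pf": "NF",
    "cyp3a5_genotype": "*3/*3",
    "slc22a1_star2": "*1/*1",
    "slc22a1_star5": "*1/*1",
    "ugt2b7": "*1/*1",
    "slc22a1_haplotype": "wild-type",
    "abcb1_haplotype": "wild-type",
    "abcb1_core_haplotype": "wild-type",
}

#: PK outcome columns analysed on the natural-log scale
PK_OUTCOMES = ["auc_dw", "cmax_dw", "tmax", "t_half", "vd_f_w", "cl_f_w"]


@dataclass
class GroupStat:
    level: str
    n: int
    mean: float
    cv_pct: float
    tested: bool


@dataclass
class UnivariateResult:
    outcome: str
    grouping: str
    groups: list[GroupStat]
    test_name: str
    statistic: float
    p_value: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.05


@dataclass
class MultivariateResult:
    outcome: str
    predictors: list[str]
    coefficients: pd.Series
    p_values: pd.Series
    r_squared: float
    alpha_star: float
    significant_05: list[str] = field(default_factory=list)
    significant_bonferroni: list[str] = field(default_factory=list)


@dataclass
class LogisticResult:
    outcome: str
    predictors: list[str]
    coefficients: pd.Series
    p_values: pd.Series | None
    pseudo_r_squared: float | None
    flags: list[str] = field(default_factory=list)


def normalize_exposure(dataset: pd.DataFrame) -> pd.DataFrame:
    """Add dose/weight-corrected exposures and natural-log PK columns.

    ``auc_dw = auc_inf / (dose/weight)`` (kg·h·ng/(mL·mg)) and likewise for
    C_max; log columns are defined only where the parameter is positive.
    """
    df = dataset.copy()
    if (df["dose_mg"] <= 0).any() or (df["weight_kg"] <= 0).any():
        raise ValueError("dose and weight must be positive")
    dw = df["dose_mg"] / df["weight_kg"]
    df["auc_dw"] = df["auc_inf"] / dw
    df["cmax_dw"] = df["cmax"] / dw
    for col in PK_OUTCOMES:
        vals = df[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            logged = np.where(vals > 0, np.log(vals), np.nan)
        df["log_" + col] = logged
    return df


def _group_stats(values: pd.Series, grouping: pd.Series,
                 min_group_n: int) -> list[GroupStat]:
    out = []
    for level, v in values.groupby(grouping, observed=True, sort=True):
        v = v.dropna()
        mean = float(v.mean()) if len(v) else np.nan
        sd = float(v.std(ddof=1)) if len(v) > 1 else np.nan
        cv = 100.0 * sd / mean if mean else np.nan
        out.append(GroupStat(level=str(level), n=len(v), mean=mean,
                             cv_pct=cv, tested=len(v) >= min_group_n))
    return out


def univariate_screen(dataset: pd.DataFrame, outcomes: list[str],
                      grouping_vars: list[str], min_group_n: int = 2,
                      welch: bool = False) -> list[UnivariateResult]:
    """Screen each (outcome, grouping) pair on the log scale.

    Group descriptives (n, mean, CV%) are reported on the original scale;
    the test statistics use ln(outcome).  Groups with fewer than
    ``min_group_n`` observations are reported descriptively only.
    """
    results = []
    for outcome, var in itertools.product(outcomes, grouping_vars):
        sub = dataset[[outcome, var]].dropna()
        groups = _group_stats(sub[outcome], sub[var], min_group_n)
        tested = [g.level for g in groups if g.tested]
        flags: list[str] = []
        log_vals = {g: np.log(sub.loc[sub[var].astype(str) == g, outcome]
                              .to_numpy(dtype=float))
                    for g in tested}
        arrays = [log_vals[g] for g in tested]
        if len(tested) < 2:
            results.append(UnivariateResult(outcome, var, groups, "none",
                                            np.nan, np.nan,
                                            flags=["insufficient_groups"]))
            continue
        if all(np.ptp(a) == 0 for a in arrays) and \
                np.ptp(np.concatenate(arrays)) == 0:
            results.append(UnivariateResult(outcome, var, groups, "none",
                                            np.nan, np.nan,
                                            flags=["zero_variance"]))
            continue
        if len(tested) == 2:
            stat, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
            results.append(UnivariateResult(outcome, var, groups, "t-test",
                                            float(stat), float(p), flags=flags))
        else:
            stat, p = sps.f_oneway(*arrays)
            n_pairs = len(tested) * (len(tested) - 1) // 2
            posthoc = {}
            for a, b in itertools.combinations(tested, 2):
                _, p_ab = sps.ttest_ind(log_vals[a], log_vals[b],
                                        equal_var=not welch)
                posthoc[(a, b)] = min(1.0, float(p_ab) * n_pairs)
            results.append(UnivariateResult(outcome, var, groups, "anova",
                                            float(stat), float(p),
                                            posthoc=posthoc, flags=flags))
    return results


def bonferroni_alpha(k: int) -> float:
    """Multivariate significance threshold α* = 0.05 / k."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return 0.05 / k


def _design_matrix(dataset: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    cols = []
    for pred in predictors:
        s = dataset[pred]
        if s.dtype.kind in "bifc" and s.dtype.kind != "b" \
                and not isinstance(s.dtype, pd.CategoricalDtype):
            cols.append(s.astype(float).rename(pred))
            continue
        ref = REFERENCE_LEVELS.get(pred)
        if isinstance(ref, bool) or s.dtype.kind == "b":
            cols.append(s.astype(bool).astype(float).rename(f"{pred}[True]"))
            continue
        levels = sorted(str(l) for l in pd.unique(s))
        if ref is not None and str(ref) in levels:
            levels.remove(str(ref))
            levels = [str(ref)] + levels
        for level in levels[1:]:
            cols.append((s.astype(str) == level).astype(float)
                        .rename(f"{pred}[{level}]"))
    return pd.concat(cols, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")


def multivariate_model(dataset: pd.DataFrame, outcome: str,
                       predictors: list[str],
                       k: int | None = None) -> MultivariateResult:
    """OLS of the log outcome on the screened-in predictors.

    ``k`` is the number of covariates behind the Bonferroni threshold
    (defaults to the number of predictors entered here).
    """
    if not predictors:
        raise ValueError("no predictors passed the univariate screen")
    sub = dataset[[outcome] + predictors].dropna()
    y = np.log(sub[outcome].to_numpy(dtype=float))
    X = _design_matrix(sub, predictors)
    _check_rank(X)
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    alpha_star = bonferroni_alpha(k if k is not None else len(predictors))
    coef = fit.params.drop("const")
    pvals = fit.pvalues.drop("const")
    return MultivariateResult(
        outcome=outcome, predictors=predictors, coefficients=coef,
        p_values=pvals, r_squared=float(fit.rsquared), alpha_star=alpha_star,
        significant_05=list(pvals.index[pvals < 0.05]),
        significant_bonferroni=list(pvals.index[pvals < alpha_star]),
    )


def adr_incidence_test(dataset: pd.DataFrame, indicator: str,
                       grouping: str) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square of an ADR indicator against a categorical variable."""
    table = pd.crosstab(dataset[grouping], dataset[indicator].astype(bool))
    if table.shape[0] < 2:
        raise ValueError("need at least two groups")
    if table.shape[1] < 2:       # no events (or all events): statistic is 0
        return 0.0, 1.0, table
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p), table


def logistic_adr_model(dataset: pd.DataFrame, outcome: str,
                       predictors: list[str],
                       penalized_fallback: bool = True) -> LogisticResult:
    """Logistic regression of an ADR indicator with separation detection.

    Quasi- or complete separation is reported as a flag; when
    ``penalized_fallback`` is set, an L2-penalised fit supplies the
    coefficients instead of the divergent maximum-likelihood estimates.
    """
    sub = dataset[[outcome] + predictors].dropna()
    y = sub[outcome].astype(bool).astype(float).to_numpy()
    X = _design_matrix(sub, predictors)
    _check_rank(X)
    Xc = sm.add_constant(X)
    flags: list[str] = []
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if (not fit.mle_retvals.get("converged", True)
                or np.abs(fit.params.drop("const")).max() > 15):
            separated = True
    except Exception:
        separated = True
        fit = None

    if not separated and fit is not None:
        return LogisticResult(outcome, predictors,
                              coefficients=fit.params.drop("const"),
                              p_values=fit.pvalues.drop("const"),
                              pseudo_r_squared=float(fit.prsquared),
                              flags=flags)

    flags.append("quasi_separation")
    if not penalized_fallback:
        return LogisticResult(outcome, predictors,
                              coefficients=pd.Series(np.nan, index=X.columns),
                              p_values=None, pseudo_r_squared=None, flags=flags)
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1.0, max_iter=1000)
    lr.fit(X.to_numpy(), y)
    coefs = pd.Series(lr.coef_[0], index=X.columns)
    flags.append("penalized_estimates")
    return LogisticResult(outcome, predictors, coefficients=coefs,
                          p_values=None, pseudo_r_squared=None, flags=flags)


def merge_small_levels(series: pd.Series, min_n: int = 6,
                       sep: str = " or ") -> pd.Series:
    """Merge levels with fewer than ``min_n`` observations into one combined
    level named by joining the merged labels."""
    counts = series.value_counts()
    small = [l for l in counts.index if counts[l] < min_n]  # by size, desc
    if len(small) < 2:
        return series
    label = sep.join(str(s) for s in small)
    return series.where(~series.isin(small), label)


def screened_predictors(univariate: list[UnivariateResult],
                        outcomes: list[str] | None = None) -> list[str]:
    """Unique grouping variables with univariate p < 0.05 (across outcomes)."""
    seen: list[str] = []
    for res in univariate:
        if outcomes is not None and res.outcome not in outcomes:
            continue
        if res.significant and res.grouping not in seen:
            seen.append(res.grouping)
    return seen


def univariate_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    """Flatten univariate results to one row per (outcome, grouping, level)."""
    rows = []
    for r in results:
        for g in r.groups:
            rows.append({"outcome": r.outcome, "grouping": r.grouping,
                         "level": g.level, "n": g.n, "mean": g.mean,
                         "cv_pct": g.cv_pct, "tested": g.tested,
                         "test": r.test_name, "statistic": r.statistic,
                         "p_value": r.p_value, "flags": ";".join(r.flags)})
    return pd.DataFrame(rows)
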