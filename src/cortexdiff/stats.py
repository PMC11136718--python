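"""Statistical primitives for the group-comparison and regression battery.

Thin, fully-specified wrappers over scipy / statsmodels with a uniform
:class:`StatResult` record: Welch and pooled t (from samples or summary
statistics), Pearson chi-square without continuity correction, paired t,
Mann-Whitney U and Kruskal-Wallis H with tie-corrected normal
approximation, covariate-adjusted group F with partial eta^2 and post-hoc
contrasts, multinomial logistic regression with Wald odds-ratio CIs,
Bonferroni correction, the log(x+1) transform, a Lilliefors-corrected
normality screen, and backward-elimination linear regression with
standardized coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .errors import ConvergenceError, DegenerateDataError

ALPHA = 0.05


@dataclass
class StatResult:
    """One test outcome with its correction bookkeeping."""

    test_name: str
    statistic: float
    df: float | tuple | None
    p_raw: float
    n_used: int | None = None
    effect_size: float | None = None
    effect_name: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_corrected: float | None = None
    correction_family_size: int | None = None
    extra: dict = field(default_factory=dict)

    def correct(self, family_size: int) -> "StatResult":
        """Apply Bonferroni for a family of ``family_size`` comparisons."""
        self.correction_family_size = int(family_size)
        self.p_corrected = bonferroni(self.p_raw, family_size)
        return self

    @property
    def significant_corrected(self) -> bool:
        return self.p_corrected is not None and self.p_corrected < ALPHA


# ----------------------------------------------------------------------
# t-family
def welch_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """Welch two-sample t with Satterthwaite df from summary statistics."""
    if n1 < 2 or n2 < 2 or sd1 <= 0 or sd2 <= 0:
        raise DegenerateDataError("need n >= 2 and positive SDs per group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult("welch_t", float(t), float(df), float(p), n_used=n1 + n2)


def pooled_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """Student pooled-variance t, df = n1 + n2 - 2, from summary statistics."""
    if n1 < 2 or n2 < 2 or (sd1 <= 0 and sd2 <= 0):
        raise DegenerateDataError("need n >= 2 and a positive SD")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult("pooled_t", float(t), float(df), float(p), n_used=n1 + n2)


def _t_from_samples(x, y, equal_var: bool) -> StatResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("need >= 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    name = "pooled_t" if equal_var else "welch_t"
    return StatResult(
        name, float(res.statistic), float(res.df), float(res.pvalue),
        n_used=x.size + y.size,
    )


def welch_t(x, y) -> StatResult:
    """Welch t from raw samples (NaNs dropped)."""
    return _t_from_samples(x, y, equal_var=False)


def pooled_t(x, y) -> StatResult:
    """Pooled-variance t from raw samples (NaNs dropped)."""
    return _t_from_samples(x, y, equal_var=True)


def choose_t(x, y, alpha: float = ALPHA) -> StatResult:
    """Variance-ratio screen: Levene p < alpha -> Welch, else pooled."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    lev_p = sps.levene(x, y).pvalue
    res = _t_from_samples(x, y, equal_var=lev_p >= alpha)
    res.extra["levene_p"] = float(lev_p)
    return res


def paired_t(values_a, values_b) -> StatResult:
    """Paired t on within-subject differences, df = n - 1."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise DegenerateDataError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise DegenerateDataError("need >= 2 complete pairs")
    d = a - b
    if np.all(d == 0):  # identical pairs: no effect, not an error
        return StatResult("paired_t", 0.0, float(a.size - 1), 1.0, n_used=int(a.size))
    if np.allclose(d, d[0]):
        raise DegenerateDataError("constant paired differences")
    res = sps.ttest_rel(a, b)
    return StatResult(
        "paired_t", float(res.statistic), float(a.size - 1), float(res.pvalue),
        n_used=int(a.size),
    )


# ----------------------------------------------------------------------
def pearson_chi_square(contingency_table) -> StatResult:
    """Pearson chi-square without Yates continuity correction."""
    obs = np.asarray(contingency_table, float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise DegenerateDataError("need at least a 2x2 table")
    if (obs < 0).any():
        raise DegenerateDataError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero marginal total")
    chi2, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return StatResult(
        "chi_square", float(chi2), float(df), float(p), n_used=int(obs.sum())
    )


def mann_whitney_u(x, y) -> StatResult:
    """Mann-Whitney U (statistic for ``x``), tie-corrected normal p.

    No continuity correction, matching the usual asymptotic reporting
    convention for rank tests alongside parametric models.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("both samples must be nonempty")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return StatResult(
        "mann_whitney_u", float(res.statistic), None, float(res.pvalue),
        n_used=x.size + y.size,
    )


def kruskal_wallis(*groups) -> StatResult:
    """Kruskal-Wallis H over >= 2 groups, tie-corrected, df = k - 1."""
    clean = [np.asarray(g, float) for g in groups]
    clean = [g[~np.isnan(g)] for g in clean]
    if any(g.size == 0 for g in clean):
        raise DegenerateDataError("all groups must be nonempty")
    h, p = sps.kruskal(*clean)
    return StatResult(
        "kruskal_wallis", float(h), float(len(clean) - 1), float(p),
        n_used=int(sum(g.size for g in clean)),
    )


# ----------------------------------------------------------------------
# Canonical ordering so CP (or HC) is the reference/dropped dummy level.
_LEVEL_ORDER = {"HC": 0, "CP": 1, "mildly_CI": 2, "CI": 3, "MS": 4}


def _ordered_levels(levels) -> list:
    return sorted(levels, key=lambda l: (_LEVEL_ORDER.get(str(l), 99), str(l)))


def _design(group: pd.Series, covariates: pd.DataFrame | None):
    """Intercept + group dummies (+ covariates, age centered).

    The first level in canonical order (HC/CP before impaired groups) is the
    dropped reference, so post-hoc contrasts read e.g. ``CI_vs_CP``.
    """
    cat = pd.Categorical(group, categories=_ordered_levels(group.unique()))
    dummies = pd.get_dummies(pd.Series(cat, index=group.index),
                             drop_first=True, dtype=float)
    parts = [dummies]
    if covariates is not None and covariates.shape[1]:
        cov = covariates.astype(float).copy()
        if "age" in cov:
            cov["age"] = cov["age"] - cov["age"].mean()
        parts.append(cov)
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X, has_constant="add"), list(dummies.columns)


def glm_group_f(
    outcome: pd.Series,
    group_factor: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> StatResult:
    """Partial F for the group block in a covariate-adjusted linear model.

    Fits outcome ~ intercept + group dummies + covariates by least squares;
    reports the group-block F with (g-1, N-1-(g-1)-c) df, partial eta^2 =
    SS_group / (SS_group + SS_residual), and post-hoc pairwise adjusted
    mean differences with 95% CIs in ``extra["posthoc"]``.
    """
    df_all = pd.DataFrame({"__y": outcome, "__g": group_factor})
    if covariates is not None:
        df_all = pd.concat([df_all, covariates], axis=1)
    df_all = df_all.dropna()
    y = df_all["__y"].astype(float)
    g = df_all["__g"]
    cov = df_all.drop(columns=["__y", "__g"])
    cov = cov if cov.shape[1] else None
    levels = _ordered_levels(g.unique())
    if len(levels) < 2:
        raise DegenerateDataError("group factor needs >= 2 levels")

    X_full, gcols = _design(g, cov)
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise DegenerateDataError("singular design matrix")
    full = sm.OLS(y, X_full).fit()
    X_red = X_full.drop(columns=gcols)
    red = sm.OLS(y, X_red).fit()

    ss_group = red.ssr - full.ssr
    df_num = len(gcols)
    df_den = full.df_resid
    tss = float(((y - y.mean()) ** 2).sum())
    tol = 1e-10 * max(tss, 1.0)  # numerically-exact fits count as zero SS
    if ss_group <= tol:
        f, p, eta2 = 0.0, 1.0, 0.0
    elif full.ssr <= tol:
        f, p, eta2 = np.inf, 0.0, 1.0
    else:
        f = (ss_group / df_num) / (full.ssr / df_den)
        p = float(sps.f.sf(f, df_num, df_den))
        eta2 = ss_group / (ss_group + full.ssr)

    posthoc = {}
    ref = levels[0]  # dummies are relative to the first (dropped) level
    for lvl in levels[1:]:
        col = lvl  # dummy columns carry the level name
        est = full.params[col]
        lo, hi = full.conf_int().loc[col]
        posthoc[f"{lvl}_vs_{ref}"] = {
            "mean_diff": float(est), "ci_low": float(lo), "ci_high": float(hi),
            "p": float(full.pvalues[col]),
        }
    return StatResult(
        "glm_group_f", float(f), (float(df_num), float(df_den)), p,
        n_used=int(len(y)), effect_size=float(eta2), effect_name="partial_eta2",
        extra={"posthoc": posthoc, "group_levels": levels},
    )


def multinomial_logistic(
    outcome: pd.Series,
    predictor: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference_level: str | None = None,
) -> dict[str, StatResult]:
    """Multinomial logit: OR per non-reference level for ``predictor``.

    Maximum-likelihood (Newton) fit of a 3-level outcome on the predictor
    plus covariates, reference level first; returns, per non-reference
    level, OR = exp(beta) with Wald 95% CI.
    """
    df_all = pd.DataFrame({"__y": outcome, "__x": predictor})
    if covariates is not None:
        df_all = pd.concat([df_all, covariates], axis=1)
    df_all = df_all.dropna()
    levels = sorted(df_all["__y"].unique())
    if reference_level is None:
        reference_level = levels[0]
    if reference_level not in levels:
        raise DegenerateDataError(f"reference level {reference_level!r} absent")
    ordered = [reference_level] + [l for l in levels if l != reference_level]
    codes = df_all["__y"].map({l: i for i, l in enumerate(ordered)}).astype(int)

    cov = df_all.drop(columns=["__y", "__x"])
    X = pd.concat([df_all["__x"].astype(float).rename("predictor"), cov.astype(float)], axis=1)
    if "age" in X:
        X["age"] = X["age"] - X["age"].mean()
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            # non-convergence is detected below and raised as an error
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(codes.to_numpy(), X.to_numpy()).fit(
                method="newton", disp=0, maxiter=200
            )
    except Exception as exc:  # noqa: BLE001 - statsmodels raises plain errors
        raise ConvergenceError(f"multinomial fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError("multinomial fit did not converge (separation?)")

    pred_idx = list(X.columns).index("predictor")
    out: dict[str, StatResult] = {}
    params = np.asarray(fit.params)  # (k_exog, n_levels - 1)
    pvals = np.asarray(fit.pvalues)
    conf = np.asarray(fit.conf_int())  # (n_levels - 1, k_exog, 2)
    for eq, lvl in enumerate(ordered[1:]):
        beta = float(params[pred_idx, eq])
        lo, hi = conf[eq, pred_idx]
        p = float(pvals[pred_idx, eq])
        with np.errstate(over="ignore"):  # huge Wald CI bounds become inf
            out[str(lvl)] = StatResult(
                "multinomial_logistic", beta, None, p,
                n_used=int(len(codes)),
                effect_size=float(np.exp(beta)), effect_name="odds_ratio",
                ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
                extra={"reference": reference_level},
            )
    return out


# ----------------------------------------------------------------------
def bonferroni(p: float, family_size: int) -> float:
    """min(1, m * p)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(min(1.0, family_size * p))


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Per-comparison threshold alpha / m."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(alpha / family_size)


def log1p_transform(x):
    """Natural log(x + 1), vectorized; domain x >= 0."""
    arr = np.asarray(x, float)
    if np.nanmin(arr) < 0:
        raise ValueError("log(x+1) transform requires x >= 0")
    return np.log1p(arr)


def log1p_inverse(y):
    """Inverse of :func:`log1p_transform`."""
    return np.expm1(np.asarray(y, float))


def percent_increase(reference, other, method: str = "median") -> float:
    """Percent increase of ``other`` over ``reference`` for skewed data.

    ``method="median"`` compares raw medians; ``method="log_mean"``
    back-transforms the difference of mean log(x+1) values. Both
    conventions are in circulation for lesion counts/volumes, so both are
    provided; neither is canonical.
    """
    ref = np.asarray(reference, float)
    oth = np.asarray(other, float)
    ref, oth = ref[~np.isnan(ref)], oth[~np.isnan(oth)]
    if method == "median":
        m = np.median(ref)
        if m == 0:
            raise DegenerateDataError("reference median is zero")
        return float(100.0 * (np.median(oth) - m) / m)
    if method == "log_mean":
        return float(100.0 * np.expm1(np.mean(np.log1p(oth)) - np.mean(np.log1p(ref))))
    raise ValueError("method must be 'median' or 'log_mean'")


def normality_screen(x, alpha: float = ALPHA) -> StatResult:
    """Lilliefors-corrected KS test against a fitted normal.

    Flags non-normal at p < alpha (statistic NaN and p 0 for degenerate
    constant input). ``extra["normal"]`` carries the branch decision.
    """
    arr = np.asarray(x, float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 8:
        raise DegenerateDataError("normality screen needs n >= 8")
    if np.allclose(arr, arr[0]):
        return StatResult(
            "lilliefors", float("nan"), None, 0.0, n_used=arr.size,
            extra={"normal": False, "degenerate": True},
        )
    stat, p = lilliefors(arr, dist="norm")
    return StatResult(
        "lilliefors", float(stat), None, float(p), n_used=arr.size,
        extra={"normal": bool(p >= alpha), "degenerate": False},
    )


# ----------------------------------------------------------------------
@dataclass
class RegressionModel:
    """Final model from (optionally backward-eliminated) least squares."""

    retained: list[str]
    dropped: list[str]
    terms: dict[str, StatResult]  # standardized beta per retained candidate
    adj_r2: float
    n_used: int
    forced: list[str] = field(default_factory=list)
    condition_number: float = float("nan")

    @property
    def ill_conditioned(self) -> bool:
        return np.isfinite(self.condition_number) and self.condition_number > 1e8


def linear_model(
    outcome: pd.Series,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> RegressionModel:
    """Single least-squares fit with standardized betas for ``predictors``."""
    return backward_regression(
        outcome, predictors, covariates, alpha_stay=float("inf")
    )


def backward_regression(
    outcome: pd.Series,
    candidates: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha_stay: float = ALPHA,
) -> RegressionModel:
    """Backward elimination over ``candidates`` with forced covariates.

    Iteratively removes the candidate with the largest p-value until every
    remaining candidate has p < ``alpha_stay`` (covariates are never
    removed). Reports standardized beta (beta * sd_x / sd_y) with a 95% CI
    on the same scale, and the final model's adjusted R^2.
    """
    if candidates.shape[1] < 1:
        raise DegenerateDataError("need >= 1 candidate predictor")
    frame = pd.concat(
        [outcome.rename("__y"), candidates]
        + ([covariates] if covariates is not None else []),
        axis=1,
    ).dropna()
    y = frame["__y"].astype(float)
    cand_cols = list(candidates.columns)
    forced = list(covariates.columns) if covariates is not None else []

    cond = float(np.linalg.cond(frame[cand_cols].to_numpy().astype(float)))

    current = list(cand_cols)
    dropped: list[str] = []
    while True:
        X = sm.add_constant(frame[current + forced].astype(float), has_constant="add")
        fit = sm.OLS(y, X).fit()
        if not current:
            break
        pvals = fit.pvalues[current]
        if pvals.isna().any():  # rank deficiency: shed an unidentified term
            worst, worst_p = pvals.index[pvals.isna()][0], np.inf
        else:
            worst = pvals.idxmax()
            worst_p = float(pvals[worst])
        if worst_p >= alpha_stay:
            current.remove(worst)
            dropped.append(worst)
        else:
            break

    sd_y = y.std(ddof=1)
    terms: dict[str, StatResult] = {}
    conf = fit.conf_int()
    for c in current:
        sd_x = frame[c].astype(float).std(ddof=1)
        scale = sd_x / sd_y if sd_y > 0 else np.nan
        terms[c] = StatResult(
            "linear_term", float(fit.params[c] * scale), float(fit.df_resid),
            float(fit.pvalues[c]), n_used=int(len(y)),
            effect_size=float(fit.params[c] * scale),
            effect_name="standardized_beta",
            ci_low=float(conf.loc[c, 0] * scale),
            ci_high=float(conf.loc[c, 1] * scale),
            extra={"unstandardized": float(fit.params[c])},
        )
    return RegressionModel(
        retained=current,
        dropped=dropped,
        terms=terms,
        adj_r2=float(fit.rsquared_adj),
        n_used=int(len(y)),
        forced=forced,
        condition_number=cond,
    )
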