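"""Statistical cascade: group comparisons, correlation-screened logistic
regression, and interrupted time-series analysis at event onset.

All tests are two-sided and exploratory (no multiplicity correction).  Rank
tests (Mann-Whitney U, Wilcoxon signed-rank) serve the skewed glycemic
indices; t-tests (plain or bootstrap-t) serve baseline continuous covariates;
Fisher's exact test serves 2x2 frequency tables.  The regression cascade
screens collinear predictors by Pearson correlation before univariate and
multivariable logistic fits, and the interrupted time series is a segmented
OLS with a level change at the event plus separate pre/post slopes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_BOOTSTRAP_REPS = 10_000


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    groups: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    summaries: dict[str, str]
    degenerate: bool = False


def _summary(x: np.ndarray, style: Literal["median_iqr", "mean_sd"]) -> str:
    if style == "median_iqr":
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return f"{med:.1f} ({q1:.1f}-{q3:.1f})"
    return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"


def compare_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    family: Literal["rank", "t", "bootstrap_t"] = "rank",
    *,
    variable: str = "",
    groups: tuple[str, str] = ("a", "b"),
    n_boot: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int | None = None,
) -> ComparisonResult:
    """Two-sided unpaired comparison.

    ``rank`` is the Mann-Whitney U test (exact for small untied samples),
    ``t`` the classic two-sample t-test, and ``bootstrap_t`` resamples the
    t statistic under the pooled null (seeded, ``n_boot`` replicates) for
    skewed variables.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    style = "median_iqr" if family == "rank" else "mean_sd"
    summaries = {groups[0]: _summary(a, style), groups[1]: _summary(b, style)}
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult(variable, groups, family, math.nan, 1.0, summaries, True)
    if family == "rank":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "mann-whitney-u"
    elif family == "t":
        res = stats.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "t"
    elif family == "bootstrap_t":
        stat = float(stats.ttest_ind(a, b).statistic)
        rng = np.random.default_rng(seed)
        grand = np.mean(np.concatenate([a, b]))
        a0, b0 = a - a.mean() + grand, b - b.mean() + grand
        exceed = 0
        for _ in range(n_boot):
            ra = rng.choice(a0, size=a.size, replace=True)
            rb = rng.choice(b0, size=b.size, replace=True)
            if np.ptp(np.concatenate([ra, rb])) == 0:
                exceed += 1
                continue
            if abs(stats.ttest_ind(ra, rb).statistic) >= abs(stat):
                exceed += 1
        p = (exceed + 1) / (n_boot + 1)
        test = "bootstrap-t"
    else:
        raise ValueError(f"unknown test family {family!r}")
    return ComparisonResult(variable, groups, test, stat, p, summaries)


def compare_paired(
    pre: Sequence[float],
    post: Sequence[float],
    *,
    variable: str = "",
) -> ComparisonResult:
    """Wilcoxon matched-pairs signed-rank test (two-sided); pairs with a
    missing member are dropped."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    if pre.size < 2:
        raise ValueError("need at least 2 complete pairs")
    summaries = {"pre": _summary(pre, "median_iqr"), "post": _summary(post, "median_iqr")}
    diffs = post - pre
    if np.all(diffs == 0):
        return ComparisonResult(variable, ("pre", "post"), "wilcoxon", math.nan, 1.0,
                                summaries, True)
    res = stats.wilcoxon(post, pre, alternative="two-sided")
    return ComparisonResult(variable, ("pre", "post"), "wilcoxon",
                            float(res.statistic), float(res.pvalue), summaries)


def fisher_2x2(table: Sequence[Sequence[int]], *, variable: str = "") -> ComparisonResult:
    """Fisher's exact test (two-sided) on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    summaries = {"row1": f"{t[0, 0]}/{t[0].sum()}", "row2": f"{t[1, 0]}/{t[1].sum()}"}
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return ComparisonResult(variable, ("row1", "row2"), "fisher-exact", math.nan,
                                1.0, summaries, True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return ComparisonResult(variable, ("row1", "row2"), "fisher-exact",
                            float(odds), float(p), summaries)


# ---------------------------------------------------------------------------
# logistic-regression cascade
# ---------------------------------------------------------------------------

@dataclass
class PredictorFit:
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    flag: str | None = None  # e.g. "separation", "non-convergence"


@dataclass
class RegressionReport:
    stage: Literal["univariate", "multivariable"]
    fits: list[PredictorFit]
    screening_log: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": [f.predictor for f in self.fits],
                "odds_ratio": [f.odds_ratio for f in self.fits],
                "ci_low": [f.ci_low for f in self.fits],
                "ci_high": [f.ci_high for f in self.fits],
                "p_value": [f.p_value for f in self.fits],
                "flag": [f.flag for f in self.fits],
            }
        )


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> sm.Logit | None:
    try:
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        res = model.fit(disp=0, maxiter=200)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
        return None  # quasi-separation: absurd standard errors
    return res


def _wald_rows(res, predictors: Sequence[str]) -> list[PredictorFit]:
    rows = []
    for name in predictors:
        coef = float(res.params[name])
        se = float(res.bse[name])
        rows.append(
            PredictorFit(
                predictor=name,
                odds_ratio=math.exp(coef),
                ci_low=math.exp(coef - 1.96 * se),
                ci_high=math.exp(coef + 1.96 * se),
                p_value=float(res.pvalues[name]),
                coef=coef,
            )
        )
    return rows


def _univariate_p(y: np.ndarray, x: pd.Series) -> float:
    res = _fit_logit(y, x.to_frame())
    return math.nan if res is None else float(res.pvalues[x.name])


def screen_predictors(
    features: pd.DataFrame,
    outcome: str,
    r_threshold: float = 0.50,
) -> tuple[list[str], list[str]]:
    """Collinearity screen before regression.

    Pearson correlations among predictors are computed; predictors linked by
    r >= ``r_threshold`` are grouped by transitive closure and, within each
    group, only the member with the lowest univariate logistic p-value against
    the outcome is retained.  Constant predictors are excluded.  Returns the
    retained predictor names (original column order) and a human-readable log.
    """
    preds = [c for c in features.columns if c != outcome]
    y = features[outcome].to_numpy(dtype=float)
    logbook: list[str] = []
    usable = []
    for c in preds:
        if features[c].nunique() <= 1:
            logbook.append(f"excluded {c}: constant predictor")
        else:
            usable.append(c)
    if not usable:
        return [], logbook

    corr = features[usable].corr(method="pearson")
    # union-find over pairs with r >= threshold
    parent = {c: c for c in usable}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, ci in enumerate(usable):
        for cj in usable[i + 1:]:
            r = corr.loc[ci, cj]
            if r >= r_threshold:
                logbook.append(f"correlated pair: {ci} ~ {cj} (r = {r:.2f})")
                parent[find(ci)] = find(cj)

    groups: dict[str, list[str]] = {}
    for c in usable:
        groups.setdefault(find(c), []).append(c)
    retained: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            retained.add(members[0])
            continue
        pvals = {c: _univariate_p(y, features[c]) for c in members}
        best = min(members, key=lambda c: (math.inf if math.isnan(pvals[c]) else pvals[c]))
        retained.add(best)
        dropped = [c for c in members if c != best]
        logbook.append(
            "group {" + ", ".join(sorted(members)) + "}: retained " + best
            + f" (univariate p = {pvals[best]:.3g}), dropped " + ", ".join(sorted(dropped))
        )
    return [c for c in usable if c in retained], logbook


def logistic_cascade(
    features: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[RegressionReport, RegressionReport]:
    """Univariate logistic fits per predictor, then one joint multivariable
    fit of the predictors with univariate p < ``alpha``.

    Odds ratios are per unit of the predictor, with Wald 95% CIs
    (exp(coef +/- 1.96 SE)).  Non-convergent or separated predictors are
    flagged and excluded from the joint model.
    """
    if predictors is None:
        predictors = [c for c in features.columns if c != outcome]
    y = features[outcome].to_numpy(dtype=float)
    uni_fits: list[PredictorFit] = []
    logbook: list[str] = []
    for name in predictors:
        res = _fit_logit(y, features[name].to_frame())
        if res is None:
            uni_fits.append(PredictorFit(name, math.nan, math.nan, math.nan, math.nan,
                                         math.nan, flag="non-convergence-or-separation"))
            logbook.append(f"{name}: univariate fit failed (separation or non-convergence)")
        else:
            uni_fits.append(_wald_rows(res, [name])[0])
    univariate = RegressionReport("univariate", uni_fits, logbook)

    candidates = [f.predictor for f in uni_fits if f.flag is None and f.p_value < alpha]
    multi_fits: list[PredictorFit] = []
    multi_log = [f"multivariable candidates (univariate p < {alpha}): "
                 + (", ".join(candidates) if candidates else "none")]
    if candidates:
        res = _fit_logit(y, features[candidates])
        if res is None:
            multi_log.append("joint fit failed (separation or non-convergence)")
        else:
            multi_fits = _wald_rows(res, candidates)
    multivariable = RegressionReport("multivariable", multi_fits, multi_log)
    return univariate, multivariable


# ---------------------------------------------------------------------------
# interrupted time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITSResult:
    """Segmented-regression summary of an event-aligned period series."""

    series: str
    level_change: float
    level_change_p: float
    pre_slope: float
    pre_slope_p: float
    post_slope: float
    post_slope_p: float
    n_pre: int
    n_post: int


def interrupted_time_series(
    points: Sequence[tuple[int, float]], *, series: str = "value"
) -> ITSResult:
    """Segmented OLS on signed event-aligned periods.

    Model: value ~ b0 + b1*k + b2*step(k > 0) + b3*(k - k_plus)*step(k > 0),
    where k_plus is the first post period, so b2 is the level change at the
    event, b1 the pre slope and b1 + b3 the post slope.  Periods with NaN
    values are dropped; each segment needs at least 3 points.
    """
    pts = [(int(k), float(v)) for k, v in points if not math.isnan(float(v))]
    if any(k == 0 for k, _ in pts):
        raise ValueError("event-aligned series have no period 0")
    pts.sort()
    k = np.array([p[0] for p in pts], dtype=float)
    v = np.array([p[1] for p in pts], dtype=float)
    n_pre, n_post = int((k < 0).sum()), int((k > 0).sum())
    if n_pre < 3 or n_post < 3:
        raise ValueError("need at least 3 points on each side of the event")
    k_plus = k[k > 0].min()
    step = (k > 0).astype(float)
    X = sm.add_constant(
        pd.DataFrame({"k": k, "step": step, "post_trend": (k - k_plus) * step})
    )
    res = sm.OLS(v, X).fit()
    post = res.t_test(np.array([0.0, 1.0, 0.0, 1.0]))
    return ITSResult(
        series=series,
        level_change=float(res.params["step"]),
        level_change_p=float(res.pvalues["step"]),
        pre_slope=float(res.params["k"]),
        pre_slope_p=float(res.pvalues["k"]),
        post_slope=float(np.atleast_1d(post.effect)[0]),
        post_slope_p=float(np.atleast_1d(post.pvalue)[0]),
        n_pre=n_pre,
        n_post=n_post,
    )
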