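"""Cohort-level statistics for the iron/vitamin-D analysis.

Implements the statistical toolkit of the study design:

* normality-routed group comparisons (t-test/ANOVA vs Mann-Whitney/
  Kruskal-Wallis; chi-square for categorical data) with Bonferroni
  pairwise post-hoc p-values;
* Pearson/Spearman correlation with normality-based method choice;
* 2x2 odds ratios with Woolf (log) 95% confidence intervals, equivalent to
  the single-predictor logistic Wald interval;
* univariate screen followed by forward-stepwise multiple linear
  regression (entry p <= 0.05, removal p > 0.10) with standardized betas
  and VIF/tolerance collinearity diagnostics;
* empirical ROC analysis with trapezoidal AUC (= Mann-Whitney statistic),
  DeLong 95% CI and the Youden-index optimal cut-off.

The unpaired two-group rank test is Mann-Whitney (rank-sum): a signed-rank
test would require paired observations this cross-sectional design does
not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "RegressionReport",
    "RocReport",
    "GroupComparison",
    "compare_groups",
    "correlate",
    "odds_ratio_2x2",
    "stepwise_t2star_model",
    "roc_youden",
    "is_normal",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality & group comparisons


def is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Kolmogorov-Smirnov check against a normal with the sample moments."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    stat = stats.kstest(x, "norm", args=(x.mean(), sd))
    return stat.pvalue > alpha


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    pairwise_bonferroni: dict[tuple, float] = field(default_factory=dict)


def _pairwise(groups: dict, parametric: bool, n_pairs: int) -> dict:
    out = {}
    for (la, xa), (lb, xb) in combinations(groups.items(), 2):
        if parametric:
            p = stats.ttest_ind(xa, xb).pvalue
        else:
            p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
        out[(la, lb)] = min(1.0, float(p) * n_pairs)
    return out


def compare_groups(values: Sequence, groups: Sequence,
                   categorical: bool = False) -> GroupComparison:
    """Compare a variable across 2 or 3 groups with test routing.

    Continuous data: every group normal by the KS check routes to the
    t-test (2 groups) or one-way ANOVA (3 groups); otherwise Mann-Whitney
    or Kruskal-Wallis.  Categorical data route to the chi-square test on
    the label x group contingency table.  Pairwise post-hoc p-values are
    Bonferroni-multiplied (capped at 1).
    """
    values = np.asarray(values)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    split = {g: values[labels == g] for g in uniq}
    if any(len(v) < 2 for v in split.values()):
        raise ValueError("every group needs at least 2 observations")

    if categorical:
        table = pd.crosstab(pd.Series(values), pd.Series(labels))
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
        return GroupComparison(test="chi2", statistic=float(chi2), p_value=float(p))

    data = {g: np.asarray(v, dtype=float) for g, v in split.items()}
    parametric = all(is_normal(v) for v in data.values())
    n_pairs = len(uniq) * (len(uniq) - 1) // 2
    samples = list(data.values())

    if all(np.ptp(v) == 0 for v in samples) and len({v[0] for v in samples}) == 1:
        # identical constant groups: no variance anywhere -> null result
        return GroupComparison(test="anova", statistic=0.0, p_value=1.0,
                               pairwise_bonferroni={k: 1.0 for k in
                                                    combinations(data.keys(), 2)})
    if len(uniq) == 2:
        if parametric:
            res = stats.ttest_ind(*samples)
            name = "t-test"
        else:
            res = stats.mannwhitneyu(*samples, alternative="two-sided")
            name = "mann-whitney"
    else:
        if parametric:
            res = stats.f_oneway(*samples)
            name = "anova"
        else:
            res = stats.kruskal(*samples)
            name = "kruskal-wallis"
    pairwise = _pairwise(data, parametric, n_pairs) if len(uniq) > 2 else {}
    return GroupComparison(test=name, statistic=float(res.statistic),
                           p_value=float(res.pvalue), pairwise_bonferroni=pairwise)


def correlate(x: Sequence[float], y: Sequence[float],
              force_method: Literal["pearson", "spearman"] | None = None
              ) -> tuple[float, float, str]:
    """Correlation coefficient with normality-based method routing.

    Pearson when both vectors pass the KS normality check, Spearman
    otherwise; ``force_method`` overrides.  Returns (R, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    method = force_method
    if method is None:
        method = "pearson" if (is_normal(x) and is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


# ---------------------------------------------------------------------------
# odds ratios


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b (exposed with/without outcome), c, d (unexposed)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    log_se: float
    p_value: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def odds_ratio_2x2(table: ContingencyTable2x2,
                   continuity_correction: float | None = None) -> OddsRatioResult:
    """Crude odds ratio with Woolf 95% CI.

    OR = ad / bc; the log-scale standard error is
    sqrt(1/a + 1/b + 1/c + 1/d) and the CI is exp(ln OR +/- 1.96 SE).  For
    a single binary predictor this matches the logistic-regression Wald
    estimate.  Zero cells raise unless a ``continuity_correction`` (e.g.
    0.5) is supplied, which is added to every cell.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if continuity_correction is None:
            raise ValueError("undefined OR: zero cell without continuity correction")
        a, b, c, d = (v + continuity_correction for v in (a, b, c, d))
    or_value = (a * d) / (b * c)
    log_se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(0.975)
    log_or = np.log(or_value)
    ci_low = float(np.exp(log_or - z * log_se))
    ci_high = float(np.exp(log_or + z * log_se))
    p = float(2 * stats.norm.sf(abs(log_or) / log_se))
    return OddsRatioResult(or_value=float(or_value), ci_low=ci_low,
                           ci_high=ci_high, log_se=log_se, p_value=p)


# ---------------------------------------------------------------------------
# stepwise regression


@dataclass(frozen=True)
class RegressionReport:
    univariate: pd.DataFrame        # index: candidate; columns: beta, p_value
    multivariate: pd.DataFrame      # index: retained; columns: beta, p_value, vif, tolerance
    retained: tuple[str, ...]
    model_f: float
    model_p: float

    def to_dict(self) -> dict:
        return {
            "univariate": self.univariate.to_dict(orient="index"),
            "multivariate": self.multivariate.to_dict(orient="index"),
            "retained": list(self.retained),
            "model_f": self.model_f,
            "model_p": self.model_p,
        }


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """OLS with intercept: (coefs, p_values, F, F_p). X columns are predictors."""
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return (np.asarray(model.params[1:]), np.asarray(model.pvalues[1:]),
            float(model.fvalue), float(model.f_pvalue))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor cannot be standardized")
    return (v - v.mean()) / sd


def stepwise_t2star_model(cohort: pd.DataFrame, outcome: str,
                          candidates: Sequence[str],
                          entry_p: float = 0.05,
                          removal_p: float = 0.10) -> RegressionReport:
    """Univariate screen + forward-stepwise linear regression with diagnostics.

    Each candidate is first regressed alone on the outcome (standardized
    beta = Pearson r, with its p-value).  Candidates significant at
    ``entry_p`` enter forward-stepwise selection: at each step the
    candidate with the smallest partial p-value <= ``entry_p`` is added,
    then any included variable whose p-value rises above ``removal_p`` is
    dropped.  Standardized betas, VIF and tolerance are reported for the
    final model.
    """
    candidates = list(candidates)
    n = len(cohort)
    if n <= 10 * len(candidates):
        raise ValueError(f"need n > 10 x candidates ({10 * len(candidates)}), got {n}")
    y = _standardize(cohort[outcome].to_numpy(dtype=float))
    X = {c: _standardize(cohort[c].to_numpy(dtype=float)) for c in candidates}

    # collinearity-to-singularity guard
    mat = np.column_stack(list(X.values()))
    if len(candidates) > 1:
        rank = np.linalg.matrix_rank(np.corrcoef(mat, rowvar=False))
        if rank < len(candidates):
            raise ValueError(f"design is singular; collinear candidates among {candidates}")

    uni = {}
    for c in candidates:
        beta, p, _, _ = _ols(y, X[c][:, None])
        uni[c] = {"beta": float(beta[0]), "p_value": float(p[0])}
    univariate = pd.DataFrame.from_dict(uni, orient="index")

    pool = [c for c in candidates if uni[c]["p_value"] < entry_p]
    included: list[str] = []
    while True:
        # forward step: best new candidate by partial p-value
        best_c, best_p = None, entry_p
        for c in pool:
            if c in included:
                continue
            _, pvals, _, _ = _ols(y, np.column_stack([X[v] for v in included + [c]]))
            if pvals[-1] <= best_p:
                best_c, best_p = c, pvals[-1]
        if best_c is None:
            break
        included.append(best_c)
        # backward step: drop anything above the removal threshold
        while len(included) > 1:
            _, pvals, _, _ = _ols(y, np.column_stack([X[v] for v in included]))
            worst = int(np.argmax(pvals))
            if pvals[worst] > removal_p:
                included.pop(worst)
            else:
                break

    if not included:
        return RegressionReport(univariate=univariate,
                                multivariate=pd.DataFrame(columns=["beta", "p_value",
                                                                   "vif", "tolerance"]),
                                retained=(), model_f=float("nan"), model_p=float("nan"))

    Xf = np.column_stack([X[v] for v in included])
    betas, pvals, model_f, model_p = _ols(y, Xf)
    vif, tol = [], []
    for j in range(len(included)):
        if len(included) == 1:
            r2 = 0.0
        else:
            others = np.delete(Xf, j, axis=1)
            import statsmodels.api as sm
            r2 = sm.OLS(Xf[:, j], sm.add_constant(others)).fit().rsquared
        tol_j = 1.0 - r2
        tol.append(tol_j)
        vif.append(1.0 / tol_j if tol_j > 0 else float("inf"))
    multivariate = pd.DataFrame({"beta": betas, "p_value": pvals,
                                 "vif": vif, "tolerance": tol}, index=included)
    return RegressionReport(univariate=univariate, multivariate=multivariate,
                            retained=tuple(included), model_f=model_f, model_p=model_p)


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class RocReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    optimal_cutoff: float
    sensitivity: float              # percent, at the cutoff
    specificity: float              # percent, at the cutoff
    direction: str                  # 'high' or 'low' value predicts the event
    p_value: float                  # H0: AUC = 0.5 (DeLong z-test)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and variance via placement values (midranks for ties)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    order = stats.rankdata(allv)          # midranks over the pooled sample
    r_pos = order[:m]
    r_neg = order[m:]
    rp = stats.rankdata(pos)
    rn = stats.rankdata(neg)
    auc = (r_pos.sum() - rp.sum()) / (m * n)
    v10 = (r_pos - rp) / n                # placement of each positive
    v01 = 1.0 - (r_neg - rn) / m          # placement of each negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var)


def roc_youden(scores: Sequence[float], labels: Sequence,
               direction: Literal["high", "low"] = "high") -> RocReport:
    """Empirical ROC with DeLong CI and Youden-index optimal cut-off.

    ``direction='high'`` means larger scores predict the event;
    ``direction='low'`` means smaller scores do (as for vitamin D
    predicting myocardial iron).  The AUC is the trapezoidal area,
    identical to the tie-corrected Mann-Whitney concordance probability.
    The cut-off maximizes J = sensitivity + specificity - 1 over the
    observed values; ties favor the higher-sensitivity cut-off.  The
    reported cut-off is on the original score scale; under ``'low'`` a
    patient is called positive when score <= cutoff, under ``'high'`` when
    score >= cutoff.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if s.size != lab.size:
        raise ValueError("scores and labels must have the same length")
    if lab.all() or not lab.any():
        raise ValueError("both outcome classes must be present")

    work = s if direction == "high" else -s
    pos, neg = work[lab], work[~lab]
    auc, var = _delong_variance(pos, neg)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    p = float(2 * stats.norm.sf(abs(auc - 0.5) / se)) if se > 0 else 0.0

    # exhaustive Youden sweep over observed thresholds (positive if work >= t)
    cand = np.unique(work)
    best = None
    for t in cand:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12
                                                   and sens > best[1]):
            best = (j, sens, spec, t)
    _, sens, spec, t = best
    cutoff = float(t if direction == "high" else -t)
    return RocReport(auc=auc, auc_ci_low=ci_low, auc_ci_high=ci_high,
                     optimal_cutoff=cutoff, sensitivity=100.0 * sens,
                     specificity=100.0 * spec, direction=direction, p_value=p)
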