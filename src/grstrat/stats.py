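"""Inferential statistics for the GRS-stratified contrast analyses.

One-way ANOVA and Tukey HSD (raw-data and summary-statistic forms),
Kruskal-Wallis, r x c chi-squared with adjusted standardized residuals,
allele-based 2x2 association with odds ratios, inverse-variance fixed-effect
meta-analysis, covariate-adjusted logistic association, and logistic
gene-gene interaction tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    pvalue: float
    df_between: int
    df_within: int


def _split_groups(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    out = {}
    for g in pd.unique(groups):
        out[g] = values[groups == g]
    return out


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way ANOVA; F = 0, p = 1 when all values are identical."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    all_vals = np.concatenate(list(by.values()))
    grand = all_vals.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in by.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    dfb = len(by) - 1
    dfw = all_vals.size - len(by)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(float("inf"), 0.0, dfb, dfw)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), float(sps.f.sf(F, dfb, dfw)), dfb, dfw)


@dataclass(frozen=True)
class GroupSummaries:
    """Per-group n / mean / sd, the printable summary form of group data."""

    labels: tuple
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.n) == len(self.mean) == len(self.sd) == k):
            raise ValueError("labels, n, mean, sd must have equal length")
        if any(ni < 2 for ni in self.n):
            raise ValueError("each group needs n >= 2 for variance-based tests")
        if any(s < 0 for s in self.sd):
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_raw(cls, values, groups) -> "GroupSummaries":
        by = _split_groups(values, groups)
        labels = tuple(by)
        return cls(
            labels=labels,
            n=tuple(int(by[g].size) for g in labels),
            mean=tuple(float(by[g].mean()) for g in labels),
            sd=tuple(float(by[g].std(ddof=1)) for g in labels),
        )


@dataclass
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons."""

    pairs: pd.DataFrame  # columns: group1, group2, diff, se, q, pvalue
    mse: float
    df: int
    k: int

    def pvalue(self, a, b) -> float:
        for row in self.pairs.itertuples(index=False):
            if {row.group1, row.group2} == {a, b}:
                return float(row.pvalue)
        raise KeyError(f"no pair ({a!r}, {b!r})")


def tukey_from_summary(summaries: GroupSummaries) -> TukeyResult:
    """Tukey-Kramer adjusted p-values computed from n / mean / sd alone.

    Uses the pooled MSE = sum (n_i - 1) s_i^2 / sum (n_i - 1) and the
    studentized-range distribution with k groups and the pooled df.  Equals
    the raw-data version exactly when the summaries are exact.
    """
    k = len(summaries.labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.asarray(summaries.n, dtype=float)
    means = np.asarray(summaries.mean, dtype=float)
    sds = np.asarray(summaries.sd, dtype=float)
    df = int((ns - 1).sum())
    mse = float(((ns - 1) * sds ** 2).sum() / df)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0.0:
                q = 0.0 if diff == 0.0 else float("inf")
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df))
            rows.append({"group1": summaries.labels[i], "group2": summaries.labels[j],
                         "diff": float(diff), "se": float(se), "q": float(q),
                         "pvalue": min(1.0, max(0.0, p))})
    return TukeyResult(pairs=pd.DataFrame(rows), mse=mse, df=df, k=k)


def tukey_hsd(values, groups) -> TukeyResult:
    """Tukey HSD on raw data (summarises exactly, then delegates)."""
    return tukey_from_summary(GroupSummaries.from_raw(values, groups))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) and chi-squared p."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    arrays = list(by.values())
    if np.ptp(np.concatenate(arrays)) == 0.0:
        return 0.0, 1.0
    stat, p = sps.kruskal(*arrays)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    dof: int
    expected: np.ndarray
    adjusted_residuals: np.ndarray


def chi2_rxc(observed) -> Chi2Result:
    """Pearson chi-squared on an r x c table plus adjusted standardized
    residuals (O - E) / sqrt(E (1 - row/N) (1 - col/N))."""
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2:
        raise ValueError("observed must be 2-dimensional")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    N = O.sum()
    if N < 1:
        raise ValueError("grand total must be >= 1")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    E = np.outer(row, col) / N
    stat = float(((O - E) ** 2 / E).sum())
    dof = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof)) if dof > 0 else 1.0
    denom = np.sqrt(E * (1.0 - row[:, None] / N) * (1.0 - col[None, :] / N))
    adj = (O - E) / denom
    return Chi2Result(stat, p, dof, E, adj)


# ---------------------------------------------------------------------------
# allele association and meta-analysis


@dataclass
class AssocResult:
    or_point: float
    log_or: float
    log_or_se: float
    pvalue: float
    test: str
    counts: tuple[float, float, float, float]  # a, b, c, d as used for the OR


def allele_assoc_2x2(risk_count_case: int, allele_total_case: int,
                     risk_count_ctrl: int, allele_total_ctrl: int,
                     yates: bool = False) -> AssocResult:
    """Allele-based 2x2 association: Pearson chi-squared p and cross-product
    odds ratio (case odds of the risk allele over control odds).

    A Haldane-Anscombe +0.5 correction is applied to all cells for the OR and
    its SE iff any cell is zero; the chi-squared uses the raw counts.
    """
    for name, v in (("risk_count_case", risk_count_case),
                    ("allele_total_case", allele_total_case),
                    ("risk_count_ctrl", risk_count_ctrl),
                    ("allele_total_ctrl", allele_total_ctrl)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if allele_total_case == 0 or allele_total_ctrl == 0:
        raise ValueError("zero allele total in one arm")
    if risk_count_case > allele_total_case or risk_count_ctrl > allele_total_ctrl:
        raise ValueError("risk count exceeds allele total")

    a = float(risk_count_case)
    b = float(allele_total_case - risk_count_case)
    c = float(risk_count_ctrl)
    d = float(allele_total_ctrl - risk_count_ctrl)

    O = np.array([[a, b], [c, d]])
    col = O.sum(axis=0)
    if (col == 0).any():
        stat, p = 0.0, 1.0
    else:
        E = np.outer(O.sum(axis=1), col) / O.sum()
        diff = np.abs(O - E)
        if yates:
            diff = np.maximum(diff - 0.5, 0.0)
        stat = float((diff ** 2 / E).sum())
        p = float(sps.chi2.sf(stat, 1))

    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return AssocResult(or_point=float(or_point), log_or=float(math.log(or_point)),
                       log_or_se=float(se), pvalue=p,
                       test="allele chi-squared" + (" (Yates)" if yates else ""),
                       counts=(a, b, c, d))


@dataclass
class MetaResult:
    pooled_log_or: float
    pooled_se: float
    pvalue: float
    or_point: float
    q: float
    i2: float
    k: int
    study_log_ors: tuple[float, ...]
    study_ses: tuple[float, ...]


def meta_fixed(per_study: Sequence[AssocResult] | Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study log odds ratios,
    with Cochran Q and I-squared heterogeneity."""
    if len(per_study) < 1:
        raise ValueError("need at least one study")
    logs, ses = [], []
    for s in per_study:
        if isinstance(s, AssocResult):
            lo, se = s.log_or, s.log_or_se
        else:
            lo, se = float(s[0]), float(s[1])
        if not math.isfinite(lo):
            raise ValueError("non-finite study log OR")
        if not (math.isfinite(se) and se > 0):
            raise ValueError("study SE must be positive and finite")
        logs.append(lo)
        ses.append(se)
    logs_a = np.array(logs)
    w = 1.0 / np.array(ses) ** 2
    pooled = float((w * logs_a).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    q = float((w * (logs_a - pooled) ** 2).sum())
    k = len(logs)
    i2 = 0.0 if (k < 2 or q <= 0) else max(0.0, (q - (k - 1)) / q) * 100.0
    return MetaResult(pooled_log_or=pooled, pooled_se=se, pvalue=p,
                      or_point=float(math.exp(pooled)), q=q, i2=i2, k=k,
                      study_log_ors=tuple(logs), study_ses=tuple(ses))


# ---------------------------------------------------------------------------
# logistic models


@dataclass
class LogisticResult:
    or_point: float
    log_or: float
    se: float
    pvalue: float
    converged: bool
    separation: bool
    nobs: int


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.abs(res.params).max() > 15 or np.abs(res.bse).max() > 100:
        return None  # quasi-separation: estimates diverging
    return res


def _design(dosage, covariates, extra_cols=()):
    cols = [np.ones(len(dosage))]
    cols.append(np.asarray(dosage, dtype=float))
    for c in extra_cols:
        cols.append(np.asarray(c, dtype=float))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
    return np.column_stack(cols)


def logistic_adjusted(outcome, dosage, covariates=None) -> LogisticResult:
    """Covariate-adjusted additive-dosage logistic association (Wald OR / p).

    Perfect or quasi-separation is flagged and no estimate is returned
    (NaN fields, ``separation=True``).
    """
    y = np.asarray(outcome, dtype=float)
    X = _design(dosage, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    res = _fit_logit(y, X)
    if res is None:
        return LogisticResult(float("nan"), float("nan"), float("nan"), float("nan"),
                              converged=False, separation=True, nobs=len(y))
    beta = float(res.params[1])
    se = float(res.bse[1])
    p = float(res.pvalues[1])
    return LogisticResult(or_point=math.exp(beta), log_or=beta, se=se, pvalue=p,
                          converged=True, separation=False, nobs=len(y))


@dataclass
class InteractionResult:
    coef: float
    se: float
    pvalue: float
    dropped: bool
    reason: str | None
    nobs: int


def glm_interaction(outcome, dosage_a, dosage_b, covariates=None) -> InteractionResult:
    """Logistic model with both main effects and their product; Wald test on
    the product coefficient.  A constant dosage drops the term with a flag."""
    y = np.asarray(outcome, dtype=float)
    da = np.asarray(dosage_a, dtype=float)
    db = np.asarray(dosage_b, dtype=float)
    if np.ptp(da) == 0.0 or np.ptp(db) == 0.0:
        which = "dosage_a" if np.ptp(da) == 0.0 else "dosage_b"
        return InteractionResult(float("nan"), float("nan"), float("nan"),
                                 dropped=True, reason=f"{which} is constant",
                                 nobs=len(y))
    X = _design(da, covariates, extra_cols=(db, da * db))
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    res = _fit_logit(y, X)
    if res is None:
        return InteractionResult(float("nan"), float("nan"), float("nan"),
                                 dropped=True, reason="separation or non-convergence",
                                 nobs=len(y))
    # product term is column 3 of [const, a, b, a*b, covariates...]
    return InteractionResult(coef=float(res.params[3]), se=float(res.bse[3]),
                             pvalue=float(res.pvalues[3]), dropped=False,
                             reason=None, nobs=len(y))


# ---------------------------------------------------------------------------
# pooled summaries (combined-group construction rule)


def pooled_mean(ns: Sequence[float], means: Sequence[float]) -> float:
    """Size-weighted mean of subgroup means."""
    ns_a = np.asarray(ns, dtype=float)
    if (ns_a <= 0).any():
        raise ValueError("group sizes must be positive")
    return float((ns_a * np.asarray(means, dtype=float)).sum() / ns_a.sum())


def pooled_mean_sd(ns: Sequence[float], means: Sequence[float],
                   sds: Sequence[float]) -> tuple[float, float]:
    """Mean and sd of the pooled sample reconstructed from subgroup n/mean/sd."""
    ns_a = np.asarray(ns, dtype=float)
    means_a = np.asarray(means, dtype=float)
    sds_a = np.asarray(sds, dtype=float)
    n = ns_a.sum()
    m = float((ns_a * means_a).sum() / n)
    ss = ((ns_a - 1) * sds_a ** 2).sum() + (ns_a * (means_a - m) ** 2).sum()
    sd = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
    return m, sd
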