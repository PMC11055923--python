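"""Univariate battery statistics, association tests, and rater agreement.

Group comparisons follow the battery's decision rule: a two-sample t-test
when both groups look normal under a Kolmogorov–Smirnov check, otherwise the
Wilcoxon rank-sum test. Variance equality uses Levene's test (mean-centered).
Cluster × class association uses Pearson's chi-squared without continuity
correction. Rater agreement offers Cohen's kappa for event sequences,
Pearson's r, and the absolute-agreement intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import BehavioralDataset, DegenerateDataError

__all__ = [
    "TestResult",
    "ContingencyResult",
    "AgreementResult",
    "ks_normality",
    "compare_groups",
    "levene",
    "chi2_association",
    "cohens_kappa",
    "icc_absolute",
    "pearson_r",
    "battery_table",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a univariate hypothesis test."""

    statistic: float
    df: float | tuple[float, float] | None
    p: float
    method: str
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-squared association between two categorical partitions."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AgreementResult:
    """Inter-rater agreement summary: kappa, Pearson r, ICC(2,1)."""

    kappa: float | None
    pearson_r: float
    icc: float
    model: str = "ICC(2,1) absolute agreement, two-way random, single measure"


# -- normality and group comparison -------------------------------------------


def ks_normality(x: Sequence[float], *, lilliefors: bool = False) -> TestResult:
    """One-sample Kolmogorov–Smirnov test of normality.

    The sample is standardized with its fitted mean and SD and compared to the
    standard normal CDF. Because the parameters are estimated, the classic KS
    p value is conservative; ``lilliefors=True`` applies the Lilliefors
    correction (via statsmodels) instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"KS normality needs n >= 4, got n={x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
        return TestResult(float(stat), None, float(p), "lilliefors")
    z = (x - x.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return TestResult(float(stat), None, float(p), "ks")


def _ranksum(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Wilcoxon rank-sum test reporting W of the first sample.

    The p value comes from the Mann–Whitney construction: exact enumeration
    when the smaller group has n <= 10 and there are no ties, otherwise the
    tie-corrected normal approximation with continuity correction. W and U
    differ by the constant n_x(n_x+1)/2.
    """
    nx = x.size
    has_ties = np.unique(np.concatenate([x, y])).size < nx + y.size
    method = "exact" if (min(nx, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    w = u1 + nx * (nx + 1) / 2.0
    return TestResult(w, None, float(res.pvalue), "ranksum", extra={"U": u1, "p_method": method})


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    route: str = "auto",
    *,
    alpha_normality: float = 0.05,
) -> TestResult:
    """Compare two independent samples by t-test or Wilcoxon rank-sum.

    ``route="auto"`` uses Student's t-test when both samples pass
    :func:`ks_normality` at ``alpha_normality`` (and are large enough to test),
    otherwise the rank-sum test. The t route reports ``t`` with
    df = n_x + n_y − 2; the rank-sum route reports W of the first sample with
    the Mann–Whitney U in ``extra``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    if route not in {"auto", "t", "ranksum"}:
        raise ValueError(f"unknown route {route!r}")
    if route == "auto":
        try:
            normal = (
                ks_normality(x).p > alpha_normality and ks_normality(y).p > alpha_normality
            )
        except (ValueError, DegenerateDataError):
            normal = False
        route = "t" if normal else "ranksum"
    if route == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(float(res.statistic), float(x.size + y.size - 2), float(res.pvalue), "t")
    return _ranksum(x, y)


def levene(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Levene's test for equality of variances, centered at the group means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise DegenerateDataError("both groups constant: variance test undefined")
    res = sps.levene(x, y, center="mean")
    return TestResult(float(res.statistic), (1.0, float(x.size + y.size - 2)), float(res.pvalue), "levene")


# -- association --------------------------------------------------------------


def chi2_association(table: np.ndarray | Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson chi-squared test of independence, no continuity correction.

    df = (r−1)(c−1); every expected count must be positive, which requires
    all row and column marginals to be nonzero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table must be non-negative")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    chi2, p, df, expected = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        observed=obs, expected=np.asarray(expected), chi2=float(chi2), df=int(df), p=float(p)
    )


# -- rater agreement ----------------------------------------------------------


def cohens_kappa(a: Sequence, b: Sequence) -> float:
    """Cohen's kappa between two categorical event sequences.

    kappa = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the two
    raters' marginal label frequencies. If both raters are constant and
    identical, p_e = 1 and agreement is perfect; kappa is defined as 1.
    """
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    labels = sorted(set(a) | set(b), key=str)
    ai = np.searchsorted(np.asarray([str(l) for l in labels]), [str(v) for v in a])
    bi = np.searchsorted(np.asarray([str(l) for l in labels]), [str(v) for v in b])
    k = len(labels)
    conf = np.zeros((k, k))
    np.add.at(conf, (ai, bi), 1)
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def icc_absolute(ratings: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares on a complete subjects × raters table:

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n)

    where MS_R, MS_C, MS_E are the row (subject), column (rater) and residual
    mean squares, n subjects and k raters. With no between-subject variance
    the numerator is ≤ 0 and the returned value is ≤ 0 (no reliability).
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete subjects x raters matrix, >=2 each")
    if np.isnan(X).any():
        raise ValueError("ratings matrix must be complete")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0  # all mean squares zero: identical constant raters
    return float((ms_r - ms_e) / denom)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


# -- battery-level convenience -------------------------------------------------


def battery_table(dataset: BehavioralDataset, route: str = "auto") -> pd.DataFrame:
    """Per-variable NS vs IS comparison table.

    For each behavioral variable: the group comparison (auto t / rank-sum
    route) and Levene's variance-equality p. Mirrors the univariate battery
    summary reported alongside the multivariate analyses.
    """
    is_ns = dataset.group == "NS"
    rows = []
    for j, name in enumerate(dataset.variable_names):
        x = dataset.values[is_ns, j]
        y = dataset.values[~is_ns, j]
        res = compare_groups(x, y, route=route)
        lev = levene(x, y)
        rows.append(
            {
                "variable": name,
                "test": dataset.meta[j].test,
                "method": res.method,
                "statistic": res.statistic,
                "p": res.p,
                "levene_p": lev.p,
                "mean_NS": float(x.mean()),
                "mean_IS": float(y.mean()),
            }
        )
    return pd.DataFrame(rows)
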