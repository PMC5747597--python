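"""Test-retest reliability: ICC with F-based confidence intervals, SEM,
session-change paired t-tests and a Monte-Carlo Lilliefors normality check.

The ICC comes from the classical two-way ANOVA decomposition of a subjects x
measurements matrix.  Two single-measure forms are offered:

* ``two_way_random_absolute`` — ICC(2,1), absolute agreement, the default
  for device readings that should be interchangeable in value;
* ``two_way_mixed_consistency`` — ICC(3,1), insensitive to constant
  between-column shifts.

Confidence intervals follow the standard F-distribution constructions
(Shrout & Fleiss; McGraw & Wong).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import Variable

__all__ = [
    "IccModel",
    "RepeatedMeasuresMatrix",
    "ReliabilityEstimate",
    "PairedTestResult",
    "NormalityResult",
    "icc_estimate",
    "sem_from_summary",
    "intersession_change_test",
    "normality_check",
    "landis_koch_label",
]


class IccModel(str, Enum):
    TWO_WAY_RANDOM_ABSOLUTE = "two_way_random_absolute"
    TWO_WAY_MIXED_CONSISTENCY = "two_way_mixed_consistency"


@dataclass(frozen=True)
class RepeatedMeasuresMatrix:
    """n subjects x k repeated measurements of a single variable."""

    values: np.ndarray
    variable: Optional[Variable] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (subjects x measurements)")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"need at least 2 subjects and 2 measurements, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("matrix contains missing or non-finite cells")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def landis_koch_label(icc: float) -> str:
    """Agreement label for an ICC point estimate.

    Cutpoints 0.20 / 0.40 / 0.60 / 0.80, with "almost perfect" starting at
    0.81 (the 0.80-0.81 gap belongs to "substantial").
    """
    if icc >= 0.81:
        return "almost perfect"
    if icc > 0.60:
        return "substantial"
    if icc > 0.40:
        return "moderate"
    if icc > 0.20:
        return "fair"
    return "slight"


@dataclass(frozen=True)
class ReliabilityEstimate:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    mean: float
    sd: float
    range: tuple[float, float]
    n: int
    k: int
    model: IccModel
    interpretation: str
    degenerate: bool = False


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares for rows (subjects), columns (measurements) and error."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_estimate(
    matrix: RepeatedMeasuresMatrix,
    model: IccModel | str = IccModel.TWO_WAY_RANDOM_ABSOLUTE,
    confidence: float = 0.95,
) -> ReliabilityEstimate:
    """Single-measures ICC with an F-based confidence interval and SEM.

    SEM uses the pooled SD of all cells and the ICC point estimate:
    ``sem = sd * sqrt(1 - icc)``.  A matrix with no between-subject variance
    has no defined ICC; a degenerate estimate (icc = nan) is returned rather
    than raising.
    """
    model = IccModel(model)
    x = matrix.values
    n, k = x.shape
    pooled_sd = float(np.std(x, ddof=1))
    summary = dict(
        mean=float(x.mean()),
        sd=pooled_sd,
        range=(float(x.min()), float(x.max())),
        n=n,
        k=k,
        model=model,
    )

    msr, msc, mse = _anova_mean_squares(x)
    alpha = 1.0 - confidence

    if math.isclose(msr, 0.0, abs_tol=1e-12) and math.isclose(mse, 0.0, abs_tol=1e-12):
        return ReliabilityEstimate(
            icc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            sem=float("nan"), interpretation="undefined", degenerate=True, **summary,
        )

    if model is IccModel.TWO_WAY_MIXED_CONSISTENCY:
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse if mse > 0 else math.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_crit_u = stats.f.ppf(1 - alpha / 2, df1, df2)
        f_crit_l = stats.f.ppf(1 - alpha / 2, df2, df1)
        fl = f_obs / f_crit_u
        fu = f_obs * f_crit_l
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1) if math.isfinite(fu) else 1.0
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if icc < 1.0 and mse > 0:
            # McGraw & Wong (1996) Satterthwaite interval for ICC(2,1)
            a = k * icc / (n * (1 - icc))
            b = 1 + k * icc * (n - 1) / (n * (1 - icc))
            denom = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = (a * msc + b * mse) ** 2 / denom
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            lo = hi = icc
    icc = float(icc)
    lo = float(min(max(lo, -1.0), icc))
    hi = float(max(min(hi, 1.0), icc))
    sem = sem_from_summary(pooled_sd, min(icc, 1.0))
    return ReliabilityEstimate(
        icc=icc, ci_low=lo, ci_high=hi, sem=sem,
        interpretation=landis_koch_label(icc), **summary,
    )


def sem_from_summary(sd: float, icc: float) -> float:
    """Standard error of measurement: sd * sqrt(1 - icc)."""
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if icc > 1:
        raise ValueError(f"icc must not exceed 1, got {icc}")
    return float(sd * math.sqrt(1.0 - icc))


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    mean_change: float
    sd_change: float
    n: int
    degenerate: bool = False


def intersession_change_test(
    session1_means: Sequence[float], session2_means: Sequence[float]
) -> PairedTestResult:
    """Paired t-test on session-2 minus session-1 participant means.

    Degenerate cases return flagged results rather than raising: identical
    vectors give t = 0, p = 1; a constant non-zero shift gives an infinite t
    with p = 0.
    """
    a = np.asarray(session1_means, dtype=float)
    b = np.asarray(session2_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd == 0.0:
        if md == 0.0:
            return PairedTestResult(t=0.0, p=1.0, mean_change=0.0, sd_change=0.0,
                                    n=n, degenerate=True)
        t = math.copysign(math.inf, md)
        return PairedTestResult(t=t, p=0.0, mean_change=md, sd_change=0.0,
                                n=n, degenerate=True)
    t, p = stats.ttest_rel(b, a)
    return PairedTestResult(t=float(t), p=float(p), mean_change=md, sd_change=sd, n=n)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p: float
    n: int
    n_replicates: int
    degenerate: bool = False


def normality_check(
    values: Sequence[float],
    n_replicates: int = 9999,
    seed: int = 0,
) -> NormalityResult:
    """Kolmogorov-Smirnov test against a normal with estimated parameters.

    The p-value is Monte-Carlo (Lilliefors-corrected): the KS statistic is
    recomputed on ``n_replicates`` standard-normal samples of the same size,
    each with its own estimated mean/SD, and the p-value is the fraction of
    replicate statistics at least as large as the observed one (with the
    usual +1 continuity correction).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-d sample with n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        return NormalityResult(statistic=float("nan"), p=float("nan"), n=x.size,
                               n_replicates=0, degenerate=True)
    obs = stats.kstest(x, "norm", args=(x.mean(), sd)).statistic
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal(size=(n_replicates, x.size))
    mu = sims.mean(axis=1, keepdims=True)
    s = sims.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((sims - mu) / s, axis=1)
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, x.size + 1) / x.size
    d_plus = (grid - cdf).max(axis=1)
    d_minus = (cdf - (np.arange(x.size) / x.size)).max(axis=1)
    sim_stats = np.maximum(d_plus, d_minus)
    p = (np.sum(sim_stats >= obs - 1e-12) + 1) / (n_replicates + 1)
    return NormalityResult(statistic=float(obs), p=float(p), n=x.size,
                           n_replicates=n_replicates)
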