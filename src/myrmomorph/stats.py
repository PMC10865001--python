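"""Group-comparison statistics: Cohen's d, BCa bootstrap CIs, F-tests.

The effect size for mean accuracy differences is Cohen's d with the pooled
standard deviation; its confidence interval is the bias-corrected and
accelerated (BCa) bootstrap, resampling each group independently with
replacement.  Bias correction z0 comes from the fraction of bootstrap
statistics below the point estimate, and the acceleration from the jackknife
skewness over the pooled observations.  Variance ratios are compared with the
classical F-test; the one-sided confidence bound matches R's ``var.test``
convention (upper bound f / F_quantile(alpha; df1, df2) for the
``less`` alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

DEFAULT_N_BOOT = 10_000
#: fraction of degenerate (zero-variance) resamples tolerated before erroring
MAX_REDRAW_FRACTION = 0.10


@dataclass
class EffectSizeResult:
    """Point estimate with BCa bootstrap confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int | None
    statistic: str = "cohens_d"
    z0: float = 0.0
    acceleration: float = 0.0
    n_redraws: int = 0

    def __iter__(self):  # convenient unpacking: d, lo, hi
        return iter((self.estimate, self.ci_low, self.ci_high))


@dataclass
class VarianceTestResult:
    """Variance-ratio F-test (numerator = first sample)."""

    f: float
    df1: int
    df2: int
    p: float
    ci_low: float
    ci_high: float
    alternative: str
    level: float = 0.95


def cohens_d(sample1, sample2) -> float:
    """Standardized mean difference (first minus second) with pooled SD.

    d = (mean1 - mean2) / s_pooled,
    s_pooled**2 = ((n1-1) s1**2 + (n2-1) s2**2) / (n1 + n2 - 2).
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if pooled <= 0.0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    return float((x1.mean() - x2.mean()) / np.sqrt(pooled))


def mean_difference(sample1, sample2) -> float:
    """Plain difference in means (first minus second)."""
    return float(np.mean(sample1) - np.mean(sample2))


def _boot_stats(x1, x2, idx1, idx2, statistic):
    """Vectorized bootstrap statistics; NaN marks degenerate resamples."""
    s1, s2 = x1[idx1], x2[idx2]
    m1, m2 = s1.mean(axis=1), s2.mean(axis=1)
    if statistic == "mean_diff":
        return m1 - m2
    n1, n2 = s1.shape[1], s2.shape[1]
    v1, v2 = s1.var(axis=1, ddof=1), s2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (m1 - m2) / np.sqrt(pooled)
    out[pooled <= 0.0] = np.nan
    return out


def _jackknife(x1, x2, stat_func):
    """Delete-one jackknife statistics over the pooled observations."""
    vals = []
    for i in range(len(x1)):
        vals.append(stat_func(np.delete(x1, i), x2))
    for j in range(len(x2)):
        vals.append(stat_func(x1, np.delete(x2, j)))
    return np.asarray(vals)


def bca_bootstrap_ci(
    sample1,
    sample2,
    statistic: str = "cohens_d",
    level: float = 0.95,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> EffectSizeResult:
    """BCa bootstrap confidence interval for a two-sample statistic.

    ``statistic`` is ``"cohens_d"``, ``"mean_diff"`` or a callable
    ``f(sample1, sample2) -> float``.  Groups are resampled independently
    with replacement; resamples on which the statistic is undefined (zero
    pooled variance) are redrawn and counted, erroring if more than 10% of
    ``n_boot`` need redrawing.  Deterministic given ``seed``.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("both samples need at least 2 values")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable BCa quantiles")

    if callable(statistic):
        stat_func, stat_name = statistic, getattr(statistic, "__name__", "custom")
    elif statistic == "cohens_d":
        stat_func, stat_name = cohens_d, "cohens_d"
    elif statistic == "mean_diff":
        stat_func, stat_name = mean_difference, "mean_diff"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    theta_hat = stat_func(x1, x2)
    rng = np.random.default_rng(seed)

    if callable(statistic) and stat_name == "custom":
        boot = np.empty(n_boot)
        n_redraws = 0
        for b in range(n_boot):
            for _ in range(100):
                try:
                    boot[b] = stat_func(
                        rng.choice(x1, size=len(x1)), rng.choice(x2, size=len(x2))
                    )
                    break
                except ValueError:
                    n_redraws += 1
            else:
                raise ValueError("could not draw a valid bootstrap resample")
    else:
        idx1 = rng.integers(0, len(x1), size=(n_boot, len(x1)))
        idx2 = rng.integers(0, len(x2), size=(n_boot, len(x2)))
        boot = _boot_stats(x1, x2, idx1, idx2, stat_name)
        n_redraws = 0
        bad = np.flatnonzero(np.isnan(boot))
        while len(bad):
            n_redraws += len(bad)
            if n_redraws > MAX_REDRAW_FRACTION * n_boot:
                raise ValueError(
                    f"more than {MAX_REDRAW_FRACTION:.0%} of bootstrap resamples "
                    "were degenerate (zero variance)"
                )
            idx1b = rng.integers(0, len(x1), size=(len(bad), len(x1)))
            idx2b = rng.integers(0, len(x2), size=(len(bad), len(x2)))
            boot[bad] = _boot_stats(x1, x2, idx1b, idx2b, stat_name)
            bad = bad[np.isnan(boot[bad])]

    # fully degenerate bootstrap distribution -> a point interval
    if np.allclose(boot, theta_hat, atol=1e-12):
        return EffectSizeResult(
            theta_hat, theta_hat, theta_hat, level, n_boot, seed, stat_name,
            n_redraws=n_redraws,
        )

    p_less = np.mean(boot < theta_hat)
    p_less = min(max(p_less, 0.5 / n_boot), 1.0 - 0.5 / n_boot)
    z0 = sstats.norm.ppf(p_less)

    jack = _jackknife(x1, x2, stat_func)
    resid = jack.mean() - jack
    denom = (resid**2).sum() ** 1.5
    accel = float((resid**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    alpha = 1.0 - level
    ci = []
    for z_alpha in (sstats.norm.ppf(alpha / 2.0), sstats.norm.ppf(1.0 - alpha / 2.0)):
        adj = z0 + (z0 + z_alpha) / (1.0 - accel * (z0 + z_alpha))
        ci.append(float(np.quantile(boot, sstats.norm.cdf(adj))))

    return EffectSizeResult(
        float(theta_hat), ci[0], ci[1], level, n_boot, seed, stat_name,
        z0=float(z0), acceleration=accel, n_redraws=n_redraws,
    )


def variance_ratio_test(
    sample1, sample2, alternative: str = "less", level: float = 0.95
) -> VarianceTestResult:
    """F-test for the ratio of two variances (numerator = first sample).

    ``alternative='less'`` tests whether the first group's variance is
    smaller: p = P(F_{df1,df2} <= f), CI = [0, f / F_quantile(1 - level)].
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 values")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 <= 0.0 or v2 <= 0.0:
        raise ValueError("zero variance in a sample: F-test undefined")
    return variance_ratio_test_from_stats(v1 / v2, n1 - 1, n2 - 1, alternative, level)


def variance_ratio_test_from_stats(
    f: float, df1: int, df2: int, alternative: str = "less", level: float = 0.95
) -> VarianceTestResult:
    """F-test p-value and CI from an already-computed variance ratio."""
    if f <= 0 or df1 < 1 or df2 < 1:
        raise ValueError("need f > 0 and positive degrees of freedom")
    dist = sstats.f(df1, df2)
    alpha = 1.0 - level
    if alternative == "less":
        p = dist.cdf(f)
        ci = (0.0, f / dist.ppf(alpha))
    elif alternative == "greater":
        p = dist.sf(f)
        ci = (f / dist.ppf(level), np.inf)
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
        ci = (f / dist.ppf(1.0 - alpha / 2.0), f / dist.ppf(alpha / 2.0))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return VarianceTestResult(
        float(f), int(df1), int(df2), float(p), float(ci[0]), float(ci[1]),
        alternative, level,
    )
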