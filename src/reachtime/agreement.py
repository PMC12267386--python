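"""Method-agreement and validation statistics.

The instrument-validation layer: Pearson correlation between paired
measurements from two methods, Bland–Altman bias and limits of agreement,
one-way repeated-measures ANOVA with Mauchly's sphericity test and the
Greenhouse–Geisser degrees-of-freedom correction, nonparametric paired
comparisons (Wilcoxon signed-rank, Friedman), Bonferroni multiplicity
control, and a priori power/sample-size for a correlation test using the
exact sampling distribution of r under bivariate normality (Hotelling's
density), which is what dedicated power software computes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, special, stats

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement
SPHERICITY_ALPHA = 0.05


class AnalysisError(ValueError):
    """Degenerate or insufficient input to a statistical routine."""


def pearson_validate(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, int]:
    """Product-moment correlation with two-tailed t-based p; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be paired 1-D vectors")
    if len(x) < 4:
        raise AnalysisError("correlation needs at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("undefined correlation: zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of paired measurements a (method A) vs b."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_slope: float
    prop_slope_p: float
    n: int


def bland_altman(a: Sequence[float], b: Sequence[float]) -> AgreementResult:
    """Bias = mean(a−b); limits of agreement = bias ± 1.96·SD(a−b).

    Proportional bias is the least-squares slope of the differences on the
    pairwise means with its t-test p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("a and b must be paired 1-D vectors")
    if len(a) < 3:
        raise AnalysisError("Bland–Altman needs at least 3 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean) > 0:
        reg = stats.linregress(mean, diff)
        slope, slope_p = float(reg.slope), float(reg.pvalue)
    else:
        slope, slope_p = 0.0, 1.0
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        prop_slope=slope,
        prop_slope_p=slope_p,
        n=len(a),
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA with sphericity diagnostics.

    ``df1``/``df2`` are Greenhouse–Geisser-corrected when Mauchly's test
    rejects sphericity (p < .05); ``gg_epsilon`` is always reported.
    """

    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    sphericity_violated: bool


def rm_anova_f(data: np.ndarray) -> tuple[float, float, float, float]:
    """Uncorrected one-way RM-ANOVA from a subjects × conditions matrix.

    Returns (F, df1, df2, partial eta squared) from the classical sums of
    squares: SS_effect over conditions, SS_error as the residual after
    removing subject means.
    """
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    eta = ss_cond / (ss_cond + ss_err)
    return float(F), float(df1), float(df2), float(eta)


def rm_anova_gg(data) -> AnovaResult:
    """Repeated-measures ANOVA on a complete subjects × conditions matrix.

    Mauchly's W and the Greenhouse–Geisser epsilon come from the sample
    covariance of the repeated measures; the correction multiplies both
    degrees of freedom by epsilon when sphericity is rejected at p < .05.
    With two conditions sphericity holds trivially (epsilon = 1) and
    F equals the squared paired t statistic.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise AnalysisError("data must be a subjects × conditions matrix")
    if np.isnan(X).any():
        raise AnalysisError("missing cells are not allowed (no imputation)")
    n, k = X.shape
    if k < 2 or n < k:
        raise AnalysisError("need k >= 2 conditions and n >= k subjects")

    F, df1, df2, eta = rm_anova_f(X)
    if k == 2:
        w, w_p, eps = 1.0, 1.0, 1.0
    else:
        df = pd.DataFrame(X, columns=[f"c{j}" for j in range(k)])
        spher = pg.sphericity(df)
        w, w_p = float(spher.W), float(spher.pval)
        eps = float(pg.epsilon(df, correction="gg"))
    violated = w_p < SPHERICITY_ALPHA
    if violated:
        df1, df2 = df1 * eps, df2 * eps
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        partial_eta_sq=eta,
        mauchly_w=w,
        mauchly_p=w_p,
        gg_epsilon=eps,
        sphericity_violated=violated,
    )


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Paired signed-rank test; zero differences dropped (Wilcoxon's rule).

    Uses the exact null distribution for small samples without ties and the
    normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("a and b must be paired 1-D vectors")
    diff = a - b
    diff = diff[diff != 0]
    if len(diff) == 0:
        raise AnalysisError("degenerate test: all differences are zero")
    res = stats.wilcoxon(diff, alternative=alternative, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


def friedman(data) -> Tuple[float, float]:
    """Friedman chi-square test on a subjects × conditions matrix."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise AnalysisError("Friedman needs a matrix with at least 3 conditions")
    res = stats.friedmanchisquare(*(X[:, j] for j in range(X.shape[1])))
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Adjusted per-test alpha = alpha/m, reported at 4 decimals."""
    if m < 1:
        raise AnalysisError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must lie in (0, 1)")
    return round(alpha / m, 4)


def _log_pdf_r(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log density of the sample correlation coefficient (Hotelling form)."""
    return (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2 * math.log1p(-rho * rho)
        + (n - 4) / 2 * np.log1p(-r * r)
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2))
    )


def power_pearson_exact(effect_r: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of the t-based test of rho = 0 at sample size n."""
    if n < 4:
        return 0.0
    q = alpha / 2 if tails == 2 else alpha
    tc = stats.t.ppf(1 - q, n - 2)
    rc = tc / math.sqrt(n - 2 + tc * tc)
    f = lambda r: np.exp(_log_pdf_r(np.asarray(r), effect_r, n))
    upper, _ = integrate.quad(f, rc, 1.0)
    if tails == 2:
        lower, _ = integrate.quad(f, -1.0, -rc)
        return float(upper + lower)
    return float(upper)


def power_pearson_n_fisher(
    effect_r: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2
) -> int:
    """Approximate required n via the Fisher-z transformation:
    n = ((z_{alpha} + z_{beta}) / atanh(r))^2 + 3, rounded up."""
    q = alpha / 2 if tails == 2 else alpha
    za = stats.norm.ppf(1 - q)
    zb = stats.norm.ppf(power)
    return math.ceil(((za + zb) / math.atanh(effect_r)) ** 2 + 3)


@dataclass(frozen=True)
class PowerSpec:
    """A priori sample-size result for a correlation test."""

    effect_r: float
    alpha: float
    power: float
    tails: int
    n_required: int


def power_spec(
    effect_r: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2
) -> PowerSpec:
    return PowerSpec(
        effect_r=effect_r,
        alpha=alpha,
        power=power,
        tails=tails,
        n_required=power_pearson_n(effect_r, alpha, power, tails),
    )


def power_pearson_n(
    effect_r: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest n whose exact two-tailed (or one-tailed) test of rho = 0
    attains the requested power when the true correlation is ``effect_r``."""
    if not 0 < effect_r < 1:
        raise AnalysisError("effect_r must lie in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise AnalysisError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise AnalysisError("tails must be 1 or 2")
    # start a little below the Fisher-z estimate and scan upward
    n = max(4, power_pearson_n_fisher(effect_r, alpha, power, tails) - 10)
    while power_pearson_exact(effect_r, n, alpha, tails) < power:
        n += 1
        if n > n_max:
            raise AnalysisError("requested power unreachable within n_max")
    # the scan may have started above the true minimum; walk back down
    while n > 4 and power_pearson_exact(effect_r, n - 1, alpha, tails) >= power:
        n -= 1
    return n
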