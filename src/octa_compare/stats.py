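"""Agreement statistics: paired t-tests, least-squares regression and
Bland-Altman limits of agreement.

Conventions follow common ophthalmic reporting practice: sample (n−1)
standard deviations, two-sided tests, significance at α = 0.05, and exactly
1.96·SD for the 95 % limits of agreement (the normal-quantile convention,
not a t quantile).  No multiple-testing correction is applied by default; a
Bonferroni helper is provided for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError

ALPHA = 0.05


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("inputs must be 1-D")
    if x.shape != y.shape:
        raise ValidationError(f"unequal lengths {x.size} != {y.size}")
    return x, y


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_difference: float
    sd_difference: float
    t_statistic: float
    degrees_freedom: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def paired_t_test(x, y) -> PairedTestResult:
    """Two-sided paired t-test on differences ``d = y − x``.

    Requires n ≥ 2 and non-zero variance of the differences; identical
    samples are a degenerate input (the t statistic is undefined), not a
    p = 0 result.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise DegenerateInputError("paired t-test requires n >= 2")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero-variance differences")
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return PairedTestResult(n=n, mean_difference=mean, sd_difference=sd,
                            t_statistic=float(t), degrees_freedom=n - 1,
                            p_value=p)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R² and the two-sided slope
    p-value (df = n − 2)."""
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise DegenerateInputError("regression requires n >= 2")
    if float(np.ptp(x)) == 0.0:
        raise DegenerateInputError("constant regressor")
    res = sps.linregress(x, y)
    p = float(res.pvalue) if n >= 3 else float("nan")
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2,
                            p_value=p, n=n)


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    outliers: np.ndarray  # boolean flags, pairs outside the limits

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.outliers))


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Differences are ``d = y − x``; the 95 % limits of agreement are
    mean(d) ± 1.96·sd(d) with the sample standard deviation, and every pair
    with d outside [lower, upper] is flagged.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 2:
        raise DegenerateInputError("Bland-Altman requires n >= 2")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower = mean - 1.96 * sd
    upper = mean + 1.96 * sd
    outliers = (d < lower) | (d > upper)
    return BlandAltmanResult(n=n, mean_difference=mean, sd_difference=sd,
                             lower_limit=lower, upper_limit=upper,
                             outliers=outliers)


def bonferroni(p_values, alpha: float = ALPHA) -> np.ndarray:
    """Bonferroni-adjusted significance flags (off by default in reports;
    provided for sensitivity analyses only)."""
    p = np.asarray(p_values, dtype=float)
    return p < alpha / max(p.size, 1)
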