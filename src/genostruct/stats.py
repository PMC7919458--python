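"""Proportion tests, exact binomial, paired t, and per-Myr rate arithmetic.

The one-sample proportion test is the normal-approximation z-test with an
optional Yates continuity correction,

    z = sign(p̂ − p0) · max(|p̂ − p0| − c/n, 0) / sqrt(p0 (1 − p0) / n),

with c = 0.5 when the correction is on.  With the correction and a two-sided
alternative this is equivalent to R's ``prop.test``; the exact binomial test
(minimum-likelihood two-sided rule) is provided as an oracle for the
approximation.  Tail probabilities come from scipy's distribution machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

TWO_SIDED = "two_sided"
GREATER = "greater"
LESS = "less"
_ALTERNATIVES = (TWO_SIDED, GREATER, LESS)


@dataclass(frozen=True)
class PropTestResult:
    x: int
    n: int
    p0: float
    z: float
    p_value: float
    alternative: str
    continuity: bool


@dataclass(frozen=True)
class PairedTResult:
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p_value: float | None
    degenerate: bool = False


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _z_pvalue(z: float, alternative: str) -> float:
    if alternative == TWO_SIDED:
        return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    if alternative == GREATER:
        return float(sps.norm.sf(z))
    return float(sps.norm.cdf(z))


def prop_test_one_sample(
    x: int,
    n: int,
    p0: float,
    alternative: str = TWO_SIDED,
    continuity: bool = True,
) -> PropTestResult:
    """One-sample proportion z-test of x/n against a null proportion p0."""
    _check_alternative(alternative)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must satisfy 0 <= x <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    phat = x / n
    diff = phat - p0
    c = 0.5 / n if continuity else 0.0
    magnitude = max(abs(diff) - c, 0.0)
    z = math.copysign(magnitude, diff) / math.sqrt(p0 * (1.0 - p0) / n)
    return PropTestResult(x, n, p0, z, _z_pvalue(z, alternative), alternative, continuity)


def prop_test_two_sample(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: str = TWO_SIDED,
    continuity: bool = True,
) -> PropTestResult:
    """Two-sample pooled-variance proportion z-test (x1/n1 vs x2/n2)."""
    _check_alternative(alternative)
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError("degenerate pooled proportion (all successes or all failures)")
    diff = x1 / n1 - x2 / n2
    c = (0.5 * (1.0 / n1 + 1.0 / n2)) if continuity else 0.0
    magnitude = max(abs(diff) - c, 0.0)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = math.copysign(magnitude, diff) / se
    # p0 slot carries the second-sample proportion for reporting.
    return PropTestResult(x1, n1, x2 / n2, z, _z_pvalue(z, alternative), alternative, continuity)


def binom_exact(x: int, n: int, p0: float, alternative: str = TWO_SIDED) -> float:
    """Exact binomial tail probability; two-sided via the minimum-likelihood rule."""
    _check_alternative(alternative)
    if n < 1 or not 0 <= x <= n:
        raise ValueError("require n >= 1 and 0 <= x <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    dist = sps.binom(n, p0)
    if alternative == GREATER:
        return float(dist.sf(x - 1))
    if alternative == LESS:
        return float(dist.cdf(x))
    pmf = dist.pmf(np.arange(n + 1))
    # include all outcomes no more likely than the observed one (with a
    # relative fudge for floating-point ties, as R's binom.test does)
    keep = pmf <= pmf[x] * (1.0 + 1e-7)
    return float(min(1.0, pmf[keep].sum()))


def paired_t(diffs) -> PairedTResult:
    """Paired t-test on per-item differences.

    Zero variance is flagged degenerate: all-zero differences report p = 1
    (no evidence of a shift); a constant non-zero shift has an undefined
    t statistic and reports no p-value.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(n, 0.0, 0.0, 0.0, n - 1, 1.0, degenerate=True)
        return PairedTResult(n, mean, 0.0, math.inf if mean > 0 else -math.inf,
                             n - 1, None, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 1)))
    return PairedTResult(n, mean, sd, t, n - 1, p)


def rate_per_myr(count: int, myr: float) -> dict[str, float | None]:
    """Events per Myr and the waiting time in years per event.

    ``years_per_event`` is reported as None when the count is zero.
    """
    if myr <= 0:
        raise ValueError("duration must be > 0 Myr")
    if count < 0:
        raise ValueError("count must be >= 0")
    rate = count / myr
    years = (1e6 * myr / count) if count > 0 else None
    return {"rate": rate, "years_per_event": years}
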