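"""Chi-squared power analysis via the noncentral chi-squared distribution.

For a chi-squared test with ``df`` degrees of freedom at significance
level ``alpha``, sample size ``n`` and Cohen effect size ``w``, the test
statistic under the alternative is noncentral chi-squared with
noncentrality ``lambda = n * w**2``, so

    power = P[ X > c ],  X ~ ncx2(df, n*w^2),  c = chi2.isf(alpha, df).

``required_n`` and ``detectable_effect`` invert this relation in ``n``
and ``w`` respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats

__all__ = ["PowerSpec", "chisq_power", "required_n", "detectable_effect"]


@dataclass(frozen=True)
class PowerSpec:
    """A fully specified chi-squared power computation."""

    effect_size_w: float
    df: int
    alpha: float
    power: float
    n: int

    @property
    def noncentrality(self) -> float:
        return self.n * self.effect_size_w**2


def _validate(w=None, n=None, df=None, alpha=None, power=None) -> None:
    if w is not None and w < 0:
        raise ValueError("effect size w must be non-negative")
    if n is not None and n < 1:
        raise ValueError("sample size n must be at least 1")
    if df is not None and df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    if alpha is not None and not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if power is not None and not 0 < power < 1:
        raise ValueError("target power must lie in (0, 1)")


def chisq_power(w: float, n: int, df: int, alpha: float) -> float:
    """Achieved power of the chi-squared test.

    Exact up to scipy's noncentral chi-squared CDF (well beyond six
    significant digits in this parameter range).  At w=0 the statistic is
    central and the power equals alpha.
    """
    _validate(w=w, n=n, df=df, alpha=alpha)
    crit = stats.chi2.isf(alpha, df)
    if w == 0:
        return alpha
    return float(stats.ncx2.sf(crit, df, n * w * w))


def required_n(w: float, df: int, alpha: float, power: float) -> int:
    """Smallest sample size reaching the target power."""
    _validate(w=w, df=df, alpha=alpha, power=power)
    if w == 0:
        raise ValueError("power above alpha is unreachable at w = 0")
    lo, hi = 1, 2
    while chisq_power(w, hi, df, alpha) < power:
        lo, hi = hi, hi * 2
        if hi > 10**12:
            raise RuntimeError("sample size search exploded")
    while lo < hi:
        mid = (lo + hi) // 2
        if chisq_power(w, mid, df, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def detectable_effect(n: int, df: int, alpha: float, power: float) -> float:
    """Effect size w at which the test attains exactly the target power."""
    _validate(n=n, df=df, alpha=alpha, power=power)

    def gap(w: float) -> float:
        return chisq_power(w, n, df, alpha) - power

    hi = 0.1
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("effect size search exploded")
    return float(optimize.brentq(gap, 1e-12, hi, xtol=1e-12, rtol=1e-14))
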