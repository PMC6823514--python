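"""Miyata's equations for the strength of male mutation bias.

alpha is the male/female germ-line mutation-rate ratio.  Because the Y
spends all its time in males, autosomes half, and the X one third, the
observed rate ratios between chromosome classes determine alpha:

    Y/X = 3 alpha / (2 + alpha)        =>  alpha = 2 / (3X/Y - 1)
    Y/A = 2 alpha / (1 + alpha)        =>  alpha = 1 / (2A/Y - 1)
    X/A = 2 (2 + alpha) / (3 (1 + alpha))
                                       =>  alpha = (4 - 3X/A) / (3X/A - 2)

Each inversion has a pole (the ratio the comparison saturates at as
alpha -> infinity); rates past the pole are flagged as undefined rather than
clipped, and alpha < 1 estimates are flagged out-of-model, so pathological
inputs stay visible.  Confidence intervals propagate the paired bootstrap
replicates of the two rates through the same equations (replicate-matched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bootstrap import BootstrapDistribution

YX, YA, XA = "YX", "YA", "XA"
COMPARISONS = (YX, YA, XA)


@dataclass
class AlphaEstimate:
    comparison: str
    alpha: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_replicates: int = 0
    n_undefined: int = 0
    unstable: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.alpha) and not self.unstable


def alpha_yx(x: float, y: float) -> float:
    """alpha from the Y/X rate comparison; inf past the pole Y >= 3X."""
    _check_rates(x, y)
    denom = 3.0 * x / y - 1.0
    if denom <= 0:
        return math.inf
    return 2.0 / denom


def alpha_ya(y: float, a: float) -> float:
    """alpha from the Y/A rate comparison; inf past the pole Y >= 2A."""
    _check_rates(y, a)
    denom = 2.0 * a / y - 1.0
    if denom <= 0:
        return math.inf
    return 1.0 / denom


def alpha_xa(x: float, a: float) -> float:
    """alpha from the X/A rate comparison.

    inf past the pole X/A <= 2/3; values with X/A >= 4/3 come out <= 0 and
    are returned as computed (out-of-model, caller sees the flag).
    """
    _check_rates(x, a)
    r = 3.0 * x / a
    if r - 2.0 <= 0:
        return math.inf
    return (4.0 - r) / (r - 2.0)


def _check_rates(u: float, v: float):
    if u <= 0 or v <= 0:
        raise ValueError("substitution rates must be positive")


def expected_ratio(comparison: str, alpha: float) -> float:
    """Rate ratio implied by a given alpha (inverse of the estimators)."""
    if alpha < 1:
        import warnings
        warnings.warn(f"alpha={alpha} < 1 is outside the male-bias model")
    if comparison == XA:
        return 2.0 * (2.0 + alpha) / (3.0 * (1.0 + alpha))
    if comparison == YA:
        return 2.0 * alpha / (1.0 + alpha)
    if comparison == YX:
        return 3.0 * alpha / (2.0 + alpha)
    raise ValueError(f"unknown comparison {comparison!r}")


_ESTIMATORS = {YX: lambda num, den: alpha_yx(den, num),   # num=Y, den=X
               YA: lambda num, den: alpha_ya(num, den),   # num=Y, den=A
               XA: lambda num, den: alpha_xa(num, den)}   # num=X, den=A


def _pair_for(comparison: str, x, y, a):
    if comparison == YX:
        return y, x
    if comparison == YA:
        return y, a
    if comparison == XA:
        return x, a
    raise ValueError(f"unknown comparison {comparison!r}")


def alpha_point(comparison: str, x: float, y: float, a: float) -> float:
    num, den = _pair_for(comparison, x, y, a)
    return _ESTIMATORS[comparison](num, den)


@dataclass
class RateTriple:
    """Median X, Y, A rates with their bootstrap distributions."""

    x: BootstrapDistribution
    y: BootstrapDistribution
    a: BootstrapDistribution

    @property
    def medians(self) -> tuple:
        return self.x.point, self.y.point, self.a.point


def alpha_with_ci(rates: RateTriple, comparison: str,
                  max_undefined_frac: float = 0.5) -> AlphaEstimate:
    """Point alpha from median rates; CI from replicate-matched propagation.

    alpha is computed for each bootstrap replicate pair (matched by replicate
    index) and the 95% percentile interval taken over the defined, in-model
    replicates.  Estimates with more than half the replicates undefined are
    flagged unstable.
    """
    x_med, y_med, a_med = rates.medians
    point = alpha_point(comparison, x_med, y_med, a_med)

    series = {YX: (rates.y.values, rates.x.values),
              YA: (rates.y.values, rates.a.values),
              XA: (rates.x.values, rates.a.values)}[comparison]
    num, den = series
    n = min(num.size, den.size)
    reps = np.empty(n)
    undefined = 0
    for i in range(n):
        try:
            v = _ESTIMATORS[comparison](num[i], den[i])
        except ValueError:
            v = math.nan
        if not math.isfinite(v):
            undefined += 1
            v = math.nan
        reps[i] = v
    good = reps[np.isfinite(reps)]
    est = AlphaEstimate(comparison=comparison, alpha=point,
                        n_replicates=n, n_undefined=undefined)
    if n == 0 or undefined / max(n, 1) > max_undefined_frac or good.size == 0:
        est.unstable = True
        return est
    est.ci_low, est.ci_high = (float(v) for v in np.percentile(good, [2.5, 97.5]))
    return est


def alpha_report(rates: RateTriple) -> str:
    """TSV report over the three comparisons."""
    lines = ["comparison\talpha\tci_low\tci_high\tn_replicates\tn_undefined"]
    for comp in COMPARISONS:
        e = alpha_with_ci(rates, comp)
        lines.append(f"{e.comparison}\t{e.alpha:.6g}\t{e.ci_low:.6g}\t"
                     f"{e.ci_high:.6g}\t{e.n_replicates}\t{e.n_undefined}")
    return "\n".join(lines) + "\n"
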