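"""Power and minimum-detectable-effect calculations for MR studies.

Follows the non-centrality-parameter approximation used by the mRnd-style
online calculators.  For a continuous outcome, the two-sided test of the
causal effect has approximate non-centrality

    NCP = n · R² · β²

with n the outcome sample size, R² the exposure variance explained by the
instruments and β the standardized causal effect (SD outcome per SD
exposure); power at level α is the probability a unit-variance normal
shifted by √NCP leaves the acceptance region.  For a binary outcome the
variance deflation by the case fraction φ gives

    NCP = n · R² · φ(1−φ) · log(OR)².

Minimum detectable effects invert these monotone relations numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "PowerSpec",
    "power_continuous",
    "power_binary",
    "min_detectable_effect",
    "min_detectable_or",
]


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for an MR power calculation.

    ``effect`` is the standardized causal effect for a continuous outcome
    or the log odds ratio for a binary one; ``case_fraction`` applies to
    binary outcomes only.
    """

    n: int
    r2: float
    effect: float
    alpha: float = 0.05
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise PowerError(f"n must be positive, got {self.n}")
        if not (0 <= self.r2 < 1):
            raise PowerError(f"r2 must be in [0,1), got {self.r2}")
        if not (0 < self.alpha < 1):
            raise PowerError(f"alpha must be in (0,1), got {self.alpha}")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise PowerError(f"case_fraction must be in (0,1), got {self.case_fraction}")


def _power_from_ncp(ncp: float, alpha: float) -> float:
    z = stats.norm.ppf(1 - alpha / 2)
    s = math.sqrt(ncp)
    return float(stats.norm.sf(z - s) + stats.norm.cdf(-z - s))


def power_continuous(spec: PowerSpec) -> float:
    """Two-sided power for a continuous outcome; equals alpha at effect 0."""
    ncp = spec.n * spec.r2 * spec.effect**2
    return _power_from_ncp(ncp, spec.alpha)


def power_binary(spec: PowerSpec) -> float:
    """Two-sided power for a binary outcome; ``effect`` is log(OR)."""
    if spec.case_fraction is None:
        raise PowerError("binary-outcome power needs case_fraction")
    phi = spec.case_fraction
    ncp = spec.n * spec.r2 * phi * (1 - phi) * spec.effect**2
    return _power_from_ncp(ncp, spec.alpha)


def _invert_ncp(per_unit: float, alpha: float, target_power: float) -> float:
    """Solve NCP = per_unit · x² for the x ≥ 0 achieving target_power."""
    if not (alpha < target_power < 1):
        raise PowerError(
            f"target_power must be in (alpha, 1), got {target_power} with alpha={alpha}"
        )
    if per_unit <= 0:
        raise PowerError("power cannot increase with a zero-information design (n·r2 = 0)")

    def gap(x: float) -> float:
        return _power_from_ncp(per_unit * x * x, alpha) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise PowerError("target power unattainable")
    return float(brentq(gap, 0.0, hi, rtol=1e-10, xtol=1e-14))


def min_detectable_effect(
    n: int, r2: float, alpha: float = 0.05, target_power: float = 0.8
) -> float:
    """Smallest standardized effect detectable with the given power.

    Inverts :func:`power_continuous` by bracketed root-finding; the power at
    the returned effect matches ``target_power`` to ~1e-8 relative.
    """
    PowerSpec(n=n, r2=r2, effect=0.0, alpha=alpha)  # validate
    return _invert_ncp(n * r2, alpha, target_power)


def min_detectable_or(
    n: int,
    case_fraction: float,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> float:
    """Smallest detectable odds ratio (≥ 1) for a binary outcome.

    Power depends on log(OR)² only, so OR and 1/OR are equivalent; the
    value above 1 is returned.
    """
    PowerSpec(n=n, r2=r2, effect=0.0, alpha=alpha, case_fraction=case_fraction)
    log_or = _invert_ncp(n * r2 * case_fraction * (1 - case_fraction), alpha, target_power)
    return math.exp(log_or)
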