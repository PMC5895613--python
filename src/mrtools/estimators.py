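"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized variants with exposure effects βx_j (SE sx_j) and outcome
effects βy_j (SE sy_j), the per-variant Wald ratio θ_j = βy_j / βx_j
estimates the causal effect.  The estimators differ in how they pool:

* **IVW (fixed effects)** — inverse-variance-weighted mean of the Wald
  ratios with first-order weights w_j = βx_j² / sy_j²; identical to the
  weighted least-squares slope of βy on βx through the origin with weights
  1/sy_j².  Unbiased only if every instrument is valid.
* **MR-Egger** — weighted least squares of βy on βx *with* an intercept,
  after orienting every variant so βx_j ≥ 0.  The slope is the causal
  estimate; the intercept estimates the average directional pleiotropy
  (zero under no pleiotropy or balanced pleiotropy).  Coefficient standard
  errors use a residual scale floored at 1, so under-dispersion can never
  shrink them below the fixed-effect value; p-values use t with J−2 df.
* **Weighted median** — the 50% point of the Wald ratios under standardized
  cumulative weights; consistent as long as ≥ 50% of the total weight comes
  from valid instruments.  Its SE comes from a seeded parametric bootstrap.

Wald/IVW/median p-values are two-sided normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw_fixed",
    "egger",
    "weighted_median",
    "weighted_median_point",
]

_TINY_P = 5e-324  # smallest subnormal float; keeps p in (0, 1]


class EstimatorError(ValueError):
    pass


class InsufficientInstrumentsError(EstimatorError):
    pass


@dataclass(frozen=True)
class MRResult:
    """A causal-effect estimate.

    ``beta`` is in outcome units per exposure unit.  ``intercept`` /
    ``intercept_se`` / ``intercept_p`` are populated for MR-Egger only;
    ``boot_reps`` / ``seed`` for the weighted median only.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_variants: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    boot_reps: int | None = None
    seed: int | None = None

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def _usable(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if not p.excluded]


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    sx = np.array([p.se_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    sy = np.array([p.se_outcome for p in pairs], dtype=float)
    return bx, sx, by, sy


def _norm_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


def wald_ratio(pair: HarmonizedPair) -> MRResult:
    """Single-variant causal estimate βy/βx with first-order SE sy/|βx|."""
    if pair.excluded:
        raise EstimatorError(f"pair {pair.variant_id} was excluded at harmonization")
    if pair.beta_exposure == 0:
        raise EstimatorError(f"undefined Wald ratio: beta_exposure is 0 for {pair.variant_id}")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return MRResult("wald_ratio", beta, se, _norm_p(beta / se), 1)


def ivw_fixed(pairs: Sequence[HarmonizedPair]) -> MRResult:
    """Fixed-effects inverse-variance-weighted estimate.

    With a single pair this degrades to the Wald ratio (a notice-level
    situation the caller may log); it refuses an empty collection.
    """
    use = _usable(pairs)
    if not use:
        raise EstimatorError("ivw_fixed needs at least one usable pair")
    if len(use) == 1:
        r = wald_ratio(use[0])
        return MRResult("ivw_fixed", r.beta, r.se, r.pvalue, 1)
    bx, _, by, sy = _arrays(use)
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    if denom <= 0:
        raise EstimatorError("degenerate weights in IVW")
    beta = float(np.sum(bx * by * w)) / denom
    se = 1.0 / math.sqrt(denom)
    return MRResult("ivw_fixed", beta, se, _norm_p(beta / se), len(use))


def egger(pairs: Sequence[HarmonizedPair], floor_scale: bool = True) -> MRResult:
    """MR-Egger regression: weighted LS of βy on βx with an intercept.

    Every variant is first oriented so βx_j ≥ 0 (negating both betas where
    needed; the estimate is invariant to joint sign flips, the intercept is
    not).  With ``floor_scale`` the residual scale √(RSS_w/(J−2)) is floored
    at 1 before entering the coefficient SEs; over-dispersion still inflates
    them (a multiplicative random-effects correction).  An intercept p-value
    below 0.10 is conventionally read as evidence of directional pleiotropy.
    """
    use = _usable(pairs)
    if len(use) < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 usable pairs, got {len(use)}"
        )
    bx, _, by, sy = _arrays(use)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise EstimatorError("singular design in MR-Egger (no spread in beta_exposure)") from exc
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    df = len(use) - 2
    sigma2 = float(np.sum(w * resid**2)) / df
    scale2 = max(sigma2, 1.0) if floor_scale else sigma2
    ses = np.sqrt(np.diag(cov_unscaled) * scale2)

    def t_p(est: float, se: float) -> float:
        return max(2.0 * stats.t.sf(abs(est / se), df), _TINY_P)

    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_s = float(ses[0]), float(ses[1])
    return MRResult(
        "egger",
        beta=slope,
        se=se_s,
        pvalue=t_p(slope, se_s),
        n_variants=len(use),
        intercept=intercept,
        intercept_se=se_i,
        intercept_p=t_p(intercept, se_i),
    )


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median under standardized cumulative weights.

    Sort θ ascending; with p_j = (Σ_{k≤j} w_k − w_j/2)/Σw, linearly
    interpolate θ across the p_j that bracket 0.5.
    """
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise EstimatorError("weights must be positive")
    order = np.argsort(theta, kind="stable")
    th, w = theta[order], weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(th[0])
    if 0.5 >= p[-1]:
        return float(th[-1])
    return float(np.interp(0.5, p, th))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    boot_reps: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Weights are w_j = βx_j²/sy_j² (inverse variance of the Wald ratio to
    first order).  The bootstrap resamples βx_j ~ N(β̂x_j, sx_j) and
    βy_j ~ N(β̂y_j, sy_j) and recomputes the weighted median; the SE is the
    standard deviation over ``boot_reps`` replicates.  ``seed`` is required
    so runs are reproducible.
    """
    use = _usable(pairs)
    if len(use) < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 usable pairs, got {len(use)}"
        )
    if boot_reps < 100:
        raise EstimatorError("boot_reps must be >= 100")
    if seed is None:
        raise EstimatorError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(use)
    if np.any(bx == 0):
        raise EstimatorError("beta_exposure of 0 gives an undefined Wald ratio")
    theta = by / bx
    w = bx**2 / sy**2
    beta = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(boot_reps, len(use)))
    by_b = rng.normal(by, sy, size=(boot_reps, len(use)))
    bx_b[bx_b == 0] = np.finfo(float).tiny  # keep ratios defined
    th_b = by_b / bx_b
    w_b = bx_b**2 / sy**2
    order = np.argsort(th_b, axis=1, kind="stable")
    th_s = np.take_along_axis(th_b, order, axis=1)
    w_s = np.take_along_axis(w_b, order, axis=1)
    p = (np.cumsum(w_s, axis=1) - 0.5 * w_s) / np.sum(w_s, axis=1, keepdims=True)
    ests = np.empty(boot_reps)
    for i in range(boot_reps):  # interp has no axis support; J is small
        ests[i] = np.interp(0.5, p[i], th_s[i])
    se = float(np.std(ests, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny
        pvalue = _TINY_P if beta != 0 else 1.0
    else:
        pvalue = _norm_p(beta / se)
    return MRResult(
        "weighted_median",
        beta=beta,
        se=se,
        pvalue=pvalue,
        n_variants=len(use),
        boot_reps=boot_reps,
        seed=seed,
    )
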