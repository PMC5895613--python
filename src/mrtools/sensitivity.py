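"""Heterogeneity, exclusion-rerun cascade, instrument strength and the
p-threshold relaxation scan.

Cochran's Q tests whether the per-variant Wald ratios are mutually
consistent with a single causal effect: Q = Σ_j w_j (θ_j − β_IVW)² with
w_j = βx_j²/sy_j², referred to chi-square with J−1 df.  A heterogeneity
p-value below 0.05 triggers a rerun of all estimators after removing the
variants that are individually associated with the outcome (p_outcome
below a cutoff, default 0.05).

Instrument strength is summarized by F = [R²(n−1−K)] / [(1−R²)K], where R²
is the exposure variance the K instruments jointly explain and n the
exposure GWAS sample size; F ≤ 10 flags weak instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimators import (
    EstimatorError,
    InsufficientInstrumentsError,
    MRResult,
    egger,
    ivw_fixed,
    weighted_median,
)
from .harmonize import HarmonizationConfig, HarmonizedPair, harmonize_set
from .sumstats import VariantAssociation, select_instruments

__all__ = [
    "HeterogeneityResult",
    "ExclusionRerun",
    "FStatistic",
    "SensitivityReport",
    "cochran_q",
    "exclusion_rerun",
    "f_statistic",
    "threshold_scan",
]

EGGER_INTERCEPT_ALPHA = 0.10  # intercept p below this flags pleiotropy
HETEROGENEITY_ALPHA = 0.05


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float
    per_variant_Q: dict[str, float]

    @property
    def heterogeneous(self) -> bool:
        return self.pvalue < HETEROGENEITY_ALPHA


@dataclass(frozen=True)
class FStatistic:
    value: float
    weak: bool  # True when F <= 10

    def __float__(self) -> float:
        return self.value


@dataclass
class ExclusionRerun:
    """Result of removing outcome-associated variants and re-estimating."""

    excluded_variants: list[str]
    exclusion_reasons: dict[str, str]
    results: dict[str, MRResult] | None  # None when non-estimable
    heterogeneity: HeterogeneityResult | None
    non_estimable_reason: str = ""


@dataclass
class SensitivityReport:
    heterogeneity: HeterogeneityResult
    f_statistic: FStatistic | None
    egger_pleiotropy_flag: bool | None
    rerun: ExclusionRerun | None = None  # present iff heterogeneity p < 0.05


def _wald_arrays(pairs: Sequence[HarmonizedPair]):
    use = [p for p in pairs if not p.excluded]
    bx = np.array([p.beta_exposure for p in use])
    by = np.array([p.beta_outcome for p in use])
    sy = np.array([p.se_outcome for p in use])
    return use, by / bx, bx**2 / sy**2


def cochran_q(pairs: Sequence[HarmonizedPair], ivw: MRResult) -> HeterogeneityResult:
    """Cochran's Q around a fixed-effects IVW estimate.

    ``ivw`` must have been computed on exactly these pairs (checked via the
    variant count).
    """
    use, theta, w = _wald_arrays(pairs)
    if len(use) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 usable pairs")
    if ivw.n_variants != len(use):
        raise ValueError(
            f"IVW was computed on {ivw.n_variants} pairs but {len(use)} were given"
        )
    contrib = w * (theta - ivw.beta) ** 2
    Q = float(np.sum(contrib))
    df = len(use) - 1
    p = float(stats.chi2.sf(Q, df))
    return HeterogeneityResult(
        Q=Q,
        df=df,
        pvalue=max(p, 5e-324),
        per_variant_Q={u.variant_id: float(c) for u, c in zip(use, contrib)},
    )


def exclusion_rerun(
    pairs: Sequence[HarmonizedPair],
    outcome_p_cutoff: float = 0.05,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> ExclusionRerun:
    """Remove variants individually associated with the outcome and rerun.

    A variant is removed when its outcome-association p-value is below
    ``outcome_p_cutoff``.  IVW, MR-Egger and the weighted median (and the
    heterogeneity test) are recomputed on the remainder; a remainder too
    small to estimate is reported as non-estimable, never raised.
    """
    use = [p for p in pairs if not p.excluded]
    kept = [p for p in use if not p.p_outcome < outcome_p_cutoff]
    dropped = [p for p in use if p.p_outcome < outcome_p_cutoff]
    reasons = {
        p.variant_id: f"outcome association p={p.p_outcome:.3g} < {outcome_p_cutoff}"
        for p in dropped
    }
    out = ExclusionRerun(
        excluded_variants=[p.variant_id for p in dropped],
        exclusion_reasons=reasons,
        results=None,
        heterogeneity=None,
    )
    if not kept:
        out.non_estimable_reason = "all variants excluded by the outcome-p cutoff"
        return out
    results: dict[str, MRResult] = {"ivw_fixed": ivw_fixed(kept)}
    # IVW alone is still reported when the sensitivity estimators cannot run
    # (too few variants, or a degenerate design such as constant beta_exposure)
    try:
        results["egger"] = egger(kept)
    except EstimatorError:
        pass
    try:
        results["weighted_median"] = weighted_median(kept, boot_reps=boot_reps, seed=seed)
    except EstimatorError:
        pass
    out.results = results
    if len(kept) >= 2:
        out.heterogeneity = cochran_q(kept, results["ivw_fixed"])
    return out


def f_statistic(r2: float, n: int, k: int) -> FStatistic:
    """Instrument-strength F-statistic: [R²(n−1−K)] / [(1−R²)K].

    ``r2`` is the fraction of exposure variance explained by the K
    instruments jointly, ``n`` the exposure GWAS sample size.  Values at or
    below 10 set the weak-instrument flag.
    """
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    value = (r2 * (n - 1 - k)) / ((1 - r2) * k)
    return FStatistic(value=value, weak=value <= 10)


def threshold_scan(
    exposure_assocs: Sequence[VariantAssociation],
    outcome_assocs: Sequence[VariantAssociation],
    thresholds: Sequence[float],
    harmonization: HarmonizationConfig = HarmonizationConfig(),
    clump_window: int = 1_000_000,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> list[dict]:
    """Re-select instruments at progressively relaxed p-value thresholds and
    re-estimate at each.

    ``thresholds`` must be sorted ascending (most stringent first); the
    instrument count is then non-decreasing across the scan.  Each entry
    carries the threshold, instrument/pair counts and the estimator results
    (methods that need more instruments than survive are omitted for that
    threshold).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    entries: list[dict] = []
    for thr in thresholds:
        instruments = select_instruments(
            exposure_assocs, p_threshold=thr, clump_window=clump_window
        )
        pairs, summary = harmonize_set(instruments, outcome_assocs, harmonization)
        usable = [p for p in pairs if not p.excluded]
        entry: dict = {
            "p_threshold": thr,
            "n_instruments": len(instruments),
            "n_usable_pairs": len(usable),
            "harmonization": summary,
            "results": {},
        }
        if usable:
            entry["results"]["ivw_fixed"] = ivw_fixed(usable)
            try:
                entry["results"]["egger"] = egger(usable)
            except EstimatorError:
                pass
            try:
                entry["results"]["weighted_median"] = weighted_median(
                    usable, boot_reps=boot_reps, seed=seed
                )
            except EstimatorError:
                pass
        entries.append(entry)
    return entries
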