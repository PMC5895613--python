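"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the ingredients of a two-sample MR study of a
quantitative risk factor on a quantitative ECG trait: a set of independent
instruments with genome-wide-significant exposure associations in one large
GWAS, and the same variants' outcome associations in a second, non-
overlapping GWAS.

Model (standardized traits, additive per-allele effects):

* allele frequency p_j ~ Uniform(maf_range); per-study sampling SE of a
  per-allele effect is 1/√(2 p_j (1−p_j) n), the usual GWAS approximation.
* true exposure effect γ_j = z_j · SE_exposure with |z_j| ~
  Uniform(z_abs_range) (default 8–35, so every instrument clears P < 5e-8,
  as published instrument lists do).  γ_j > 0: effect alleles are oriented
  to the exposure-increasing allele, the convention of instrument tables.
* true outcome effect = causal_effect · γ_j + α_j, with pleiotropy α_j = 0
  (``none``), ~N(0, sd) (``balanced``) or ~N(mean, sd) (``directional``),
  applied to a ``pleiotropy_fraction`` subset of variants.
* observed betas add N(0, SE) sampling noise per study.

``corrupt_alleles`` then rewrites a controllable fraction of rows to
exercise harmonization: effect/other allele swaps (with beta and frequency
mirrored, so the signal is preserved), strand complements, and replacement
by palindromic allele pairs whose frequency nearness to 0.5 is an input.
Every rewrite is logged so tests can check recovery action-for-action.

No linkage disequilibrium is simulated (variants are independent);
clumping is exercised with explicitly constructed positional clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats import VariantAssociation

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_two_sample", "corrupt_alleles"]

_TINY_P = 5e-324
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one two-sample dataset.

    Defaults mirror the blood-pressure-on-Cornell arm of the study design:
    55 instruments, exposure GWAS of 201,529 and outcome GWAS of 73,518.
    ``seed`` is mandatory: every draw flows from it.
    """

    seed: int
    n_variants: int = 55
    causal_effect: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_fraction: float = 1.0  # fraction of variants carrying pleiotropy
    n_exposure: int = 201_529
    n_outcome: int = 73_518
    maf_range: tuple[float, float] = (0.05, 0.45)
    z_abs_range: tuple[float, float] = (8.0, 35.0)
    flip_fraction: float = 0.0
    complement_fraction: float = 0.0
    palindrome_fraction: float = 0.0
    palindrome_eaf: float = 0.25  # planted palindrome frequency; near 0.5 = ambiguous
    eaf_noise_sd: float = 0.0  # between-cohort frequency jitter

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5):
            raise SyntheticError(f"degenerate maf_range {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SyntheticError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        fracs = (self.flip_fraction, self.complement_fraction, self.palindrome_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise SyntheticError("corruption fractions must lie in [0,1] and sum to <= 1")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise SyntheticError("pleiotropy_fraction must be in [0,1]")
        if not (0 < self.palindrome_eaf < 1):
            raise SyntheticError("palindrome_eaf must be in (0,1)")
        if self.n_variants < 1:
            raise SyntheticError("n_variants must be >= 1")


@dataclass
class SyntheticTruth:
    """Generating truth: per-variant exposure effect and pleiotropy, plus the
    global causal effect.  Outcome expectation per variant is
    causal_effect · gamma_j + alpha_j."""

    variant_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    causal_effect: float
    pleiotropic_ids: list[str]
    config: SyntheticConfig

    def expected_outcome_beta(self) -> np.ndarray:
        return self.causal_effect * self.gamma + self.alpha


def _se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, _TINY_P)


def generate_two_sample(
    cfg: SyntheticConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], SyntheticTruth]:
    """Draw one exposure table, one outcome table and the generating truth.

    Bit-identical for a given config (including seed).  Variants are placed
    ≥ 3 Mb apart within a chromosome so default distance clumping keeps all
    of them.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_variants

    eaf = rng.uniform(*cfg.maf_range, size=J)
    eaf_out = eaf
    if cfg.eaf_noise_sd > 0:
        eaf_out = np.clip(eaf + rng.normal(0, cfg.eaf_noise_sd, size=J), 0.001, 0.999)
    sx = _se(eaf, cfg.n_exposure)
    sy = _se(eaf_out, cfg.n_outcome)

    z = rng.uniform(*cfg.z_abs_range, size=J)
    gamma = z * sx

    alpha = np.zeros(J)
    pleio_ids: list[str] = []
    if cfg.pleiotropy_mode != "none":
        k = int(round(cfg.pleiotropy_fraction * J))
        idx = rng.permutation(J)[:k]
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[idx] = rng.normal(mean, cfg.pleiotropy_sd, size=k)

    bx = gamma + rng.normal(0.0, sx)
    by = cfg.causal_effect * gamma + alpha + rng.normal(0.0, sy)
    px = _pvals(bx, sx)
    py = _pvals(by, sy)

    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=J)

    exposure: list[VariantAssociation] = []
    outcome: list[VariantAssociation] = []
    ids: list[str] = []
    for j in range(J):
        vid = f"rs{j + 1:06d}"
        ids.append(vid)
        ea, oa = _NONPALINDROMIC_PAIRS[pair_idx[j]]
        chrom = str(j % 22 + 1)
        pos = 10_000_000 + (j // 22) * 3_000_000
        exposure.append(
            VariantAssociation(
                variant_id=vid, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
                beta=float(bx[j]), se=float(sx[j]), pvalue=float(px[j]),
                n=cfg.n_exposure,
            )
        )
        outcome.append(
            VariantAssociation(
                variant_id=vid, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, eaf=float(eaf_out[j]),
                beta=float(by[j]), se=float(sy[j]), pvalue=float(py[j]),
                n=cfg.n_outcome,
            )
        )
    pleio_ids = [ids[j] for j in range(J) if alpha[j] != 0.0]
    truth = SyntheticTruth(
        variant_ids=ids,
        gamma=gamma,
        alpha=alpha,
        causal_effect=cfg.causal_effect,
        pleiotropic_ids=pleio_ids,
        config=cfg,
    )
    return exposure, outcome, truth


def corrupt_alleles(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    truth: SyntheticTruth,
    cfg: SyntheticConfig | None = None,
) -> tuple[list[VariantAssociation], list[VariantAssociation], list[dict]]:
    """Rewrite allele representations to exercise the harmonizer.

    Disjoint row subsets (sizes ``round(fraction · n)``) receive:

    * ``flip`` — outcome effect/other alleles swapped, beta negated, eaf
      mirrored (signal preserved; the harmonizer must flip it back);
    * ``complement`` — outcome alleles strand-complemented, values intact;
    * ``palindrome`` — the variant's allele pair becomes A/T or C/G on BOTH
      tables with frequency ``palindrome_eaf``; half the planted palindromes
      are additionally strand-swapped on the outcome side (beta negated,
      frequency mirrored), which only the frequency rule can undo.

    Returns the (possibly rewritten) exposure table, the corrupted outcome
    table and a per-action log.  Deterministic given the config seed.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 104729])  # independent corruption stream
    n = len(outcome)
    k_flip = int(round(cfg.flip_fraction * n))
    k_comp = int(round(cfg.complement_fraction * n))
    k_pal = int(round(cfg.palindrome_fraction * n))
    order = rng.permutation(n)
    flip_idx = set(order[:k_flip].tolist())
    comp_idx = set(order[k_flip:k_flip + k_comp].tolist())
    pal_idx = order[k_flip + k_comp:k_flip + k_comp + k_pal].tolist()
    pal_pairs = rng.integers(0, 2, size=len(pal_idx))  # 0 -> A/T, 1 -> C/G
    pal_swap = rng.integers(0, 2, size=len(pal_idx)).astype(bool)

    exposure_out = list(exposure)
    outcome_out = list(outcome)
    log: list[dict] = []

    for i in sorted(flip_idx):
        o = outcome_out[i]
        outcome_out[i] = replace(
            o,
            effect_allele=o.other_allele,
            other_allele=o.effect_allele,
            beta=-o.beta,
            eaf=None if o.eaf is None else 1.0 - o.eaf,
        )
        log.append({"variant_id": o.variant_id, "action": "flip"})
    for i in sorted(comp_idx):
        o = outcome_out[i]
        outcome_out[i] = replace(
            o,
            effect_allele=_COMPLEMENT[o.effect_allele],
            other_allele=_COMPLEMENT[o.other_allele],
        )
        log.append({"variant_id": o.variant_id, "action": "complement"})
    for i, pair_kind, swap in zip(pal_idx, pal_pairs, pal_swap):
        ea, oa = ("A", "T") if pair_kind == 0 else ("C", "G")
        e = exposure_out[i]
        o = outcome_out[i]
        exposure_out[i] = replace(e, effect_allele=ea, other_allele=oa, eaf=cfg.palindrome_eaf)
        new_eaf = cfg.palindrome_eaf
        new_beta = o.beta
        if swap:  # report the opposite strand's allele as the effect allele
            new_eaf = 1.0 - new_eaf
            new_beta = -o.beta
        outcome_out[i] = replace(o, effect_allele=ea, other_allele=oa, eaf=new_eaf, beta=new_beta)
        log.append(
            {
                "variant_id": o.variant_id,
                "action": "palindrome",
                "strand_swapped": bool(swap),
                "planted_eaf": cfg.palindrome_eaf,
            }
        )
    return exposure_out, outcome_out, log
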