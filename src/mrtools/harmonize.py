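"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR combines per-variant effects from two GWAS.  Before doing so
the outcome effect must refer to the same effect allele as the exposure
effect.  Four benign representations of the same variant exist (same
orientation, effect/other swapped, opposite strand, opposite strand and
swapped); the harmonizer detects each and negates the outcome beta (and
mirrors its allele frequency) where needed.

Palindromic variants (A/T or C/G) are strand-ambiguous: the allele pair
looks identical on both strands, so only the allele frequency can orient
them.  Following common practice, a palindrome is kept only when the minor
allele frequency on *both* sides is at most ``palindrome_maf_limit``
(default 0.42, i.e. the frequency is informative, not ~0.5); it is then
aligned by frequency concordance (effect frequencies on opposite sides of
0.5 imply opposite orientation).  Palindromes nearer 0.5, or with a missing
frequency on either side, are excluded, as are allele pairs that cannot be
reconciled at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .sumstats import InstrumentSet, VariantAssociation

__all__ = [
    "Action",
    "AlleleRelation",
    "HarmonizationConfig",
    "HarmonizedPair",
    "classify_alleles",
    "harmonize_pair",
    "harmonize_set",
    "write_harmonized_table",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


class HarmonizeError(ValueError):
    pass


class AlleleRelation(str, Enum):
    SAME = "same"
    FLIPPED = "flipped"
    COMPLEMENT = "complement"
    COMPLEMENT_FLIPPED = "complement_flipped"
    PALINDROMIC = "palindromic"
    INCOMPATIBLE = "incompatible"


class Action(str, Enum):
    UNCHANGED = "unchanged"
    OUTCOME_FLIPPED = "outcome_flipped"
    STRAND_COMPLEMENTED = "strand_complemented"
    COMPLEMENTED_AND_FLIPPED = "complemented_and_flipped"
    PALINDROME_ALIGNED = "palindrome_aligned"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class HarmonizationConfig:
    """``palindrome_maf_limit``: maximum minor-allele frequency at which a
    palindromic variant is still considered orientable (default 0.42)."""

    palindrome_maf_limit: float = 0.42
    drop_incompatible: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.palindrome_maf_limit < 0.5):
            raise HarmonizeError(
                f"palindrome_maf_limit must be in (0,0.5), got {self.palindrome_maf_limit}"
            )


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure/outcome pair oriented to the exposure's effect allele.

    When ``action`` is ``excluded`` the betas must not be used downstream;
    ``exclusion_reason`` says why.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    effect_allele: str = ""
    other_allele: str = ""
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action: Action = Action.UNCHANGED
    exclusion_reason: str = ""

    @property
    def excluded(self) -> bool:
        return self.action is Action.EXCLUDED


def classify_alleles(exp_ea: str, exp_oa: str, out_ea: str, out_oa: str) -> AlleleRelation:
    """Classify how the outcome's allele pair relates to the exposure's.

    A palindromic exposure pair ({A,T} or {C,G}) is reported as such
    regardless of the outcome orientation, since strand cannot be resolved
    from alleles alone.
    """
    for a in (exp_ea, exp_oa, out_ea, out_oa):
        if a not in _COMPLEMENT:
            raise HarmonizeError(f"invalid allele {a!r}")
    if exp_ea == exp_oa:
        raise HarmonizeError("exposure effect and other allele must differ")

    if {exp_ea, exp_oa} in _PALINDROMIC_PAIRS:
        return AlleleRelation.PALINDROMIC
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return AlleleRelation.SAME
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return AlleleRelation.FLIPPED
    comp = (_COMPLEMENT[exp_ea], _COMPLEMENT[exp_oa])
    if (out_ea, out_oa) == comp:
        return AlleleRelation.COMPLEMENT
    if (out_ea, out_oa) == comp[::-1]:
        return AlleleRelation.COMPLEMENT_FLIPPED
    return AlleleRelation.INCOMPATIBLE


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    cfg: HarmonizationConfig = HarmonizationConfig(),
) -> HarmonizedPair:
    """Orient one outcome association to the exposure's effect allele."""
    if exp.variant_id != out.variant_id:
        raise HarmonizeError(
            f"variant_id mismatch: {exp.variant_id!r} vs {out.variant_id!r}"
        )

    relation = classify_alleles(
        exp.effect_allele, exp.other_allele, out.effect_allele, out.other_allele
    )

    base = dict(
        variant_id=exp.variant_id,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=out.beta,
        se_outcome=out.se,
        p_outcome=out.pvalue,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        eaf_exposure=exp.eaf,
        eaf_outcome=out.eaf,
    )

    def excluded(reason: str) -> HarmonizedPair:
        return HarmonizedPair(**base, action=Action.EXCLUDED, exclusion_reason=reason)

    def flipped_outcome(action: Action) -> HarmonizedPair:
        base["beta_outcome"] = -out.beta
        if out.eaf is not None:
            base["eaf_outcome"] = 1.0 - out.eaf
        return HarmonizedPair(**base, action=action)

    if relation is AlleleRelation.SAME:
        return HarmonizedPair(**base, action=Action.UNCHANGED)
    if relation is AlleleRelation.FLIPPED:
        return flipped_outcome(Action.OUTCOME_FLIPPED)
    if relation is AlleleRelation.COMPLEMENT:
        return HarmonizedPair(**base, action=Action.STRAND_COMPLEMENTED)
    if relation is AlleleRelation.COMPLEMENT_FLIPPED:
        return flipped_outcome(Action.COMPLEMENTED_AND_FLIPPED)
    if relation is AlleleRelation.INCOMPATIBLE:
        return excluded(
            f"alleles do not correspond ({out.effect_allele}/{out.other_allele} "
            f"vs {exp.effect_allele}/{exp.other_allele})"
        )

    # palindromic: orient by allele-frequency concordance
    if exp.eaf is None or out.eaf is None:
        return excluded("palindromic variant with missing allele frequency")
    limit = cfg.palindrome_maf_limit
    if _maf(exp.eaf) > limit or _maf(out.eaf) > limit:
        return excluded(
            f"palindromic variant with allele frequency above the {limit} limit "
            f"(exposure eaf {exp.eaf:.3f}, outcome eaf {out.eaf:.3f})"
        )
    if (exp.eaf - 0.5) * (out.eaf - 0.5) < 0:
        base["beta_outcome"] = -out.beta
        base["eaf_outcome"] = 1.0 - out.eaf
    return HarmonizedPair(**base, action=Action.PALINDROME_ALIGNED)


def harmonize_set(
    instruments: InstrumentSet | Sequence[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    cfg: HarmonizationConfig = HarmonizationConfig(),
) -> tuple[list[HarmonizedPair], dict]:
    """Harmonize every instrument against an outcome association table.

    Pairs are formed by ``variant_id`` intersection; instruments absent from
    the outcome table are reported in the summary (``missing``), not raised.
    Returns the pairs (retained and excluded) plus summary counts.
    """
    exp_variants = list(instruments.variants if isinstance(instruments, InstrumentSet) else instruments)
    out_by_id = {v.variant_id: v for v in outcome}

    pairs: list[HarmonizedPair] = []
    missing: list[str] = []
    counts = {
        "instruments": len(exp_variants),
        "matched": 0,
        "retained": 0,
        "flipped": 0,
        "palindrome_aligned": 0,
        "palindrome_dropped": 0,
        "palindrome_missing_eaf": 0,
        "incompatible_dropped": 0,
        "missing": 0,
    }
    for exp in exp_variants:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            missing.append(exp.variant_id)
            continue
        pair = harmonize_pair(exp, out, cfg)
        pairs.append(pair)
        counts["matched"] += 1
        if pair.action in (Action.OUTCOME_FLIPPED, Action.COMPLEMENTED_AND_FLIPPED):
            counts["flipped"] += 1
        if pair.action is Action.PALINDROME_ALIGNED:
            counts["palindrome_aligned"] += 1
        if pair.excluded:
            if "missing allele frequency" in pair.exclusion_reason:
                counts["palindrome_missing_eaf"] += 1
            elif "palindromic" in pair.exclusion_reason:
                counts["palindrome_dropped"] += 1
            else:
                counts["incompatible_dropped"] += 1
        else:
            counts["retained"] += 1
    counts["missing"] = len(missing)
    summary = dict(counts)
    summary["missing_variant_ids"] = missing
    summary["palindrome_maf_limit"] = cfg.palindrome_maf_limit
    # the frequency rule is enforced on BOTH cohorts' frequencies
    summary["palindrome_rule"] = "maf <= limit required on exposure and outcome sides"
    return pairs, summary


_PAIR_FIELDS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "eaf_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
    "eaf_outcome",
    "action",
    "exclusion_reason",
)


def write_harmonized_table(pairs: Iterable[HarmonizedPair], dest: str | Path, sep: str = "\t") -> None:
    """Write harmonized pairs as TSV, including action and exclusion_reason."""

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, Action):
            return v.value
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines = [sep.join(_PAIR_FIELDS)]
    for p in pairs:
        lines.append(sep.join(fmt(getattr(p, f)) for f in _PAIR_FIELDS))
    Path(dest).write_text("\n".join(lines) + "\n")
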