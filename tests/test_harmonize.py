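"""Allele orientation, strand resolution and the palindrome frequency rule."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrtools.harmonize import (
    Action,
    AlleleRelation,
    HarmonizationConfig,
    HarmonizeError,
    classify_alleles,
    harmonize_pair,
    harmonize_set,
)
from mrtools.sumstats import VariantAssociation

from conftest import make_assoc


@pytest.mark.parametrize(
    "exp, out, expected",
    [
        (("A", "G"), ("A", "G"), AlleleRelation.SAME),
        (("A", "G"), ("G", "A"), AlleleRelation.FLIPPED),
        (("A", "G"), ("T", "C"), AlleleRelation.COMPLEMENT),
        (("A", "G"), ("C", "T"), AlleleRelation.COMPLEMENT_FLIPPED),
        (("A", "T"), ("A", "T"), AlleleRelation.PALINDROMIC),
        (("A", "T"), ("T", "A"), AlleleRelation.PALINDROMIC),
        (("C", "G"), ("G", "C"), AlleleRelation.PALINDROMIC),
        (("A", "G"), ("A", "C"), AlleleRelation.INCOMPATIBLE),
        (("A", "G"), ("A", "T"), AlleleRelation.INCOMPATIBLE),
    ],
)
def test_classify_alleles(exp, out, expected):
    assert classify_alleles(*exp, *out) is expected


def test_classify_rejects_invalid_allele():
    with pytest.raises(HarmonizeError, match="invalid allele"):
        classify_alleles("A", "N", "A", "G")


class TestHarmonizePair:
    def test_flipped_outcome_negates_beta_and_mirrors_eaf(self):
        exp = make_assoc("rs1", ea="A", oa="G", beta=0.10, eaf=0.3)
        out = make_assoc("rs1", ea="G", oa="A", beta=0.03, eaf=0.6)
        pair = harmonize_pair(exp, out)
        assert pair.action is Action.OUTCOME_FLIPPED
        assert pair.beta_outcome == -0.03
        assert pair.eaf_outcome == pytest.approx(0.4)

    def test_complement_keeps_values(self):
        exp = make_assoc("rs1", ea="A", oa="G", beta=0.10)
        out = make_assoc("rs1", ea="T", oa="C", beta=0.03)
        pair = harmonize_pair(exp, out)
        assert pair.action is Action.STRAND_COMPLEMENTED and pair.beta_outcome == 0.03

    def test_palindrome_concordant_below_limit_retained(self):
        exp = make_assoc("rs1", ea="A", oa="T", eaf=0.20, beta=0.1)
        out = make_assoc("rs1", ea="A", oa="T", eaf=0.21, beta=0.03)
        pair = harmonize_pair(exp, out)
        assert pair.action is Action.PALINDROME_ALIGNED and pair.beta_outcome == 0.03

    def test_palindrome_discordant_frequencies_flip_the_outcome(self):
        exp = make_assoc("rs1", ea="A", oa="T", eaf=0.20, beta=0.1)
        out = make_assoc("rs1", ea="T", oa="A", eaf=0.78, beta=-0.03)
        pair = harmonize_pair(exp, out)
        assert pair.action is Action.PALINDROME_ALIGNED
        assert pair.beta_outcome == 0.03 and pair.eaf_outcome == pytest.approx(0.22)

    def test_palindrome_above_042_limit_excluded(self):
        # frequency too near 0.5 to orient the strand
        exp = make_assoc("rs1", ea="A", oa="T", eaf=0.45, beta=0.1)
        out = make_assoc("rs1", ea="A", oa="T", eaf=0.45, beta=0.03)
        pair = harmonize_pair(exp, out)
        assert pair.excluded and "0.42" in pair.exclusion_reason

    def test_palindrome_missing_eaf_excluded(self):
        exp = make_assoc("rs1", ea="A", oa="T", eaf=None)
        out = make_assoc("rs1", ea="A", oa="T", eaf=0.2)
        pair = harmonize_pair(exp, out)
        assert pair.excluded and "missing" in pair.exclusion_reason

    def test_incompatible_excluded(self):
        pair = harmonize_pair(
            make_assoc("rs1", ea="A", oa="G"), make_assoc("rs1", ea="A", oa="T")
        )
        assert pair.excluded and "correspond" in pair.exclusion_reason

    def test_variant_id_mismatch_is_usage_error(self):
        with pytest.raises(HarmonizeError, match="mismatch"):
            harmonize_pair(make_assoc("rs1"), make_assoc("rs2"))

    def test_flip_of_representation_is_self_inverse(self):
        # swapping the outcome's allele roles (and negating beta, mirroring
        # eaf) changes the representation, not the association: harmonization
        # recovers the same oriented beta, and a double swap is the identity.
        exp = make_assoc("rs1", ea="A", oa="G", beta=0.1)
        rep0 = make_assoc("rs1", ea="A", oa="G", beta=0.03, eaf=0.4)
        rep1 = dataclasses.replace(
            rep0, effect_allele="G", other_allele="A", beta=-rep0.beta, eaf=1 - rep0.eaf
        )
        rep2 = dataclasses.replace(
            rep1, effect_allele="A", other_allele="G", beta=-rep1.beta, eaf=1 - rep1.eaf
        )
        assert rep2 == rep0
        assert (
            harmonize_pair(exp, rep0).beta_outcome
            == harmonize_pair(exp, rep1).beta_outcome
            == 0.03
        )

    @given(
        eaf_exp=st.floats(0.01, 0.42), eaf_out=st.floats(0.01, 0.42),
        low=st.floats(0.05, 0.41), high=st.floats(0.05, 0.41),
    )
    def test_palindrome_exclusion_monotone_in_maf_limit(self, eaf_exp, eaf_out, low, high):
        low, high = sorted((low, high))
        exp = make_assoc("rs1", ea="C", oa="G", eaf=eaf_exp)
        out = make_assoc("rs1", ea="C", oa="G", eaf=eaf_out, beta=0.02)
        kept_low = not harmonize_pair(exp, out, HarmonizationConfig(low)).excluded
        kept_high = not harmonize_pair(exp, out, HarmonizationConfig(high)).excluded
        # a lower limit never retains a variant the higher limit dropped
        assert not (kept_low and not kept_high)


class TestHarmonizeSet:
    def test_intersection_and_missing_reported(self):
        instruments = [make_assoc(f"rs{i}") for i in range(5)]
        outcome = [make_assoc(f"rs{i}", beta=0.01) for i in range(4)]
        pairs, summary = harmonize_set(instruments, outcome)
        assert len(pairs) == 4 and summary["missing"] == 1
        assert summary["missing_variant_ids"] == ["rs4"]
        assert all(p.action is Action.UNCHANGED for p in pairs)

    def test_idempotence(self):
        instruments = [
            make_assoc("rs1", ea="A", oa="G", beta=0.1, eaf=0.3),
            make_assoc("rs2", ea="C", oa="G", beta=0.2, eaf=0.2),
        ]
        outcome = [
            make_assoc("rs1", ea="G", oa="A", beta=0.05, eaf=0.7),
            make_assoc("rs2", ea="C", oa="G", beta=-0.01, eaf=0.21),
        ]
        pairs1, _ = harmonize_set(instruments, outcome)
        # feed the harmonized orientation back in as a new outcome table
        outcome2 = [
            VariantAssociation(
                variant_id=p.variant_id, effect_allele=p.effect_allele,
                other_allele=p.other_allele, eaf=p.eaf_outcome,
                beta=p.beta_outcome, se=p.se_outcome, pvalue=p.p_outcome,
            )
            for p in pairs1
        ]
        pairs2, _ = harmonize_set(instruments, outcome2)
        assert [(p.variant_id, p.beta_outcome, p.eaf_outcome) for p in pairs1] == [
            (p.variant_id, p.beta_outcome, p.eaf_outcome) for p in pairs2
        ]

    def test_empty_intersection_is_empty_not_an_error(self):
        pairs, summary = harmonize_set([make_assoc("rs1")], [make_assoc("rs2")])
        assert pairs == [] and summary["missing"] == 1
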