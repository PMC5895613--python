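"""Cochran's Q, exclusion-rerun cascade, F-statistics and threshold scan."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrtools.estimators import InsufficientInstrumentsError, ivw_fixed
from mrtools.harmonize import harmonize_set
from mrtools.sensitivity import (
    cochran_q,
    exclusion_rerun,
    f_statistic,
    threshold_scan,
)
from mrtools.synthetic import SyntheticConfig, generate_two_sample

from conftest import make_assoc, make_pair


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        pairs = [make_pair(f"rs{i}", 0.1 * (i + 1), 0.01, 0.02 * (i + 1)) for i in range(4)]
        het = cochran_q(pairs, ivw_fixed(pairs))
        assert het.Q == pytest.approx(0, abs=1e-18) and het.pvalue == pytest.approx(1)

    def test_two_variant_hand_toy(self):
        # theta (0.1, 0.3), weights (100, 100): beta_IVW = 0.2, Q = 2
        pairs = [make_pair("a", 1.0, 0.1, 0.1), make_pair("b", 1.0, 0.1, 0.3)]
        het = cochran_q(pairs, ivw_fixed(pairs))
        assert het.Q == pytest.approx(2.0)
        assert het.df == 1
        assert het.pvalue == pytest.approx(0.15729920705, abs=1e-6)

    def test_permutation_invariance_and_decomposition(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        sy = rng.uniform(0.01, 0.1, 8)
        by = rng.normal(0.2 * bx, sy)
        pairs = [make_pair(f"rs{i}", bx[i], sy[i], by[i]) for i in range(8)]
        het = cochran_q(pairs, ivw_fixed(pairs))
        assert het.Q == pytest.approx(sum(het.per_variant_Q.values()), rel=1e-12)
        perm = [pairs[i] for i in rng.permutation(8)]
        het2 = cochran_q(perm, ivw_fixed(perm))
        assert het2.Q == pytest.approx(het.Q, rel=1e-12)

    def test_mismatched_ivw_rejected(self):
        pairs = [make_pair("a", 1.0, 0.1, 0.1), make_pair("b", 1.0, 0.1, 0.3)]
        with pytest.raises(ValueError, match="pairs"):
            cochran_q(pairs, ivw_fixed(pairs[:1]))


class TestExclusionRerun:
    def _pairs(self, p_outcomes):
        return [
            make_pair(f"rs{i}", 0.1, 0.01, 0.02 + 0.001 * i, p_out=p)
            for i, p in enumerate(p_outcomes)
        ]

    def test_threshold_filter(self):
        frag = exclusion_rerun(self._pairs([0.001, 0.20, 0.30, 0.04]), seed=1, boot_reps=100)
        assert frag.excluded_variants == ["rs0", "rs3"]
        assert frag.results["ivw_fixed"].n_variants == 2

    def test_no_variant_below_cutoff_is_a_no_op(self):
        pairs = self._pairs([0.2, 0.3, 0.4, 0.5])
        frag = exclusion_rerun(pairs, seed=1, boot_reps=100)
        assert frag.excluded_variants == []
        ref = ivw_fixed(pairs)
        assert frag.results["ivw_fixed"].beta == ref.beta

    def test_all_excluded_reported_not_raised(self):
        frag = exclusion_rerun(self._pairs([0.001, 0.002]), seed=1)
        assert frag.results is None and "all variants excluded" in frag.non_estimable_reason

    def test_deterministic(self):
        pairs = self._pairs([0.001, 0.2, 0.3, 0.4, 0.04])
        a = exclusion_rerun(pairs, seed=5, boot_reps=100)
        b = exclusion_rerun(pairs, seed=5, boot_reps=100)
        assert a.excluded_variants == b.excluded_variants
        assert a.results["ivw_fixed"].beta == b.results["ivw_fixed"].beta

    def test_planted_outliers_carry_the_heterogeneity(self):
        # variants with large pleiotropy show strong outcome associations;
        # removing outcome-associated variants must calm Cochran's Q
        cfg = SyntheticConfig(
            seed=11, n_variants=40, causal_effect=0.0,
            pleiotropy_mode="balanced", pleiotropy_sd=0.05, pleiotropy_fraction=0.2,
        )
        exposure, outcome, _ = generate_two_sample(cfg)
        pairs, _ = harmonize_set(exposure, outcome)
        het_before = cochran_q(pairs, ivw_fixed(pairs))
        assert het_before.pvalue < 0.05
        frag = exclusion_rerun(pairs, seed=11, boot_reps=100)
        assert frag.heterogeneity.pvalue > het_before.pvalue


class TestFStatistic:
    def test_zero_r2(self):
        f = f_statistic(0.0, 1000, 10)
        assert f.value == 0 and f.weak

    def test_formula_evaluation(self):
        # R^2 x (n - 1 - K) / ((1 - R^2) x K) at the blood-pressure scale
        f = f_statistic(0.034, 201_529, 55)
        assert f.value == pytest.approx(128.93, abs=0.01)
        assert not f.weak

    @given(r2=st.floats(0.001, 0.98), delta=st.floats(1e-4, 0.01))
    def test_strictly_increasing_in_r2(self, r2, delta):
        hi = min(r2 + delta, 0.99)
        assert f_statistic(hi, 10_000, 20).value > f_statistic(r2, 10_000, 20).value

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 5), (0.1, 6, 5), (0.1, 100, 0)])
    def test_domain_errors(self, r2, n, k):
        with pytest.raises(ValueError):
            f_statistic(r2, n, k)


class TestThresholdScan:
    @staticmethod
    def _planted_tables():
        # 12 variants below 5e-8 and 5 more between 5e-8 and 1e-6
        exposure = [
            make_assoc(f"rs{i:03d}", pos=10_000_000 + 3_000_000 * i, p=1e-10, beta=0.1)
            for i in range(12)
        ] + [
            make_assoc(f"rs1{i:02d}", pos=200_000_000 + 3_000_000 * i, p=5e-7, beta=0.05)
            for i in range(5)
        ]
        outcome = [
            make_assoc(v.variant_id, pos=v.pos, beta=0.2 * v.beta, se=0.01, p=0.3)
            for v in exposure
        ]
        return exposure, outcome

    def test_planted_counts_are_recovered_and_non_decreasing(self):
        exposure, outcome = self._planted_tables()
        entries = threshold_scan(exposure, outcome, [5e-8, 1e-6], seed=2, boot_reps=100)
        counts = [e["n_instruments"] for e in entries]
        assert counts == [12, 17]

    def test_single_threshold_matches_direct_run(self):
        exposure, outcome = self._planted_tables()
        (entry,) = threshold_scan(exposure, outcome, [5e-8], seed=2, boot_reps=100)
        pairs, _ = harmonize_set(
            [v for v in exposure if v.pvalue < 5e-8], outcome
        )
        assert entry["results"]["ivw_fixed"].beta == ivw_fixed(pairs).beta

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            threshold_scan([], [], [1e-6, 5e-8])

    def test_estimates_stable_across_thresholds_without_pleiotropy(self):
        # on pleiotropy-free synthetic data relaxing the threshold must not
        # move the estimate outside the tighter run's 95% CI
        cfg = SyntheticConfig(seed=21, n_variants=60, causal_effect=0.2, z_abs_range=(4.0, 30.0))
        exposure, outcome, _ = generate_two_sample(cfg)
        entries = threshold_scan(
            exposure, outcome, [5e-8, 1e-6, 1e-4], seed=21, boot_reps=100
        )
        counts = [e["n_instruments"] for e in entries]
        assert counts == sorted(counts) and counts[-1] > counts[0]
        ivws = [e["results"]["ivw_fixed"] for e in entries]
        lo, hi = ivws[0].ci()
        assert all(lo <= r.beta <= hi for r in ivws)
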