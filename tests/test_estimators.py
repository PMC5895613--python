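"""Wald ratio, IVW, MR-Egger and weighted-median estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrtools.estimators import (
    EstimatorError,
    InsufficientInstrumentsError,
    egger,
    ivw_fixed,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)

from conftest import make_pair


class TestWaldRatio:
    def test_direct_division(self):
        r = wald_ratio(make_pair("rs1", 0.10, 0.01, 0.02))
        assert r.beta == pytest.approx(0.2) and r.se == pytest.approx(0.1)

    def test_null_numerator(self):
        r = wald_ratio(make_pair("rs1", 0.10, 0.01, 0.0))
        assert r.beta == 0 and r.pvalue == 1

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(make_pair("rs1", 0.10, 0.01, 0.02))
        b = wald_ratio(make_pair("rs1", -0.10, 0.01, -0.02))
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_zero_exposure_beta_is_an_error(self):
        with pytest.raises(EstimatorError, match="undefined"):
            wald_ratio(make_pair("rs1", 0.0, 0.01, 0.02))


class TestIVW:
    def test_worked_toy(self, ivw_toy_pairs):
        r = ivw_fixed(ivw_toy_pairs)
        assert r.beta == pytest.approx(13 / 60)  # 0.21667
        assert r.se == pytest.approx(1 / np.sqrt(300))  # 0.05774

    def test_null_outcomes_give_zero(self):
        pairs = [make_pair(f"rs{i}", 0.1 * (i + 1), 0.01, 0.0) for i in range(4)]
        assert ivw_fixed(pairs).beta == 0

    def test_single_pair_reduces_to_wald(self):
        p = make_pair("rs1", 0.10, 0.01, 0.02)
        r, w = ivw_fixed([p]), wald_ratio(p)
        assert (r.beta, r.se, r.pvalue) == (w.beta, w.se, w.pvalue)

    def test_empty_input_is_an_error(self):
        with pytest.raises(EstimatorError):
            ivw_fixed([])


class TestEgger:
    def test_perfect_fit_toy(self):
        pairs = [
            make_pair("rs1", 1.0, 0.1, 0.7),
            make_pair("rs2", 2.0, 0.1, 0.9),
            make_pair("rs3", 3.0, 0.1, 1.1),
        ]
        r = egger(pairs)
        assert r.intercept == pytest.approx(0.5, abs=1e-12)
        assert r.beta == pytest.approx(0.2, abs=1e-12)

    def test_flat_outcomes_give_zero_slope_and_mean_intercept(self):
        pairs = [make_pair(f"rs{i}", 0.5 + 0.2 * i, 0.1, 0.7) for i in range(5)]
        r = egger(pairs)
        assert r.beta == pytest.approx(0.0, abs=1e-12)
        assert r.intercept == pytest.approx(0.7)

    def test_fewer_than_three_pairs_refused(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([make_pair("rs1", 1, 0.1, 0.7), make_pair("rs2", 2, 0.1, 0.9)])

    def test_scale_floor_never_shrinks_ses(self):
        # near-perfect fit: unfloored residual scale << 1
        pairs = [
            make_pair("rs1", 1.0, 0.1, 0.700001),
            make_pair("rs2", 2.0, 0.1, 0.9),
            make_pair("rs3", 3.0, 0.1, 1.1),
            make_pair("rs4", 4.0, 0.1, 1.3),
        ]
        floored, raw = egger(pairs), egger(pairs, floor_scale=False)
        assert floored.se > raw.se and floored.intercept_se > raw.intercept_se
        assert floored.beta == raw.beta

    def test_joint_sign_flips_leave_estimate_unchanged(self):
        pairs = [make_pair(f"rs{i}", bx, 0.1, 0.5 * bx + 0.1) for i, bx in enumerate((1.0, 2.0, 3.0, 4.0))]
        flipped = [
            make_pair(p.variant_id, -p.beta_exposure, p.se_outcome, -p.beta_outcome)
            for p in pairs[:2]
        ] + list(pairs[2:])
        a, b = egger(pairs), egger(flipped)
        assert a.beta == pytest.approx(b.beta) and a.intercept == pytest.approx(b.intercept)


class TestWeightedMedian:
    def test_equal_weight_toy(self):
        assert weighted_median_point([0.1, 0.2, 0.3], [1, 1, 1]) == pytest.approx(0.2)

    def test_unequal_weight_toy(self):
        # p = (0.125, 0.375, 0.75); interpolate 0.5 between 0.2 and 0.3
        assert weighted_median_point([0.1, 0.2, 0.3], [1, 1, 2]) == pytest.approx(0.7 / 3)

    def test_degenerate_equal_ratios(self):
        pairs = [make_pair(f"rs{i}", 0.1 * (i + 1), 0.01, 0.05 * (i + 1)) for i in range(4)]
        r = weighted_median(pairs, boot_reps=200, seed=1)
        assert r.beta == pytest.approx(0.5)
        assert r.se < 0.2  # bootstrap noise only

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(EstimatorError, match="positive"):
            weighted_median_point([0.1, 0.2], [1.0, 0.0])

    def test_seeded_bootstrap_reproducible_and_seed_required(self, ivw_toy_pairs):
        a = weighted_median(ivw_toy_pairs, boot_reps=300, seed=7)
        b = weighted_median(ivw_toy_pairs, boot_reps=300, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)
        with pytest.raises(EstimatorError, match="seed"):
            weighted_median(ivw_toy_pairs, boot_reps=300, seed=None)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.05, 2.0), st.floats(0.01, 0.5), st.floats(-1.0, 1.0)
            ),
            min_size=3,
            max_size=15,
        )
    )
    def test_estimate_within_ratio_range(self, data):
        pairs = [make_pair(f"rs{i}", bx, sy, by) for i, (bx, sy, by) in enumerate(data)]
        theta = [p.beta_outcome / p.beta_exposure for p in pairs]
        r = weighted_median(pairs, boot_reps=100, seed=3)
        assert min(theta) - 1e-12 <= r.beta <= max(theta) + 1e-12


class TestOracleEquivalence:
    """IVW and Egger agree with generic weighted-least-squares solves."""

    @staticmethod
    def _wls_oracle(bx, by, sy, intercept):
        import statsmodels.api as sm

        X = sm.add_constant(bx) if intercept else bx[:, None]
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        return fit

    def test_ivw_matches_wls_through_origin(self, rng):
        for _ in range(50):
            J = rng.integers(3, 20)
            bx = rng.normal(0.1, 0.05, J)
            bx[bx == 0] = 0.01
            sy = rng.uniform(0.01, 0.2, J)
            by = rng.normal(0.2 * bx, sy)
            pairs = [make_pair(f"rs{i}", bx[i], sy[i], by[i]) for i in range(J)]
            r = ivw_fixed(pairs)
            fit = self._wls_oracle(bx, by, sy, intercept=False)
            assert r.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effects SE: unscale the WLS covariance by its residual variance
            se_fixed = fit.bse[0] / np.sqrt(fit.mse_resid)
            assert r.se == pytest.approx(se_fixed, abs=1e-10)

    def test_egger_matches_wls_with_intercept(self, rng):
        for _ in range(50):
            J = rng.integers(3, 20)
            bx = np.abs(rng.normal(0.1, 0.05, J)) + 0.01
            sy = rng.uniform(0.01, 0.2, J)
            by = rng.normal(0.05 + 0.2 * bx, sy)
            pairs = [make_pair(f"rs{i}", bx[i], sy[i], by[i]) for i in range(J)]
            r = egger(pairs, floor_scale=False)
            fit = self._wls_oracle(bx, by, sy, intercept=True)
            assert r.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert r.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert r.intercept_se == pytest.approx(fit.bse[0], abs=1e-10)
            assert r.se == pytest.approx(fit.bse[1], abs=1e-10)
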