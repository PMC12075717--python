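"""The five-estimator battery: closed-form oracles, invariances, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from tsmr.estimators import (
    _mode_point,
    _weighted_median_point,
    egger,
    estimate_all,
    ivw,
    mode_estimator,
    wald_ratio,
    weighted_median,
)
from tsmr.exceptions import InsufficientInstrumentsError, NoInstrumentsError

from conftest import make_hd, random_hd


class TestWaldRatio:
    def test_hand_arithmetic(self):
        hd = make_hd([0.2], [0.1], [0.02])
        r = wald_ratio(hd.pairs[0])
        assert r.ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_zero_outcome_effect(self):
        r = wald_ratio(make_hd([0.2], [0.0], [0.02]).pairs[0])
        assert r.ratio == 0.0

    def test_joint_sign_flip_leaves_ratio_unchanged(self):
        a = wald_ratio(make_hd([0.2], [0.1], [0.02]).pairs[0])
        b = wald_ratio(make_hd([-0.2], [-0.1], [0.02]).pairs[0])
        assert a.ratio == b.ratio and a.se_ratio == b.se_ratio

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValueError):
            wald_ratio(make_hd([0.0], [0.1], [0.02]).pairs[0])


class TestIVW:
    def test_two_snp_hand_example(self, hand_ivw_pair):
        est = ivw(hand_ivw_pair, effects_model="fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(math.sqrt(1 / 500), abs=1e-12)

    def test_exact_proportional_fit_has_no_heterogeneity(self):
        bx = np.array([0.1, 0.2, 0.3])
        hd = make_hd(bx, 0.7 * bx, [0.01, 0.02, 0.03])
        fixed = ivw(hd, "fixed")
        mre = ivw(hd, "mre")
        assert fixed.beta == pytest.approx(0.7, abs=1e-12)
        assert mre.beta == fixed.beta
        assert mre.se == fixed.se  # Q = 0, floor at 1

    def test_single_pair_reduces_to_wald_ratio(self):
        hd = make_hd([0.2], [0.1], [0.02])
        est = ivw(hd)
        r = wald_ratio(hd.pairs[0])
        assert est.beta == pytest.approx(r.ratio)
        assert est.se == pytest.approx(r.se_ratio)
        assert est.n_snp == 1

    def test_no_instruments_raises(self):
        with pytest.raises(NoInstrumentsError):
            ivw(make_hd([], [], []))

    def test_mre_never_tighter_than_fixed(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            hd = random_hd(rng, j=int(rng.integers(2, 15)))
            assert ivw(hd, "mre").se >= ivw(hd, "fixed").se - 1e-15

    def test_matches_wls_through_origin_oracle(self):
        """IVW equals statsmodels WLS of beta_out on beta_exp with no
        intercept and weights 1/se_out^2."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(25):
            hd = random_hd(rng, j=int(rng.integers(2, 20)))
            df = hd.to_frame()
            res = sm.WLS(df.beta_out, df.beta_exp, weights=1 / df.se_out**2).fit()
            est = ivw(hd, "fixed")
            assert est.beta == pytest.approx(res.params.iloc[0], abs=1e-10)

    def test_invariant_to_joint_sign_flips(self):
        rng = np.random.default_rng(4)
        hd = random_hd(rng, j=10)
        df = hd.to_frame()
        flip = rng.choice([-1.0, 1.0], size=10)
        import tsmr.sumstats as ss

        flipped = make_hd(df.beta_exp * flip, df.beta_out * flip, df.se_out, df.se_exp)
        assert ivw(flipped).beta == pytest.approx(ivw(hd).beta, abs=1e-12)
        assert isinstance(hd, ss.HarmonizedDataset)


class TestEgger:
    def test_exact_linear_fit_recovered_to_machine_precision(self, exact_linear_hd):
        est = egger(exact_linear_hd)
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.02, abs=1e-10)
        assert est.extras["residual_scale"] == pytest.approx(0.0, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hd([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_matches_statsmodels_wls_oracle(self):
        """Slope/intercept equal a WLS fit with intercept; SEs equal the
        unscaled WLS SEs inflated by max(1, sqrt(residual scale))."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        for _ in range(20):
            hd = random_hd(rng, j=int(rng.integers(3, 20)))
            df = hd.to_frame()
            sign = np.sign(df.beta_exp).replace(0, 1)
            bx, by = df.beta_exp * sign, df.beta_out * sign
            X = sm.add_constant(bx.to_numpy())
            res = sm.WLS(by.to_numpy(), X, weights=1 / df.se_out**2).fit()
            est = egger(hd)
            assert est.extras["intercept"] == pytest.approx(res.params[0], abs=1e-10)
            assert est.beta == pytest.approx(res.params[1], abs=1e-10)
            infl = max(1.0, math.sqrt(res.scale))
            bse_unscaled = np.sqrt(np.diag(res.cov_params() / res.scale))
            assert est.se == pytest.approx(infl * bse_unscaled[1], rel=1e-8)


class TestWeightedMedian:
    def test_equal_weights_interpolates_to_middle_ratio(self):
        assert _weighted_median_point(
            np.array([0.1, 0.5, 0.9]), np.ones(3)
        ) == pytest.approx(0.5)

    def test_dominant_weight_snp_wins(self):
        hd = make_hd([0.1, 0.1, 0.1], [0.02, 0.05, 0.09], [0.001, 0.1, 0.1])
        est = weighted_median(hd, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=0.02)  # ratio of the precise SNP

    @given(st.integers(3, 15))
    @seed(2024)
    @settings(max_examples=20, deadline=None)
    def test_equal_weights_odd_j_equals_sample_median(self, half):
        j = 2 * half + 1
        rng = np.random.default_rng(j)
        ratios = rng.normal(0.5, 0.3, j)
        assert _weighted_median_point(ratios, np.ones(j)) == pytest.approx(
            float(np.median(ratios)), abs=1e-12
        )

    def test_bootstrap_se_deterministic_under_seed(self, exact_linear_hd):
        a = weighted_median(exact_linear_hd, n_boot=100, seed=7)
        b = weighted_median(exact_linear_hd, n_boot=100, seed=7)
        c = weighted_median(exact_linear_hd, n_boot=100, seed=8)
        assert a.se == b.se
        assert a.se != c.se


class TestModeEstimators:
    def test_simple_mode_finds_the_cluster(self):
        # ratios 0.5, 0.5, 0.5, 5.0 -> kernel density peaks at 0.5
        hd = make_hd([0.1, 0.2, 0.4, 0.1], [0.05, 0.10, 0.20, 0.5], [0.01] * 4)
        est = mode_estimator(hd, weighted=False, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.05)
        assert est.method == "simple-mode"

    def test_mode_point_matches_brute_force_grid(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ratios = rng.normal(0.4, 0.2, 9)
            w = rng.uniform(0.5, 2.0, 9)
            point = _mode_point(ratios, w)
            # independent dense-grid argmax of the same weighted KDE
            s = np.std(ratios, ddof=1)
            iqr = np.subtract(*np.percentile(ratios, [75, 25]))
            h = 0.9 * min(s, iqr / 1.349) * 9 ** (-0.2)
            grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20001)
            wn = w / w.sum()
            dens = sum(
                wn[i] * np.exp(-0.5 * ((grid - ratios[i]) / h) ** 2)
                for i in range(9)
            )
            assert point == pytest.approx(grid[np.argmax(dens)], abs=2 * h / 100)

    def test_identical_ratios_return_common_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        hd = make_hd(bx, 0.3 * bx, [0.01] * 3)
        est = mode_estimator(hd, weighted=True, n_boot=20, seed=2)
        assert est.beta == pytest.approx(0.3, abs=1e-12)

    def test_all_weight_on_one_snp(self):
        assert _mode_point(
            np.array([0.1, 0.9, 0.5]), np.array([1e-9, 1e-9, 1.0])
        ) == pytest.approx(0.5, abs=0.01)


class TestEstimateAll:
    def test_exact_origin_fixture_all_methods_agree(self, exact_origin_hd):
        ests = estimate_all(exact_origin_hd, n_boot=50, seed=3)
        assert set(ests) == {"IVW", "MR-Egger", "weighted-median",
                             "weighted-mode", "simple-mode"}
        for est in ests.values():
            assert est.beta == pytest.approx(0.3, abs=1e-6), est.method

    def test_two_snps_only_ivw_computed(self):
        hd = make_hd([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        ests = estimate_all(hd, seed=1)
        assert set(ests) == {"IVW"}

    def test_or_scale_consistency(self, exact_linear_hd):
        ests = estimate_all(exact_linear_hd, n_boot=50, seed=5)
        for est in ests.values():
            assert est.odds_ratio == pytest.approx(math.exp(est.beta))
            lo, hi = est.or_ci
            assert lo == pytest.approx(math.exp(est.ci_low))
            assert hi == pytest.approx(math.exp(est.ci_high))
            assert est.ci_low <= est.beta <= est.ci_high

    def test_shared_seed_reproducible(self, exact_linear_hd):
        a = estimate_all(exact_linear_hd, n_boot=100, seed=9)
        b = estimate_all(exact_linear_hd, n_boot=100, seed=9)
        for m in a:
            assert a[m].beta == b[m].beta and a[m].se == b[m].se
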