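"""Causal estimators: closed-form oracles, robustness, equivariance."""
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkit import estimators, instruments, synthetic
from mrkit.types import DataError
from conftest import make_h, true_iv_harmonized


class TestRatios:
    @pytest.mark.parametrize(
        "bx,sx,by,sy,ratio,se",
        [
            (1.0, 0.0, 2.0, 1.0, 2.0, 1.0),
            (2.0, 0.0, 4.0, 1.0, 2.0, 0.5),
            (1.0, 0.1, 2.0, 0.3, 2.0, np.sqrt(0.13)),
        ],
    )
    def test_delta_method_second_order(self, bx, sx, by, sy, ratio, se):
        h = [make_h(bx, by, sy, se_exp=sx)]
        (_, r, s), = estimators.ratio_estimates(h)
        assert r == pytest.approx(ratio, abs=1e-12)
        assert s == pytest.approx(se, abs=1e-12)

    def test_zero_exposure_effect_excluded_with_warning(self):
        h = [make_h(0.0, 1.0, 1.0), make_h(1.0, 1.0, 1.0)]
        with pytest.warns(UserWarning, match="beta_exp = 0"):
            out = estimators.ratio_estimates(h)
        assert len(out) == 1


class TestIVW:
    def test_hand_computed_weighted_mean(self, three_iv_oracle):
        fit = estimators.ivw(three_iv_oracle)
        assert fit.beta == pytest.approx(7.0 / 6.0, abs=1e-10)
        assert fit.k_used == 3

    def test_homogeneous_ratios_are_exact_with_zero_q(self):
        h = [make_h(1.0, 1.5, 1.0), make_h(2.0, 3.0, 0.5), make_h(0.5, 0.75, 2.0)]
        mult = estimators.ivw(h, "multiplicative")
        fixed = estimators.ivw(h, "fixed")
        assert mult.beta == pytest.approx(1.5, abs=1e-12)
        assert mult.extra["Q"] == pytest.approx(0.0, abs=1e-12)
        assert mult.se == pytest.approx(fixed.se)

    def test_multiplicative_se_never_below_fixed(self, three_iv_oracle):
        mult = estimators.ivw(three_iv_oracle, "multiplicative")
        fixed = estimators.ivw(three_iv_oracle, "fixed")
        assert mult.se >= fixed.se

    def test_single_instrument_is_hard_error(self):
        with pytest.raises(DataError, match="at least 2"):
            estimators.ivw([make_h(1.0, 1.0, 1.0)])


class TestEgger:
    def test_closed_form_simple_regression(self):
        h = [make_h(1.0, 1.0, 1.0), make_h(2.0, 3.0, 1.0), make_h(3.0, 5.0, 1.0)]
        fit = estimators.egger(h)
        assert fit.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.extra["intercept"] == pytest.approx(-1.0, abs=1e-10)

    def test_line_through_origin_gives_zero_intercept(self):
        h = [make_h(1.0, 0.7, 1.0), make_h(2.0, 1.4, 0.5), make_h(3.0, 2.1, 2.0)]
        fit = estimators.egger(h)
        assert fit.beta == pytest.approx(0.7, abs=1e-10)
        assert fit.extra["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(DataError, match="at least 3"):
            estimators.egger([make_h(1, 1, 1), make_h(2, 2, 1)])

    def test_intercept_type_i_controlled_under_balanced_pleiotropy(self):
        # mean-zero direct effects, InSIDE satisfied, instruments strong
        # enough (and numerous enough) for the normal approximation
        rej = 0
        n = 300
        for s in range(n):
            truth = synthetic.SimTruth(
                seed=940_000 + s, n_iv=50, r2_total=0.023, n_exp=2e6,
                pleiotropy_model="balanced", pleiotropy_sd=0.01,
                n_null=0, palindromic_rate=0.0, flip_rate=0.0,
            )
            fit = estimators.egger(true_iv_harmonized(truth))
            rej += fit.extra["intercept_p"] < 0.05
        half = 3 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= rej / n <= 0.05 + half

    def test_directional_pleiotropy_centres_intercept_on_truth(self):
        # strong instruments so the no-measurement-error assumption holds
        ints = []
        for s in range(60):
            truth = synthetic.SimTruth(
                seed=70_000 + s, n_exp=2e6, pleiotropy_model="directional",
                pleiotropy_mean=0.02, pleiotropy_sd=0.005,
                n_null=0, palindromic_rate=0.0, flip_rate=0.0,
            )
            ints.append(estimators.egger(true_iv_harmonized(truth)).extra["intercept"])
        assert np.mean(ints) == pytest.approx(0.02, abs=0.004)


class TestI2GX:
    def test_identical_exposure_effects_give_zero(self):
        h = [make_h(1.0, 1.0, 1.0, se_exp=0.5) for _ in range(4)]
        assert estimators.i2_gx(h) == 0.0

    def test_negligible_noise_approaches_one(self):
        h = [make_h(0.5 + 0.2 * i, 1.0, 1.0, se_exp=1e-4) for i in range(5)]
        assert estimators.i2_gx(h) > 0.99

    def test_strong_instrument_sets_pass_egger_gate(self):
        vals = [
            estimators.i2_gx(
                true_iv_harmonized(
                    synthetic.SimTruth(seed=75_000 + s, n_exp=2e6, n_null=0,
                                       palindromic_rate=0.0, flip_rate=0.0)
                )
            )
            for s in range(20)
        ]
        assert np.mean([v > 0.9 for v in vals]) >= 0.9


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        h = [make_h(1.0, 1.0, 1.0), make_h(1.0, 2.0, 1.0), make_h(1.0, 9.0, 1.0)]
        fit = estimators.weighted_median(h, n_boot=50, seed=1)
        assert fit.beta == pytest.approx(2.0, abs=1e-10)

    def test_cumulative_weight_interpolation_hand_case(self):
        # ratios {1, 2}, weights {3, 1}: percentile positions 0.375 and
        # 0.875 -> interpolated 50th percentile = 1.25
        r = np.array([1.0, 2.0])
        w = np.array([3.0, 1.0])
        assert estimators._weighted_median_point(r, w) == pytest.approx(1.25, abs=1e-12)

    def test_majority_valid_beats_ivw_under_forty_pct_invalid(self):
        wm, iv = [], []
        for s in range(120):
            truth = synthetic.SimTruth(
                beta_causal=0.5, seed=50_000 + s, pleiotropy_model="correlated",
                pleiotropy_mean=1.5, pleiotropy_sd=0.0, pleiotropy_fraction=0.4,
                n_null=0, palindromic_rate=0.0, flip_rate=0.0,
            )
            use = true_iv_harmonized(truth)
            iv.append(estimators.ivw(use).beta)
            rr = estimators.ratio_estimates(use)
            wm.append(
                estimators._weighted_median_point(
                    np.array([r for _, r, _ in rr]),
                    1.0 / np.array([s_ for _, _, s_ in rr]) ** 2,
                )
            )
        assert abs(np.mean(wm) - 0.5) < abs(np.mean(iv) - 0.5)
        assert abs(np.mean(wm) - 0.5) < 0.1


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        h = [make_h(1.0, 1.0, 1.0), make_h(1.0, 1.01, 1.0),
             make_h(1.0, 0.99, 1.0), make_h(1.0, 5.0, 1.0)]
        fit = estimators.weighted_mode(h, n_boot=50, seed=1)
        assert fit.beta == pytest.approx(1.0, abs=0.1)

    def test_single_cluster_returns_its_value(self):
        h = [make_h(1.0, 0.8, 1.0)] * 4
        fit = estimators.weighted_mode(h, n_boot=50, seed=1)
        assert fit.beta == pytest.approx(0.8, abs=1e-10)

    def test_plurality_valid_recovery(self):
        # 40% valid at 0.5; two invalid 30% clusters at distinct biases
        rng = np.random.default_rng(8)
        est = []
        for _ in range(40):
            k = 20
            ratios = np.concatenate([
                0.5 + rng.normal(0, 0.03, 8),
                1.5 + rng.normal(0, 0.03, 6),
                -0.8 + rng.normal(0, 0.03, 6),
            ])
            h = [make_h(1.0, r, 0.05) for r in ratios]
            est.append(estimators.weighted_mode(h, n_boot=10, seed=2).beta)
        assert np.median(est) == pytest.approx(0.5, abs=0.1)


class TestPresso:
    def _null_set(self, seed):
        return true_iv_harmonized(
            synthetic.SimTruth(seed=seed, n_null=0, palindromic_rate=0.0, flip_rate=0.0)
        )

    def test_homogeneous_set_no_outliers_and_null_global_p(self):
        use = self._null_set(40_003)
        fit = estimators.mr_presso(use, n_sim=1000, seed=3)
        assert fit.extra["outlier_snps"] == []
        assert fit.extra["global_p"] > 0.05

    def test_planted_ten_se_outlier_flagged(self):
        use = self._null_set(40_001)
        x0 = use[0]
        planted = [replace(x0, beta_out=x0.beta_out + 10 * x0.se_out)] + list(use[1:])
        fit = estimators.mr_presso(planted, n_sim=1000, seed=4)
        assert fit.extra["outlier_snps"] == [x0.snp_id]
        assert fit.extra["global_p"] < 0.05

    def test_outlier_free_correction_equals_plain_ivw(self):
        use = self._null_set(40_003)  # asserted outlier-free above
        fit = estimators.mr_presso(use, n_sim=1000, seed=3)
        assert fit.beta == pytest.approx(estimators.ivw(use).beta, abs=1e-12)

    def test_minimum_instruments_and_nsim_guards(self):
        h = [make_h(1, 1, 1)] * 3
        with pytest.raises(DataError, match="at least 4"):
            estimators.mr_presso(h)
        h = [make_h(1.0, 1.0 + 0.01 * i, 1.0, snp_id=f"r{i}") for i in range(4)]
        with pytest.raises(DataError, match="n_sim"):
            estimators.mr_presso(h, n_sim=50)
        with pytest.raises(DataError, match="resolve"):
            estimators.mr_presso(h, n_sim=100, outlier_alpha=0.01)


class TestCorrelatedIVW:
    def test_identity_ld_reduces_to_fixed_effects_ivw(self, three_iv_oracle):
        fit = estimators.ivw_correlated(three_iv_oracle, np.eye(3))
        fixed = estimators.ivw(three_iv_oracle, "fixed")
        assert fit.beta == pytest.approx(fixed.beta, abs=1e-12)
        assert fit.se == pytest.approx(fixed.se, abs=1e-12)

    def test_perfectly_correlated_duplicates_collapse(self):
        one = [make_h(1.0, 2.0, 1.0, snp_id="a"), make_h(2.0, 2.0, 1.0, snp_id="b")]
        dup = [one[0], replace(one[0], snp_id="a2"), one[1]]
        ld = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        f_dup = estimators.ivw_correlated(dup, ld)
        f_one = estimators.ivw_correlated(one, np.eye(2))
        assert f_dup.beta == pytest.approx(f_one.beta, abs=1e-10)
        assert f_dup.se == pytest.approx(f_one.se, abs=1e-10)

    def test_indefinite_matrix_is_hard_error(self):
        h = [make_h(1.0, 1.0, 1.0), make_h(1.0, 1.2, 1.0)]
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(DataError, match="positive semi-definite"):
            estimators.ivw_correlated(h, bad)

    def test_coverage_with_correlated_instruments(self):
        cov = 0
        n = 300
        for s in range(n):
            # strong instruments: GLS models outcome-side correlation only
            truth = synthetic.SimTruth(
                seed=80_000 + s, n_exp=2e6, n_null=0, palindromic_rate=0.0,
                flip_rate=0.0, ld_block_spec=((2, 0.6), (2, 0.6)),
            )
            ds = synthetic.simulate_iv_dataset(truth)
            ivset = [r for r in ds.exposure if r.snp_id in set(ds.iv_ids)]
            use = instruments.usable(instruments.harmonize(ivset, ds.outcome))
            ids = [x.snp_id for x in use]
            ld_r = np.sqrt(ds.ld.loc[ids, ids].to_numpy(dtype=float))
            fit = estimators.ivw_correlated(use, ld_r)
            cov += fit.ci_low <= -0.72 <= fit.ci_high
        assert 0.90 <= cov / n <= 0.98


class TestEquivariance:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        c=st.floats(0.1, 10.0),
        seed=st.integers(0, 10_000),
        k=st.integers(3, 8),
    )
    def test_scale_and_sign_equivariance(self, c, seed, k):
        rng = np.random.default_rng(seed)
        h = [
            make_h(
                float(rng.uniform(0.2, 2.0) * rng.choice([-1, 1])),
                float(rng.normal(0, 1)),
                float(rng.uniform(0.2, 2.0)),
                se_exp=float(rng.uniform(0.01, 0.2)),
                snp_id=f"r{i}",
            )
            for i in range(k)
        ]
        scaled = [
            replace(x, beta_exp=c * x.beta_exp, se_exp=c * x.se_exp) for x in h
        ]
        negated = [replace(x, beta_out=-x.beta_out) for x in h]
        for fn in (
            lambda hh: estimators.ivw(hh).beta,
            lambda hh: estimators.egger(hh).beta,
            lambda hh: estimators.weighted_median(hh, n_boot=10, seed=0).beta,
            lambda hh: estimators.weighted_mode(hh, n_boot=10, seed=0).beta,
        ):
            b = fn(h)
            assert fn(scaled) == pytest.approx(b / c, rel=1e-6, abs=1e-9)
            assert fn(negated) == pytest.approx(-b, rel=1e-6, abs=1e-9)

    def test_homogeneous_ratios_make_all_estimators_agree(self):
        h = [make_h(float(b), 0.8 * float(b), 1.0, snp_id=f"r{i}")
             for i, b in enumerate([1.0, 1.5, 2.0, 2.5])]
        beta = 0.8
        assert estimators.ivw(h).beta == pytest.approx(beta, abs=1e-10)
        assert estimators.egger(h).beta == pytest.approx(beta, abs=1e-10)
        assert estimators.weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(beta, abs=1e-10)
        assert estimators.weighted_mode(h, n_boot=10, seed=0).beta == pytest.approx(beta, abs=1e-10)
        assert estimators.mr_presso(h, n_sim=1000, seed=0).beta == pytest.approx(beta, abs=1e-10)
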