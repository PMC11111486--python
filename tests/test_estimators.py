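"""The five MR estimators and the odds-ratio transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrcausal.estimators import (
    EggerEstimator,
    IVWEstimator,
    METHOD_LABELS,
    ModeEstimator,
    WeightedMedianEstimator,
    ivw,
    mode_estimate,
    mr_egger,
    run_all_methods,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from mrcausal.exceptions import (
    CollinearDesignError,
    TooFewInstrumentsError,
    ZeroExposureEffectError,
)

from conftest import make_instruments


class TestWaldRatios:
    def test_direct_division(self):
        r = wald_ratios(make_instruments([0.1], [0.05], [0.01]))
        assert r.wald_ratio.iloc[0] == pytest.approx(0.5)
        assert r.wald_se.iloc[0] == pytest.approx(0.1)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroExposureEffectError):
            wald_ratios(make_instruments([0.0], [0.05], [0.01]))

    def test_sign_invariance(self):
        a = wald_ratios(make_instruments([0.1], [0.05], [0.01]))
        b = wald_ratios(make_instruments([-0.1], [-0.05], [0.01]))
        assert a.wald_ratio.iloc[0] == b.wald_ratio.iloc[0]


class TestIVW:
    def test_hand_computed_two_snp_fixture(self, two_snp_instruments):
        est = IVWEstimator().fit(two_snp_instruments)
        assert est.b_ == pytest.approx(0.75)
        assert est.se_fixed_ == pytest.approx(1 / np.sqrt(200), abs=1e-12)
        assert est.q_ == pytest.approx(12.5)
        assert est.se_random_ == pytest.approx(0.25)
        assert est.se_ == est.se_random_  # default multiplicative random effects

    def test_identical_instruments_have_no_heterogeneity(self):
        inst = make_instruments([1.0, 1.0], [0.3, 0.3], [0.1, 0.1])
        est = IVWEstimator().fit(inst)
        assert est.b_ == pytest.approx(0.3)
        assert est.q_ == pytest.approx(0.0, abs=1e-12)
        assert est.se_random_ == est.se_fixed_

    def test_equal_weights_match_unweighted_origin_regression(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, 5)
        by = rng.normal(0.1 * bx, 0.01)
        inst = make_instruments(bx, by, np.full(5, 0.03))
        est = IVWEstimator().fit(inst)
        assert est.b_ == pytest.approx(np.sum(bx * by) / np.sum(bx**2), abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(TooFewInstrumentsError):
            IVWEstimator().fit(make_instruments([0.1], [0.05], [0.01]))

    def test_matches_wls_oracle(self, two_snp_instruments):
        sm = pytest.importorskip("statsmodels.api")
        x = two_snp_instruments.beta_exp.to_numpy()[:, None]
        res = sm.WLS(
            two_snp_instruments.beta_out,
            x,
            weights=1 / two_snp_instruments.se_out**2,
        ).fit()
        est = IVWEstimator().fit(two_snp_instruments)
        assert est.b_ == pytest.approx(np.asarray(res.params)[0], abs=1e-12)
        assert est.se_fixed_ == pytest.approx(
            float(np.sqrt(np.asarray(res.cov_params(scale=1.0))[0, 0])), abs=1e-12
        )


class TestEgger:
    def test_exact_line_recovered(self):
        inst = make_instruments([1.0, 2.0, 3.0], [0.4, 0.7, 1.0], [0.1, 0.1, 0.1])
        est = EggerEstimator().fit(inst)
        assert est.b_ == pytest.approx(0.3, abs=1e-12)
        assert est.intercept_ == pytest.approx(0.1, abs=1e-12)
        assert est.q_ == pytest.approx(0.0, abs=1e-12)
        assert est.exact_fit_

    def test_collinear_design_raises(self):
        inst = make_instruments([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        with pytest.raises(CollinearDesignError):
            EggerEstimator().fit(inst)

    def test_orientation_invariance(self):
        inst = make_instruments([1.0, 2.0, 3.0], [0.4, 0.7, 1.0], [0.1, 0.2, 0.1])
        flipped = make_instruments([1.0, -2.0, 3.0], [0.4, -0.7, 1.0], [0.1, 0.2, 0.1])
        a = EggerEstimator().fit(inst)
        b = EggerEstimator().fit(flipped)
        assert a.b_ == pytest.approx(b.b_, abs=1e-12)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-12)


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        assert weighted_median_point(np.array([1.0, 2.0, 3.0]), np.ones(3)) == pytest.approx(2.0)

    def test_dominant_weight_pins_estimate(self):
        inst = make_instruments([1.0, 1.0, 1.0], [0.2, 0.9, 1.1], [0.005, 1.0, 1.0])
        est = WeightedMedianEstimator(n_boot=0).fit(inst)
        assert est.b_ == pytest.approx(0.2, abs=0.01)

    def test_seed_reproducibility(self):
        inst = make_instruments([1.0, 1.5, 2.0], [0.4, 0.8, 1.1], [0.1, 0.1, 0.1])
        a = WeightedMedianEstimator(n_boot=200, random_state=3).fit(inst)
        b = WeightedMedianEstimator(n_boot=200, random_state=3).fit(inst)
        assert a.se_ == b.se_

    def test_lies_between_extreme_ratios_and_matches_ivw_when_homogeneous(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 7)
        by = rng.normal(0.1 * bx, 0.02)
        inst = make_instruments(bx, by, np.full(7, 0.03))
        wm = WeightedMedianEstimator(n_boot=0).fit(inst)
        ratios = by / bx
        assert ratios.min() <= wm.b_ <= ratios.max()
        same = make_instruments([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
        assert WeightedMedianEstimator(n_boot=0).fit(same).b_ == pytest.approx(
            IVWEstimator().fit(same).b_
        )


class TestModeEstimators:
    def test_cluster_defines_simple_mode(self):
        inst = make_instruments(np.ones(4), [1.0, 1.0, 1.0, 5.0], np.full(4, 0.1))
        est = ModeEstimator(weighted=False, n_boot=0).fit(inst)
        grid_step = (5.0 - 1.0 + 6 * 0.04) / 511  # range + 6h over 512 points
        assert abs(est.b_ - 1.0) <= grid_step

    def test_all_equal_ratios_exact(self):
        inst = make_instruments(np.ones(3), np.full(3, 0.7), np.full(3, 0.1))
        assert ModeEstimator(weighted=False, n_boot=0).fit(inst).b_ == pytest.approx(0.7)

    def test_majority_cluster_defines_weighted_mode(self):
        inst = make_instruments(np.ones(5), [1.0, 1.0, 5.0, 5.0, 5.0], np.full(5, 0.1))
        est = ModeEstimator(weighted=True, n_boot=0).fit(inst)
        grid_step = (5.0 - 1.0 + 6 * 0.04) / 511
        assert abs(est.b_ - 5.0) <= grid_step

    def test_seed_reproducibility(self):
        inst = make_instruments([1.0, 1.5, 2.0], [0.4, 0.8, 1.1], [0.1, 0.1, 0.1])
        a = ModeEstimator(n_boot=100, random_state=5).fit(inst)
        b = ModeEstimator(n_boot=100, random_state=5).fit(inst)
        assert a.se_ == b.se_


class TestOddsRatioTransform:
    @pytest.mark.parametrize(
        "b, expected_or",
        [(0.099, 1.104), (0.082, 1.085), (0.078, 1.081), (0.036, 1.037), (0.015, 1.015)],
    )
    def test_published_log_odds_reproduce_published_ors(self, b, expected_or):
        or_, _, _ = to_odds_ratio(b, 0.02)
        assert round(or_, 3) == expected_or

    def test_null_effect_symmetric_interval(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert np.log(lo) == pytest.approx(-np.log(hi))

    def test_interval_from_unrounded_se(self):
        or_, lo, hi = to_odds_ratio(0.099, 0.019)
        assert lo == pytest.approx(1.0637, abs=5e-5)
        assert hi == pytest.approx(1.1459, abs=5e-4)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, -0.01)


class TestRunAllMethods:
    def test_canonical_labels_and_order(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 5)
        by = rng.normal(0.1 * bx, 0.01)
        inst = make_instruments(bx, by, np.full(5, 0.02))
        results = run_all_methods(inst, n_boot=50, seed=0)
        assert tuple(r.method for r in results) == METHOD_LABELS

    def test_homogeneous_ratios_agree_across_methods(self):
        # every Wald ratio equals 0.5; all five methods must agree there
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        inst = make_instruments(bx, 0.5 * bx, np.full(5, 0.05))
        results = run_all_methods(inst, n_boot=20, seed=0)
        for r in results:
            assert r.b == pytest.approx(0.5, abs=1e-9)

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, 6)
        by = rng.normal(0.1 * bx, 0.01)
        inst = make_instruments(bx, by, np.full(6, 0.02))
        a = run_all_methods(inst, n_boot=100, seed=11)
        b = run_all_methods(inst, n_boot=100, seed=11)
        assert [r.as_row() for r in a] == [r.as_row() for r in b]

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_exposure_rescaling_rescales_slopes(self, c):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.2, 6)
        by = rng.normal(0.1 * bx, 0.01) + 0.002
        base = make_instruments(bx, by, np.full(6, 0.02))
        scaled = make_instruments(c * bx, by, np.full(6, 0.02))
        for est_cls in (IVWEstimator, EggerEstimator):
            b0 = est_cls().fit(base).b_
            b1 = est_cls().fit(scaled).b_
            assert b1 == pytest.approx(b0 / c, rel=1e-9)
        assert EggerEstimator().fit(scaled).intercept_ == pytest.approx(
            EggerEstimator().fit(base).intercept_, rel=1e-9
        )
        for est in (WeightedMedianEstimator(n_boot=0), ModeEstimator(n_boot=0)):
            b0 = est.fit(base).b_
            b1 = est.fit(scaled).b_
            assert b1 == pytest.approx(b0 / c, rel=1e-6)

    @pytest.mark.parametrize(
        "cls, kwargs, minimum",
        [
            (IVWEstimator, {}, 2),
            (EggerEstimator, {}, 3),
            (WeightedMedianEstimator, {"n_boot": 0}, 3),
            (ModeEstimator, {"n_boot": 0}, 3),
        ],
    )
    def test_minimum_instrument_floors(self, cls, kwargs, minimum):
        inst = make_instruments(
            np.full(minimum - 1, 0.1), np.full(minimum - 1, 0.05), np.full(minimum - 1, 0.01)
        )
        with pytest.raises(TooFewInstrumentsError) as exc:
            cls(**kwargs).fit(inst)
        assert exc.value.minimum == minimum

    def test_or_consistency_invariant(self, two_snp_instruments):
        est = ivw(two_snp_instruments)
        assert est.or_ == pytest.approx(np.exp(est.b), abs=1e-12)
        assert est.ci_low < est.or_ < est.ci_high


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self):
        est = WeightedMedianEstimator(n_boot=77, random_state=5)
        params = est.get_params()
        assert params == {"n_boot": 77, "random_state": 5}
        est.set_params(n_boot=10)
        assert est.n_boot == 10

    def test_array_interface_matches_frame_interface(self, two_snp_instruments):
        from_frame = IVWEstimator().fit(two_snp_instruments)
        from_arrays = IVWEstimator().fit(
            two_snp_instruments.beta_exp.to_numpy(),
            y=two_snp_instruments.beta_out.to_numpy(),
            se=two_snp_instruments.se_out.to_numpy(),
        )
        assert from_frame.b_ == from_arrays.b_
        assert from_frame.se_ == from_arrays.se_
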