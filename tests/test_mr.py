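"""Univariable MR estimators against closed forms, planted effects and
algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrpleio as m
from mrpleio.mr import MRError, _weighted_median_point


def _frame(bx, bx_se, by, by_se):
    k = len(bx)
    return pd.DataFrame({"snp": [f"s{i}" for i in range(k)],
                         "bx": bx, "bx_se": bx_se, "by": by, "by_se": by_se})


class TestWaldRatio:
    def test_arithmetic(self):
        est = m.wald_ratio({"bx": 0.1, "by": 0.2, "by_se": 0.05})
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert m.wald_ratio({"bx": 0.1, "by": 0.0, "by_se": 0.05}).beta == 0.0

    def test_zero_exposure_effect_fatal(self):
        with pytest.raises(MRError):
            m.wald_ratio({"bx": 0.0, "by": 0.1, "by_se": 0.05})


class TestIVW:
    def test_consensus_ratio_recovered_exactly(self):
        ivs = _frame([0.1, 0.2, 0.4], [0.01] * 3,
                     [0.05, 0.10, 0.20], [0.01] * 3)
        for weighting in ("first", "second", "modified_second"):
            est = m.ivw(ivs, weighting=weighting, model="fixed")
            assert est.beta == pytest.approx(0.5, abs=1e-12)
            assert est.extra["q"] == pytest.approx(0.0, abs=1e-16)

    def test_two_instrument_closed_form(self):
        ivs = _frame([1.0, 1.0], [0.0, 0.0], [1.0, 3.0], [1.0, 1.0])
        est = m.ivw(ivs, weighting="first", model="fixed")
        assert est.beta == pytest.approx(2.0, abs=1e-14)
        assert est.se == pytest.approx(1 / np.sqrt(2), abs=1e-14)

    def test_matches_weighted_mean_closed_form(self):
        rng = np.random.default_rng(0)
        ivs = _frame(rng.normal(0.1, 0.03, 20), rng.uniform(0.005, 0.02, 20),
                     rng.normal(0.02, 0.02, 20), rng.uniform(0.005, 0.02, 20))
        est = m.ivw(ivs, weighting="first", model="fixed")
        w = ivs.bx**2 / ivs.by_se**2
        ratios = ivs.by / ivs.bx
        assert est.beta == pytest.approx((w * ratios).sum() / w.sum(),
                                         abs=1e-12)

    def test_recovers_simulated_effect(self):
        est = m.ivw(m.simulate_instruments(k=50, theta=0.1, seed=5,
                                           by_se=0.01))
        assert abs(est.beta - 0.1) < 3 * est.se

    def test_single_instrument_fatal(self):
        with pytest.raises(MRError):
            m.ivw(_frame([0.1], [0.01], [0.05], [0.01]))


class TestRadial:
    def test_point_estimate_equals_modified_second_ivw(self):
        for seed in range(5):
            ivs = m.simulate_instruments(k=25, theta=0.05, seed=seed)
            rad = m.ivw_radial(ivs)
            est = m.ivw(ivs, weighting="modified_second")
            assert rad.estimate.beta == pytest.approx(est.beta, abs=1e-8)

    def test_homogeneous_ratios_give_no_outliers(self):
        ivs = _frame([0.1, 0.2, 0.3, 0.4], [1e-6] * 4,
                     [0.05, 0.10, 0.15, 0.20], [0.01] * 4)
        rad = m.ivw_radial(ivs)
        assert rad.outliers == set()
        assert rad.q_total == pytest.approx(0.0, abs=1e-12)

    def test_q_contributions_sum_to_total(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=2, n_pleio=5,
                                     pleio_sd=0.05)
        rad = m.ivw_radial(ivs)
        assert rad.q_contributions["q"].sum() == pytest.approx(rad.q_total,
                                                               abs=1e-8)

    def test_planted_outlier_flagged(self):
        hits = 0
        for s in range(20):
            ivs = m.simulate_instruments(k=50, theta=0.1, seed=900 + s,
                                         by_se=0.01)
            ivs.loc[7, "by"] += 10 * 0.01   # 10 SDs off
            rad = m.ivw_radial(ivs)
            hits += "s8" not in rad.outliers and "iv8" in rad.outliers
        assert hits >= 19

    def test_outliers_invariant_to_input_order(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=4, n_pleio=6,
                                     pleio_sd=0.08)
        shuffled = ivs.sample(frac=1.0, random_state=1)
        assert m.ivw_radial(ivs).outliers == m.ivw_radial(shuffled).outliers


class TestCochranQ:
    def test_identical_ratios(self):
        ivs = _frame([0.1, 0.2], [0.01] * 2, [0.05, 0.10], [0.01] * 2)
        q, df, p = m.cochran_q(ivs)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_two_instrument_hand_computation(self):
        # ratios 1 and 3, first-order weights bx^2/by_se^2 = 1 each,
        # theta = 2 -> Q = 1*(1-2)^2 + 1*(3-2)^2 = 2
        ivs = _frame([1.0, 1.0], [0.0] * 2, [1.0, 3.0], [1.0, 1.0])
        est = m.ivw(ivs, weighting="first", model="fixed")
        q, df, p = m.cochran_q(ivs, est, weighting="first")
        assert q == pytest.approx(2.0, abs=1e-12)

    def test_q_increases_with_pleiotropy(self):
        medians = []
        for sd in (0.0, 0.05, 0.15):
            qs = []
            for s in range(20):
                ivs = m.simulate_instruments(k=30, theta=0.1, seed=600 + s,
                                             n_pleio=15, pleio_sd=sd)
                qs.append(m.cochran_q(ivs)[0])
            medians.append(np.median(qs))
        assert medians[0] < medians[1] < medians[2]


class TestEgger:
    def test_directional_offset_recovered(self):
        delta = 0.05
        ivs = m.simulate_instruments(k=60, theta=0.1, seed=10, by_se=0.01,
                                     bx_spread=0.08,
                                     directional_offset=delta)
        slope, b0, b0_se, b0_p = m.egger(ivs)
        assert abs(b0 - delta) < 3 * b0_se

    def test_clean_intercept_near_zero(self):
        ivs = m.simulate_instruments(k=60, theta=0.1, seed=11, by_se=0.01,
                                     bx_spread=0.08)
        _, b0, b0_se, _ = m.egger(ivs)
        assert abs(b0) < 3 * b0_se

    def test_slope_close_to_ivw_without_pleiotropy(self):
        ivs = m.simulate_instruments(k=80, theta=0.1, seed=12, by_se=0.005,
                                     bx_se=0.002, bx_spread=0.08)
        slope, *_ = m.egger(ivs)
        est = m.ivw(ivs)
        assert abs(slope.beta - est.beta) < 3 * slope.se

    def test_too_few_instruments_fatal(self):
        with pytest.raises(MRError):
            m.egger(_frame([0.1, 0.2], [0.01] * 2, [0.0, 0.1], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        ratios = np.array([1.0, 3.0, 10.0])
        got = _weighted_median_point(ratios, np.ones(3))
        assert got == pytest.approx(3.0)

    def test_hand_fixture_matches_cumulative_scan(self):
        ratios = np.array([1.0, 2.0, 4.0])
        weights = np.array([1.0, 1.0, 2.0])
        # cumulative (w - w/2)/W: 0.125, 0.375, 0.75 -> interpolate between
        # ratio 2 (0.375) and ratio 4 (0.75) at 0.5
        expect = 2.0 + (4.0 - 2.0) * (0.5 - 0.375) / (0.75 - 0.375)
        assert _weighted_median_point(ratios, weights) == pytest.approx(expect)

    def test_breakdown_under_minority_contamination(self):
        # 40% of instruments strongly invalid: median still near truth
        ok = 0
        for s in range(10):
            ivs = m.simulate_instruments(k=30, theta=0.1, seed=700 + s,
                                         by_se=0.005, n_pleio=12,
                                         pleio_sd=0.08)
            est = m.weighted_median(ivs, n_boot=300, seed=s)
            ok += abs(est.beta - 0.1) < 3 * est.se
        assert ok >= 9


class TestWeightedMode:
    def test_unanimous_ratios(self):
        ivs = _frame([0.1, 0.2, 0.4], [0.01] * 3,
                     [0.05, 0.10, 0.20], [0.01] * 3)
        est = m.weighted_mode(ivs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_mode_wins_bimodal(self):
        # 70% of weight at ratio 0.5, 30% at ratio 2.0
        bx = np.ones(10) * 0.2
        by = np.where(np.arange(10) < 7, 0.1, 0.4)
        rng = np.random.default_rng(0)
        by = by + rng.normal(0, 0.002, 10)
        est = m.weighted_mode(_frame(bx, [0.001] * 10, by, [0.01] * 10),
                              n_boot=50, seed=0)
        assert abs(est.beta - 0.5) < 0.1

    def test_large_bandwidth_approaches_weighted_mean(self):
        ivs = m.simulate_instruments(k=40, theta=0.1, seed=3)
        est = m.weighted_mode(ivs, bandwidth_phi=200.0, n_boot=50, seed=0)
        w = ivs.bx**2 / ivs.by_se**2
        wmean = float((w * ivs.by / ivs.bx).sum() / w.sum())
        assert est.beta == pytest.approx(wmean, abs=0.02)


class TestRAPS:
    def test_identity_psi_reduces_to_ivw(self):
        ivs = m.simulate_instruments(k=40, theta=0.1, seed=2, bx_se=1e-14,
                                     by_se=0.02)
        r = m.raps(ivs, k_tuning=1e6, overdispersion=False)
        e = m.ivw(ivs, weighting="first", model="fixed")
        assert r.beta == pytest.approx(e.beta, abs=1e-6)

    def test_overdispersion_detected(self):
        ivs = m.simulate_instruments(k=60, theta=0.1, seed=14, by_se=0.005,
                                     n_pleio=60, pleio_sd=0.01)
        r = m.raps(ivs, overdispersion=True)
        assert r.extra["tau2"] > 0

    def test_coverage_under_overdispersion(self):
        hits = 0
        reps = 60
        for s in range(reps):
            ivs = m.simulate_instruments(k=40, theta=0.1, seed=2000 + s,
                                         by_se=0.01, n_pleio=40,
                                         pleio_sd=0.008)
            r = m.raps(ivs)
            hits += abs(r.beta - 0.1) < 1.96 * r.se
        assert hits / reps >= 0.90


class TestPresso:
    def test_no_outliers_means_corrected_equals_raw(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=21, by_se=0.01)
        res = m.mr_presso(ivs, n_sim=500, seed=0)
        assert res.outliers == set()
        assert res.corrected.beta == res.raw.beta
        assert np.isnan(res.distortion_p)

    def test_planted_outlier_flagged_and_corrected(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=22, by_se=0.01)
        ivs.loc[4, "by"] += 10 * 0.01
        res = m.mr_presso(ivs, n_sim=1000, seed=1)
        assert res.global_p < 0.05
        assert "iv5" in res.outliers
        assert res.corrected.beta != res.raw.beta

    def test_refuses_tiny_simulation_count(self):
        ivs = m.simulate_instruments(k=10, theta=0.0, seed=0)
        with pytest.raises(MRError, match="n_sim"):
            m.mr_presso(ivs, n_sim=50, seed=0)


class TestSteiger:
    def test_direction_from_explained_variance(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=30)
        res = m.steiger_test(ivs)
        assert res.direction_correct
        assert 0 <= res.r2_outcome < res.r2_exposure <= 1

    def test_antisymmetric_under_swap(self):
        ivs = m.simulate_instruments(k=30, theta=0.1, seed=31)
        swapped = ivs.rename(columns={"bx": "by", "by": "bx",
                                      "bx_se": "by_se", "by_se": "bx_se",
                                      "nx": "ny", "ny": "nx"})
        res = m.steiger_test(ivs)
        res_swap = m.steiger_test(swapped)
        assert res.direction_correct and not res_swap.direction_correct
        assert res.steiger_p == pytest.approx(res_swap.steiger_p, rel=1e-10)


class TestLeaveOneOutAndFunnel:
    def test_homogeneous_rows_equal_full_estimate(self):
        ivs = _frame([0.1, 0.2, 0.3, 0.4], [1e-8] * 4,
                     [0.05, 0.10, 0.15, 0.20], [0.01] * 4)
        table = m.leave_one_out(ivs)
        assert len(table) == 4
        full = m.ivw(ivs).beta
        assert np.allclose(table["beta"], full, atol=1e-10)
        assert not table["flagged"].any()

    def test_dominant_instrument_flagged(self):
        ivs = m.simulate_instruments(k=20, theta=0.0, seed=40, by_se=0.02)
        # one hugely precise instrument with a deviating ratio drives the fit
        ivs.loc[0, ["bx", "by", "by_se"]] = [0.5, 0.25, 0.001]
        table = m.leave_one_out(ivs)
        assert table.loc[table["excluded_snp"] == "iv1", "flagged"].item()

    def test_funnel_symmetry_and_shape(self):
        theta = 0.2
        bx = np.array([0.1, 0.1, 0.2, 0.2, 0.3, 0.3])
        dev = np.array([0.05, -0.05, 0.02, -0.02, 0.0, 0.0])
        by = theta * bx + dev * bx
        ivs = _frame(bx, [1e-9] * 6, by, [0.01] * 6)
        df, asym_p = m.funnel_data(ivs)
        assert len(df) == 6
        ratios = df["ratio"].to_numpy()
        assert np.allclose(np.sort(ratios - theta), np.sort(theta - ratios))


class TestEquivariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.2, max_value=5.0),
           seed=st.integers(min_value=0, max_value=50))
    def test_outcome_scale_equivariance(self, c, seed):
        ivs = m.simulate_instruments(k=15, theta=0.1, seed=seed)
        scaled = ivs.assign(by=ivs.by * c, by_se=ivs.by_se * c)
        for fit in (lambda d: m.ivw(d).beta,
                    lambda d: m.egger(d)[0].beta,
                    lambda d: m.weighted_median(d, n_boot=10, seed=0).beta,
                    lambda d: m.raps(d).beta):
            assert fit(scaled) == pytest.approx(c * fit(ivs), rel=1e-6,
                                                abs=1e-7)
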