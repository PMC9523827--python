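"""Spending functions, boundary recursion, monitoring and repeated CIs."""

import numpy as np
import pytest
from scipy import optimize, stats

import gsrank as g
from gsrank.errors import InvalidInputError, MonotonicityError
from gsrank.rank_core import EffectEstimate
from gsrank.sequential_design import canonical_probabilities

ALPHA = 0.025

# frozen oracle values (scipy bivariate normal CDF + root solve, corr sqrt(1/2))
POCOCK_F_HALF = 0.015502862673956938
OF_F_HALF = 0.0015253227579889112
POCOCK_C = (2.156999218344682, 2.20097696715763)
OF_C = (2.9625880427275666, 1.9685956406374348)


class TestSpendingValue:
    @pytest.mark.parametrize("kind", ["pocock", "obrien_fleming"])
    def test_boundary_conditions(self, kind):
        assert g.spending_value(kind, ALPHA, 0.0) == 0.0
        assert g.spending_value(kind, ALPHA, 1.0) == pytest.approx(ALPHA)
        assert g.spending_value(kind, ALPHA, 3.7) == pytest.approx(ALPHA)

    def test_pocock_half(self):
        assert g.spending_value("pocock", ALPHA, 0.5) == pytest.approx(POCOCK_F_HALF)

    def test_obrien_fleming_half(self):
        assert g.spending_value("obrien_fleming", ALPHA, 0.5) == pytest.approx(OF_F_HALF)

    @pytest.mark.parametrize("kind", ["pocock", "obrien_fleming"])
    def test_nondecreasing(self, kind):
        grid = np.linspace(0, 1.2, 200)
        vals = g.spending_value(kind, ALPHA, grid)
        assert np.all(np.diff(vals) >= -1e-15)

    def test_negative_fraction_raises(self):
        with pytest.raises(InvalidInputError):
            g.spending_value("pocock", ALPHA, -0.1)


class TestSpendIncrements:
    def design(self, K, spending="pocock"):
        return g.SequentialDesign(K=K, alpha=ALPHA, spending=spending, Imax=1.0)

    def test_single_stage_spends_everything(self):
        assert g.spend_increments(self.design(1), [0.8]) == pytest.approx([ALPHA])

    def test_two_stage_pocock(self):
        pi = g.spend_increments(self.design(2), [0.5, 1.0])
        assert pi == pytest.approx([POCOCK_F_HALF, ALPHA - POCOCK_F_HALF])
        assert pi.sum() == pytest.approx(ALPHA)

    def test_final_stage_spends_remainder_even_below_imax(self):
        pi = g.spend_increments(self.design(2), [0.5, 0.8])
        assert pi[1] == pytest.approx(ALPHA - POCOCK_F_HALF)

    def test_nonincreasing_information_raises(self):
        with pytest.raises(MonotonicityError):
            g.spend_increments(self.design(2), [0.5, 0.5])


class TestBoundaries:
    def test_single_stage_is_normal_quantile(self):
        bs = g.boundaries(g.SequentialDesign(K=1, Imax=1.0), [1.0])
        assert bs.crit_values[0] == pytest.approx(1.9599639845400545, abs=1e-6)

    @pytest.mark.parametrize(
        "spending,expected", [("pocock", POCOCK_C), ("obrien_fleming", OF_C)]
    )
    def test_two_stage_equal_information_vs_mvn_oracle(self, spending, expected):
        bs = g.boundaries(
            g.SequentialDesign(K=2, spending=spending, Imax=1.0), [0.5, 1.0]
        )
        assert bs.crit_values == pytest.approx(expected, abs=2e-6)

    def test_obrien_fleming_boundaries_decrease(self):
        bs = g.boundaries(
            g.SequentialDesign(K=3, spending="obrien_fleming", Imax=1.0), [1 / 3, 2 / 3, 1.0]
        )
        assert bs.crit_values[0] > bs.crit_values[1] > bs.crit_values[2]

    def test_total_crossing_probability_is_alpha(self):
        for K, spending in [(2, "pocock"), (4, "obrien_fleming")]:
            taus = np.arange(1, K + 1) / K
            bs = g.boundaries(g.SequentialDesign(K=K, spending=spending, Imax=1.0), taus)
            exit_probs, _ = canonical_probabilities(taus, bs.crit_values)
            assert exit_probs.sum() == pytest.approx(ALPHA, abs=1e-6)

    def test_pocock_levels_near_constant_of_levels_escalating(self):
        taus = [0.25, 0.5, 0.75, 1.0]
        po = g.boundaries(g.SequentialDesign(K=4, spending="pocock", Imax=1.0), taus)
        of = g.boundaries(g.SequentialDesign(K=4, spending="obrien_fleming", Imax=1.0), taus)
        assert po.stage_levels.max() / po.stage_levels.min() < 3
        assert of.stage_levels[0] < of.stage_levels[-1] / 10

    def test_correlation_matrix(self):
        bs = g.boundaries(g.SequentialDesign(K=2, Imax=1.0), [0.5, 1.0])
        assert bs.correlation[0, 1] == pytest.approx(np.sqrt(0.5))


class TestCanonicalProbabilities:
    def test_single_stage_tail(self):
        ex, non = canonical_probabilities([1.0], [1.6448536269514722])
        assert ex[0] == pytest.approx(0.05, abs=1e-9)
        assert non == pytest.approx(0.95, abs=1e-9)

    def test_matches_scipy_mvn(self):
        taus = np.array([0.4, 0.7, 1.0])
        u = np.array([2.2, 2.0, 1.9])
        corr = np.sqrt(np.minimum.outer(taus, taus) / np.maximum.outer(taus, taus))
        oracle = stats.multivariate_normal(mean=np.zeros(3), cov=corr).cdf(u)
        _, non = canonical_probabilities(taus, u)
        # scipy's MVN CDF is itself quasi-Monte-Carlo with ~1e-5 accuracy
        assert non == pytest.approx(oracle, abs=2e-5)

    def test_infinite_limit_cannot_exit(self):
        ex, _ = canonical_probabilities([0.5, 1.0], [np.inf, 1.96])
        assert ex[0] == 0.0
        assert ex[1] > 0


class TestRepeatedPValue:
    def test_values(self):
        assert g.repeated_p_value(0.0) == pytest.approx(0.5)
        assert g.repeated_p_value(1.9599639845400545) == pytest.approx(0.025)
        assert g.repeated_p_value(2.0, df=18) == pytest.approx(0.030410732834666217)

    def test_t_variant_exceeds_normal_for_positive_z(self):
        for z in (0.5, 1.5, 2.5):
            assert g.repeated_p_value(z, df=10) > g.repeated_p_value(z)


def staged_data(x1_stage1, x2_stage1, x1_stage2, x2_stage2):
    v1 = np.concatenate([x1_stage1, x1_stage2])
    v2 = np.concatenate([x2_stage1, x2_stage2])
    s1 = np.r_[np.ones(len(x1_stage1), int), np.full(len(x1_stage2), 2)]
    s2 = np.r_[np.ones(len(x2_stage1), int), np.full(len(x2_stage2), 2)]
    return g.TwoArmStageData(v1, v2, s1, s2, K=2)


class TestMonitor:
    def test_null_like_data_never_rejects(self, rng):
        x = rng.normal(size=40)
        data = staged_data(x[:10], x[10:20], x[20:30], x[30:])
        imax = g.true_information(g.normal_model(0, 1, 0, 1), "bm", 20, 20)
        res = g.monitor(data, g.SequentialDesign(K=2, Imax=imax), "bm")
        assert len(res) == 2
        assert not any(d.reject for d in res)
        assert all(d.p_value > d.stage_level for d in res)

    def test_strong_separation_stops_at_first_stage(self):
        data = staged_data(np.arange(10), np.arange(10) + 100, np.arange(5), np.arange(5) + 100)
        imax = g.true_information(g.normal_model(0, 1, 3, 1), "wmw", 15, 15)
        res = g.monitor(data, g.SequentialDesign(K=2, spending="pocock", Imax=imax), "wmw")
        assert len(res) == 1
        assert res[0].reject

    def test_information_frozen_and_fractions_increase(self, rng):
        x1 = rng.normal(0, 1, 60)
        x2 = rng.normal(0.3, 1, 60)
        data = staged_data(x1[:30], x2[:30], x1[30:], x2[30:])
        imax = g.true_information(g.normal_model(0, 1, 0.3, 1), "bm", 60, 60)
        res = g.monitor(data, g.SequentialDesign(K=2, Imax=imax), "bm")
        fracs = [d.info_fraction for d in res]
        assert fracs == sorted(fracs)

    def test_reject_iff_p_below_stage_level(self, ordinal_model, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x1 = g.sample(ordinal_model, 1, 80, r)
            x2 = g.sample(ordinal_model, 2, 80, r)
            data = staged_data(x1[:40], x2[:40], x1[40:], x2[40:])
            imax = g.true_information(ordinal_model, "lwo", 80, 80)
            res = g.monitor(data, g.SequentialDesign(K=2, spending="pocock", Imax=imax), "lwo")
            for d in res:
                assert d.reject == (d.p_value <= d.stage_level)

    def test_wmw_has_no_ci(self, rng):
        x = rng.normal(size=20)
        data = staged_data(x[:5], x[5:10], x[10:15], x[15:])
        res = g.monitor(data, g.SequentialDesign(K=2, Imax=100.0), "wmw")
        assert all(d.ci_lo is None for d in res)

    def test_unknown_method_raises(self, rng):
        data = staged_data([1, 2], [3, 4], [5], [6])
        with pytest.raises(InvalidInputError):
            g.monitor(data, g.SequentialDesign(K=2, Imax=10.0), "wilcoxon")


def _estimate(p_hat=0.558, info_bm=400.0, df=18.0):
    info_lwo = (p_hat * (1 - p_hat)) ** 2 * info_bm
    psi = np.log(p_hat / (1 - p_hat))
    return EffectEstimate(
        stage=1, n1=10, n2=10, p_hat=p_hat, psi_hat=psi, sigmaR2_hat=1.0,
        sigma1sq_hat=0.1, sigma2sq_hat=0.1, info_wmw=300.0, info_bm=info_bm,
        info_lwo=info_lwo, df_hat=df, z_wmw=0.0, z_bm=0.0, z_lwo=0.0,
    )


class TestRepeatedCI:
    def test_bm_arithmetic(self):
        lo, hi = g.repeated_ci(_estimate(), 1.96, "bm")
        assert (lo, hi) == pytest.approx((0.460, 0.656))

    def test_t_variant_is_wider(self):
        lo_n, hi_n = g.repeated_ci(_estimate(), 2.0, "bm")
        lo_t, hi_t = g.repeated_ci(_estimate(), 2.0, "bm_t")
        assert lo_t < lo_n and hi_t > hi_n

    def test_lwo_symmetric_about_half(self):
        lo, hi = g.repeated_ci(_estimate(p_hat=0.5), 2.0, "lwo")
        assert lo + hi == pytest.approx(1.0)
        assert 0 < lo < hi < 1

    def test_lwo_always_inside_unit_interval(self):
        lo, hi = g.repeated_ci(_estimate(p_hat=0.9, info_bm=100.0), 2.5, "lwo")
        assert 0 < lo < hi < 1
        # bm interval at the same point would be truncated at 1
        _, hi_bm = g.repeated_ci(_estimate(p_hat=0.9, info_bm=100.0), 2.5, "bm")
        assert hi_bm == 1.0

    def test_truncation_to_unit_interval(self):
        lo, hi = g.repeated_ci(_estimate(p_hat=0.97, info_bm=50.0), 3.0, "bm")
        assert hi == 1.0

    def test_contains_point_estimate(self):
        est = _estimate(p_hat=0.62)
        for method in ("bm", "bm_t", "lwo"):
            lo, hi = g.repeated_ci(est, 2.1, method)
            assert lo <= est.p_hat <= hi
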