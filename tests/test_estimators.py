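import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from mrkit.estimators import (
    egger,
    ivw,
    mode_estimate,
    mvmr_ivw,
    wald_ratio,
    weighted_median,
)
from mrkit.exceptions import (
    CollinearityError,
    MethodMinimumError,
    UndefinedRatioError,
)
from mrkit.harmonize import HarmonizedSet
from mrkit.synth import SynthConfig, simulate_pair
from mrkit.harmonize import harmonize


def _meta_of_wald_ratios(bx, by, sy):
    """Independent oracle: inverse-variance meta-analysis of per-SNP Wald
    ratios with weights bx^2/sy^2."""
    theta = np.asarray(by) / np.asarray(bx)
    w = np.asarray(bx) ** 2 / np.asarray(sy) ** 2
    est = np.sum(w * theta) / np.sum(w)
    se = np.sqrt(1.0 / np.sum(w))
    return est, se


class TestWaldRatio:
    def test_direct_formula(self):
        r = wald_ratio(0.5, 0.01, 0.25, 0.1)
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        r = wald_ratio(0.5, 0.01, 0.0, 0.1)
        assert r.beta == 0.0
        assert r.pval == 1.0

    def test_negative_ratio(self):
        r = wald_ratio(0.6, 0.01, -0.3, 0.06)
        assert r.beta == pytest.approx(-0.5)
        assert r.se == pytest.approx(0.1)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.1)


class TestIVW:
    def test_three_snp_worked_example(self, three_snp_h):
        est, _ = _meta_of_wald_ratios(three_snp_h.bx, three_snp_h.by, three_snp_h.sy)
        r = ivw(three_snp_h)
        assert r.beta == pytest.approx(0.4921, abs=5e-4)
        assert r.beta == pytest.approx(est, rel=1e-12)

    def test_identical_ratios_floor_binds(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], 0.01,
                                      [0.05, 0.10, 0.20], [0.02, 0.02, 0.02])
        r = ivw(h)
        assert r.beta == pytest.approx(0.5, rel=1e-12)
        assert r.extra["Q"] == pytest.approx(0.0, abs=1e-20)
        assert r.se == pytest.approx(r.extra["se_fixed"], rel=1e-12)

    def test_matches_statsmodels_wls_through_origin(self, three_snp_h):
        """Cross-check: the closed-form IVW slope equals a WLS regression of
        by on bx through the origin with weights 1/sy^2."""
        h = three_snp_h
        fit = sm.WLS(h.by, h.bx[:, None], weights=1.0 / h.sy**2).fit()
        assert ivw(h).beta == pytest.approx(float(fit.params[0]), rel=1e-12)

    def test_sign_flip_invariance(self, three_snp_h):
        h = three_snp_h
        flip = np.array([1, -1, 1.0])
        h2 = HarmonizedSet.from_arrays(h.bx * flip, h.sx, h.by * flip, h.sy)
        assert ivw(h2).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert ivw(h2).se == pytest.approx(ivw(h).se, rel=1e-12)

    def test_method_minimum(self):
        h = HarmonizedSet.from_arrays([0.1], 0.01, [0.05], [0.02])
        with pytest.raises(MethodMinimumError, match="wald"):
            ivw(h)

    def test_single_ratio_meta_equals_wald(self):
        """Meta-analysis identity at J=1: the IVW formula reduces to the
        Wald ratio."""
        est, se = _meta_of_wald_ratios([0.1], [0.05], [0.02])
        r = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est == pytest.approx(r.beta, rel=1e-12)
        assert se == pytest.approx(r.se, rel=1e-12)


class TestEgger:
    def test_exact_line_with_intercept(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.03 + 0.4 * bx
        h = HarmonizedSet.from_arrays(bx, 0.01, by, np.full(8, 0.02))
        r = egger(h)
        assert r.beta == pytest.approx(0.4, abs=1e-12)
        assert r.extra["egger_intercept"] == pytest.approx(0.03, abs=1e-12)

    def test_origin_line_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0.01, 0.5 * bx, np.full(4, 0.02))
        r = egger(h)
        assert r.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(2)
        bx = rng.normal(0.1, 0.1, 12)
        by = 0.02 - 0.5 * bx + rng.normal(0, 0.02, 12)
        h1 = HarmonizedSet.from_arrays(bx, 0.01, by, np.full(12, 0.02))
        flip = rng.choice([-1.0, 1.0], 12)
        h2 = HarmonizedSet.from_arrays(bx * flip, 0.01, by * flip, np.full(12, 0.02))
        assert egger(h2).beta == pytest.approx(egger(h1).beta, rel=1e-12)

    def test_method_minimum(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], 0.01, [0.05, 0.1], [0.02, 0.02])
        with pytest.raises(MethodMinimumError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = HarmonizedSet.from_arrays([1.0, 1.0, 1.0], 0.01,
                                      [0.4, 0.5, 0.6], [0.1, 0.1, 0.1])
        assert weighted_median(h, n_boot=100, seed=0).beta == pytest.approx(0.5)

    def test_interpolation_hand_oracle(self):
        """Ratios {0, 10, 10, 10, 10} with 90% of the weight on the first:
        sorted s = (0.45, 0.9125, ...), so the interpolated estimate is
        0 + 10*(0.5-0.45)/(0.9125-0.45) = 1.0810811."""
        bx = np.array([3.0, 0.5, 0.5, 0.5, 0.5])
        by = np.array([0.0, 5.0, 5.0, 5.0, 5.0])
        sy = np.ones(5)  # weights bx^2: 9, .25 x4 -> normalized .9, .025 x4
        h = HarmonizedSet.from_arrays(bx, 0.01, by, sy)
        r = weighted_median(h, n_boot=100, seed=3)
        assert r.beta == pytest.approx(10 * 0.05 / 0.4625, rel=1e-9)
        r2 = weighted_median(h, n_boot=100, seed=3)
        assert r2.beta == r.beta and r2.se == r.se  # seed-reproducible

    def test_bootstrap_se_converges(self, three_snp_h):
        se1 = weighted_median(three_snp_h, n_boot=1000, seed=5).se
        se2 = weighted_median(three_snp_h, n_boot=10000, seed=5).se
        assert abs(se1 - se2) / se2 < 0.10


class TestModes:
    def test_majority_cluster_wins(self):
        h = HarmonizedSet.from_arrays([1, 1, 1, 1.0], 0.01,
                                      [0.5, 0.5, 0.5, 5.0], np.ones(4))
        r = mode_estimate(h, weighted=False, n_boot=100, seed=0)
        assert r.beta == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_identical_ratios(self):
        h = HarmonizedSet.from_arrays([1, 1, 1.0], 0.01, [0.3, 0.3, 0.3], np.ones(3))
        r = mode_estimate(h, weighted=True, n_boot=100, seed=0)
        assert r.beta == pytest.approx(0.3)
        assert r.se > 0

    def test_weighted_mode_recovers_truth_under_pleiotropy(self):
        """30% directional-pleiotropy invalid instruments: the mode tracks
        the valid majority cluster."""
        cfg = SynthConfig(n_snps=50, theta=-0.5, gamma_mean=0.15, gamma_sd=0.06,
                          se_x=0.005, se_y=0.02, pleiotropy_frac=0.3,
                          pleiotropy_mean=0.2, pleiotropy_sd=0.02, seed=11)
        e, o, _ = simulate_pair(cfg)
        h = harmonize(e, o)
        r = mode_estimate(h, weighted=True, n_boot=200, seed=11)
        assert abs(r.beta - (-0.5)) < 0.1

    def test_bootstrap_bitwise_reproducible(self, three_snp_h):
        a = mode_estimate(three_snp_h, weighted=True, n_boot=500, seed=7)
        b = mode_estimate(three_snp_h, weighted=True, n_boot=500, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestMVMR:
    def test_exact_two_exposure_solve(self):
        rng = np.random.default_rng(3)
        bx1 = rng.uniform(0.05, 0.3, 10)
        bx2 = rng.uniform(-0.2, 0.2, 10)
        by = 0.3 * bx1 - 0.2 * bx2
        res = mvmr_ivw(np.column_stack([bx1, bx2]), by, np.full(10, 0.02))
        assert res[0].beta == pytest.approx(0.3, abs=1e-12)
        assert res[1].beta == pytest.approx(-0.2, abs=1e-12)

    def test_k1_reduces_to_ivw(self, three_snp_h):
        h = three_snp_h
        res = mvmr_ivw(h.bx[:, None], h.by, h.sy)[0]
        r = ivw(h)
        assert res.beta == pytest.approx(r.beta, rel=1e-14)
        # k=1 leaves J-1 residual df, so even the sigma-hat floor coincides;
        # only the p-value reference (t vs normal) differs
        assert res.se == pytest.approx(r.se, rel=1e-12)

    def test_collinearity_error_names_columns(self):
        bx1 = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.raises(CollinearityError, match="mediator"):
            mvmr_ivw(np.column_stack([bx1, 2 * bx1]), bx1, np.full(5, 0.02),
                     exposure_ids=["taxon", "mediator"])

    def test_method_minimum(self):
        with pytest.raises(MethodMinimumError):
            mvmr_ivw(np.ones((3, 2)), np.ones(3), np.ones(3))


@given(st.integers(0, 10_000))
def test_ivw_equals_meta_analysis_oracle(seed):
    """Property: fixed-effect IVW == inverse-variance meta-analysis of Wald
    ratios, on random instances."""
    rng = np.random.default_rng(seed)
    J = rng.integers(2, 31)
    bx = rng.normal(0.1, 0.05, J)
    bx[np.abs(bx) < 1e-3] = 0.05
    by = rng.normal(-0.05, 0.1, J)
    sy = rng.uniform(0.01, 0.2, J)
    h = HarmonizedSet.from_arrays(bx, 0.01, by, sy)
    est, se = _meta_of_wald_ratios(bx, by, sy)
    r = ivw(h, re_mode="fixed")
    assert r.beta == pytest.approx(est, rel=1e-12, abs=1e-12)
    assert r.se == pytest.approx(se, rel=1e-12)
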