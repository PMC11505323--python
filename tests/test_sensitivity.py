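import numpy as np
import pytest

from mrkit.estimators import egger, ivw
from mrkit.exceptions import MethodMinimumError
from mrkit.harmonize import HarmonizedSet, harmonize
from mrkit.sensitivity import (
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    plot_data,
)
from mrkit.synth import SynthConfig, simulate_pair


def _null_h(seed, J=20, theta=-0.5, se_y=0.05, **kw):
    e, o, _ = simulate_pair(SynthConfig(n_snps=J, theta=theta, se_y=se_y,
                                        seed=seed, **kw))
    return harmonize(e, o)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], 0.01,
                                      [0.05, 0.1, 0.2], [0.02] * 3)
        res = cochran_q(h)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)
        assert res.df == 2

    def test_hand_summation_oracle(self, three_snp_h):
        """Q computed by direct summation over Wald ratios."""
        h = three_snp_h
        theta_j = h.by / h.bx
        w = h.bx**2 / h.sy**2
        pooled = np.sum(w * theta_j) / np.sum(w)
        q_hand = float(np.sum(w * (theta_j - pooled) ** 2))
        res = cochran_q(h)
        assert res.Q == pytest.approx(q_hand, rel=1e-12)
        assert res.df == 2

    def test_sigma_hat_decomposition(self):
        """The multiplicative-scale relation sigma^2 = Q/(J-1) holds."""
        h = _null_h(21)
        r = ivw(h)
        q = cochran_q(h)
        assert r.extra["sigma_hat"] ** 2 == pytest.approx(q.Q / q.df, rel=1e-12)

    def test_egger_basis_df(self):
        h = _null_h(22, J=10)
        res = cochran_q(h, basis="egger")
        assert res.df == 8
        assert res.Q >= 0

    def test_method_minimum(self):
        h = HarmonizedSet.from_arrays([0.1], 0.01, [0.05], [0.02])
        with pytest.raises(MethodMinimumError):
            cochran_q(h)


class TestEggerIntercept:
    def test_origin_line_null(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0.01, 0.5 * bx, [0.02] * 4)
        res = egger_intercept_test(h)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.pval == pytest.approx(1.0)

    def test_exact_offset_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = HarmonizedSet.from_arrays(bx, 0.01, 0.03 + 0.4 * bx, [1e-4] * 4)
        res = egger_intercept_test(h)
        assert res.intercept == pytest.approx(0.03, abs=1e-12)
        # noise-free fit: the max(1, sigma-hat) floor keeps the SE at the
        # fixed-effect level (not zero); the offset is still detected
        assert res.se > 0
        assert res.pval < 1e-3  # t(2) reference: heavy tails even at t ~ 245

    def test_matches_egger_fit(self):
        h = _null_h(23, J=12)
        r = egger(h)
        res = egger_intercept_test(h)
        assert res.intercept == r.extra["egger_intercept"]
        assert res.pval == r.extra["egger_intercept_p"]


class TestPresso:
    def test_null_data_clean(self):
        """No-pleiotropy data: global test quiet, no outliers flagged."""
        h = _null_h(3)
        res = mr_presso(h, n_sim=1000, seed=3)
        assert res.global_p > 0.05
        assert res.outliers == []
        assert res.corrected_estimate is None
        assert res.distortion_p is None

    def test_seed_determinism(self):
        h = _null_h(4)
        a = mr_presso(h, n_sim=500, seed=9)
        b = mr_presso(h, n_sim=500, seed=9)
        assert a.global_p == b.global_p
        assert (a.outlier_pvals == b.outlier_pvals).all()

    def test_injected_outlier_flagged_and_corrected(self):
        """A +10*sy shift on one SNP is flagged; removing it moves the
        estimate back toward truth."""
        cfg = SynthConfig(n_snps=20, theta=-0.5, se_y=0.05,
                          outlier_idx=(7,), outlier_shift=0.5, seed=3)
        e, o, _ = simulate_pair(cfg)
        h = harmonize(e, o)
        res = mr_presso(h, n_sim=1000, seed=3)
        assert "rs8" in res.outliers
        assert res.corrected_estimate is not None
        assert abs(res.corrected_estimate.beta - (-0.5)) < abs(
            res.raw_estimate.beta - (-0.5)
        )
        assert res.distortion_p is not None

    def test_method_minimum_and_nsim_floor(self):
        h = HarmonizedSet.from_arrays([0.1] * 3, 0.01, [0.05] * 3, [0.02] * 3)
        with pytest.raises(MethodMinimumError):
            mr_presso(h)
        with pytest.raises(ValueError):
            mr_presso(_null_h(5), n_sim=50)

    def test_low_resolution_warns(self):
        h = _null_h(6, J=20)
        with pytest.warns(UserWarning, match="resolve"):
            mr_presso(h, n_sim=100, outlier_sig=0.05, seed=0)


class TestLeaveOneOut:
    def test_identical_ratios_all_rows_equal(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.4], 0.01,
                                      [0.05, 0.1, 0.2], [0.02] * 3)
        rows = leave_one_out(h)
        betas = {r.estimate.beta for r in rows}
        assert len(rows) == 4  # 3 omissions + the all-SNP row
        assert rows[-1].omitted_snp is None
        assert max(betas) - min(betas) < 1e-12

    def test_row_count_matches_instruments(self):
        h = _null_h(7, J=15)
        rows = leave_one_out(h)
        assert sum(r.omitted_snp is not None for r in rows) == 15

    def test_outlier_omission_departs_most(self):
        cfg = SynthConfig(n_snps=20, theta=-0.5, se_y=0.05,
                          outlier_idx=(4,), outlier_shift=0.5, seed=8)
        e, o, _ = simulate_pair(cfg)
        h = harmonize(e, o)
        rows = leave_one_out(h)
        full = rows[-1].estimate.beta
        departures = {
            r.omitted_snp: abs(r.estimate.beta - full)
            for r in rows if r.omitted_snp
        }
        assert max(departures, key=departures.get) == "rs5"


class TestPlotData:
    def test_shapes_and_slope_columns(self):
        h = _null_h(9, J=12)
        results = [ivw(h), egger(h)]
        scatter, funnel = plot_data(h, results)
        assert len(scatter) == len(funnel) == 12
        slopes = [c for c in scatter.columns if c.startswith("slope_")]
        assert len(slopes) == len(results)
        assert "intercept_egger" in scatter.columns

    def test_funnel_symmetry_under_null(self):
        """Funnel points scatter symmetrically about the pooled estimate."""
        h = _null_h(10, J=400, se_y=0.05)
        _, funnel = plot_data(h, [])
        pooled = ivw(h, re_mode="fixed").beta
        signs = np.sign(funnel["wald_ratio"] - pooled)
        imbalance = abs(signs.sum())
        assert imbalance < 3 * np.sqrt(len(funnel))  # binomial noise bound
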