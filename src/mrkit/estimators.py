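"""Causal-effect estimators for two-sample MR.

Given J harmonized instruments with SNP-exposure effects ``bx_j`` (SE
``sx_j``) and SNP-outcome effects ``by_j`` (SE ``sy_j``):

* **Wald ratio** — single-SNP estimate ``by/bx`` with first-order SE
  ``|sy/bx|``.
* **IVW** — weighted regression of by on bx through the origin with
  weights ``1/sy²``; identical to the inverse-variance meta-analysis of
  the per-SNP Wald ratios.  Default inference is multiplicative
  random-effects with the scale floored at 1, so the SE never undercuts
  the fixed-effect SE; ``re_mode="fixed"`` gives the plain fixed-effect
  z-test.
* **MR-Egger** — the same regression with an intercept; the slope is a
  pleiotropy-adjusted causal estimate and the intercept the average
  directional pleiotropy.  Inference from t(J-2) with the max(1, σ̂)
  scale floor; rows are oriented so bx >= 0 before fitting.
* **Weighted median** — consistent when instruments carrying at least
  half the weight are valid; SE from a parametric bootstrap.
* **Mode-based estimators** (simple and weighted) — kernel-density mode
  of the Wald-ratio distribution, bandwidth from a modified Silverman
  rule scaled by ``phi``; consistent when the largest cluster of
  instruments is valid; SE from a parametric bootstrap.
* **Multivariable IVW** — weighted regression of by on several exposures'
  betas jointly (no intercept), giving each exposure's direct effect.

Binary-outcome betas are log-odds throughout; odds ratios and their
``exp(beta ± 1.96 se)`` CIs are carried on every result for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError, MethodMinimumError, UndefinedRatioError
from .harmonize import HarmonizedSet

Z95 = float(sps.norm.ppf(0.975))

METHOD_LABELS = {
    "wald": "Wald ratio",
    "ivw": "Inverse variance weighted",
    "egger": "MR-Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
    "mvmr_ivw": "Multivariable IVW",
}


@dataclass
class MRResult:
    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_value: float
    or_low: float
    or_high: float
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_beta_se(cls, method, n_snp, beta, se, df=None, extra=None):
        """Assemble a result; p two-sided normal, or from t(df) when given."""
        beta = float(beta)
        se = float(se)
        if se > 0:
            z = abs(beta) / se
            pval = 2 * sps.t.sf(z, df) if df is not None else 2 * sps.norm.sf(z)
        else:
            pval = 1.0 if beta == 0 else 0.0
        pval = float(min(max(pval, np.nextafter(0.0, 1.0)), 1.0))
        lo, hi = beta - Z95 * se, beta + Z95 * se
        return cls(
            method=method,
            n_snp=int(n_snp),
            beta=beta,
            se=se,
            ci_low=lo,
            ci_high=hi,
            pval=pval,
            or_value=math.exp(beta),
            or_low=math.exp(lo),
            or_high=math.exp(hi),
            extra=extra or {},
        )


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRResult:
    """Single-SNP causal estimate by/bx with first-order delta-method SE."""
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined for bx = 0")
    return MRResult.from_beta_se("wald", 1, by / bx, abs(sy / bx))


def _ivw_point(bx, by, sy):
    w = 1.0 / np.asarray(sy, dtype=float) ** 2
    den = np.sum(w * bx * bx)
    return np.sum(w * bx * by) / den, den


def ivw(h: HarmonizedSet, re_mode: str = "multiplicative_floor") -> MRResult:
    """Inverse-variance-weighted estimate over all instruments.

    ``re_mode="multiplicative_floor"`` (default) scales the fixed-effect SE
    by max(1, σ̂) with σ̂² = Q/(J-1); ``"fixed"`` uses the fixed-effect SE.
    """
    if re_mode not in ("multiplicative_floor", "fixed"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    J = h.j
    if J < 2:
        raise MethodMinimumError("IVW needs >= 2 instruments; use wald_ratio for 1 SNP")
    bx, by, sy = h.bx, h.by, h.sy
    beta, den = _ivw_point(bx, by, sy)
    se_fixed = math.sqrt(1.0 / den)
    q = float(np.sum(((by - beta * bx) / sy) ** 2))
    sigma_hat = math.sqrt(q / (J - 1))
    se = se_fixed * max(1.0, sigma_hat) if re_mode == "multiplicative_floor" else se_fixed
    return MRResult.from_beta_se(
        "ivw", J, beta, se,
        extra={"Q": q, "sigma_hat": sigma_hat, "re_mode": re_mode, "se_fixed": se_fixed},
    )


def _orient(bx, by):
    s = np.where(bx < 0, -1.0, 1.0)
    return bx * s, by * s


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of by on bx with an intercept."""
    J = h.j
    if J < 3:
        raise MethodMinimumError("MR-Egger needs >= 3 instruments")
    bx, by = _orient(h.bx, h.by)
    w = 1.0 / h.sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    sigma_hat = math.sqrt(fit.scale)  # weighted residual SS / (J - 2)
    scale = max(1.0, sigma_hat)
    se_unit = fit.bse / sigma_hat if sigma_hat > 0 else fit.bse * 0.0
    slope, slope_se = float(fit.params[1]), float(se_unit[1] * scale)
    inter, inter_se = float(fit.params[0]), float(se_unit[0] * scale)
    inter_p = (
        float(2 * sps.t.sf(abs(inter) / inter_se, J - 2)) if inter_se > 0
        else (1.0 if inter == 0 else 0.0)
    )
    return MRResult.from_beta_se(
        "egger", J, slope, slope_se, df=J - 2,
        extra={
            "egger_intercept": inter,
            "egger_intercept_se": inter_se,
            "egger_intercept_p": inter_p,
            "sigma_hat": sigma_hat,
        },
    )


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with linear interpolation at cumulative
    weight 0.5 (standardized cumulative weights s_j = cum(w)_j - w_j/2)."""
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(ws, axis=1) - ws / 2.0
    out = np.empty(theta.shape[0])
    for i in range(theta.shape[0]):
        out[i] = np.interp(0.5, s[i], th[i])
    return out


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimate; SE from a parametric bootstrap that
    resamples bx and by from their reported sampling distributions."""
    J = h.j
    if J < 3:
        raise MethodMinimumError("weighted median needs >= 3 instruments")
    theta = h.by / h.bx
    w = h.bx**2 / h.sy**2
    point = float(_weighted_median_rows(theta[None, :], w[None, :])[0])
    se = _bootstrap_se(_weighted_median_rows, h, n_boot, seed, weighted=True)
    return MRResult.from_beta_se(
        "weighted_median", J, point, se, extra={"bootstrap_reps": n_boot}
    )


def _mode_rows(theta: np.ndarray, w: np.ndarray, phi: float = 1.0) -> np.ndarray:
    """Row-wise mode of the weighted Gaussian-kernel density of the ratios,
    evaluated on the ratio grid; bandwidth 0.9·phi·min(sd, mad·1.4826)·J^(-1/5)."""
    B, J = theta.shape
    sd = theta.std(axis=1, ddof=1)
    mad = np.median(np.abs(theta - np.median(theta, axis=1, keepdims=True)), axis=1)
    s = np.minimum(sd, mad * 1.4826)
    bw = phi * 0.9 * s * J ** (-0.2)
    out = np.empty(B)
    degenerate = bw <= 0
    out[degenerate] = theta[degenerate, 0]
    idx = np.nonzero(~degenerate)[0]
    for i in idx:
        d = (theta[i][:, None] - theta[i][None, :]) / bw[i]
        dens = (w[i][None, :] * np.exp(-0.5 * d * d)).sum(axis=1)
        out[i] = theta[i][np.argmax(dens)]
    return out


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Simple (unweighted) or weighted mode-based estimate."""
    J = h.j
    if J < 3:
        raise MethodMinimumError("mode estimators need >= 3 instruments")
    theta = h.by / h.bx
    w = h.bx**2 / h.sy**2 if weighted else np.ones(J)
    w = w / w.sum()
    point = float(_mode_rows(theta[None, :], w[None, :], phi)[0])
    fn = lambda th, ww: _mode_rows(th, ww, phi)  # noqa: E731
    se = _bootstrap_se(fn, h, n_boot, seed, weighted=weighted)
    method = "weighted_mode" if weighted else "simple_mode"
    return MRResult.from_beta_se(
        method, J, point, se, extra={"bootstrap_reps": n_boot, "bandwidth_phi": phi}
    )


def _bootstrap_se(row_fn, h: HarmonizedSet, n_boot: int, seed: int, weighted: bool,
                  chunk: int = 200) -> float:
    """Parametric bootstrap: bx* ~ N(bx, sx²), by* ~ N(by, sy²)."""
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    done = 0
    J = h.j
    while done < n_boot:
        b = min(chunk, n_boot - done)
        bxs = rng.normal(h.bx, h.sx, size=(b, J))
        bys = rng.normal(h.by, h.sy, size=(b, J))
        theta = bys / bxs
        w = bxs**2 / h.sy**2 if weighted else np.ones_like(theta)
        w = w / w.sum(axis=1, keepdims=True)
        ests[done : done + b] = row_fn(theta, w)
        done += b
    return float(ests.std(ddof=1))


def mvmr_ivw(
    bx_matrix: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    exposure_ids=None,
    snp_count: int | None = None,
) -> list[MRResult]:
    """Multivariable IVW: WLS of by on k exposure-beta columns, no intercept,
    weights 1/sy²; per-coefficient SE scaled by max(1, σ̂), p from t(J-k).

    Returns one :class:`MRResult` per exposure column, in column order.
    """
    X = np.atleast_2d(np.asarray(bx_matrix, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(by)) == X.shape[1]:
        X = X.T
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    J, k = X.shape
    if exposure_ids is None:
        exposure_ids = [f"exposure_{i + 1}" for i in range(k)]
    if J < k + 2:
        raise MethodMinimumError(f"MVMR with k={k} exposures needs >= {k + 2} instruments")
    w = 1.0 / sy**2
    Xw = X * np.sqrt(w)[:, None]
    r_diag = np.abs(np.diag(np.linalg.qr(Xw, mode="r")))
    if np.any(r_diag < 1e-10 * max(r_diag.max(), 1.0)):
        bad = [exposure_ids[i] for i in np.nonzero(
            r_diag < 1e-10 * max(r_diag.max(), 1.0))[0]]
        raise CollinearityError(f"rank-deficient exposure matrix; offending columns: {bad}")
    fit = sm.WLS(by, X, weights=w).fit()
    sigma_hat = math.sqrt(fit.scale)  # weighted residual SS / (J - k)
    scale = max(1.0, sigma_hat)
    se_unit = fit.bse / sigma_hat if sigma_hat > 0 else fit.bse * 0.0
    out = []
    for i, eid in enumerate(exposure_ids):
        out.append(
            MRResult.from_beta_se(
                "mvmr_ivw",
                snp_count or J,
                float(fit.params[i]),
                float(se_unit[i] * scale),
                df=J - k,
                extra={"exposure": eid, "k": k, "sigma_hat": sigma_hat},
            )
        )
    return out
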