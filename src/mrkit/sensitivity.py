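"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

* Cochran's Q on the IVW basis (deviations of Wald ratios from the pooled
  fixed-effect estimate, weights bx²/sy², chi-square with J-1 df) or the
  Egger basis (residuals about the Egger line, J-2 df).
* The Egger intercept test for average directional pleiotropy.
* MR-PRESSO: a simulation-based residual test.  The observed residual sum
  of squares ``RSS = Σ w_j (by_j - θ̂_(-j) bx_j)²`` (w_j = 1/sy_j²,
  θ̂_(-j) the leave-one-out fixed-effect IVW slope) is compared with its
  distribution under the no-pleiotropy model by simulating
  ``bx* ~ N(bx, sx²)``, ``by* ~ N(θ̂_(-j) bx, sy²)``; empirical p-values
  use the (1 + exceedances)/(n_sim + 1) convention.  Per-SNP squared
  residuals give Bonferroni-adjusted outlier p-values; when outliers are
  found, the distortion test compares the raw-vs-corrected estimate shift
  against the shift from removing random subsets of the same size.
* Leave-one-out: the IVW estimate omitting each instrument in turn.
* Plot-data export: scatter (bx vs by with per-method fitted lines) and
  funnel (Wald ratio vs its precision) tables, ready for any plotting tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MRResult, _ivw_point, _orient, egger, ivw
from .exceptions import MethodMinimumError
from .harmonize import HarmonizedSet


@dataclass
class HeterogeneityResult:
    method_basis: str  # "ivw" | "egger"
    Q: float
    df: int
    pval: float


class EggerIntercept(NamedTuple):
    intercept: float
    se: float
    pval: float


@dataclass
class LeaveOneOutRow:
    omitted_snp: Optional[str]  # None = all-SNP reference row
    estimate: MRResult


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    n_sim: int
    outlier_pvals: pd.Series
    outliers: list
    distortion_p: Optional[float]
    raw_estimate: MRResult
    corrected_estimate: Optional[MRResult]


def cochran_q(h: HarmonizedSet, basis: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic across instruments."""
    J = h.j
    if basis == "ivw":
        if J < 2:
            raise MethodMinimumError("Cochran's Q (IVW basis) needs >= 2 instruments")
        beta, _ = _ivw_point(h.bx, h.by, h.sy)
        q = float(np.sum(((h.by - beta * h.bx) / h.sy) ** 2))
        df = J - 1
    elif basis == "egger":
        if J < 3:
            raise MethodMinimumError("Cochran's Q (Egger basis) needs >= 3 instruments")
        res = egger(h)
        bx, by = _orient(h.bx, h.by)
        fitted = res.extra["egger_intercept"] + res.beta * bx
        q = float(np.sum(((by - fitted) / h.sy) ** 2))
        df = J - 2
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return HeterogeneityResult(basis, q, df, float(sps.chi2.sf(q, df)))


def egger_intercept_test(h: HarmonizedSet) -> EggerIntercept:
    """Average directional pleiotropy: the intercept block of the Egger fit."""
    res = egger(h)
    return EggerIntercept(
        res.extra["egger_intercept"],
        res.extra["egger_intercept_se"],
        res.extra["egger_intercept_p"],
    )


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effect IVW slope for each SNP, vectorized.

    Accepts 1D (J,) or 2D (B, J) arrays; returns the same shape.
    """
    sxy = (w * bx * by).sum(axis=-1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_sig: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests (seed-deterministic)."""
    J = h.j
    if J < 4:
        raise MethodMinimumError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if J / (n_sim + 1) > outlier_sig:
        warnings.warn(
            f"n_sim={n_sim} cannot resolve Bonferroni-adjusted p below "
            f"{J / (n_sim + 1):.3g}; outlier_sig={outlier_sig} may be unreachable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = h.bx, h.by, h.sx, h.sy
    w = 1.0 / sy**2

    loo = _loo_slopes(bx, by, w)
    resid = by - loo * bx
    t_obs = w * resid**2
    rss_obs = float(t_obs.sum())

    bxs = rng.normal(bx, sx, size=(n_sim, J))
    bys = rng.normal(loo * bx, sy, size=(n_sim, J))
    loo_s = _loo_slopes(bxs, bys, w)
    t_sim = w * (bys - loo_s * bxs) ** 2
    rss_sim = t_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + (t_sim >= t_obs).sum(axis=0)) / (n_sim + 1)
    outlier_pvals = pd.Series(np.minimum(1.0, p_raw * J), index=h.snp_ids)
    outliers = outlier_pvals.index[outlier_pvals < outlier_sig].tolist()

    raw = ivw(h)
    corrected = None
    distortion_p = None
    if outliers:
        corrected = ivw(h.drop(outliers))
        d_obs = raw.beta - corrected.beta
        n_out = len(outliers)
        if J - n_out >= 2:
            subsets = np.array(
                [rng.choice(J, size=n_out, replace=False) for _ in range(n_sim)]
            )
            mask = np.ones((n_sim, J), dtype=bool)
            mask[np.arange(n_sim)[:, None], subsets] = False
            num = (mask * (w * bx * by)).sum(axis=1)
            den = (mask * (w * bx * bx)).sum(axis=1)
            d_sim = raw.beta - num / den
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        distortion_p=distortion_p,
        raw_estimate=raw,
        corrected_estimate=corrected,
    )


def leave_one_out(h: HarmonizedSet, re_mode: str = "multiplicative_floor"):
    """IVW re-estimated with each instrument omitted in turn, plus the
    all-SNP reference row (omitted_snp=None) last."""
    if h.j < 3:
        raise MethodMinimumError("leave-one-out needs >= 3 instruments")
    rows = [
        LeaveOneOutRow(snp, ivw(h.drop([snp]), re_mode=re_mode)) for snp in h.snp_ids
    ]
    rows.append(LeaveOneOutRow(None, ivw(h, re_mode=re_mode)))
    return rows


def plot_data(h: HarmonizedSet, results):
    """Scatter and funnel tables for external plotting.

    Scatter: per-SNP (bx, sx, by, sy) plus one constant ``slope_<method>``
    column per supplied result (and the Egger intercept).  Funnel: per-SNP
    Wald ratio against its precision |bx|/sy.
    """
    scatter = h.table[["snp_id", "bx", "sx", "by", "sy"]].copy()
    for r in results:
        scatter[f"slope_{r.method}"] = r.beta
        if r.method == "egger":
            scatter["intercept_egger"] = r.extra["egger_intercept"]
    funnel = pd.DataFrame(
        {
            "snp_id": h.snp_ids,
            "wald_ratio": h.by / h.bx,
            "precision": np.abs(h.bx) / h.sy,
        }
    )
    return scatter, funnel
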