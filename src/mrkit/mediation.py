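"""Two-step mediation MR.

The total effect of the exposure on the outcome (α), the exposure's effect
on a candidate mediator (β1) and the mediator's direct effect on the
outcome given the exposure (β2, from multivariable MR over the union of
both traits' instruments) combine into the mediated share

    proportion = β1 · β2 / α,

the fraction of the total effect transmitted through the mediator
(signed: positive means the indirect path acts in the same direction as
the total effect).  Its SE comes from a first-order delta method treating
the three estimates as independent — an approximation, since the same
outcome sample enters α and β2, but the three are estimated from
different regressions and largely different instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .estimators import MRResult, Z95, ivw, mvmr_ivw
from .harmonize import harmonize
from .instruments import clump, select_instruments
from .sumstats import SumStats

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    alpha: MRResult  # UVMR exposure -> outcome (total effect)
    beta1: MRResult  # UVMR exposure -> mediator
    beta2: MRResult  # MVMR mediator -> outcome | exposure
    indirect: float
    proportion: float  # NaN when undefined
    proportion_se: float
    proportion_ci: tuple
    proportion_defined: bool


@dataclass
class ScreenResult:
    selected: list  # [(mediator_id, MRResult)] with p < sig
    all_results: dict  # mediator_id -> MRResult for every screenable mediator
    skipped: dict  # mediator_id -> reason


def screen_mediators(
    mediator_panel,
    outcome: SumStats,
    sig: float = 0.05,
    ld=None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
    f_threshold: float = 10.0,
) -> ScreenResult:
    """UVMR of each candidate mediator on the outcome; mediators whose IVW
    p-value falls below ``sig`` are retained as candidates."""
    panel = list(mediator_panel)
    if not panel:
        raise ValueError("mediator panel is empty")
    selected, all_results, skipped = [], {}, {}
    for med in panel:
        iv, _ = select_instruments(
            med, ld, p_threshold, r2_threshold, window_kb, f_threshold
        )
        if iv.n_snps < 2:
            skipped[med.trait_id] = f"{iv.n_snps} instrument(s) after selection"
            log.info("screen: skipping %s (%s)", med.trait_id, skipped[med.trait_id])
            continue
        h = harmonize(iv, outcome)
        if h.j < 2:
            skipped[med.trait_id] = f"{h.j} instrument(s) after harmonization"
            continue
        res = ivw(h)
        res.extra["trait"] = med.trait_id
        all_results[med.trait_id] = res
        if res.pval < sig:
            selected.append((med.trait_id, res))
    return ScreenResult(selected, all_results, skipped)


def _union_mvmr_beta2(exposure, mediator, outcome, iv_x, iv_m, ld,
                      r2_threshold, window_kb):
    """β2: the mediator coefficient from MVMR of the outcome on
    (exposure, mediator) betas over the union instrument set."""
    union_ids = list(dict.fromkeys(iv_x.snp_ids + iv_m.snp_ids))
    # every SNP must be present in all three traits (no proxies)
    for trait in (exposure, mediator, outcome):
        avail = set(trait.snp_ids)
        union_ids = [s for s in union_ids if s in avail]
    ex_union = exposure.restrict(union_ids)
    med_union = mediator.restrict(union_ids)
    # rank the union for re-clumping by the smaller of the two source p-values
    pm = dict(zip(med_union.table["snp_id"], med_union.table["pval"]))
    ex_union.table["pval"] = np.minimum(
        ex_union.table["pval"], ex_union.table["snp_id"].map(pm)
    )
    ex_union = clump(ex_union, ld, r2_threshold, window_kb)
    union_ids = ex_union.snp_ids

    h_uo = harmonize(exposure.restrict(union_ids), outcome)
    h_um = harmonize(exposure.restrict(union_ids), mediator)
    merged = h_uo.table.merge(
        h_um.table[["snp_id", "by", "sy"]].rename(columns={"by": "bm", "sy": "sm"}),
        on="snp_id",
    )
    X = merged[["bx", "bm"]].to_numpy()
    res = mvmr_ivw(
        X,
        merged["by"].to_numpy(),
        merged["sy"].to_numpy(),
        exposure_ids=[exposure.trait_id, mediator.trait_id],
    )
    return res[1], len(merged)


def two_step_mediation(
    exposure: SumStats,
    mediator: SumStats,
    outcome: SumStats,
    ld=None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
    f_threshold: float = 10.0,
) -> MediationResult:
    """α, β1, β2 and the mediated proportion β1·β2/α for one
    exposure/mediator/outcome triple."""
    iv_x, _ = select_instruments(
        exposure, ld, p_threshold, r2_threshold, window_kb, f_threshold
    )
    iv_m, _ = select_instruments(
        mediator, ld, p_threshold, r2_threshold, window_kb, f_threshold
    )
    alpha = ivw(harmonize(iv_x, outcome))
    beta1 = ivw(harmonize(iv_x, mediator))
    beta2, _ = _union_mvmr_beta2(
        exposure, mediator, outcome, iv_x, iv_m, ld, r2_threshold, window_kb
    )

    indirect = beta1.beta * beta2.beta
    defined = abs(alpha.beta) > 1e-12
    if defined:
        proportion = indirect / alpha.beta
        a, b1, b2 = alpha.beta, beta1.beta, beta2.beta
        var_p = (
            (b2 / a) ** 2 * beta1.se**2
            + (b1 / a) ** 2 * beta2.se**2
            + (b1 * b2 / a**2) ** 2 * alpha.se**2
        )
        p_se = float(np.sqrt(var_p))
        ci = (proportion - Z95 * p_se, proportion + Z95 * p_se)
    else:
        log.warning("total effect is zero within tolerance; proportion undefined")
        proportion, p_se, ci = float("nan"), float("nan"), (float("nan"), float("nan"))
    return MediationResult(
        alpha=alpha,
        beta1=beta1,
        beta2=beta2,
        indirect=indirect,
        proportion=proportion,
        proportion_se=p_se,
        proportion_ci=ci,
        proportion_defined=defined,
    )
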