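"""Instrument selection: p-value threshold, greedy LD clumping, F-statistic
strength filter, and exclusion-list screening.

The fixed composition order is p-filter → clump → F-filter → exclusion,
with per-step counts recorded in :class:`InstrumentSet.selection_log`.
Boundary conventions (all strict, matching the usual GWAS tooling):
retain p < threshold, discard pairs with r² >= threshold, retain F > threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import LDTableError
from .sumstats import SumStats

log = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    exposure_id: str
    snps: list
    f_stats: pd.Series
    selection_log: dict


def filter_by_pvalue(stats: SumStats, p_threshold: float) -> SumStats:
    """Retain rows with p strictly below ``p_threshold``."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    keep = stats.table["pval"] < p_threshold
    return replace(stats, table=stats.table.loc[keep].reset_index(drop=True), n_dropped=0)


def compute_f_stats(stats: SumStats) -> pd.Series:
    """Per-SNP instrument strength F = beta^2 / se^2, indexed by snp_id."""
    t = stats.table
    return pd.Series((t["beta"] / t["se"]) ** 2, name="F").set_axis(t["snp_id"].values)


def filter_weak_instruments(stats: SumStats, f_threshold: float = 10.0) -> SumStats:
    """Retain rows with F strictly above ``f_threshold``."""
    if f_threshold < 0:
        raise ValueError("f_threshold must be >= 0")
    f = compute_f_stats(stats)
    keep = (f > f_threshold).values
    return replace(stats, table=stats.table.loc[keep].reset_index(drop=True), n_dropped=0)


def apply_exclusion_list(stats: SumStats, excluded, reason_map: dict | None = None) -> SumStats:
    """Drop SNPs on a user-supplied exclusion list (e.g. confounder-associated
    variants screened externally); exclusions are logged with reasons."""
    excluded = set(excluded)
    hit = stats.table["snp_id"].isin(excluded)
    for snp in stats.table.loc[hit, "snp_id"]:
        reason = (reason_map or {}).get(snp, "on exclusion list")
        log.info("%s: excluding %s (%s)", stats.trait_id, snp, reason)
    out = replace(stats, table=stats.table.loc[~hit].reset_index(drop=True), n_dropped=0)
    if out.n_snps == 0 and stats.n_snps > 0:
        log.warning("%s: exclusion list removed every instrument", stats.trait_id)
    return out


def _ld_lookup(ld: pd.DataFrame | None) -> dict:
    """Symmetrized {(a, b): r2} lookup; raises on contradictory entries."""
    table: dict = {}
    if ld is None:
        return table
    for a, b, r2 in ld[["snp_a", "snp_b", "r2"]].itertuples(index=False):
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key in table and abs(table[key] - r2) > 1e-12:
            raise LDTableError(f"asymmetric r2 for pair {key}: {table[key]} vs {r2}")
        table[key] = float(r2)
    return table


def clump(
    stats: SumStats,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
) -> SumStats:
    """Greedy LD clumping.

    Repeatedly take the unselected SNP with the smallest p-value (ties broken
    lexicographically by snp_id) as an index SNP and discard every remaining
    SNP with r² >= ``r2_threshold`` against it.  When both SNPs carry
    positions on the same chromosome, only pairs within ``window_kb`` are
    eligible for discarding; without positions the window is ignored.  Pairs
    absent from the (sparse) ``ld`` table count as r² = 0.
    """
    lookup = _ld_lookup(ld)
    t = stats.table
    if not lookup:  # every pair r2 = 0: nothing can be discarded
        return replace(stats, table=t.reset_index(drop=True), n_dropped=0)
    has_pos = "pos" in t.columns and "chrom" in t.columns and t["pos"].notna().all()
    order = t.assign(_i=np.arange(len(t))).sort_values(["pval", "snp_id"])
    pos = dict(zip(t["snp_id"], t["pos"])) if has_pos else {}
    chrom = dict(zip(t["snp_id"], t["chrom"])) if has_pos else {}

    kept: list[str] = []
    discarded: set[str] = set()
    for snp in order["snp_id"]:
        if snp in discarded:
            continue
        kept.append(snp)
        for other in order["snp_id"]:
            if other == snp or other in discarded:
                continue
            key = (snp, other) if snp <= other else (other, snp)
            r2 = lookup.get(key, 0.0)
            if r2 < r2_threshold:
                continue
            if has_pos and window_kb is not None:
                if chrom[snp] != chrom[other]:
                    continue
                if abs(pos[snp] - pos[other]) > window_kb * 1000:
                    continue
            discarded.add(other)
    keep_mask = t["snp_id"].isin(kept)
    return replace(stats, table=t.loc[keep_mask].reset_index(drop=True), n_dropped=0)


def select_instruments(
    stats: SumStats,
    ld: pd.DataFrame | None = None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.001,
    window_kb: int = 10000,
    f_threshold: float = 10.0,
    excluded=(),
    reason_map: dict | None = None,
):
    """Full selection chain; returns ``(selected SumStats, InstrumentSet)``."""
    n_input = stats.n_snps
    s1 = filter_by_pvalue(stats, p_threshold)
    s2 = clump(s1, ld, r2_threshold, window_kb)
    s3 = filter_weak_instruments(s2, f_threshold)
    s4 = apply_exclusion_list(s3, excluded, reason_map)
    sel_log = {
        "input": n_input,
        "post_p_filter": s1.n_snps,
        "post_clump": s2.n_snps,
        "post_f_filter": s3.n_snps,
        "post_exclusion": s4.n_snps,
    }
    log.info("%s: instrument selection %s", stats.trait_id, sel_log)
    iv = InstrumentSet(
        exposure_id=stats.trait_id,
        snps=s4.snp_ids,
        f_stats=compute_f_stats(s4),
        selection_log=sel_log,
    )
    return s4, iv
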