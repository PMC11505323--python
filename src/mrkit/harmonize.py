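"""Allele harmonization across two GWAS samples.

Two-sample MR needs the SNP-exposure and SNP-outcome effects expressed per
copy of the *same* effect allele.  For each SNP present in both traits:

* outcome alleles identical to the exposure's → kept as-is;
* outcome alleles swapped (effect/other exchanged) → outcome beta negated
  and eaf reflected (``flipped``);
* alleles matching only under strand complement → complemented first, then
  the two rules above;
* palindromic SNPs (A/T or C/G) cannot be resolved from alleles alone:
  they are dropped when either eaf is missing or falls inside the ambiguity
  band (default (0.42, 0.58)); outside the band the strand is inferred from
  whether the two frequencies sit on the same side of 0.5;
* irreconcilable allele sets (and indels / multi-base alleles) are dropped
  as incompatible.

Wald ratios are invariant to which of the two alleles is declared the
effect allele — flipping negates both betas — so harmonization affects
results only through which SNPs survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")

ACTION_KEPT = "kept"
ACTION_FLIPPED = "flipped"
ACTION_DROP_PALINDROMIC = "dropped_palindromic"
ACTION_DROP_INCOMPATIBLE = "dropped_incompatible"


@dataclass
class HarmonizedSet:
    """Per-SNP exposure/outcome effects aligned to a shared effect allele."""

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame  # kept rows: snp_id, effect_allele, other_allele, bx, sx, by, sy, eaf_x, eaf_y, action
    actions: pd.DataFrame = field(default=None, repr=False)  # every merged row with its action

    def __post_init__(self):
        if self.actions is None:
            self.actions = self.table[["snp_id", "action"]].copy()

    @property
    def j(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @property
    def bx(self) -> np.ndarray:
        return self.table["bx"].to_numpy()

    @property
    def sx(self) -> np.ndarray:
        return self.table["sx"].to_numpy()

    @property
    def by(self) -> np.ndarray:
        return self.table["by"].to_numpy()

    @property
    def sy(self) -> np.ndarray:
        return self.table["sy"].to_numpy()

    def drop(self, snp_ids) -> "HarmonizedSet":
        keep = ~self.table["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.table.loc[keep].reset_index(drop=True),
            self.actions,
        )

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            self.table.loc[keep].reset_index(drop=True),
            self.actions,
        )

    @classmethod
    def from_arrays(cls, bx, sx, by, sy, snp_ids=None, exposure_id="x", outcome_id="y"):
        """Build directly from aligned effect arrays (synthetic/test use)."""
        bx = np.asarray(bx, dtype=float)
        n = len(bx)
        if snp_ids is None:
            snp_ids = [f"rs{j + 1}" for j in range(n)]
        table = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": "A",
                "other_allele": "G",
                "bx": bx,
                "sx": np.broadcast_to(np.asarray(sx, dtype=float), (n,)).copy(),
                "by": np.asarray(by, dtype=float),
                "sy": np.broadcast_to(np.asarray(sy, dtype=float), (n,)).copy(),
                "eaf_x": np.nan,
                "eaf_y": np.nan,
                "action": ACTION_KEPT,
            }
        )
        return cls(exposure_id, outcome_id, table)


def _complement(s: pd.Series) -> pd.Series:
    return s.str.translate(_COMP)


def harmonize(
    exposure: SumStats,
    outcome: SumStats,
    palindromic_eaf_band: tuple = (0.42, 0.58),
) -> HarmonizedSet:
    """Align ``outcome`` effects to ``exposure``'s effect alleles per SNP."""
    ex = exposure.table.rename(
        columns={"beta": "bx", "se": "sx", "eaf": "eaf_x", "pval": "pval_x"}
    )[["snp_id", "effect_allele", "other_allele", "bx", "sx", "eaf_x"]]
    ou = outcome.table.rename(
        columns={
            "beta": "by",
            "se": "sy",
            "eaf": "eaf_y",
            "effect_allele": "ea_y",
            "other_allele": "oa_y",
        }
    )[["snp_id", "ea_y", "oa_y", "by", "sy", "eaf_y"]]
    m = ex.merge(ou, on="snp_id", how="inner")
    if m.empty:
        log.warning(
            "harmonize(%s, %s): no shared SNPs", exposure.trait_id, outcome.trait_id
        )
        empty = m.assign(action=pd.Series(dtype=str))
        return HarmonizedSet(exposure.trait_id, outcome.trait_id, empty)

    single = (
        (m["effect_allele"].str.len() == 1)
        & (m["other_allele"].str.len() == 1)
        & (m["ea_y"].str.len() == 1)
        & (m["oa_y"].str.len() == 1)
    )
    cea, coa = _complement(m["ea_y"]), _complement(m["oa_y"])
    same = (m["ea_y"] == m["effect_allele"]) & (m["oa_y"] == m["other_allele"])
    swapped = (m["ea_y"] == m["other_allele"]) & (m["oa_y"] == m["effect_allele"])
    comp_same = (cea == m["effect_allele"]) & (coa == m["other_allele"])
    comp_swapped = (cea == m["other_allele"]) & (coa == m["effect_allele"])
    palin = single & (m["effect_allele"] == _complement(m["other_allele"]))

    lo, hi = palindromic_eaf_band
    eaf_missing = m["eaf_x"].isna() | m["eaf_y"].isna()
    in_band = (
        ((m["eaf_x"] > lo) & (m["eaf_x"] < hi)) | ((m["eaf_y"] > lo) & (m["eaf_y"] < hi))
    )
    palin_drop = palin & (eaf_missing | in_band)
    palin_keep_aligned = palin & ~palin_drop & (
        (m["eaf_x"] - 0.5) * (m["eaf_y"] - 0.5) > 0
    )
    palin_flip = palin & ~palin_drop & ~palin_keep_aligned

    action = np.full(len(m), ACTION_DROP_INCOMPATIBLE, dtype=object)
    nonpal = single & ~palin
    action[(nonpal & (same | comp_same)).values] = ACTION_KEPT
    action[(nonpal & ~(same | comp_same) & (swapped | comp_swapped)).values] = ACTION_FLIPPED
    action[palin_drop.values] = ACTION_DROP_PALINDROMIC
    action[palin_keep_aligned.values] = ACTION_KEPT
    action[palin_flip.values] = ACTION_FLIPPED
    m["action"] = action

    n_indel = int((~single).sum())
    if n_indel:
        log.info("harmonize: dropped %d indel/multi-allelic records", n_indel)

    flip = m["action"] == ACTION_FLIPPED
    m.loc[flip, "by"] = -m.loc[flip, "by"]
    m.loc[flip, "eaf_y"] = 1.0 - m.loc[flip, "eaf_y"]

    kept = m.loc[m["action"].isin([ACTION_KEPT, ACTION_FLIPPED])].reset_index(drop=True)
    kept = kept[
        [
            "snp_id",
            "effect_allele",
            "other_allele",
            "bx",
            "sx",
            "by",
            "sy",
            "eaf_x",
            "eaf_y",
            "action",
        ]
    ]
    if kept.empty:
        log.warning(
            "harmonize(%s, %s): empty harmonized set", exposure.trait_id, outcome.trait_id
        )
    return HarmonizedSet(
        exposure.trait_id, outcome.trait_id, kept, m[["snp_id", "action"]].copy()
    )
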