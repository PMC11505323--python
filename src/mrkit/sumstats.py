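"""Reading, validating and writing GWAS summary-statistic tables.

A summary-statistics table has one row per SNP with, at minimum, an
identifier, effect/other allele, effect size (``beta``, log-odds for binary
traits), its standard error and a p-value; effect-allele frequency,
chromosome/position and sample size are optional.  Consortium exports
(MiBioGen, FinnGen, EBI, ...) differ in column naming and delimiter, so
reading goes through a configurable column map and the delimiter is
sniffed among tab/comma/semicolon unless given explicitly.

Rows violating the per-SNP invariants (se > 0, p in (0, 1], eaf in [0, 1],
distinct alleles over A/C/G/T) are dropped and counted, never silently
altered — with one exception: input p-values of exactly 0 (common in
consortium exports after rounding) are clamped to the smallest positive
float and logged, since downstream code takes -log p.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ColumnMapError, EmptyInputError

log = logging.getLogger(__name__)

#: canonical field -> default source column name
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")

_ALLELE_CHARS = frozenset("ACGT")
_TINY_P = float(np.nextafter(0.0, 1.0))


@dataclass
class SumStats:
    """One GWAS: per-SNP association records for a single trait.

    ``table`` holds canonical columns ``snp_id, effect_allele, other_allele,
    eaf, beta, se, pval`` plus optional ``chrom, pos, n``.  ``snp_id`` is
    unique within a table.
    """

    trait_id: str
    table: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "continuous"  # or "binary"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.trait_label:
            self.trait_label = self.trait_id
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id in {self.trait_id}: {dups[:5]}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def restrict(self, snp_ids) -> "SumStats":
        """Rows for the given SNPs, in the table's own order; missing ids ignored."""
        keep = self.table["snp_id"].isin(set(snp_ids))
        return replace(self, table=self.table.loc[keep].reset_index(drop=True), n_dropped=0)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_id: str | None = None,
    trait_label: str = "",
    trait_type: str = "continuous",
    delimiter: str | None = None,
) -> SumStats:
    """Read a delimited summary-statistics table into a validated :class:`SumStats`.

    ``column_map`` maps canonical field names (see :data:`DEFAULT_COLUMN_MAP`)
    to the file's column names; unmapped optional fields are simply absent.
    Invalid rows are dropped with a logged count.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype={cmap["snp_id"]: str})

    def _resolve(f):
        # explicit mapping first, then the canonical field name itself
        if cmap[f] in raw.columns:
            return cmap[f]
        if f in raw.columns and (column_map is None or f not in column_map):
            return f
        return None

    for f in REQUIRED_FIELDS:
        if _resolve(f) is None:
            raise ColumnMapError(
                f"{path.name}: required column {cmap[f]!r} (field {f!r}) not found; "
                f"available: {list(raw.columns)}"
            )
    present = [f for f in REQUIRED_FIELDS + OPTIONAL_FIELDS if _resolve(f)]
    df = raw[[_resolve(f) for f in present]].copy()
    df.columns = present

    n_in = len(df)
    df["snp_id"] = df["snp_id"].astype(str).str.strip()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("beta", "se", "pval", "eaf", "pos", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        log.warning("%s: clamped %d zero p-values to %.3g", path.name, n_zero_p, _TINY_P)
        df.loc[df["pval"] == 0, "pval"] = _TINY_P

    allele_ok = df["effect_allele"].map(_valid_allele) & df["other_allele"].map(_valid_allele)
    ok = (
        (df["snp_id"] != "")
        & allele_ok
        & (df["effect_allele"] != df["other_allele"])
        & np.isfinite(df["beta"])
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
    )
    if "eaf" in df.columns:
        ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    ok &= ~df["snp_id"].duplicated(keep="first")

    dropped = int(n_in - ok.sum())
    if dropped:
        log.info("%s: dropped %d/%d rows failing validation", path.name, dropped, n_in)
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")

    for col in ("eaf",):
        if col not in df.columns:
            df[col] = np.nan
    return SumStats(
        trait_id=trait_id or path.stem,
        trait_label=trait_label,
        trait_type=trait_type,
        table=df,
        n_dropped=dropped,
    )


def _valid_allele(a: str) -> bool:
    return len(a) >= 1 and set(a) <= _ALLELE_CHARS


def write_sumstats(stats: SumStats, path, delimiter: str = "\t") -> None:
    """Write a :class:`SumStats` table (canonical column names, 12 significant digits)."""
    stats.table.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


RESULT_COLUMNS = ("trait", "method", "n_snp", "beta", "se", "pval")


def write_results_table(results, path, trait_ids=None) -> None:
    """Write MR results as a 6-column TSV: trait, method, n_snp, beta, se, pval.

    Numeric fields carry 12 significant digits so a read-back reproduces the
    estimates beyond 1e-10.  ``results`` is a non-empty iterable of
    :class:`~mrkit.estimators.MRResult`; ``trait_ids`` optionally supplies a
    parallel list of trait labels (default: taken from each result's
    ``extra['trait']`` or empty).
    """
    results = list(results)
    if not results:
        raise EmptyInputError("no results to write")
    if trait_ids is None:
        trait_ids = [r.extra.get("trait", "") for r in results]
    rows = [
        {
            "trait": t,
            "method": r.method,
            "n_snp": r.n_snp,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pval,
        }
        for t, r in zip(trait_ids, results)
    ]
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_or_ci(result) -> str:
    """`"0.61 (0.40-0.93)"` — odds-ratio with 95% CI, two decimals."""
    return f"{result.or_value:.2f} ({result.or_low:.2f}-{result.or_high:.2f})"
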