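"""Study orchestration: per-taxon MR, the sensitivity battery, panel-wide
screening, replication against a second outcome, and mediation.

Per-taxon stochastic stages (bootstraps, MR-PRESSO) receive seeds derived
by hashing (run seed, taxon id, stage name), so per-taxon results are
reproducible regardless of the order in which taxa are processed.

Significance defaults to raw IVW p < 0.05 with no multiple-testing
correction, matching common practice in panel-wide microbiome MR screens;
a Benjamini-Hochberg switch (``use_fdr``) is provided and recommended for
new analyses.  Replication re-estimates significant taxa against the
replication outcome using the *same* exposure instruments (re-estimation,
not re-selection).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimators import MRResult, egger, ivw, mode_estimate, weighted_median
from .exceptions import EmptyInputError
from .harmonize import HarmonizedSet, harmonize
from .instruments import InstrumentSet, select_instruments
from .mediation import MediationResult, screen_mediators, two_step_mediation
from .sensitivity import (
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_presso,
    plot_data,
)
from .sumstats import SumStats, format_or_ci, write_results_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    p_instr: float = 1e-5
    r2: float = 0.001
    window_kb: int = 10000
    f_min: float = 10.0
    sig: float = 0.05
    n_boot: int = 1000
    n_sim_presso: int = 1000
    seed: int = 0
    re_mode: str = "multiplicative_floor"
    use_fdr: bool = False
    palindromic_band: tuple = (0.42, 0.58)
    excluded_snps: tuple = ()
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if not 0 < self.p_instr <= 1 or not 0 < self.sig <= 1:
            raise ValueError("p_instr and sig must lie in (0, 1]")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")
        if self.f_min < 0 or self.n_boot < 1 or self.n_sim_presso < 100:
            raise ValueError("invalid f_min / n_boot / n_sim_presso")


def derive_seed(seed: int, *parts) -> int:
    """Deterministic per-(taxon, stage) seed below 2^31 via blake2b."""
    token = "|".join([str(seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.blake2b(token, digest_size=4).digest(), "big") % (2**31)


@dataclass
class TaxonReport:
    taxon_id: str
    skipped_reason: Optional[str] = None
    instruments: Optional[InstrumentSet] = None
    harmonized: Optional[HarmonizedSet] = None
    results: dict = field(default_factory=dict)  # method -> MRResult
    heterogeneity: dict = field(default_factory=dict)  # basis -> HeterogeneityResult
    egger_intercept: Optional[tuple] = None
    presso: object = None
    loo: list = field(default_factory=list)
    scatter: Optional[pd.DataFrame] = None
    funnel: Optional[pd.DataFrame] = None


def run_taxon(
    exposure: SumStats,
    outcome: SumStats,
    cfg: RunConfig,
    ld=None,
) -> TaxonReport:
    """Selection → harmonization → five estimators → sensitivity battery."""
    cfg.validate()
    report = TaxonReport(taxon_id=exposure.trait_id)
    selected, iv = select_instruments(
        exposure, ld, cfg.p_instr, cfg.r2, cfg.window_kb, cfg.f_min, cfg.excluded_snps
    )
    report.instruments = iv
    h = harmonize(selected, outcome, cfg.palindromic_band)
    report.harmonized = h
    if h.j < 2:
        report.skipped_reason = f"{h.j} instrument(s) after harmonization (< 2)"
        log.warning("%s: skipped — %s", exposure.trait_id, report.skipped_reason)
        return report

    res: dict[str, MRResult] = {"ivw": ivw(h, re_mode=cfg.re_mode)}
    if h.j >= 3:
        res["egger"] = egger(h)
        res["weighted_median"] = weighted_median(
            h, cfg.n_boot, derive_seed(cfg.seed, exposure.trait_id, "wmedian")
        )
        res["simple_mode"] = mode_estimate(
            h, weighted=False, n_boot=cfg.n_boot,
            seed=derive_seed(cfg.seed, exposure.trait_id, "smode"),
        )
        res["weighted_mode"] = mode_estimate(
            h, weighted=True, n_boot=cfg.n_boot,
            seed=derive_seed(cfg.seed, exposure.trait_id, "wmode"),
        )
    for r in res.values():
        r.extra["trait"] = exposure.trait_id
    report.results = res

    report.heterogeneity["ivw"] = cochran_q(h, "ivw")
    if h.j >= 3:
        report.heterogeneity["egger"] = cochran_q(h, "egger")
        report.egger_intercept = egger_intercept_test(h)
        report.loo = leave_one_out(h, re_mode=cfg.re_mode)
    if h.j >= 4:
        report.presso = mr_presso(
            h, cfg.n_sim_presso, cfg.sig,
            derive_seed(cfg.seed, exposure.trait_id, "presso"),
        )
    report.scatter, report.funnel = plot_data(h, list(res.values()))
    return report


@dataclass
class PanelReport:
    taxa: dict  # taxon_id -> TaxonReport
    results_table: pd.DataFrame
    significant: list
    replication: dict = field(default_factory=dict)  # taxon_id -> MRResult
    significant_replicated: list = field(default_factory=list)
    mediator_screen: object = None
    mediation: dict = field(default_factory=dict)  # (taxon, mediator) -> MediationResult


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj


def run_panel(
    exposures,
    outcome: SumStats,
    cfg: RunConfig,
    replication: Optional[SumStats] = None,
    mediator_panel=None,
    ld=None,
) -> PanelReport:
    """Panel-wide MR screen with optional replication and mediation stages."""
    exposures = list(exposures)
    if not exposures:
        raise EmptyInputError("exposure panel is empty")
    cfg.validate()

    taxa = {}
    for exp in sorted(exposures, key=lambda s: s.trait_id):
        taxa[exp.trait_id] = run_taxon(exp, outcome, cfg, ld)

    rows = []
    for tid, rep in taxa.items():
        for r in rep.results.values():
            rows.append(
                {"trait": tid, "method": r.method, "n_snp": r.n_snp,
                 "beta": r.beta, "se": r.se, "pval": r.pval}
            )
    results_table = pd.DataFrame(
        rows, columns=["trait", "method", "n_snp", "beta", "se", "pval"]
    )

    ivw_rows = results_table[results_table["method"] == "ivw"].copy()
    if cfg.use_fdr and len(ivw_rows):
        ivw_rows["p_screen"] = _bh_adjust(ivw_rows["pval"].to_numpy())
    else:
        ivw_rows["p_screen"] = ivw_rows["pval"]
    significant = ivw_rows.loc[ivw_rows["p_screen"] < cfg.sig, "trait"].tolist()

    report = PanelReport(taxa, results_table, significant)

    if replication is not None:
        for tid in significant:
            rep = taxa[tid]
            if rep.harmonized is None or rep.instruments is None:
                continue
            # same instruments, second outcome: re-estimation, not re-selection
            exp = next(e for e in exposures if e.trait_id == tid)
            h_rep = harmonize(
                exp.restrict(rep.instruments.snps), replication, cfg.palindromic_band
            )
            if h_rep.j < 2:
                continue
            r = ivw(h_rep, re_mode=cfg.re_mode)
            r.extra["trait"] = tid
            report.replication[tid] = r
        report.significant_replicated = [
            tid for tid, r in report.replication.items() if r.pval < cfg.sig
        ]

    if mediator_panel is not None and report.significant_replicated:
        screen = screen_mediators(
            mediator_panel, outcome, cfg.sig, ld,
            cfg.p_instr, cfg.r2, cfg.window_kb, cfg.f_min,
        )
        report.mediator_screen = screen
        med_by_id = {m.trait_id: m for m in mediator_panel}
        for tid in report.significant_replicated:
            exp = next(e for e in exposures if e.trait_id == tid)
            for mid, _ in screen.selected:
                report.mediation[(tid, mid)] = two_step_mediation(
                    exp, med_by_id[mid], outcome, ld,
                    cfg.p_instr, cfg.r2, cfg.window_kb, cfg.f_min,
                )
    return report


def write_report(report: PanelReport, outdir, cfg: RunConfig, input_paths=()) -> None:
    """Emit result tables, plot data and a JSON run manifest.

    Re-running an identical configuration reproduces every file
    byte-for-byte (no timestamps; fixed column orders and float formats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report.results_table.to_csv(
        outdir / "results.tsv", sep="\t", index=False, float_format="%.12g"
    )
    pretty = []
    for tid in sorted(report.taxa):
        for r in report.taxa[tid].results.values():
            pretty.append(
                {"trait": tid, "method": r.method, "n_snp": r.n_snp,
                 "or_95ci": format_or_ci(r), "pval": f"{r.pval:.3g}"}
            )
    pd.DataFrame(
        pretty, columns=["trait", "method", "n_snp", "or_95ci", "pval"]
    ).to_csv(outdir / "results_or.tsv", sep="\t", index=False)

    for tid, rep in sorted(report.taxa.items()):
        if rep.scatter is not None:
            rep.scatter.to_csv(
                outdir / f"scatter_{tid}.tsv", sep="\t", index=False, float_format="%.12g"
            )
            rep.funnel.to_csv(
                outdir / f"funnel_{tid}.tsv", sep="\t", index=False, float_format="%.12g"
            )
        if rep.loo:
            loo_df = pd.DataFrame(
                {
                    "omitted_snp": [row.omitted_snp or "ALL" for row in rep.loo],
                    "beta": [row.estimate.beta for row in rep.loo],
                    "se": [row.estimate.se for row in rep.loo],
                    "pval": [row.estimate.pval for row in rep.loo],
                }
            )
            loo_df.to_csv(
                outdir / f"leave_one_out_{tid}.tsv", sep="\t", index=False,
                float_format="%.12g",
            )

    manifest = {
        "package": "mrkit",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in input_paths
        },
        "significant": report.significant,
        "significant_replicated": report.significant_replicated,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def taxon_results_list(report: PanelReport):
    """Flatten a panel report into an MRResult list (for write_results_table)."""
    out = []
    for tid in sorted(report.taxa):
        out.extend(report.taxa[tid].results.values())
    return out


__all__ = [
    "RunConfig",
    "TaxonReport",
    "PanelReport",
    "run_taxon",
    "run_panel",
    "write_report",
    "derive_seed",
    "write_results_table",
]
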