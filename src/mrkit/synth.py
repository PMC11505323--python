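"""Synthetic GWAS summary statistics with known ground truth.

The generator works at the summary level — the level every estimator in
this package consumes.  For each SNP j a true instrument effect
``gamma_j ~ N(gamma_mean, gamma_sd^2)`` is drawn; the observed exposure
beta is ``gamma_j`` plus sampling noise ``se_x``, and the observed outcome
beta is ``theta * gamma_j + alpha_j`` plus noise ``se_y``, where ``alpha_j``
is a direct (pleiotropic) SNP-outcome effect: zero for valid instruments,
``N(pleiotropy_mean, pleiotropy_sd^2)`` for a configurable invalid
fraction, with optional additive outlier shifts on chosen SNPs.

Defaults emulate the study conditions this package is built around:
13 instruments per taxon with per-SNP F ≈ 20 (16S microbiome-abundance
GWAS of ~18k samples) against a binary-outcome GWAS of ~2k cases /
~300k controls whose log-odds SEs are around 0.15, and a protective
causal effect theta = ln 0.61 ≈ -0.494.

For mediation studies, :func:`simulate_mediation_triple` generates a
three-trait chain exposure → mediator → outcome.  The mediator receives
``beta1 * gamma_j`` through the exposure instruments *and carries its own
block of instruments* (effects ``delta_j``, transmitted to the outcome as
``beta2 * delta_j``): multivariable MR cannot identify the
mediator-on-outcome effect without mediator-specific instruments, which
is why two-step mediation analyses take the union of both traits'
instruments.

SNPs are generated LD-free (estimators assume independent instruments);
:func:`simulate_ld_table` builds block-structured pairwise-r² fixtures so
clumping can be exercised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SumStats

_NONPALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class MediationParams:
    """Ground-truth parameters of the exposure → mediator → outcome chain.

    beta1: exposure → mediator effect; beta2: mediator → outcome effect;
    theta_direct: exposure → outcome effect not through the mediator.
    ``n_mediator_snps`` mediator-specific instruments (default: as many as
    the exposure has) with effects ``N(delta_mean, delta_sd^2)`` (defaults:
    the exposure's gamma distribution); ``se_m`` is the mediator GWAS
    sampling SE.
    """

    beta1: float
    beta2: float
    theta_direct: float
    se_m: float = 0.004
    n_mediator_snps: Optional[int] = None
    delta_mean: Optional[float] = None
    delta_sd: Optional[float] = None


@dataclass
class SynthConfig:
    n_snps: int = 13
    theta: float = float(np.log(0.61))  # ≈ -0.4943, protective effect
    gamma_mean: float = 0.10
    gamma_sd: float = 0.02
    se_x: float = 0.022  # per-SNP F = gamma^2/se_x^2 ≈ 20
    se_y: float = 0.15
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_idx: tuple = ()
    outlier_shift: float = 0.0
    mediation: Optional[MediationParams] = None
    maf_range: tuple = (0.05, 0.5)
    palindromic: bool = False
    n_exposure: int = 18340
    n_outcome: int = 302143
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("sampling SEs must be > 0")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if any(i < 0 or i >= self.n_snps for i in self.outlier_idx):
            raise ValueError("outlier_idx out of range")
        if self.mediation is not None and self.mediation.se_m <= 0:
            raise ValueError("se_m must be > 0")


@dataclass
class PairTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # bool mask, True = no direct effect


@dataclass
class MediationTruth:
    beta1: float
    beta2: float
    theta_direct: float
    total: float
    proportion: float  # NaN when flagged undefined
    proportion_defined: bool
    gamma: np.ndarray = field(default=None, repr=False)
    delta: np.ndarray = field(default=None, repr=False)


def _snp_frame(rng, cfg, n, snp_ids, beta, se, eaf, alleles, n_samples):
    z = np.abs(beta / se)
    pval = np.clip(2 * sps.norm.sf(z), np.nextafter(0.0, 1.0), 1.0)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": alleles[0],
            "other_allele": alleles[1],
            "eaf": eaf,
            "beta": beta,
            "se": np.full(n, se) if np.isscalar(se) else se,
            "pval": pval,
            "n": n_samples,
        }
    )


def _draw_alleles(rng, n, palindromic: bool):
    pairs = _PALINDROMIC_PAIRS if palindromic else _NONPALINDROMIC_PAIRS
    idx = rng.integers(0, len(pairs), n)
    ea = np.array([pairs[i][0] for i in idx])
    oa = np.array([pairs[i][1] for i in idx])
    return ea, oa


def simulate_pair(cfg: SynthConfig):
    """Exposure and outcome summary statistics for one synthetic taxon.

    Returns ``(exposure, outcome, truth)``; identical config (including
    seed) gives bit-identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps

    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, J)
    alpha = np.zeros(J)
    n_invalid = int(round(cfg.pleiotropy_frac * J))
    valid = np.ones(J, dtype=bool)
    if n_invalid:
        invalid_idx = rng.choice(J, size=n_invalid, replace=False)
        alpha[invalid_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_invalid)
        valid[invalid_idx] = False
    if cfg.outlier_idx:
        idx = np.asarray(cfg.outlier_idx, dtype=int)
        alpha[idx] += cfg.outlier_shift
        valid[idx] = False

    bx = rng.normal(gamma, cfg.se_x)
    by = rng.normal(cfg.theta * gamma + alpha, cfg.se_y)
    eaf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], J)
    ea, oa = _draw_alleles(rng, J, cfg.palindromic)
    snp_ids = [f"rs{j + 1}" for j in range(J)]

    exposure = SumStats(
        "synthetic_exposure",
        _snp_frame(rng, cfg, J, snp_ids, bx, cfg.se_x, eaf, (ea, oa), cfg.n_exposure),
        trait_type="continuous",
    )
    outcome = SumStats(
        "synthetic_outcome",
        _snp_frame(rng, cfg, J, snp_ids, by, cfg.se_y, eaf, (ea, oa), cfg.n_outcome),
        trait_type="binary",
    )
    return exposure, outcome, PairTruth(cfg.theta, gamma, alpha, valid)


def simulate_mediation_triple(cfg: SynthConfig):
    """Exposure, mediator and outcome summary statistics with a known
    mediated path.

    The first ``cfg.n_snps`` SNPs are exposure instruments (gamma block);
    the following ``n_mediator_snps`` are mediator-specific instruments
    (delta block).  Truth: ``total = theta_direct + beta1*beta2`` and
    ``proportion = beta1*beta2 / total`` (flagged undefined when the total
    vanishes while the mediated path does not).
    """
    cfg.validate()
    med = cfg.mediation
    if med is None:
        raise ValueError("cfg.mediation must be set for a mediation triple")
    rng = np.random.default_rng(cfg.seed)

    Jx = cfg.n_snps
    Jm = med.n_mediator_snps if med.n_mediator_snps is not None else cfg.n_snps
    dmean = med.delta_mean if med.delta_mean is not None else cfg.gamma_mean
    dsd = med.delta_sd if med.delta_sd is not None else cfg.gamma_sd
    J = Jx + Jm

    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, Jx)
    delta = rng.normal(dmean, dsd, Jm)
    total = med.theta_direct + med.beta1 * med.beta2

    true_x = np.concatenate([gamma, np.zeros(Jm)])
    true_m = np.concatenate([med.beta1 * gamma, delta])
    true_y = np.concatenate([total * gamma, med.beta2 * delta])

    bx = rng.normal(true_x, cfg.se_x)
    bm = rng.normal(true_m, med.se_m)
    by = rng.normal(true_y, cfg.se_y)
    eaf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], J)
    ea, oa = _draw_alleles(rng, J, cfg.palindromic)
    snp_ids = [f"rs{j + 1}" for j in range(J)]

    exposure = SumStats(
        "synthetic_exposure",
        _snp_frame(rng, cfg, J, snp_ids, bx, cfg.se_x, eaf, (ea, oa), cfg.n_exposure),
    )
    mediator = SumStats(
        "synthetic_mediator",
        _snp_frame(rng, cfg, J, snp_ids, bm, med.se_m, eaf, (ea, oa), cfg.n_exposure),
    )
    outcome = SumStats(
        "synthetic_outcome",
        _snp_frame(rng, cfg, J, snp_ids, by, cfg.se_y, eaf, (ea, oa), cfg.n_outcome),
        trait_type="binary",
    )

    mediated = med.beta1 * med.beta2
    defined = not (abs(total) < 1e-12 and abs(mediated) > 0)
    proportion = mediated / total if defined else float("nan")
    truth = MediationTruth(
        med.beta1, med.beta2, med.theta_direct, total, proportion, defined, gamma, delta
    )
    return exposure, mediator, outcome, truth


def simulate_ld_table(
    n_snps: int,
    block_structure: Sequence[int],
    within_r2: float,
    seed: int = 0,
    snp_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Block-diagonal pairwise-r² table in 3-column long form.

    Within a block every pair has ``r2 = within_r2``; across blocks r² is 0
    (omitted rows, the sparse-table convention).  Diagonal entries are
    written with r² = 1.  ``seed`` is accepted for interface symmetry with
    the other generators; the table is deterministic.
    """
    if not 0.0 <= within_r2 <= 1.0:
        raise ValueError("within_r2 must lie in [0, 1]")
    if sum(block_structure) != n_snps:
        raise ValueError("block sizes must sum to n_snps")
    if snp_ids is None:
        snp_ids = [f"rs{j + 1}" for j in range(n_snps)]
    rows = [(s, s, 1.0) for s in snp_ids]
    start = 0
    for size in block_structure:
        block = snp_ids[start : start + size]
        for i in range(size):
            for k in range(i + 1, size):
                rows.append((block[i], block[k], within_r2))
        start += size
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
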