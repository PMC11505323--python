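import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats import SumStats
from mrkit.synth import SynthConfig, simulate_pair

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def three_snp_h() -> HarmonizedSet:
    """The 3-instrument worked example used for IVW/Q hand oracles."""
    return HarmonizedSet.from_arrays(
        bx=[0.1, 0.2, 0.15],
        sx=[0.01, 0.01, 0.01],
        by=[0.05, 0.08, 0.09],
        sy=[0.02, 0.03, 0.025],
    )


def make_sumstats(trait_id, snp_ids, beta, se, pval=None, eaf=None,
                  ea="A", oa="G", n=10000, trait_type="continuous", pos=None,
                  chrom=None):
    """Hand-built SumStats for fixtures."""
    beta = np.asarray(beta, dtype=float)
    J = len(beta)
    se = np.broadcast_to(np.asarray(se, dtype=float), (J,))
    if pval is None:
        from scipy import stats as sps
        pval = 2 * sps.norm.sf(np.abs(beta / se))
        pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": ea if isinstance(ea, (list, np.ndarray)) else [ea] * J,
            "other_allele": oa if isinstance(oa, (list, np.ndarray)) else [oa] * J,
            "eaf": eaf if eaf is not None else np.nan,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    if pos is not None:
        df["pos"] = pos
        df["chrom"] = chrom if chrom is not None else "1"
    return SumStats(trait_id, df, trait_type=trait_type)


def make_panel(n_taxa, true_effects, seed, n_snps=10, se_y=0.02, outcome_noise=None):
    """Panel of taxa with disjoint instrument blocks sharing one outcome.

    ``true_effects`` maps taxon index -> theta (missing = null taxon).
    Returns (exposures list, outcome SumStats).  ``outcome_noise`` draws an
    independent second outcome sample (replication cohort) when given a seed.
    """
    exposures, out_frames = [], []
    for k in range(n_taxa):
        theta = true_effects.get(k, 0.0)
        cfg = SynthConfig(n_snps=n_snps, theta=theta, se_y=se_y,
                          seed=seed * 1000 + k)
        e, o, _ = simulate_pair(cfg)
        rename = {f"rs{j + 1}": f"t{k}_rs{j + 1}" for j in range(n_snps)}
        e.table["snp_id"] = e.table["snp_id"].map(rename)
        o.table["snp_id"] = o.table["snp_id"].map(rename)
        e.trait_id = f"taxon_{k}"
        exposures.append(e)
        out_frames.append(o.table)
    out_df = pd.concat(out_frames, ignore_index=True)
    if outcome_noise is not None:
        rng = np.random.default_rng(outcome_noise)
        out_df = out_df.copy()
        out_df["beta"] = rng.normal(out_df["beta"], out_df["se"] * 0.5)
    return exposures, SumStats("outcome", out_df, trait_type="binary")
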