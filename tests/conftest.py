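import logging

import numpy as np
import pandas as pd
import pytest

from crossmeta import simulate as sim

logging.getLogger("crossmeta").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def null_collection():
    """Four independent null traits, disjoint cohorts (quantitative)."""
    cfg = sim.SimConfig(
        n_variants=4000, n_blocks=4000, block_rho=0.0,
        n_traits=4, cohort_sizes=(1500,) * 4, study_traits=(0, 1, 2, 3),
        n_shared_causal=0, n_discordant_causal=0, n_specific_causal=0,
        seed=42)
    return sim.simulate_collection(cfg, quantitative=True)


@pytest.fixture(scope="session")
def signal_collection():
    """Four traits with planted shared/discordant/specific effects.

    Effects are strong enough that planted variants reach genome-wide
    significance in the cross-trait meta-analysis.
    """
    cfg = sim.SimConfig(
        n_variants=1500, n_blocks=150, block_rho=0.6,
        n_traits=4, cohort_sizes=(8000,) * 4, study_traits=(0, 1, 2, 3),
        n_shared_causal=10, n_discordant_causal=5, n_specific_causal=4,
        effect_size_sd=0.12, prevalence=0.1, seed=7)
    return sim.simulate_collection(cfg)


@pytest.fixture(scope="session")
def small_panel():
    cfg = sim.SimConfig(
        n_variants=200, n_blocks=20, block_rho=0.8,
        n_traits=1, cohort_sizes=(100,), study_traits=(0,),
        n_shared_causal=0, n_discordant_causal=0, n_specific_causal=0,
        seed=5)
    return sim.simulate_genotypes(cfg, 1500, np.random.default_rng(5))


def toy_sumstats(z, snps=None, n=1000.0, chrom="1"):
    """Small canonical summary-statistics frame from a Z vector."""
    from crossmeta.sumstats import z_to_p
    z = np.asarray(z, dtype=float)
    m = z.size
    if snps is None:
        snps = [f"rs{i + 1}" for i in range(m)]
    return pd.DataFrame({
        "SNP": snps, "CHR": chrom, "BP": 10_000 * (np.arange(m) + 1),
        "A1": "A", "A2": "G", "Z": z, "P": z_to_p(z), "N": float(n),
    })
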