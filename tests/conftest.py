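import numpy as np
import pandas as pd
import pytest

from funcpanel.adjust import DesignSpec, build_design, fit_and_adjust
from funcpanel.simdata import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(
        n_individuals=500,
        n_chromosomes=3,
        variants_per_chromosome=300,
        n_causal_per_trait=25,
        seed=1,
    )


@pytest.fixture(scope="session")
def sim_art(sim_config):
    """One small simulated study shared across the suite."""
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def adjusted(sim_art, sim_config):
    raw = sim_art["phenotypes"]
    design = build_design(
        raw,
        DesignSpec(
            factors=("contemporary_group", "breed"),
            covariates=("heterosis", "inbreeding"),
        ),
    )
    _, adj = fit_and_adjust(raw, design, list(sim_config.trait_names()))
    return adj.set_index("individual_id")


def independent_genotypes(n, m, seed, freq_low=0.1, freq_high=0.5):
    """Genotype matrix with mutually independent binomial variants.

    Used for calibration tests where LD between test statistics would
    break binomial error bounds.
    """
    from funcpanel._core import GenotypeMatrix

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_low, freq_high, size=m)
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    gm = GenotypeMatrix(
        individual_ids=[f"i{i:04d}" for i in range(n)],
        variant_ids=[f"chr1:{1000 * (j + 1)}" for j in range(m)],
        dosage=dosage,
    )
    catalog = pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chromosome": 1,
            "position_bp": [1000 * (j + 1) for j in range(m)],
            "ref_allele": "A",
            "alt_allele": "C",
            "maf": gm.maf(),
            "classes": [frozenset()] * m,
        }
    )
    return gm, catalog
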