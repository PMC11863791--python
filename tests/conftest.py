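import numpy as np
import pandas as pd
import pytest

from gsmrpipe import SimConfig, build_grm, simulate_genotypes, simulate_traits


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(
        n_individuals=300, n_chromosomes=3, snps_per_chrom=120,
        n_causal_exposure=20, n_pleiotropic=2, seed=5,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    return simulate_genotypes(tiny_config)


@pytest.fixture(scope="session")
def cohort1500():
    """A mid-size cohort with h2 = 0.3 traits and its autosomal GRM."""
    cfg = SimConfig(
        n_individuals=1500, n_chromosomes=4, snps_per_chrom=200,
        h2_exposure=0.3, h2_outcome=0.3, n_causal_exposure=50,
        n_pleiotropic=3, b_xy_true=0.4, seed=3,
    )
    panel = simulate_genotypes(cfg)
    phenos, truth = simulate_traits(panel, cfg)
    grm = build_grm(panel)
    return cfg, panel, phenos, truth, grm


def make_panel(dosages, chroms=None, bps=None, x_chrom=None):
    """Hand-built panel for arithmetic examples."""
    from gsmrpipe import GenotypePanel

    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    markers = pd.DataFrame({
        "id": [f"s{j}" for j in range(m)],
        "chrom": chroms if chroms is not None else [1] * m,
        "bp": bps if bps is not None else np.arange(1, m + 1) * 1000,
        "a1": ["A"] * m,
        "a2": ["G"] * m,
        "freq": dosages.mean(axis=0) / 2.0,
    })
    return GenotypePanel(dosages=dosages, markers=markers,
                         samples=[f"i{k}" for k in range(n)], x_chrom=x_chrom)
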