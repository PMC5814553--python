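import numpy as np
import pandas as pd
import pytest

import traitgs as tg


@pytest.fixture(scope="session")
def small_study():
    """A 200-line, 1000-marker panel with two correlated traits."""
    cfg = tg.SimulationConfig(n_genotypes=200, n_markers=1000,
                              heritabilities=(0.3, 0.8),
                              genetic_correlation=0.8,
                              residual_correlation=0.2,
                              n_qtl=1000, seed=11)
    return tg.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_grm(small_study):
    return tg.vanraden_grm(small_study.genotypes)


@pytest.fixture(scope="session")
def tiny_grm():
    """A well-conditioned 40-genotype relationship matrix for oracle checks."""
    cfg = tg.SimulationConfig(n_genotypes=40, n_markers=400, seed=5)
    return tg.vanraden_grm(tg.simulate_genotypes(cfg))
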