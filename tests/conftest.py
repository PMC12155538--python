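import numpy as np
import pytest

from coxsusie import SimulationConfig, SurvivalOutcome, make_finemap_dataset


@pytest.fixture
def toy_tied_outcome():
    """n = 6 with two tied event times; genotypes in {0, 1, 2}."""
    times = np.array([2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    status = np.array([1, 1, 1, 0, 1, 0])
    x = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
    return x, SurvivalOutcome(times=times, status=status)


@pytest.fixture
def medium_dataset():
    """n = 400, p = 30 correlated-genotype dataset with one causal variant."""
    cfg = SimulationConfig(n=400, p=30, maf=0.3, ld_rho=0.6,
                           causal_indices=(10,), effects=(0.8,),
                           target_censoring=0.2, seed=7)
    return make_finemap_dataset(cfg)
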