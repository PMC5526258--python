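import numpy as np
import pandas as pd
import pytest

from longmi.cohort import default_dgm_params, generate_cohort
from longmi.impute import ImputationConfig
from longmi.missingness import MissingnessSpec, apply_missingness


@pytest.fixture(scope="session")
def dgm():
    """Calibrated default generating parameters for the weak-association scenario."""
    return default_dgm_params(1.1)


@pytest.fixture(scope="session")
def panel_small(dgm):
    """A complete cohort of 800 children."""
    return generate_cohort(800, dgm, seed=101)


@pytest.fixture(scope="session")
def panel_medium(dgm):
    """A complete cohort of 5000 children (the study's per-replicate size)."""
    return generate_cohort(5000, dgm, seed=202)


@pytest.fixture(scope="session")
def masked_small(panel_small):
    """panel_small with 25% MCAR missingness imposed on the exposure."""
    pattern = apply_missingness(
        panel_small, MissingnessSpec(mechanism="MCAR", target_final=0.25), seed=7
    )
    return pattern.mask(panel_small)


@pytest.fixture()
def quick_imp_config():
    """Small iteration counts for unit tests; same code path as defaults."""
    return ImputationConfig(m=3, fcs_cycles=5, da_burnin=50, da_thin=10, twofold_among=5, seed=11)
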