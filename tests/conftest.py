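import numpy as np
import pandas as pd
import pytest

from bisim.synthetic import (PopulationConfig, TrueHealthModel, gen_panel,
                             gen_cross_section, default_panel_mix)


@pytest.fixture(scope="session")
def truth():
    return TrueHealthModel()


@pytest.fixture(scope="session")
def noise_free_truth():
    # sigma_resid must stay positive; 1e-8 is numerically noise-free
    return TrueHealthModel(sigma_individual=0.0, sigma_resid=1e-8,
                           lag_coefficient=0.0)


@pytest.fixture(scope="session")
def panel_medium(truth):
    cfg = PopulationConfig(n_households=1500, n_waves=12, seed=42,
                           demographic_mix=default_panel_mix())
    return gen_panel(cfg, truth)


@pytest.fixture(scope="session")
def panel_noise_free(noise_free_truth):
    cfg = PopulationConfig(n_households=400, n_waves=6, seed=7,
                           demographic_mix=default_panel_mix())
    return gen_panel(cfg, noise_free_truth)


@pytest.fixture(scope="session")
def cross_section_small():
    cfg = PopulationConfig(n_households=600, seed=3)
    return gen_cross_section(cfg)
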