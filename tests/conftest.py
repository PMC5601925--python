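import numpy as np
import pandas as pd
import pytest

from tetrascreen import coding
from tetrascreen.profiling import LogicleParams
from tetrascreen.synthetic import (ExperimentSpec, NoiseModel, default_experiment,
                                   simulate_experiment)


@pytest.fixture(scope="session")
def panel():
    return coding.default_channels()


@pytest.fixture(scope="session")
def antigen_panel():
    return coding.build_default_panel()


@pytest.fixture(scope="session")
def schemes(antigen_panel, panel):
    return coding.default_schemes(antigen_panel, panel, seed=0)


@pytest.fixture(scope="session")
def logicle():
    return LogicleParams()


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def noise_free():
    return NoiseModel.noise_free()


@pytest.fixture(scope="session")
def small_spec():
    return default_experiment(n_cells={"tumour": 30_000, "spleen": 10_000,
                                       "dLN": 10_000, "ndLN": 10_000})


@pytest.fixture(scope="session")
def small_sim(small_spec, schemes, noise, panel):
    """One noisy replicate of the small 4-tissue experiment (config A only)."""
    return simulate_experiment(small_spec, schemes[0], noise, seed=11, panel=panel)["A"]


@pytest.fixture(scope="session")
def noise_free_sim(small_spec, schemes, noise_free, panel):
    return simulate_experiment(small_spec, schemes[0], noise_free, seed=12,
                               panel=panel)["A"]


@pytest.fixture(scope="session")
def tumour_events(small_sim):
    return small_sim["tumour"]
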