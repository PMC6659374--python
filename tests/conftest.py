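import numpy as np
import pytest
from hypothesis import settings

import urinmr
from urinmr import synthspec

settings.register_profile("ci", deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return urinmr.default_signature_library()


@pytest.fixture(scope="session")
def lib_map(library):
    return {s.name: s for s in library}


@pytest.fixture(scope="session")
def sim_config():
    return synthspec.SimulationConfig()


@pytest.fixture(scope="session")
def mean_conc():
    calib = synthspec.load_cohort_calibration()
    return {m: float(calib.loc[m, "mean_umol_per_L"]) for m in calib.index}


@pytest.fixture(scope="session")
def rendered_sample(library, sim_config, mean_conc):
    """One default-noise spectrum of the calibration means, with truth."""
    in_tube = {k: v / sim_config.dilution for k, v in mean_conc.items()}
    spec, offsets = synthspec.render_sample(library, in_tube, sim_config, seed=123)
    return spec, mean_conc, offsets


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
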