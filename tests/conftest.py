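from dataclasses import replace

import numpy as np
import pytest

from faimsprm import method, simulate


@pytest.fixture(scope="session")
def table1_targets():
    return method.load_method_table()


@pytest.fixture(scope="session")
def single_target(table1_targets):
    # EGFR IPLENLQIIR 2+, narrowed schedule window for fast runs
    return replace(table1_targets[0], rt_window_half_min=0.35)


@pytest.fixture()
def sim_config(single_target):
    return simulate.SimConfig(
        targets=(single_target,),
        response_factor=2.0,
        background_flux=200.0,
        faims_background_retention=0.25,
        measurement_cv=0.0,
        rt_jitter_s=0.0,
        seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
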