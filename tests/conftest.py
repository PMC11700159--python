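from dataclasses import replace

import numpy as np
import pytest

from clampkit import (
    current_clamp_protocol,
    test_pulse_protocol,
    voltage_clamp_protocol,
    wt_params,
)
from clampkit.synthetic_cells import simulate_cell


@pytest.fixture(scope="session")
def noiseless_wt_params():
    return replace(wt_params(), noise_sd_mV=0.0, noise_sd_pA=0.0)


@pytest.fixture(scope="session")
def noiseless_wt_cell(noiseless_wt_params):
    """Full study battery for one noiseless wild-type cell (both conditions)."""
    recs, truth = simulate_cell(
        noiseless_wt_params, "wt_cell", "WT", "vehicle", seed=11
    )
    return recs, truth


@pytest.fixture(scope="session")
def short_cc_protocol():
    """A small current-clamp grid for fast unit tests."""
    return current_clamp_protocol(
        start_pA=-100, stop_pA=480, increment_pA=58.0, repetitions=2,
        pre_s=0.05, step_s=0.25, post_s=0.1,
    )


@pytest.fixture(scope="session")
def vc_protocol():
    return voltage_clamp_protocol()


@pytest.fixture(scope="session")
def tp_protocol():
    return test_pulse_protocol()
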