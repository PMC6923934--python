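import numpy as np
import pytest

import tevckit as tk


@pytest.fixture
def pept1a_charge():
    """Acidic-condition charge-movement scenario used throughout."""
    return tk.ChargeMovementParams(Q_max=41.0, V_half=-57.6, sigma=33.6,
                                   tau_peak=8.0)


@pytest.fixture
def pept1a_dose():
    return tk.DoseResponseModel(K_half=0.24, I_max=-75.76)


@pytest.fixture
def protocol_10k():
    """Standard 10-step protocol sampled at 10 kHz (resolves the 0.8 ms
    capacitive transient)."""
    return tk.paper_protocol(sample_rate=10000.0)


@pytest.fixture
def cell():
    return tk.CellParams()


@pytest.fixture
def presets():
    return tk.scenario_presets()


@pytest.fixture
def noiseless_pss_traces(protocol_10k, cell, pept1a_charge):
    """Noiseless no-substrate sweeps under the acidic charge scenario."""
    return tk.simulate_sweep(protocol_10k, cell, pept1a_charge, None,
                             S=0.0, noise_sd=0.0, seed=0)
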