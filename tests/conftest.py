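import numpy as np
import pytest

from lsanet import NeuronPopulation, RunConfig, SynapticState


@pytest.fixture
def rs_neuron():
    """Single regular-spiking neuron at its reset state."""
    return NeuronPopulation.create(1, 1)


@pytest.fixture
def triple():
    """Three excitatory neurons, fully connected, zero weights."""
    pop = NeuronPopulation.create(3, 3)
    exists = ~np.eye(3, dtype=bool)
    syn = SynapticState(w=np.zeros((3, 3)), exists_mask=exists,
                        is_excitatory=pop.is_excitatory, w_max=10.0)
    return pop, syn


@pytest.fixture
def tiny_run_config():
    """A fast deterministic protocol config for IO round-trip tests."""
    return RunConfig.from_dict(dict(
        n_neurons=10, frac_inhibitory=0.2, zone_sizes=(2, 2, 2),
        sigma_noise_mv=2.0, stim_amplitude_mv=10.0,
        stop_a_min=1, stop_b_max=None, w_max=10.0, w_high=5.0,
        delay_min_ms=50, delay_max_ms=80, timeout_ms=500,
        duration_ms=2000, chunk_ms=1000, seed=7, record_raster=True,
    ))
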