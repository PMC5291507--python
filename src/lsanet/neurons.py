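"""Izhikevich neuron populations and per-millisecond input assembly.

The network is made of two-variable quadratic integrate-and-fire neurons
(membrane potential v, recovery variable u):

    v' = 0.04 v^2 + 5 v + 140 - u + I,     u' = a (b v - u),

with a spike recorded when v reaches 30 mV, after which v <- c and
u <- u + d.  Excitatory neurons use the regular-spiking parameter set
(a=0.02, b=0.2, c=-65, d=8) and inhibitory neurons the fast-spiking set
(a=0.1, b=0.2, c=-65, d=2).  The simulation step is 1 ms; by default v is
advanced with two 0.5 ms sub-steps per ms for numerical stability, u once
per ms.

Each neuron's input per step is I = I_synaptic + e_external + m_noise:
weights of presynaptic neurons that fired on the previous step, external
stimulation channels (1000 Hz, i.e. applied every step while active), and
fresh zero-mean Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import SPIKE_THRESHOLD_MV

__all__ = [
    "RS_PARAMS",
    "FS_PARAMS",
    "SPIKE_THRESHOLD_MV",
    "NeuronPopulation",
    "InputVector",
    "StimulusChannel",
    "NoiseConfig",
    "izhikevich_step",
    "gather_inputs",
]

#: regular-spiking (excitatory) Izhikevich coefficients
RS_PARAMS = {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}
#: fast-spiking (inhibitory) Izhikevich coefficients
FS_PARAMS = {"a": 0.1, "b": 0.2, "c": -65.0, "d": 2.0}


@dataclass
class NeuronPopulation:
    """Per-neuron Izhikevich parameters and dynamic state.

    The first ``n_excitatory`` neurons are excitatory (regular spiking), the
    remainder inhibitory (fast spiking).  State is initialised at the reset
    potential v = c, u = b v.
    """

    params_a: np.ndarray
    params_b: np.ndarray
    params_c: np.ndarray
    params_d: np.ndarray
    is_excitatory: np.ndarray
    v: np.ndarray
    u_recovery: np.ndarray

    @property
    def n_total(self) -> int:
        return self.v.size

    @property
    def n_excitatory(self) -> int:
        return int(self.is_excitatory.sum())

    @classmethod
    def create(cls, n_total: int, n_excitatory: int) -> "NeuronPopulation":
        if not 0 <= n_excitatory <= n_total:
            raise ValueError("n_excitatory must be between 0 and n_total")
        is_exc = np.zeros(n_total, bool)
        is_exc[:n_excitatory] = True
        a = np.where(is_exc, RS_PARAMS["a"], FS_PARAMS["a"]).astype(float)
        b = np.where(is_exc, RS_PARAMS["b"], FS_PARAMS["b"]).astype(float)
        c = np.where(is_exc, RS_PARAMS["c"], FS_PARAMS["c"]).astype(float)
        d = np.where(is_exc, RS_PARAMS["d"], FS_PARAMS["d"]).astype(float)
        v = c.copy()
        u = b * v
        return cls(a, b, c, d, is_exc, v, u)

    def copy(self) -> "NeuronPopulation":
        return NeuronPopulation(
            self.params_a.copy(), self.params_b.copy(), self.params_c.copy(),
            self.params_d.copy(), self.is_excitatory.copy(),
            self.v.copy(), self.u_recovery.copy(),
        )


@dataclass
class InputVector:
    """Element-wise decomposition I_total = I_synaptic + e_external + m_noise."""

    I_synaptic: np.ndarray
    e_external: np.ndarray
    m_noise: np.ndarray

    @property
    def I_total(self) -> np.ndarray:
        return self.I_synaptic + self.e_external + self.m_noise


@dataclass
class StimulusChannel:
    """External stimulation of a fixed neuron set.

    While ``active``, every target receives ``amplitude`` mV each step
    (frequency 1000 Hz at the 1 ms resolution).
    """

    targets: np.ndarray
    amplitude: float
    active: bool = True
    frequency_hz: float = 1000.0

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.int64)


@dataclass
class NoiseConfig:
    """Zero-mean Gaussian noise, std ``sigma`` mV, independent per neuron/step."""

    sigma: float
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        self._rng = np.random.default_rng(self.seed)

    def sample(self, n: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.zeros(n)
        return self._rng.normal(0.0, self.sigma, n)


def izhikevich_step(
    pop: NeuronPopulation,
    inputs: "InputVector | np.ndarray",
    dt: float = 1.0,
    half_step: bool = True,
) -> np.ndarray:
    """Advance the population one 1 ms step under the given input.

    Returns the boolean spike flags for this step; spiking neurons are reset
    (v <- c, u <- u + d) in place.  Raises ``FloatingPointError`` if the
    state becomes non-finite (numerical blow-up).
    """
    if dt != 1.0:
        raise ValueError("the simulation step is fixed at 1 ms")
    I = inputs.I_total if isinstance(inputs, InputVector) else np.asarray(inputs, float)
    if I.shape != pop.v.shape:
        raise ValueError("input vector length does not match population size")
    fired = np.zeros(pop.n_total, bool)
    _kernels.izh_update(
        pop.v, pop.u_recovery, pop.params_a, pop.params_b,
        pop.params_c, pop.params_d, I, half_step, fired,
    )
    return fired


def gather_inputs(
    syn,
    spikes_prev: np.ndarray,
    stimuli: "list[StimulusChannel] | None" = None,
    noise: "NoiseConfig | None" = None,
    stp=None,
) -> InputVector:
    """Assemble per-neuron input from last step's spikes, stimuli and noise.

    ``syn`` is a :class:`~lsanet.plasticity.SynapticState`; if ``stp`` (an
    :class:`~lsanet.plasticity.STPState`) is given, excitatory presynaptic
    rows are scaled by their u*x release factor.
    """
    n = syn.w.shape[0]
    spikes_prev = np.asarray(spikes_prev, bool)
    if spikes_prev.size != n:
        raise ValueError("spike flag length does not match network size")
    I_syn = np.zeros(n)
    stp_on = stp is not None
    stp_x = stp.x_depress if stp_on else np.ones(n)
    stp_u = stp.u_facil if stp_on else np.ones(n)
    _kernels.synaptic_input(
        syn.w, syn.exists_mask, spikes_prev, syn.is_excitatory,
        stp_on, stp_x, stp_u, I_syn,
    )
    e_ext = np.zeros(n)
    for ch in stimuli or []:
        if ch.targets.size and (ch.targets.min() < 0 or ch.targets.max() >= n):
            raise ValueError("stimulus channel targets a neuron outside the network")
        if ch.active:
            np.add.at(e_ext, ch.targets, ch.amplitude)
    m = noise.sample(n) if noise is not None else np.zeros(n)
    return InputVector(I_syn, e_ext, m)
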