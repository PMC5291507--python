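"""Synaptic plasticity: additive STDP, weight decay, short-term plasticity.

STDP acts only on excitatory-to-excitatory connections.  The weight change
for a pre/post spike-time difference s = t_post - t_pre is

    dw(s) =  A exp(-s/tau)   for s > 0   (pre before post: potentiation)
    dw(s) = -A exp( s/tau)   for s < 0   (post before pre: depression)
    dw(0) =  0,

with A = 0.1 and tau = 20 ms by default.  Pairing is nearest-spike: each new
spike pairs once with the counterpart neuron's most recent spike, ignored
beyond a 5 tau = 100 ms cutoff where dw is negligible.  Weights are clipped
to [0, w_max] after every update; non-plastic connections (any involving an
inhibitory neuron) keep their initial weight apart from the optional global
decay w <- (1 - mu) w.

Short-term plasticity (STP) follows the phenomenological depression /
facilitation model: each excitatory presynaptic neuron carries a depression
variable x in (0, 1] and a facilitation variable u in [U, 1),

    dx/dt = (1 - x)/tau_d - u x f,      du/dt = (U - u)/tau_f + U (1 - u) f,

with U = 0.2, tau_d = 200 ms, tau_f = 600 ms, and f the spike indicator.
The effective transmitted weight is w* = u x w (u x never exceeds 1), which
suppresses sustained high-frequency firing and thereby network-wide bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import NO_SPIKE

__all__ = [
    "SynapticState",
    "STPState",
    "STDPConfig",
    "stdp_delta",
    "apply_stdp",
    "apply_decay",
    "stp_step",
    "effective_weights",
]


@dataclass
class STDPConfig:
    A: float = 0.1
    tau: float = 20.0
    pairing: str = "nearest"
    cutoff: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.pairing != "nearest":
            raise ValueError(f"unknown STDP pairing scheme: {self.pairing!r}")
        if self.cutoff is None:
            # pairing window: pre/post spikes farther apart than one time
            # constant (20 ms by default) do not pair
            self.cutoff = self.tau


@dataclass
class SynapticState:
    """Weight matrix and plasticity bookkeeping.

    ``w[j, i]`` is the weight from presynaptic neuron j to postsynaptic
    neuron i.  ``plastic_mask`` marks excitatory->excitatory connections
    (the only ones STDP touches); ``exists_mask`` marks present connections
    (self-connections are always absent).  ``last_spike_time`` supports
    nearest-spike STDP pairing.
    """

    w: np.ndarray
    exists_mask: np.ndarray
    is_excitatory: np.ndarray
    w_max: float
    last_spike_time: np.ndarray = None  # type: ignore[assignment]
    plastic_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        n = self.w.shape[0]
        if self.w.shape != (n, n) or self.exists_mask.shape != (n, n):
            raise ValueError("weight and existence matrices must be square and equal shape")
        if np.any(np.diag(self.exists_mask)):
            raise ValueError("self-connections are forbidden")
        if self.last_spike_time is None:
            self.last_spike_time = np.full(n, NO_SPIKE, dtype=np.int64)
        if self.plastic_mask is None:
            exc = self.is_excitatory
            self.plastic_mask = (
                self.exists_mask & exc[:, None] & exc[None, :]
            )
            np.fill_diagonal(self.plastic_mask, False)
        self.w = self.w * self.exists_mask  # absent connections carry weight 0

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def copy(self) -> "SynapticState":
        return SynapticState(
            self.w.copy(), self.exists_mask.copy(), self.is_excitatory.copy(),
            self.w_max, self.last_spike_time.copy(), self.plastic_mask.copy(),
        )


@dataclass
class STPState:
    """Per-presynaptic-neuron depression (x) and facilitation (u) variables."""

    x_depress: np.ndarray
    u_facil: np.ndarray
    U: float = 0.2
    tau_d: float = 200.0
    tau_f: float = 600.0

    @classmethod
    def create(cls, n: int, U: float = 0.2, tau_d: float = 200.0,
               tau_f: float = 600.0) -> "STPState":
        # rest state: fully recovered resources, baseline release probability
        return cls(np.ones(n), np.full(n, U), U, tau_d, tau_f)

    def copy(self) -> "STPState":
        return STPState(self.x_depress.copy(), self.u_facil.copy(),
                        self.U, self.tau_d, self.tau_f)


def stdp_delta(s: float, config: STDPConfig | None = None) -> float:
    """Weight change for spike-time difference s = t_post - t_pre (ms)."""
    cfg = config or STDPConfig()
    if s > 0:
        return cfg.A * np.exp(-s / cfg.tau)
    if s < 0:
        return -cfg.A * np.exp(s / cfg.tau)
    return 0.0


def apply_stdp(
    syn: SynapticState,
    spikes_now: np.ndarray,
    t: int,
    config: STDPConfig | None = None,
    update_last_spike: bool = True,
) -> SynapticState:
    """Apply nearest-pair STDP for the spikes of step ``t`` (in place).

    Every plastic connection with one endpoint spiking now and the other
    having a recorded spike within the pairing cutoff is updated by
    ``stdp_delta`` of the interval, then clipped to [0, w_max].  The
    last-spike bookkeeping is advanced afterwards unless the caller manages
    it (as the protocol kernel does).
    """
    cfg = config or STDPConfig()
    spikes_now = np.asarray(spikes_now, bool)
    _kernels.stdp_apply(
        syn.w, syn.plastic_mask, spikes_now, syn.last_spike_time,
        int(t), cfg.A, cfg.tau, cfg.cutoff, syn.w_max,
    )
    if update_last_spike:
        syn.last_spike_time[spikes_now] = int(t)
    return syn


def apply_decay(syn: SynapticState, mu: float) -> SynapticState:
    """Multiplicative decay w <- (1 - mu) w on all existing connections."""
    if not 0.0 <= mu < 1.0:
        raise ValueError("decay rate mu must be in [0, 1)")
    _kernels.weight_decay(syn.w, syn.exists_mask, mu)
    return syn


def stp_step(stp: STPState, spikes_now: np.ndarray,
             is_excitatory: np.ndarray | None = None,
             dt: float = 1.0) -> STPState:
    """Advance the depression/facilitation variables one Euler step (in place)."""
    spikes_now = np.asarray(spikes_now, bool)
    if is_excitatory is None:
        is_excitatory = np.ones(stp.x_depress.size, bool)
    _kernels.stp_update(
        stp.x_depress, stp.u_facil, spikes_now, np.asarray(is_excitatory, bool),
        stp.U, stp.tau_d, stp.tau_f, dt,
    )
    return stp


def effective_weights(syn: SynapticState, stp: STPState | None = None) -> np.ndarray:
    """Weights as seen by input gathering: w* = u x w on excitatory rows.

    STP modulates the output weights of excitatory neurons (onto both
    excitatory and inhibitory targets); inhibitory rows and disabled STP
    return the raw weights.
    """
    if stp is None:
        return syn.w.copy()
    gain = np.where(syn.is_excitatory, stp.u_facil * stp.x_depress, 1.0)
    return gain[:, None] * syn.w
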