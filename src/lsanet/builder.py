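"""Network construction: topologies, initial weights, and zone assignment.

Three topologies are supported:

* ``fully_connected`` — every ordered pair of distinct neurons is connected
  (the 100-neuron networks: 80 excitatory / 20 inhibitory, excitatory
  weights U(0, w_high), inhibitory weights U(-w_high, 0)).
* ``sparse_fixed_outdegree`` — each neuron draws M output targets with
  replacement among the other neurons; duplicate draws collapse, so the
  realised out-degree can be below M.
* ``chain3`` — three excitatory neurons, all six ordered pairs connected
  (the minimal reinforcement / pruning experiments).

Zones (stimulated input zone, monitored output zones) are disjoint subsets
of the excitatory neurons, drawn uniformly at random or taken as the first
indices for reproducible fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neurons import NeuronPopulation
from .plasticity import SynapticState

__all__ = ["Topology", "ZoneLayout", "build_network", "assign_zones",
           "forbid_direct_io"]


@dataclass
class Topology:
    kind: str = "fully_connected"
    n_neurons: int = 100
    frac_inhibitory: float = 0.2
    w_max: float = 10.0
    weight_init: str = "uniform"   # "uniform" magnitude or "offset_uniform"
    w_high: float = 5.0            # uniform: |w| ~ U(0, w_high)
    weight_mean: float = 5.0       # offset_uniform: |w| = mean + U(-var, var)
    weight_variance: float = 1.0
    connections_per_neuron: int = 20  # sparse topology only

    def __post_init__(self):
        if self.kind not in ("fully_connected", "sparse_fixed_outdegree", "chain3"):
            raise ValueError(f"unknown topology kind: {self.kind!r}")
        if self.weight_init not in ("uniform", "offset_uniform"):
            raise ValueError(f"unknown weight_init: {self.weight_init!r}")
        if not 0.0 <= self.frac_inhibitory < 1.0:
            raise ValueError("frac_inhibitory must be in [0, 1)")


@dataclass
class ZoneLayout:
    """Disjoint neuron-index zones, all subsets of the excitatory neurons.

    ``zones[0]`` is the (first) input zone; ``zones[1]``/``zones[2]`` are
    output zones A and B for the training protocols.  The robot uses four
    zones (left/right sensor inputs, left/right steering outputs).
    """

    zones: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.zones = tuple(np.asarray(z, dtype=np.int64) for z in self.zones)
        seen: set[int] = set()
        for z in self.zones:
            zs = set(int(i) for i in z)
            if zs & seen:
                raise ValueError("zones must be pairwise disjoint")
            seen |= zs

    @property
    def input_zone(self) -> np.ndarray:
        return self.zones[0]

    @property
    def output_zone_a(self) -> np.ndarray:
        return self.zones[1]

    @property
    def output_zone_b(self) -> np.ndarray:
        if len(self.zones) < 3:
            return np.empty(0, dtype=np.int64)
        return self.zones[2]


def _signed(magnitude: np.ndarray, is_exc_pre: np.ndarray) -> np.ndarray:
    """Inhibitory neurons emit negative weights; excitatory positive."""
    sign = np.where(is_exc_pre, 1.0, -1.0)
    return magnitude * sign[:, None] if magnitude.ndim == 2 else magnitude * sign


def build_network(topology: Topology, seed: int) -> tuple[NeuronPopulation, SynapticState]:
    """Construct a seeded population and synaptic state for a topology.

    Weight signs follow the presynaptic neuron's type; the plastic mask is
    excitatory->excitatory; self-connections never exist.
    """
    t = topology
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11CE]))
    n = t.n_neurons
    if t.kind == "chain3":
        n = 3
        n_exc = 3
    else:
        n_exc = n - int(round(t.frac_inhibitory * n))
    pop = NeuronPopulation.create(n, n_exc)
    exc = pop.is_excitatory

    exists = np.zeros((n, n), bool)
    w = np.zeros((n, n))
    if t.kind in ("fully_connected", "chain3"):
        exists[:] = True
        np.fill_diagonal(exists, False)
        mag = rng.uniform(0.0, t.w_high, (n, n))
        w = _signed(mag, exc)
    else:  # sparse_fixed_outdegree
        m = t.connections_per_neuron
        for j in range(n):
            others = np.concatenate([np.arange(j), np.arange(j + 1, n)])
            targets = rng.choice(others, size=m, replace=True)
            for i in targets:
                exists[j, i] = True
                if t.weight_init == "uniform":
                    mag = rng.uniform(0.0, t.w_high)
                else:
                    # sweep initialisation: |w| = mean + U(-v, v), re-drawn per
                    # draw; duplicates overwrite; clipped to preserve sign
                    mag = t.weight_mean + rng.uniform(-t.weight_variance,
                                                      t.weight_variance)
                    mag = max(mag, 0.0)
                w[j, i] = mag if exc[j] else -mag
    w *= exists

    syn = SynapticState(w=w, exists_mask=exists, is_excitatory=exc, w_max=t.w_max)
    return pop, syn


def assign_zones(
    pop: NeuronPopulation,
    sizes: tuple[int, ...],
    seed: int,
    fixed: bool = False,
) -> ZoneLayout:
    """Pick pairwise-disjoint zones of the given sizes among excitatory neurons.

    ``fixed=True`` takes consecutive low indices instead of sampling, for
    reproducible fixtures.
    """
    exc_idx = np.flatnonzero(pop.is_excitatory)
    total = int(sum(sizes))
    if total > exc_idx.size:
        raise ValueError(
            f"zone sizes sum to {total} but only {exc_idx.size} excitatory neurons exist"
        )
    if fixed:
        chosen = exc_idx[:total]
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x50ED]))
        chosen = rng.choice(exc_idx, size=total, replace=False)
    zones = []
    k = 0
    for s in sizes:
        zones.append(np.sort(chosen[k:k + s]))
        k += s
    return ZoneLayout(tuple(zones))


def forbid_direct_io(syn: SynapticState, layout: ZoneLayout,
                     output_zones: "tuple[int, ...] | None" = None) -> SynapticState:
    """Remove all connections from the input zone to the output zones.

    The weights are set to 0 and the connections masked non-existent so STDP
    can never re-potentiate them.
    """
    if output_zones is None:
        output_zones = tuple(range(1, len(layout.zones)))
    targets = np.concatenate([layout.zones[k] for k in output_zones])
    src = layout.input_zone
    syn.w[np.ix_(src, targets)] = 0.0
    syn.exists_mask[np.ix_(src, targets)] = False
    syn.plastic_mask[np.ix_(src, targets)] = False
    return syn
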