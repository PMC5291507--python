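"""Run configuration: flat keys, named presets, strict validation.

Every experiment is described by a flat :class:`RunConfig`.  Presets bundle
the parameter sets of the reference experiments:

============================ ===============================================
selective_learning           fully connected 100-neuron network (80E/20I),
                             e = 1 mV, sigma = 3 mV, w_max = 10, decay
                             mu = 5e-7, stop condition 4 spikes in zone A
                             and < 4 in zone B in the same millisecond
selective_nostim_control     same, with external stimulation disabled
sparse_steering              sparse network (20 connections/neuron,
                             |w| ~ U(0,10), w_max = 50), e = 10 mV,
                             sigma = 5 mV, stop threshold 1 (no B clause),
                             punishment when zone B fires
stp_selective                fully connected + short-term plasticity,
                             w_max = 20, e = 10 mV, sigma = 3 mV, direct
                             input->output connections removed, stop 4/4,
                             punishment threshold 1
chain3_reinforce             3 excitatory neurons; stimulation of neuron 0
                             stops when neuron 2 spikes
chain3_indirect              same with the direct 0->2 connection removed
chain3_prune                 spiking of neuron 2 *starts* 10 ms stimulation
                             of neuron 0 (punishment wiring)
sweep                        sparse simple-learning cell for the
                             connectivity / weight-variance exploration
robot_closed / robot_open    embodied wall-avoidance network defaults
============================ ===============================================
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PRESETS", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or inconsistent run configuration."""


@dataclass
class RunConfig:
    # experiment identity
    preset: str | None = None
    seed: int = 0
    duration_ms: int = 400_000

    # network topology
    n_neurons: int = 100
    frac_inhibitory: float = 0.2
    topology: str = "fully_connected"
    connections_per_neuron: int = 20
    weight_init: str = "uniform"
    w_high: float = 5.0
    weight_mean: float = 5.0
    weight_variance: float = 1.0
    w_max: float = 10.0

    # zones
    zone_sizes: tuple = (10, 10, 10)
    zone_indices: tuple | None = None   # explicit zones (fixtures, chain3)
    initial_weights: tuple | None = None  # explicit weight matrix (chain3 demos)
    fixed_zones: bool = False
    forbid_direct_io: bool = False

    # integration and noise
    dt_ms: float = 1.0
    integrator: str = "half_step"       # or "full_step"
    sigma_noise_mv: float = 3.0

    # external stimulation / stop condition
    stimulation_enabled: bool = True
    stim_amplitude_mv: float = 1.0
    stop_a_min: int = 4
    stop_b_max: int | None = 4
    timeout_ms: int = 10_000
    delay_min_ms: int = 1000
    delay_max_ms: int = 2000

    # stimulus (punishment) condition
    stimulus_condition_enabled: bool = False
    stimulus_threshold: int = 1
    punish_amplitude_mv: float | None = None   # None: same as stim amplitude
    punish_duration_ms: int = 10
    punish_targets: str = "excitatory_except_b"

    # plasticity
    stdp_enabled: bool = True
    stdp_A: float = 0.1
    stdp_tau_ms: float = 20.0
    stdp_pairing: str = "nearest"
    stdp_cutoff_ms: float | None = None        # None: one tau (20 ms window)
    decay_enabled: bool = True
    decay_mu: float = 5e-7
    stp_enabled: bool = False
    stp_U: float = 0.2
    stp_tau_d_ms: float = 200.0
    stp_tau_f_ms: float = 600.0

    # execution / recording
    chunk_ms: int = 10_000
    record_raster: bool = False
    record_debug: bool = False
    record_trajectory: bool = False
    snapshot_every_ms: int = 0

    # robot environment
    loop_mode: str = "closed"                  # closed | open | matched_open
    sensitivity_mv: float = 8.0
    const_stim_mv: float = 8.0                 # per channel, open loop
    arena_side_px: float = 1000.0
    robot_radius_px: float = 25.0
    speed_px_per_ms: float = 1.0
    sensor_range_px: float = 80.0
    sensor_angle_rad: float = math.pi / 4
    turn_rad: float = math.pi / 6
    min_sensor_distance_px: float = 1.0
    sensor_distance_mode: str = "ray_hull"   # or "ray_center"
    initial_margin_px: float = 100.0

    def validate(self) -> "RunConfig":
        if self.dt_ms != 1.0:
            raise ConfigError("dt_ms: only the 1 ms step is supported")
        if self.integrator not in ("half_step", "full_step"):
            raise ConfigError(f"integrator: unknown scheme {self.integrator!r}")
        if self.sigma_noise_mv < 0:
            raise ConfigError("sigma_noise_mv: must be non-negative")
        if not 0 <= self.decay_mu < 1:
            raise ConfigError("decay_mu: must be in [0, 1)")
        if self.delay_min_ms < 1 or self.delay_max_ms < self.delay_min_ms:
            raise ConfigError("delay_min_ms/delay_max_ms: need 1 <= min <= max")
        if self.chunk_ms % 1000 != 0 or self.chunk_ms <= 0:
            raise ConfigError("chunk_ms: must be a positive multiple of 1000")
        if self.loop_mode not in ("closed", "open", "matched_open"):
            raise ConfigError(f"loop_mode: unknown mode {self.loop_mode!r}")
        if self.sensor_distance_mode not in ("ray_hull", "ray_center"):
            raise ConfigError(
                f"sensor_distance_mode: unknown mode {self.sensor_distance_mode!r}")
        if self.topology != "chain3" and self.zone_indices is None:
            n_exc = self.n_neurons - round(self.frac_inhibitory * self.n_neurons)
            if sum(self.zone_sizes) > n_exc:
                raise ConfigError(
                    f"zone_sizes: sum {sum(self.zone_sizes)} exceeds the "
                    f"{n_exc} excitatory neurons")
        return self

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        preset = d.pop("preset", None)
        base = dict(PRESETS[preset]) if preset else {}
        unknown = set(d) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        base.update(d)
        base["preset"] = preset
        try:
            cfg = cls(**base)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc
        for name in ("zone_sizes",):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        if cfg.zone_indices is not None:
            cfg.zone_indices = tuple(tuple(z) for z in cfg.zone_indices)
        if cfg.initial_weights is not None:
            cfg.initial_weights = tuple(tuple(row) for row in cfg.initial_weights)
        return cfg.validate()

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ConfigError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return cls.from_dict({"preset": name, **overrides})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zone_sizes"] = list(self.zone_sizes)
        if self.zone_indices is not None:
            d["zone_indices"] = [list(z) for z in self.zone_indices]
        if self.initial_weights is not None:
            d["initial_weights"] = [list(r) for r in self.initial_weights]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


PRESETS: dict[str, dict] = {
    # fully connected 100-neuron selective learning
    "selective_learning": dict(
        stim_amplitude_mv=1.0, sigma_noise_mv=3.0, w_max=10.0,
        stop_a_min=4, stop_b_max=4, decay_enabled=True,
        duration_ms=400_000,
    ),
    "selective_nostim_control": dict(
        stim_amplitude_mv=1.0, sigma_noise_mv=3.0, w_max=10.0,
        stop_a_min=4, stop_b_max=4, decay_enabled=True,
        stimulation_enabled=False, duration_ms=400_000,
    ),
    # sparse network steered by stop + stimulus conditions
    "sparse_steering": dict(
        topology="sparse_fixed_outdegree", connections_per_neuron=20,
        w_high=10.0, w_max=50.0, stim_amplitude_mv=10.0, sigma_noise_mv=5.0,
        stop_a_min=1, stop_b_max=None,
        stimulus_condition_enabled=True, stimulus_threshold=1,
        decay_enabled=True, duration_ms=500_000,
    ),
    # fully connected + STP, no direct input->output connections
    "stp_selective": dict(
        w_high=5.0, w_max=20.0, stim_amplitude_mv=10.0, sigma_noise_mv=3.0,
        stp_enabled=True, forbid_direct_io=True,
        stop_a_min=4, stop_b_max=4,
        stimulus_condition_enabled=True, stimulus_threshold=1,
        decay_enabled=True, duration_ms=500_000,
    ),
    # minimal 3-neuron experiments: defined initial states, no decay, strong
    # drive (the input neuron fires every ~25 ms, inside the STDP window)
    "chain3_reinforce": dict(
        topology="chain3", n_neurons=3, frac_inhibitory=0.0,
        zone_indices=((0,), (2,)), w_max=10.0,
        initial_weights=((0.0, 2.5, 1.0), (2.5, 0.0, 2.5), (2.5, 2.5, 0.0)),
        stim_amplitude_mv=20.0, sigma_noise_mv=3.0,
        stop_a_min=1, stop_b_max=None, decay_enabled=False,
        duration_ms=1_000_000, snapshot_every_ms=10_000,
    ),
    "chain3_indirect": dict(
        topology="chain3", n_neurons=3, frac_inhibitory=0.0,
        zone_indices=((0,), (2,)), w_max=10.0, forbid_direct_io=True,
        initial_weights=((0.0, 2.5, 0.0), (2.5, 0.0, 2.5), (2.5, 2.5, 0.0)),
        stim_amplitude_mv=20.0, sigma_noise_mv=3.0,
        stop_a_min=1, stop_b_max=None, decay_enabled=False,
        duration_ms=4_000_000, snapshot_every_ms=10_000,
    ),
    "chain3_prune": dict(
        topology="chain3", n_neurons=3, frac_inhibitory=0.0,
        zone_indices=((0,), (1,), (2,)), w_max=10.0,
        initial_weights=((0.0, 2.5, 2.5), (2.5, 0.0, 2.5), (2.5, 2.5, 0.0)),
        stimulation_enabled=False, stim_amplitude_mv=20.0,
        sigma_noise_mv=3.0, stop_a_min=1, stop_b_max=None,
        stimulus_condition_enabled=True, stimulus_threshold=1,
        punish_targets="input_zone", punish_amplitude_mv=20.0,
        decay_enabled=False, duration_ms=1_000_000, snapshot_every_ms=10_000,
    ),
    # simple-learning cell for the connectivity / variance sweep
    "sweep": dict(
        topology="sparse_fixed_outdegree", connections_per_neuron=20,
        weight_init="offset_uniform", weight_mean=5.0, weight_variance=1.0,
        w_max=50.0, stim_amplitude_mv=10.0, sigma_noise_mv=5.0,
        zone_sizes=(10, 10), stop_a_min=1, stop_b_max=None,
        decay_enabled=True, duration_ms=500_000,
    ),
    # embodied wall avoidance (network identical across loop modes)
    "robot_closed": dict(
        zone_sizes=(10, 10, 10, 10), w_high=5.0, w_max=20.0,
        sigma_noise_mv=3.0, stp_enabled=True, decay_enabled=False,
        loop_mode="closed", sensitivity_mv=8.0, duration_ms=1_000_000,
    ),
    "robot_open": dict(
        zone_sizes=(10, 10, 10, 10), w_high=5.0, w_max=20.0,
        sigma_noise_mv=3.0, stp_enabled=True, decay_enabled=False,
        loop_mode="open", const_stim_mv=8.0, duration_ms=1_000_000,
    ),
}


def load_config(path_or_dict, **overrides) -> RunConfig:
    """Load a config from YAML/JSON file, mapping, or preset overrides.

    Overrides passed as keyword arguments take precedence over file values,
    which take precedence over preset defaults.  Unknown keys are rejected
    with the offending key named.
    """
    if isinstance(path_or_dict, (str, Path)):
        text = Path(path_or_dict).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path_or_dict} is not a mapping")
    elif isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    elif path_or_dict is None:
        data = {}
    else:
        raise ConfigError(f"unsupported config source: {type(path_or_dict)!r}")
    data.update(overrides)
    return RunConfig.from_dict(data)
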