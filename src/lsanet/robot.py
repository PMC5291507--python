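"""Embodied wall avoidance: a circular robot steered by the spiking network.

The robot (radius 25 px) moves at 1 px/ms inside a 1000 x 1000 px square
arena.  Two distance sensors point at +pi/4 and -pi/4 from the heading with
an 80 px range; while a sensor's ray hits a wall within range, the matching
input zone of the network receives ``sensitivity / distance`` mV every
millisecond.  Each spike in the left (right) output zone turns the robot by
+pi/6 (-pi/6) radians; motion is clamped at the walls.  Because steering
away from a wall silences the sensors, wall avoidance is exactly the
behaviour that removes external stimulation, so the network learns it
through the same spike-timing plasticity as the stationary protocols.

Loop modes: ``closed`` (sensor-driven stimulation), ``open`` (a constant
8 mV per input channel regardless of pose) and ``matched_open`` (a constant
chosen so the delivered mV/ms matches the closed-loop average).  The
stimulation ledger counts mV per channel per millisecond, summed over the
two channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .builder import Topology, assign_zones, build_network, forbid_direct_io
from .config import RunConfig
from .plasticity import STDPConfig, STPState
from .protocols import substream_seed, _STREAM_TOPOLOGY, _STREAM_ZONES, _STREAM_NOISE, _STREAM_ROBOT

__all__ = ["Arena", "RobotState", "sense", "steer_and_move", "RobotRunner",
           "RobotResult", "run_robot"]


@dataclass
class Arena:
    side: float = 1000.0


@dataclass
class RobotState:
    """Pose and sensing state of the simulated robot."""

    position: np.ndarray
    heading: float
    radius: float = 25.0
    speed: float = 1.0
    sensor_angle: float = np.pi / 4
    sensor_range: float = 80.0
    sensitivity: float = 8.0
    min_sensor_distance: float = 1.0
    hull_sensors: bool = True   # measure wall distance from the hull, not center
    sensor_distances: np.ndarray = None  # type: ignore[assignment]
    cumulative_stimulation: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        if self.sensor_distances is None:
            self.sensor_distances = np.full(2, np.inf)


def sense(arena: Arena, robot: RobotState) -> tuple[np.ndarray, np.ndarray]:
    """Ray-cast both sensors; return (distances px, inputs mV).

    A sensor is active when its ray reaches a wall within range; the input
    is sensitivity / distance, with the distance clamped at 1 px.
    """
    x, y = robot.position
    dists = np.array([
        _kernels.ray_to_wall(x, y, robot.heading + robot.sensor_angle, arena.side),
        _kernels.ray_to_wall(x, y, robot.heading - robot.sensor_angle, arena.side),
    ])
    if robot.hull_sensors:
        dists = dists - robot.radius
    robot.sensor_distances = dists
    inputs = np.zeros(2)
    for k in range(2):
        if dists[k] <= robot.sensor_range:
            inputs[k] = robot.sensitivity / max(dists[k], robot.min_sensor_distance)
    return dists, inputs


def steer_and_move(robot: RobotState, spikes_left: int, spikes_right: int,
                   arena: Arena, dt: float = 1.0) -> RobotState:
    """Turn pi/6 per output spike (left minus right), advance, clamp at walls."""
    robot.heading += (np.pi / 6) * (int(spikes_left) - int(spikes_right))
    x, y = robot.position
    x += robot.speed * dt * np.cos(robot.heading)
    y += robot.speed * dt * np.sin(robot.heading)
    lo, hi = robot.radius, arena.side - robot.radius
    robot.position = np.array([min(max(x, lo), hi), min(max(y, lo), hi)])
    return robot


@dataclass
class RobotResult:
    """Outputs of an embodied run.

    ``near_wall_frac_1s`` is the fraction of each second spent with the
    nearest wall closer than the sensor range; ``stim_mv_per_ms`` the
    per-millisecond delivered stimulation (summed over both channels).
    """

    config: RunConfig
    near_wall_frac_1s: np.ndarray
    counts_1s: np.ndarray
    cumulative_stimulation_mv: float
    stim_mv_per_ms: np.ndarray
    trajectory: pd.DataFrame | None = None

    def near_wall_fraction(self, last_s: int | None = None) -> float:
        x = self.near_wall_frac_1s
        if last_s is not None:
            x = x[-last_s:]
        return float(x.mean())

    def mean_stim_mv_per_ms(self, first_ms: int | None = None) -> float:
        x = self.stim_mv_per_ms
        if first_ms is not None:
            x = x[:first_ms]
        return float(x.mean())


class RobotRunner:
    """Chunked driver for the wall-avoidance experiment."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = c = config
        topo = Topology(
            kind="fully_connected", n_neurons=c.n_neurons,
            frac_inhibitory=c.frac_inhibitory, w_max=c.w_max,
            weight_init="uniform", w_high=c.w_high,
        )
        self.pop, self.syn = build_network(
            topo, substream_seed(c.seed, _STREAM_TOPOLOGY))
        self.layout = assign_zones(
            self.pop, tuple(c.zone_sizes),
            substream_seed(c.seed, _STREAM_ZONES), fixed=c.fixed_zones)
        if c.forbid_direct_io:
            forbid_direct_io(self.syn, self.layout, output_zones=(2, 3))
        self.stp = (STPState.create(self.pop.n_total, c.stp_U,
                                    c.stp_tau_d_ms, c.stp_tau_f_ms)
                    if c.stp_enabled else None)
        self.stdp = STDPConfig(A=c.stdp_A, tau=c.stdp_tau_ms,
                               cutoff=c.stdp_cutoff_ms)
        # random initial pose away from the walls
        prng = np.random.default_rng(
            np.random.SeedSequence([c.seed, _STREAM_ROBOT]))
        lo = c.initial_margin_px
        hi = c.arena_side_px - c.initial_margin_px
        self.rstate = np.array([
            prng.uniform(lo, hi), prng.uniform(lo, hi),
            prng.uniform(0.0, 2.0 * np.pi),
        ])
        self.ledger = np.zeros(1)
        self.fired_prev = np.zeros(self.pop.n_total, bool)
        self.t = 0

    def run(self, duration_ms: int | None = None,
            matched_mv_per_ms: float | None = None) -> RobotResult:
        """Run the experiment; ``matched_mv_per_ms`` sets the constant total
        stimulation (both channels) for ``matched_open`` mode."""
        c = self.config
        total = int(duration_ms if duration_ms is not None else c.duration_ms)
        chunk = int(c.chunk_ms)
        mode = 0 if c.loop_mode == "closed" else 1
        if c.loop_mode == "open":
            const_amp = float(c.const_stim_mv)
        elif c.loop_mode == "matched_open":
            if matched_mv_per_ms is None:
                raise ValueError(
                    "matched_open mode needs matched_mv_per_ms from closed-loop runs")
            const_amp = float(matched_mv_per_ms) / 2.0  # split over 2 channels
        else:
            const_amp = 0.0

        near_parts, counts_parts, stim_parts, traj_parts = [], [], [], []
        done = 0
        n = self.pop.n_total
        stp_on = self.stp is not None
        stp_x = self.stp.x_depress if stp_on else np.ones(n)
        stp_u = self.stp.u_facil if stp_on else np.ones(n)
        zl = self.layout.zones
        while done < total:
            this = min(chunk, total - done)
            n_sec = (this + 999) // 1000
            chunk_index = self.t // chunk
            noise_seed = substream_seed(c.seed, _STREAM_NOISE, chunk_index)
            near_count = np.zeros(n_sec, np.uint16)
            counts_1s = np.zeros((n_sec, n), np.uint32)
            traj = np.zeros((this if c.record_trajectory else 1, 3))
            stim_ms = np.zeros(this)
            _kernels.run_robot_chunk(
                self.pop.v, self.pop.u_recovery, self.pop.params_a,
                self.pop.params_b, self.pop.params_c, self.pop.params_d,
                self.pop.is_excitatory,
                self.syn.w, self.syn.exists_mask, self.syn.plastic_mask,
                float(c.w_max),
                bool(c.decay_enabled), float(c.decay_mu),
                bool(c.stdp_enabled), float(self.stdp.A), float(self.stdp.tau),
                float(self.stdp.cutoff), self.syn.last_spike_time,
                stp_on, stp_x, stp_u,
                float(c.stp_U), float(c.stp_tau_d_ms), float(c.stp_tau_f_ms),
                float(c.sigma_noise_mv), c.integrator == "half_step",
                zl[0], zl[1], zl[2], zl[3],
                mode, float(c.sensitivity_mv), const_amp,
                float(c.arena_side_px), float(c.robot_radius_px),
                float(c.speed_px_per_ms), float(c.sensor_range_px),
                float(c.sensor_angle_rad), float(c.turn_rad),
                float(c.min_sensor_distance_px),
                c.sensor_distance_mode == "ray_hull",
                self.rstate, self.ledger, self.fired_prev,
                self.t, this, noise_seed,
                near_count, counts_1s,
                bool(c.record_trajectory), traj, stim_ms,
            )
            near_parts.append(near_count.astype(float) / 1000.0)
            counts_parts.append(counts_1s)
            stim_parts.append(stim_ms)
            if c.record_trajectory:
                traj_parts.append(traj)
            self.t += this
            done += this

        trajectory = None
        if traj_parts:
            tr = np.vstack(traj_parts)
            trajectory = pd.DataFrame(tr, columns=["x", "y", "heading"])
            trajectory.insert(0, "time_ms", np.arange(len(tr)))
        return RobotResult(
            config=c,
            near_wall_frac_1s=np.concatenate(near_parts),
            counts_1s=np.vstack(counts_parts),
            cumulative_stimulation_mv=float(self.ledger[0]),
            stim_mv_per_ms=np.concatenate(stim_parts),
            trajectory=trajectory,
        )


def run_robot(loop_mode: str, sensitivity: float, duration_ms: int, seed: int,
              matched_mv_per_ms: float | None = None,
              **overrides) -> RobotResult:
    """Convenience wrapper: build the robot preset and run one experiment."""
    preset = "robot_open" if loop_mode in ("open", "matched_open") else "robot_closed"
    cfg = RunConfig.from_preset(
        preset, seed=seed, loop_mode=loop_mode,
        sensitivity_mv=sensitivity, duration_ms=int(duration_ms), **overrides)
    return RobotRunner(cfg).run(matched_mv_per_ms=matched_mv_per_ms)
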