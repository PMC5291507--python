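"""Closed-loop training protocols and derived learning statistics.

The training loop alternates two phases.  While stimulation is on, the
input zone receives the external amplitude every millisecond until either
the *stop condition* is met (>= ``a_min`` spikes in output zone A and, when
the selective clause is active, < ``b_max`` spikes in output zone B *in the
same 1 ms bin*) or a 10 s timeout elapses; the delay from stimulation onset
to the satisfying bin is the trial's reaction time.  Stimulation then stays
off for a uniformly random 1-2 s inter-trial delay before the next trial.

Independently, the *stimulus condition* (punishment) can be enabled: when
>= ``threshold`` neurons of output zone B spike, every excitatory neuron
outside zone B is stimulated for the next 10 ms (the window restarts if
zone B fires again meanwhile).

A network has learned the task when its reaction time drops below 4000 ms
and stays below for every subsequent trial (at least five of them, so a
chance sub-threshold response at the end of the budget does not count);
the learning time is the elapsed simulated time at the onset of that
earliest trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import MODE_STIM, PSTATE_LEN, PS_MODE, PS_ONSET
from .builder import Topology, ZoneLayout, assign_zones, build_network, forbid_direct_io
from .config import RunConfig
from .plasticity import STDPConfig, STPState

__all__ = [
    "ConditionSpec",
    "TrialRecord",
    "RunMetrics",
    "RunResult",
    "ProtocolRunner",
    "check_stop_condition",
    "check_stimulus_condition",
    "run_training",
    "run_preset",
    "learning_time_index",
    "learning_time",
    "compute_metrics",
    "learnability",
    "zone_rate_trajectory",
    "firing_rate_distribution",
    "raster_to_counts",
    "run_sweep",
    "substream_seed",
]

LEARNED_RT_MS = 4000  # reaction-time criterion for "task learned"

logger = logging.getLogger("lsanet")

# substream tags for fanning the master seed out to independent RNG streams
_STREAM_TOPOLOGY = 1
_STREAM_ZONES = 2
_STREAM_DELAYS = 3
_STREAM_NOISE = 4
_STREAM_ROBOT = 5


def substream_seed(master: int, stream: int, index: int = 0) -> int:
    """A 31-bit seed for a named substream of the master seed."""
    ss = np.random.SeedSequence([int(master), int(stream), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class ConditionSpec:
    """Thresholds for the stop and stimulus conditions (1 ms bins)."""

    zone_a_min_spikes: int = 4
    zone_b_max_spikes: int | None = 4       # None: selective clause off
    stimulus_threshold: int | None = None   # None: punishment off
    stimulus_duration_ms: int = 10


@dataclass
class TrialRecord:
    stim_onset: int
    response_time: int
    timed_out: bool
    timeout_limit: int = 10000


@dataclass
class RunMetrics:
    success: bool
    learning_time_s: float | None
    attained_reaction_time_ms: float | None
    reaction_times: np.ndarray
    n_trials: int


def check_stop_condition(spikes_now: np.ndarray, layout: ZoneLayout,
                         spec: ConditionSpec) -> bool:
    """True iff the desired output pattern occurs in the current 1 ms bin."""
    spikes_now = np.asarray(spikes_now, bool)
    ca = int(spikes_now[layout.output_zone_a].sum())
    if ca < spec.zone_a_min_spikes:
        return False
    if spec.zone_b_max_spikes is None:
        return True
    cb = int(spikes_now[layout.output_zone_b].sum())
    return cb < spec.zone_b_max_spikes


def check_stimulus_condition(spikes_now: np.ndarray, layout: ZoneLayout,
                             spec: ConditionSpec) -> bool:
    """True iff output zone B fired enough to trigger the punishment window."""
    if spec.stimulus_threshold is None:
        return False
    spikes_now = np.asarray(spikes_now, bool)
    return int(spikes_now[layout.output_zone_b].sum()) >= spec.stimulus_threshold


@dataclass
class RunResult:
    """Everything a protocol run produced.

    ``counts_1s`` holds per-neuron spike counts in 1 s bins for the whole
    run (shape n_seconds x n_neurons); ``trials`` one row per completed
    trial.  Raster events, per-ms debug traces (zone counts, stimulation and
    punishment activity) and weight snapshots are present when recording was
    requested.
    """

    config: RunConfig
    trials: pd.DataFrame
    counts_1s: np.ndarray
    layout: ZoneLayout
    raster: np.ndarray | None = None
    debug: pd.DataFrame | None = None
    w_snapshots: np.ndarray | None = None
    snapshot_times_ms: np.ndarray | None = None
    final_w: np.ndarray | None = None

    @property
    def metrics(self) -> RunMetrics:
        return compute_metrics(self.trials)


class ProtocolRunner:
    """Chunked driver for the training protocols.

    Builds the network and zones from a :class:`RunConfig`, then advances
    the jitted protocol kernel in chunks (a multiple of 1000 ms each) so
    runs can be snapshotted and resumed bit-exactly at chunk boundaries.
    """

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        c = config
        topo = Topology(
            kind=c.topology, n_neurons=c.n_neurons,
            frac_inhibitory=c.frac_inhibitory, w_max=c.w_max,
            weight_init=c.weight_init, w_high=c.w_high,
            weight_mean=c.weight_mean, weight_variance=c.weight_variance,
            connections_per_neuron=c.connections_per_neuron,
        )
        self.pop, self.syn = build_network(
            topo, substream_seed(c.seed, _STREAM_TOPOLOGY))
        if c.initial_weights is not None:
            w0 = np.asarray(c.initial_weights, float)
            if w0.shape != self.syn.w.shape:
                raise ValueError("initial_weights shape does not match the network")
            self.syn.w[:] = w0 * self.syn.exists_mask
        if c.zone_indices is not None:
            self.layout = ZoneLayout(tuple(np.asarray(z, np.int64)
                                           for z in c.zone_indices))
        else:
            self.layout = assign_zones(
                self.pop, tuple(c.zone_sizes),
                substream_seed(c.seed, _STREAM_ZONES), fixed=c.fixed_zones)
        if c.forbid_direct_io:
            forbid_direct_io(self.syn, self.layout)
        self.stp = (STPState.create(self.pop.n_total, c.stp_U,
                                    c.stp_tau_d_ms, c.stp_tau_f_ms)
                    if c.stp_enabled else None)
        self.stdp = STDPConfig(A=c.stdp_A, tau=c.stdp_tau_ms,
                               pairing=c.stdp_pairing,
                               cutoff=c.stdp_cutoff_ms)
        # pre-drawn inter-trial delays from their own substream
        n_delays = c.duration_ms // max(1, c.delay_min_ms) + 8
        drng = np.random.default_rng(
            np.random.SeedSequence([c.seed, _STREAM_DELAYS]))
        self.delays = drng.integers(c.delay_min_ms, c.delay_max_ms + 1,
                                    size=n_delays).astype(np.int64)
        # protocol state: stimulation on, first trial starts at t = 0
        self.pstate = np.zeros(PSTATE_LEN, np.int64)
        self.pstate[PS_MODE] = MODE_STIM
        self.pstate[PS_ONSET] = 0
        self.fired_prev = np.zeros(self.pop.n_total, bool)
        self.t = 0
        self._punish_targets = self._resolve_punish_targets()

    def _resolve_punish_targets(self) -> np.ndarray:
        c = self.config
        if not c.stimulus_condition_enabled:
            return np.empty(0, np.int64)
        if c.punish_targets == "excitatory_except_b":
            exc = np.flatnonzero(self.pop.is_excitatory)
            return np.setdiff1d(exc, self.layout.output_zone_b).astype(np.int64)
        if c.punish_targets == "input_zone":
            return self.layout.input_zone.astype(np.int64)
        raise ValueError(f"unknown punish_targets: {c.punish_targets!r}")

    def run(self, duration_ms: int | None = None) -> RunResult:
        c = self.config
        total = int(duration_ms if duration_ms is not None else c.duration_ms)
        logger.info("event=run_start preset=%s seed=%d t0=%d duration_ms=%d",
                    c.preset, c.seed, self.t, total)
        chunk = int(c.chunk_ms)
        if chunk % 1000 != 0:
            raise ValueError("chunk_ms must be a multiple of 1000")

        trials_on, trials_rt, trials_to = [], [], []
        counts_parts, raster_parts, debug_parts = [], [], []
        snaps_parts, snap_time_parts = [], []

        done = 0
        while done < total:
            this = min(chunk, total - done)
            out = self._run_chunk(this)
            trials_on.append(out["trial_onset"])
            trials_rt.append(out["trial_rt"])
            trials_to.append(out["trial_timed_out"])
            counts_parts.append(out["counts_1s"])
            if out["raster"] is not None:
                raster_parts.append(out["raster"])
            if out["debug"] is not None:
                debug_parts.append(out["debug"])
            if out["snaps"] is not None and len(out["snaps"]):
                snaps_parts.append(out["snaps"])
                snap_time_parts.append(out["snap_times"])
            done += this

        trials = pd.DataFrame({
            "onset_ms": np.concatenate(trials_on) if trials_on else np.empty(0, np.int64),
            "reaction_ms": np.concatenate(trials_rt) if trials_rt else np.empty(0, np.int64),
            "timed_out": np.concatenate(trials_to) if trials_to else np.empty(0, bool),
        })
        counts = np.vstack(counts_parts) if counts_parts else np.zeros((0, self.pop.n_total), np.uint32)
        raster = np.vstack(raster_parts) if raster_parts else (
            np.empty((0, 2), np.int64) if c.record_raster else None)
        debug = None
        if debug_parts:
            dbg = np.vstack(debug_parts)
            debug = pd.DataFrame(dbg, columns=["zone_a_spikes", "zone_b_spikes",
                                               "stim_active", "punish_active"])
        snaps = np.concatenate(snaps_parts) if snaps_parts else None
        snap_times = np.concatenate(snap_time_parts) if snap_time_parts else None
        logger.info("event=run_end preset=%s seed=%d t=%d n_trials=%d",
                    c.preset, c.seed, self.t, len(trials))
        return RunResult(
            config=c, trials=trials, counts_1s=counts, layout=self.layout,
            raster=raster, debug=debug, w_snapshots=snaps,
            snapshot_times_ms=snap_times, final_w=self.syn.w.copy(),
        )

    def _run_chunk(self, chunk_ms: int) -> dict:
        c = self.config
        n = self.pop.n_total
        n_sec = (chunk_ms + 999) // 1000
        chunk_index = self.t // int(c.chunk_ms)
        noise_seed = substream_seed(c.seed, _STREAM_NOISE, chunk_index)

        max_trials = chunk_ms // max(1, c.delay_min_ms) + 4
        trial_onset = np.zeros(max_trials, np.int64)
        trial_rt = np.zeros(max_trials, np.int64)
        trial_timed_out = np.zeros(max_trials, bool)
        trial_count = np.zeros(1, np.int64)
        counts_1s = np.zeros((n_sec, n), np.uint32)
        debug_rec = np.zeros((chunk_ms if c.record_debug else 1, 4), np.uint16)
        cap = chunk_ms * n if c.record_raster else 1
        raster_t = np.zeros(cap, np.int64)
        raster_i = np.zeros(cap, np.int64)
        event_count = np.zeros(1, np.int64)
        snap_every = int(c.snapshot_every_ms)
        n_snaps = chunk_ms // snap_every + 1 if snap_every > 0 else 1
        snaps = np.zeros((n_snaps if snap_every > 0 else 0, n, n))
        snap_count = np.zeros(1, np.int64)

        use_b = c.stop_b_max is not None
        zone_b = self.layout.output_zone_b
        punish_amp = (c.punish_amplitude_mv if c.punish_amplitude_mv is not None
                      else c.stim_amplitude_mv)
        stp_on = self.stp is not None
        stp_x = self.stp.x_depress if stp_on else np.ones(n)
        stp_u = self.stp.u_facil if stp_on else np.ones(n)

        _kernels.run_protocol_chunk(
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
            self.layout.input_zone, self.layout.output_zone_a, zone_b,
            float(c.stim_amplitude_mv) if c.stimulation_enabled else 0.0,
            int(c.stop_a_min), int(c.stop_b_max) if use_b else 0, use_b,
            bool(c.stimulus_condition_enabled), int(c.stimulus_threshold),
            float(punish_amp), int(c.punish_duration_ms), self._punish_targets,
            int(c.timeout_ms), self.delays,
            self.pstate, self.fired_prev,
            self.t, chunk_ms, noise_seed,
            trial_onset, trial_rt, trial_timed_out, trial_count,
            counts_1s,
            bool(c.record_debug), debug_rec,
            bool(c.record_raster), raster_t, raster_i, event_count,
            snap_every, snaps, snap_count,
        )

        m = int(trial_count[0])
        ne = int(event_count[0])
        ns = int(snap_count[0])
        snap_times = None
        if snap_every > 0:
            # snapshots are taken after every multiple of snap_every ms
            first = (self.t // snap_every + 1) * snap_every
            snap_times = (first + snap_every * np.arange(ns)).astype(np.int64)
        out = {
            "trial_onset": trial_onset[:m].copy(),
            "trial_rt": trial_rt[:m].copy(),
            "trial_timed_out": trial_timed_out[:m].copy(),
            "counts_1s": counts_1s,
            "debug": debug_rec[:chunk_ms].copy() if c.record_debug else None,
            "raster": (np.column_stack([raster_t[:ne], raster_i[:ne]])
                       if c.record_raster else None),
            "snaps": snaps[:ns].copy() if snap_every > 0 else None,
            "snap_times": snap_times,
        }
        self.t += chunk_ms
        return out


def run_training(config: RunConfig) -> RunResult:
    """Build a network per ``config`` and run its training protocol."""
    return ProtocolRunner(config).run()


def run_preset(name: str, seed: int, duration_ms: int | None = None,
               **overrides) -> RunResult:
    """Run a named experiment preset (see :mod:`lsanet.config`)."""
    cfg = RunConfig.from_preset(name, seed=seed, **overrides)
    if duration_ms is not None:
        cfg.duration_ms = int(duration_ms)
    return run_training(cfg)


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def learning_time_index(reaction_ms: np.ndarray,
                        threshold_ms: int = LEARNED_RT_MS) -> int | None:
    """Index of the earliest trial from which every reaction time stays
    below the threshold; None if the sequence never locks in."""
    rts = np.asarray(reaction_ms)
    if rts.size == 0 or rts[-1] >= threshold_ms:
        return None
    below = rts < threshold_ms
    # last index where the criterion is violated; learning starts just after
    bad = np.flatnonzero(~below)
    return int(bad[-1] + 1) if bad.size else 0


def learning_time(trials: pd.DataFrame,
                  threshold_ms: int = LEARNED_RT_MS) -> float | None:
    """Elapsed simulated time (s) at the onset of the learning trial."""
    k = learning_time_index(trials["reaction_ms"].to_numpy(), threshold_ms)
    if k is None:
        return None
    return float(trials["onset_ms"].iloc[k]) / 1000.0


def compute_metrics(trials: pd.DataFrame,
                    threshold_ms: int = LEARNED_RT_MS,
                    min_sustained_trials: int = 5) -> RunMetrics:
    """Success, learning time and post-learning reaction time for a run.

    A run counts as successful only when the reaction time drops below the
    threshold and *stays* below it for at least ``min_sustained_trials``
    consecutive trials through the end of the run: a couple of chance
    sub-threshold responses in the run's final trials are not evidence that
    the limit is being kept (noise-driven networks produce them regularly,
    and the reference control experiment reports a strict 0% success rate).
    """
    rts = trials["reaction_ms"].to_numpy()
    k = learning_time_index(rts, threshold_ms)
    if k is None or len(rts) - k < min_sustained_trials:
        return RunMetrics(False, None, None, rts, len(trials))
    lt = float(trials["onset_ms"].iloc[k]) / 1000.0
    attained = float(rts[k:].mean())
    return RunMetrics(True, lt, attained, rts, len(trials))


def raster_to_counts(raster: np.ndarray, n_neurons: int,
                     duration_ms: int, bin_ms: int = 1000) -> np.ndarray:
    """Bin a (time_ms, neuron_id) event list into per-neuron counts."""
    n_bins = (duration_ms + bin_ms - 1) // bin_ms
    counts = np.zeros((n_bins, n_neurons), np.uint32)
    if len(raster):
        np.add.at(counts, (raster[:, 0] // bin_ms, raster[:, 1]), 1)
    return counts


def learnability(counts_1s: np.ndarray, zone: np.ndarray,
                 window_s: int = 100) -> float:
    """Mean per-neuron zone rate (Hz) in the last window minus the first.

    The run must be at least two windows long (the reference protocol uses
    500 s runs with 100 s windows).
    """
    n_sec = counts_1s.shape[0]
    if n_sec < 2 * window_s:
        raise ValueError(f"run too short: {n_sec} s < 2 x {window_s} s windows")
    zone = np.asarray(zone, np.int64)
    first = counts_1s[:window_s][:, zone].sum() / (window_s * zone.size)
    last = counts_1s[-window_s:][:, zone].sum() / (window_s * zone.size)
    return float(last - first)


def zone_rate_trajectory(counts_1s: np.ndarray, layout: ZoneLayout,
                         bin_s: int = 1) -> pd.DataFrame:
    """Per-bin mean per-neuron firing rates (Hz) of output zones A and B."""
    n_sec = counts_1s.shape[0]
    n_bins = n_sec // bin_s
    za, zb = layout.output_zone_a, layout.output_zone_b
    rows = []
    for k in range(n_bins):
        block = counts_1s[k * bin_s:(k + 1) * bin_s]
        ra = block[:, za].sum() / (bin_s * za.size) if za.size else 0.0
        rb = block[:, zb].sum() / (bin_s * zb.size) if zb.size else 0.0
        rows.append((k * bin_s, ra, rb))
    return pd.DataFrame(rows, columns=["time_s", "rate_a_hz", "rate_b_hz"])


def firing_rate_distribution(counts_1s: np.ndarray, window: str = "first",
                             window_s: int = 100,
                             bins: "int | np.ndarray" = 20) -> tuple:
    """Histogram of per-neuron firing rates (Hz) in the first or last window."""
    if window == "first":
        block = counts_1s[:window_s]
    elif window == "last":
        block = counts_1s[-window_s:]
    else:
        raise ValueError("window must be 'first' or 'last'")
    rates = block.sum(axis=0) / window_s
    return np.histogram(rates, bins=bins)


def run_sweep(m_values, v_values, n_reps: int, seed: int = 0,
              duration_ms: int = 500_000, **overrides) -> pd.DataFrame:
    """Connectivity / weight-variance sweep of the simple-learning task.

    For each (M, v) cell, ``n_reps`` sparse networks are trained with the
    stop condition only for ``duration_ms``; learnability is the output
    zone's mean rate in the last 100 s minus the first 100 s.
    """
    rows = []
    for mi, m in enumerate(m_values):
        for vi, v in enumerate(v_values):
            for rep in range(n_reps):
                run_seed = substream_seed(seed, 1000 + mi * 100 + vi, rep)
                cfg = RunConfig.from_preset(
                    "sweep", seed=run_seed, connections_per_neuron=int(m),
                    weight_variance=float(v), duration_ms=int(duration_ms),
                    **overrides)
                res = run_training(cfg)
                learn = learnability(res.counts_1s, res.layout.output_zone_a)
                rows.append((int(m), float(v), rep, run_seed, learn))
    return pd.DataFrame(rows, columns=["M", "v", "rep", "seed", "learnability"])
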