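"""Training-loop semantics, trial bookkeeping and derived statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lsanet import (
    ConditionSpec, ProtocolRunner, RunConfig, ZoneLayout,
    apply_decay, apply_stdp, check_stimulus_condition, check_stop_condition,
    compute_metrics, firing_rate_distribution, gather_inputs, izhikevich_step,
    learnability, learning_time_index, raster_to_counts, run_training,
    stp_step, zone_rate_trajectory,
)

LAYOUT = ZoneLayout((np.arange(10), np.arange(10, 20), np.arange(20, 30)))


def spikes_with(zone_a=0, zone_b=0, n=100):
    s = np.zeros(n, bool)
    s[LAYOUT.output_zone_a[:zone_a]] = True
    s[LAYOUT.output_zone_b[:zone_b]] = True
    return s


class TestConditions:
    @pytest.mark.parametrize("a, b, expected", [
        (4, 3, True),    # both clauses met in the same bin
        (4, 4, False),   # zone B too active
        (3, 0, False),   # zone A below threshold
        (0, 0, False),
    ])
    def test_selective_stop_condition(self, a, b, expected):
        spec = ConditionSpec(zone_a_min_spikes=4, zone_b_max_spikes=4)
        assert check_stop_condition(spikes_with(a, b), LAYOUT, spec) is expected

    def test_stop_condition_without_b_clause(self):
        spec = ConditionSpec(zone_a_min_spikes=1, zone_b_max_spikes=None)
        assert check_stop_condition(spikes_with(1, 10), LAYOUT, spec)

    @pytest.mark.parametrize("b, expected", [(1, True), (0, False)])
    def test_stimulus_condition_threshold(self, b, expected):
        spec = ConditionSpec(stimulus_threshold=1)
        assert check_stimulus_condition(spikes_with(0, b), LAYOUT, spec) is expected

    def test_stimulus_condition_disabled(self):
        spec = ConditionSpec(stimulus_threshold=None)
        assert not check_stimulus_condition(spikes_with(0, 10), LAYOUT, spec)


class TestLearningTime:
    @pytest.mark.parametrize("rts, expected", [
        ([9000, 5000, 3000, 2000, 1000], 2),
        ([3000, 6000, 3000, 3000, 3000], 2),  # early dip does not count
        ([10000, 10000], None),
        ([], None),
        ([100, 100, 100], 0),
    ])
    def test_earliest_sustained_index(self, rts, expected):
        assert learning_time_index(np.array(rts, int)) == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 10000), max_size=40))
    def test_matches_suffix_scan_oracle(self, rts):
        rts = np.array(rts, int)
        oracle = next((k for k in range(len(rts))
                       if np.all(rts[k:] < 4000)), None)
        assert learning_time_index(rts) == oracle

    def test_metrics_from_trials(self):
        trials = pd.DataFrame({
            "onset_ms": [0, 12000, 24000, 30000, 33000, 36000, 39000],
            "reaction_ms": [10000, 5000, 500, 700, 600, 650, 550],
            "timed_out": [True, False, False, False, False, False, False],
        })
        m = compute_metrics(trials)
        assert m.success
        assert m.learning_time_s == 24.0
        assert m.attained_reaction_time_ms == 600.0

    def test_failure_when_never_sustained(self):
        trials = pd.DataFrame({"onset_ms": [0], "reaction_ms": [10000],
                               "timed_out": [True]})
        m = compute_metrics(trials)
        assert not m.success and m.learning_time_s is None

    def test_short_final_streak_is_not_success(self):
        # two chance sub-threshold trials at the end do not demonstrate
        # that the reaction time is being kept under the limit
        trials = pd.DataFrame({
            "onset_ms": [0, 12000, 24000],
            "reaction_ms": [10000, 500, 700],
            "timed_out": [True, False, False],
        })
        assert not compute_metrics(trials).success


class TestRateStatistics:
    def test_learnability_zero_for_stationary_rates(self):
        counts = np.full((200, 100), 2, np.uint32)
        assert learnability(counts, np.arange(10)) == 0.0

    def test_learnability_silent_to_ten_hz(self):
        counts = np.zeros((200, 100), np.uint32)
        counts[-100:, :10] = 10
        assert learnability(counts, np.arange(10)) == 10.0

    def test_learnability_requires_two_windows(self):
        with pytest.raises(ValueError):
            learnability(np.zeros((150, 10), np.uint32), np.arange(5))

    def test_learnability_matches_recount_on_random_raster(self):
        rng = np.random.default_rng(0)
        events = np.column_stack([
            rng.integers(0, 300_000, 5000), rng.integers(0, 50, 5000)])
        counts = raster_to_counts(events, 50, 300_000)
        zone = np.arange(7)
        first = events[(events[:, 0] < 100_000) & np.isin(events[:, 1], zone)]
        last = events[(events[:, 0] >= 200_000) & np.isin(events[:, 1], zone)]
        assert learnability(counts, zone) == pytest.approx(
            (len(last) - len(first)) / (100 * 7))

    def test_zone_trajectory_empty_and_single_spike(self):
        counts = np.zeros((10, 100), np.uint32)
        traj = zone_rate_trajectory(counts, LAYOUT)
        assert np.all(traj[["rate_a_hz", "rate_b_hz"]].to_numpy() == 0)
        counts[3, LAYOUT.output_zone_a[0]] = 1
        traj = zone_rate_trajectory(counts, LAYOUT)
        assert traj["rate_a_hz"].iloc[3] == pytest.approx(1 / 10)

    def test_rate_distribution_masses(self):
        counts = np.zeros((100, 20), np.uint32)
        hist, edges = firing_rate_distribution(counts, "first",
                                               bins=np.arange(6))
        assert hist[0] == 20 and hist[1:].sum() == 0
        counts[:, :] = 5
        hist, edges = firing_rate_distribution(counts, "last",
                                               bins=np.array([0, 1, 4.9, 5.1, 10]))
        assert hist.tolist() == [0, 0, 20, 0]


def tiny_deterministic_config(**over):
    base = dict(
        n_neurons=8, frac_inhibitory=0.0, zone_sizes=(2, 2, 2),
        sigma_noise_mv=0.0, stim_amplitude_mv=30.0,
        stop_a_min=1, stop_b_max=None,
        stimulus_condition_enabled=True, stimulus_threshold=1,
        punish_amplitude_mv=30.0, punish_duration_ms=3,
        w_high=10.0, w_max=12.0, decay_enabled=True, decay_mu=1e-5,
        timeout_ms=100, delay_min_ms=5, delay_max_ms=10,
        duration_ms=400, chunk_ms=1000, seed=13, record_raster=True,
        record_debug=True,
    )
    base.update(over)
    return RunConfig.from_dict(base)


def python_reference_run(runner: ProtocolRunner, duration: int):
    """Re-run the training loop with the public per-step operations.

    An independent implementation of the protocol semantics (stimulation,
    timeout, inter-trial delays, punishment window with restart, STDP order,
    decay) used to cross-check the jitted kernel on a noise-free network.
    """
    c = runner.config
    pop, syn = runner.pop.copy(), runner.syn.copy()
    stp = runner.stp.copy() if runner.stp is not None else None
    layout, delays = runner.layout, runner.delays
    exc_except_b = np.setdiff1d(np.flatnonzero(pop.is_excitatory),
                                layout.output_zone_b)
    fired_prev = np.zeros(pop.n_total, bool)
    mode, onset, delay_left, punish_left, delay_idx = "stim", 0, 0, 0, 0
    trials, raster = [], []
    for t in range(duration):
        e = np.zeros(pop.n_total)
        if mode == "stim" and c.stimulation_enabled:
            e[layout.input_zone] += c.stim_amplitude_mv
        if punish_left > 0:
            e[exc_except_b] += c.punish_amplitude_mv
            punish_left -= 1
        iv = gather_inputs(syn, fired_prev, stp=stp)
        fired = izhikevich_step(pop, iv.I_synaptic + e)
        if stp is not None:
            stp_step(stp, fired, pop.is_excitatory)
        for i in np.flatnonzero(fired):
            raster.append((t, i))
        ca = int(fired[layout.output_zone_a].sum())
        cb = int(fired[layout.output_zone_b].sum())
        if mode == "stim":
            if ca >= c.stop_a_min:
                trials.append((onset, t - onset, False))
            elif t - onset + 1 >= c.timeout_ms:
                trials.append((onset, c.timeout_ms, True))
            if len(trials) and trials[-1][0] == onset:
                mode = "delay"
                delay_left = delays[delay_idx]
                delay_idx += 1
        else:
            delay_left -= 1
            if delay_left <= 0:
                mode, onset = "stim", t + 1
        if c.stimulus_condition_enabled and cb >= c.stimulus_threshold:
            punish_left = c.punish_duration_ms
        apply_stdp(syn, fired, t, runner.stdp)
        apply_decay(syn, c.decay_mu)
        fired_prev = fired
    return trials, np.array(raster, int).reshape(-1, 2), syn.w


class TestTrainingLoop:
    def test_kernel_agrees_with_reference_implementation(self):
        cfg = tiny_deterministic_config()
        runner = ProtocolRunner(cfg)
        ref_trials, ref_raster, ref_w = python_reference_run(runner, 400)
        res = runner.run()
        got = list(zip(res.trials["onset_ms"], res.trials["reaction_ms"],
                       res.trials["timed_out"]))
        assert [(o, r, bool(x)) for o, r, x in got] == [
            (o, r, x) for o, r, x in ref_trials]
        assert np.array_equal(res.raster, ref_raster)
        assert np.allclose(runner.syn.w, ref_w, atol=1e-12)
        assert len(ref_trials) > 2 and len(ref_raster) > 10

    def test_punishment_window_restarts_on_retrigger(self):
        cfg = tiny_deterministic_config(punish_duration_ms=4, duration_ms=300)
        res = run_training(cfg)
        dbg = res.debug
        # reconstruct the punishment schedule from the zone-B spike log
        left = 0
        for t in range(len(dbg)):
            active = left > 0
            if active:
                left -= 1
            assert bool(dbg["punish_active"].iloc[t]) == active
            if dbg["zone_b_spikes"].iloc[t] >= 1:
                left = 4
        assert dbg["punish_active"].sum() > 0

    def test_trial_clock_conservation(self):
        cfg = tiny_deterministic_config(duration_ms=2000)
        res = run_training(cfg)
        tr = res.trials
        assert tr["onset_ms"].iloc[0] == 0
        for k in range(len(tr) - 1):
            dur = (cfg.timeout_ms if tr["timed_out"].iloc[k]
                   else tr["reaction_ms"].iloc[k] + 1)
            gap = tr["onset_ms"].iloc[k + 1] - tr["onset_ms"].iloc[k] - dur
            assert cfg.delay_min_ms <= gap <= cfg.delay_max_ms

    def test_silent_network_only_decays(self):
        cfg = tiny_deterministic_config(
            stimulation_enabled=False, sigma_noise_mv=0.0,
            stimulus_condition_enabled=False, duration_ms=3000,
            decay_mu=1e-4)
        runner = ProtocolRunner(cfg)
        w0 = runner.syn.w.copy()
        res = runner.run()
        assert res.counts_1s.sum() == 0
        assert np.allclose(runner.syn.w, w0 * (1 - 1e-4) ** 3000, rtol=1e-10)

    def test_fixed_seed_is_bit_reproducible(self, tiny_run_config):
        r1 = run_training(tiny_run_config)
        r2 = run_training(tiny_run_config)
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
        assert np.array_equal(r1.counts_1s, r2.counts_1s)
        assert np.array_equal(r1.raster, r2.raster)
        assert np.array_equal(r1.final_w, r2.final_w)

    def test_inhibitory_weights_fixed_without_decay(self, tiny_run_config):
        cfg = tiny_run_config
        cfg.decay_enabled = False
        cfg.sigma_noise_mv = 3.0
        runner = ProtocolRunner(cfg)
        w0 = runner.syn.w.copy()
        runner.run()
        inh = ~runner.pop.is_excitatory
        assert np.array_equal(runner.syn.w[inh], w0[inh])
        assert np.array_equal(runner.syn.w[:, inh], w0[:, inh])
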