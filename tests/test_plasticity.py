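"""STDP, weight decay and short-term plasticity arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsanet import (
    STDPConfig, STPState, SynapticState, apply_decay, apply_stdp,
    effective_weights, stdp_delta, stp_step,
)


def make_syn(n=3, w=None, w_max=10.0, exc=None):
    exists = ~np.eye(n, dtype=bool)
    exc = np.ones(n, bool) if exc is None else exc
    return SynapticState(w=np.zeros((n, n)) if w is None else w,
                         exists_mask=exists, is_excitatory=exc, w_max=w_max)


class TestStdpDelta:
    @pytest.mark.parametrize("s, expected", [
        (1, 0.1 * math.exp(-1 / 20)),      # ~ +0.09512
        (0, 0.0),
        (-20, -0.1 * math.exp(-1)),        # ~ -0.03679
        (5, 0.1 * math.exp(-5 / 20)),
    ])
    def test_exponential_window_values(self, s, expected):
        assert stdp_delta(s) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=1, max_value=200))
    def test_antisymmetric_decreasing_bounded(self, s):
        cfg = STDPConfig()
        assert stdp_delta(s, cfg) == pytest.approx(-stdp_delta(-s, cfg))
        assert abs(stdp_delta(s, cfg)) <= cfg.A
        assert abs(stdp_delta(s + 1, cfg)) < abs(stdp_delta(s, cfg))


class TestApplyStdp:
    def test_pre_before_post_potentiates(self):
        syn = make_syn(w=np.full((3, 3), 5.0))
        apply_stdp(syn, np.array([True, False, False]), t=100)
        apply_stdp(syn, np.array([False, True, False]), t=105)
        assert syn.w[0, 1] == pytest.approx(5.0 + 0.1 * math.exp(-5 / 20))
        # the reverse connection is depressed by the same pairing
        assert syn.w[1, 0] == pytest.approx(5.0 - 0.1 * math.exp(-5 / 20))

    def test_depression_clips_at_zero(self):
        syn = make_syn()
        apply_stdp(syn, np.array([False, True, False]), t=100)
        apply_stdp(syn, np.array([True, False, False]), t=105)
        assert syn.w[0, 1] == 0.0

    def test_potentiation_clips_at_w_max(self):
        syn = make_syn(w=np.full((3, 3), 10.0))
        apply_stdp(syn, np.array([True, False, False]), t=100)
        apply_stdp(syn, np.array([False, True, False]), t=105)
        assert syn.w[0, 1] == 10.0

    def test_simultaneous_spikes_change_nothing(self):
        syn = make_syn(w=np.full((3, 3), 5.0))
        apply_stdp(syn, np.array([True, True, False]), t=50)
        assert np.all(syn.w[syn.exists_mask] == 5.0)

    def test_pairs_beyond_cutoff_ignored(self):
        syn = make_syn(w=np.full((3, 3), 5.0))
        cfg = STDPConfig()
        apply_stdp(syn, np.array([True, False, False]), t=0, config=cfg)
        apply_stdp(syn, np.array([False, True, False]),
                   t=int(cfg.cutoff) + 1, config=cfg)
        assert syn.w[0, 1] == 5.0

    def test_connections_involving_inhibitory_neurons_frozen(self):
        exc = np.array([True, True, False])
        syn = make_syn(w=np.full((3, 3), 2.0), exc=exc)
        syn.w[2] *= -1  # inhibitory output weights are negative
        apply_stdp(syn, np.array([True, False, False]), t=10)
        apply_stdp(syn, np.array([False, True, True]), t=15)
        assert syn.w[0, 2] == 2.0 and syn.w[2, 1] == -2.0
        assert syn.w[0, 1] == pytest.approx(2.0 + 0.1 * math.exp(-5 / 20))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_plastic_weights_stay_in_bounds(self, seed):
        rng = np.random.default_rng(seed)
        syn = make_syn(n=5, w=rng.uniform(0, 10, (5, 5)), w_max=10.0)
        for t in range(200):
            spikes = rng.random(5) < 0.2
            apply_stdp(syn, spikes, t=t)
            if t % 3 == 0:
                apply_decay(syn, 1e-4)
        w = syn.w[syn.plastic_mask]
        assert np.all(w >= 0.0) and np.all(w <= 10.0)


class TestDecay:
    def test_single_step_arithmetic(self):
        syn = make_syn(w=np.full((3, 3), 10.0))
        apply_decay(syn, 5e-7)
        assert syn.w[0, 1] == pytest.approx(9.999995, abs=1e-12)

    def test_zero_rate_is_identity(self):
        syn = make_syn(w=np.full((3, 3), 4.2))
        apply_decay(syn, 0.0)
        assert np.all(syn.w[syn.exists_mask] == 4.2)

    def test_iteration_matches_closed_form(self):
        syn = make_syn(w=np.full((3, 3), 10.0))
        mu, k = 1e-4, 1000
        for _ in range(k):
            apply_decay(syn, mu)
        assert syn.w[0, 1] == pytest.approx(10.0 * (1 - mu) ** k, rel=1e-12)
        # the reference long-run magnitude: a million steps at mu = 5e-7
        assert 10.0 * (1 - 5e-7) ** 10 ** 6 == pytest.approx(6.0653, abs=1e-4)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_decay(make_syn(), 1.5)


def euler_stp_oracle(spike_times, T, U=0.2, tau_d=200.0, tau_f=600.0):
    """Direct integration of the depression/facilitation equations."""
    x, u = 1.0, U
    out = []
    spikes = set(spike_times)
    for t in range(T):
        f = 1.0 if t in spikes else 0.0
        x, u = (x + (1 - x) / tau_d - u * x * f,
                u + (U - u) / tau_f + U * (1 - u) * f)
        out.append((x, u))
    return out


class TestStp:
    def test_rest_fixed_point(self):
        stp = STPState.create(1)
        for t in range(20000):
            stp_step(stp, np.zeros(1, bool))
        assert stp.x_depress[0] == pytest.approx(1.0, abs=1e-9)
        assert stp.u_facil[0] == pytest.approx(0.2, abs=1e-9)

    def test_single_spike_jump(self):
        stp = STPState.create(1)
        stp_step(stp, np.ones(1, bool))
        # facilitation jumps toward 1 by U(1-u); resources depleted by u x
        assert stp.u_facil[0] == pytest.approx(0.2 + (0.2 - 0.2) / 600
                                               + 0.2 * (1 - 0.2))
        assert stp.x_depress[0] == pytest.approx(1.0 + (1 - 1.0) / 200
                                                 - 0.2 * 1.0)

    def test_matches_direct_integration_on_random_train(self):
        rng = np.random.default_rng(11)
        times = sorted(rng.choice(500, size=40, replace=False))
        oracle = euler_stp_oracle(times, 500)
        stp = STPState.create(1)
        spikes = np.zeros(1, bool)
        for t in range(500):
            spikes[0] = t in times
            stp_step(stp, spikes)
            assert stp.x_depress[0] == pytest.approx(oracle[t][0], rel=1e-12)
            assert stp.u_facil[0] == pytest.approx(oracle[t][1], rel=1e-12)

    def test_sustained_firing_depresses_below_single_spike_level(self):
        single = STPState.create(1)
        stp_step(single, np.ones(1, bool))
        single_ux = single.u_facil[0] * single.x_depress[0]
        stp = STPState.create(1)
        for t in range(5000):
            stp_step(stp, np.array([t % 10 == 0]))  # 100 Hz
        assert stp.u_facil[0] * stp.x_depress[0] < single_ux

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 0.9))
    def test_release_factor_never_exceeds_one(self, seed, rate):
        rng = np.random.default_rng(seed)
        stp = STPState.create(2)
        for _ in range(300):
            stp_step(stp, rng.random(2) < rate)
            ux = stp.u_facil * stp.x_depress
            assert np.all(ux <= 1.0)
            assert np.all(stp.x_depress > 0) and np.all(stp.x_depress <= 1.0)


class TestEffectiveWeights:
    def test_disabled_stp_is_identity(self):
        syn = make_syn(w=np.full((3, 3), 4.0))
        assert np.array_equal(effective_weights(syn), syn.w)

    def test_release_factor_scales_rows(self):
        syn = make_syn(w=np.full((3, 3), 10.0))
        stp = STPState.create(3)
        w_eff = effective_weights(syn, stp)  # u=0.2, x=1 at rest
        assert np.allclose(w_eff[syn.exists_mask], 2.0)

    def test_inhibitory_rows_not_modulated(self):
        exc = np.array([True, True, False])
        syn = make_syn(w=np.full((3, 3), 10.0), exc=exc)
        syn.w[2] *= -1
        w_eff = effective_weights(syn, STPState.create(3))
        assert np.allclose(w_eff[2][syn.exists_mask[2]], -10.0)
        assert np.allclose(w_eff[0][syn.exists_mask[0]], 2.0)
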