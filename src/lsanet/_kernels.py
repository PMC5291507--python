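"""Numba-jitted inner loops.

Everything that runs once per simulated millisecond lives here: the Izhikevich
update, synaptic input gathering, nearest-pair STDP, multiplicative weight
decay, Tsodyks-style short-term plasticity, the closed-loop training protocol
state machine, and the robot arena physics.  The public modules wrap these
functions; there is exactly one implementation of each primitive.

Conventions
-----------
* weight matrix ``w[j, i]`` is the connection *from* presynaptic neuron ``j``
  *to* postsynaptic neuron ``i`` (mV added to ``i`` when ``j`` fires).
* spikes at step ``t`` contribute to synaptic input at step ``t + 1``
  (one-step latency; no multi-ms axonal delays).
* all kernels that consume randomness call ``np.random.seed`` on entry with a
  per-chunk seed supplied by the driver, which makes runs reproducible and
  resumable at chunk boundaries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SPIKE_THRESHOLD_MV = 30.0

# protocol state vector indices (int64 array carried across chunks)
PS_MODE = 0        # 0 = stimulation on, 1 = inter-trial delay
PS_ONSET = 1       # absolute ms of current trial's stimulation onset
PS_DELAY = 2       # remaining delay ms
PS_PUNISH = 3      # remaining punishment ms
PS_DELAY_IDX = 4   # next index into the pre-drawn delay array
PS_NTRIALS = 5     # trials completed so far (bookkeeping)
PSTATE_LEN = 6

MODE_STIM = 0
MODE_DELAY = 1

NO_SPIKE = -(1 << 40)  # sentinel for "never spiked" in last_spike_time


@njit(cache=True)
def izh_update(v, u, a, b, c, d, I, half_step, fired):
    """Advance every neuron one 1 ms step; set ``fired`` and apply resets.

    ``half_step=True`` integrates v with two 0.5 ms sub-steps (u once per ms),
    which is the numerically safer scheme at 1 ms resolution; ``False`` is a
    single full Euler step.  A neuron whose v reaches 30 mV is flagged as
    firing and reset to (c, u + d) before the next step.  Once v crosses the
    30 mV peak within a sub-step the spike is definite, so integration of v
    stops there and u is updated with v capped at the peak; this bounds the
    quadratic term under strong synaptic drive (otherwise v, and through it
    u, can overflow within a single millisecond in densely bursting
    networks).
    """
    n = v.size
    for i in range(n):
        vi = v[i]
        ui = u[i]
        Ii = I[i]
        if half_step:
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii)
            if vi < SPIKE_THRESHOLD_MV:
                vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii)
        else:
            vi += 0.04 * vi * vi + 5.0 * vi + 140.0 - ui + Ii
        ui += a[i] * (b[i] * min(vi, SPIKE_THRESHOLD_MV) - ui)
        if not np.isfinite(vi) or not np.isfinite(ui):
            raise FloatingPointError(
                "membrane state became non-finite (numerical blow-up)"
            )
        if vi >= SPIKE_THRESHOLD_MV:
            fired[i] = True
            v[i] = c[i]
            u[i] = ui + d[i]
        else:
            fired[i] = False
            v[i] = vi
            u[i] = ui
    return fired


@njit(cache=True)
def synaptic_input(w, exists, fired_prev, is_exc, stp_on, stp_x, stp_u, out):
    """Sum presynaptic weights of neurons that fired last step into ``out``.

    Under STP the row of an excitatory presynaptic neuron j is scaled by
    u_j * x_j (effective weight w* = u x w).
    """
    n = w.shape[0]
    for i in range(n):
        out[i] = 0.0
    for j in range(n):
        if fired_prev[j]:
            g = 1.0
            if stp_on and is_exc[j]:
                g = stp_u[j] * stp_x[j]
            for i in range(n):
                if exists[j, i]:
                    out[i] += g * w[j, i]
    return out


@njit(cache=True)
def stdp_apply(w, plastic, fired, last_spike, t, A, tau, cutoff, w_max):
    """Nearest-pair additive STDP for every neuron that fired at time ``t``.

    Each new spike pairs once with the counterpart neuron's most recent spike
    (``last_spike``, not yet updated for step t).  Pre-before-post potentiates
    by A exp(-s/tau); post-before-pre depresses by A exp(s/tau); simultaneous
    spikes (s = 0) change nothing.  Pairs farther apart than ``cutoff`` ms are
    ignored.  Weights are clipped to [0, w_max] immediately.
    """
    n = w.shape[0]
    for i in range(n):
        if not fired[i]:
            continue
        for j in range(n):
            if j == i or fired[j]:
                continue
            s = t - last_spike[j]  # > 0: j's last spike precedes i's new one
            if s <= 0 or s > cutoff:
                continue
            dw = A * np.exp(-s / tau)
            if plastic[j, i]:
                # j (pre) fired before i (post): potentiate j -> i
                nw = w[j, i] + dw
                if nw > w_max:
                    nw = w_max
                w[j, i] = nw
            if plastic[i, j]:
                # i (pre) fires after j (post): depress i -> j
                nw = w[i, j] - dw
                if nw < 0.0:
                    nw = 0.0
                w[i, j] = nw


@njit(cache=True)
def weight_decay(w, exists, mu):
    """Multiplicative decay w <- (1 - mu) w on every existing connection."""
    n = w.shape[0]
    f = 1.0 - mu
    for j in range(n):
        for i in range(n):
            if exists[j, i]:
                w[j, i] *= f


@njit(cache=True)
def stp_update(x, uf, fired, is_exc, U, tau_d, tau_f, dt):
    """One Euler step of the depression (x) / facilitation (u) dynamics.

    dx/dt = (1 - x)/tau_d - u x f ;  du/dt = (U - u)/tau_f + U (1 - u) f,
    with f the spike indicator.  Both derivatives are evaluated at the
    current state (simultaneous update).  Only excitatory neurons carry STP.
    """
    n = x.size
    for i in range(n):
        if not is_exc[i]:
            continue
        f = 1.0 if fired[i] else 0.0
        xi = x[i]
        ui = uf[i]
        x[i] = xi + dt * ((1.0 - xi) / tau_d - ui * xi * f)
        uf[i] = ui + dt * ((U - ui) / tau_f + U * (1.0 - ui) * f)
        if not (0.0 < x[i] <= 1.0 + 1e-9) or not (0.0 <= uf[i] < 1.0 + 1e-9):
            raise FloatingPointError("STP variable left its invariant range")


@njit(cache=True)
def count_zone(fired, zone):
    c = 0
    for k in range(zone.size):
        if fired[zone[k]]:
            c += 1
    return c


@njit(cache=True)
def run_protocol_chunk(
    # neuron state
    v, u, pa, pb, pc, pd, is_exc,
    # synaptic state
    w, exists, plastic, w_max,
    decay_on, decay_mu,
    stdp_on, stdp_A, stdp_tau, stdp_cutoff, last_spike,
    stp_on, stp_x, stp_u, stp_U, stp_tau_d, stp_tau_f,
    # integration / noise
    sigma, half_step,
    # zones
    input_zone, zone_a, zone_b,
    # stop condition
    stim_amp, a_min, b_max, use_b_clause,
    # stimulus (punishment) condition
    punish_on, punish_threshold, punish_amp, punish_duration, punish_targets,
    # trial scheduling
    timeout_ms, delays,
    # carried state
    pstate, fired_prev,
    # chunk bookkeeping
    t0, chunk_ms, noise_seed,
    # outputs
    trial_onset, trial_rt, trial_timed_out, trial_count,
    counts_1s,
    debug_on, debug_rec,
    record_raster, raster_t, raster_i, event_count,
    snap_every, snaps, snap_count,
):
    """Simulate ``chunk_ms`` steps of the closed-loop training protocol.

    Per-ms order: external input assembly -> synaptic + noise summation ->
    Izhikevich update -> STP update -> recording -> stop / stimulus condition
    checks and trial scheduling -> STDP -> decay.  All mutable state arrays
    are updated in place so the driver can chain chunks (or snapshot between
    them).  Completed trials are appended to the trial_* buffers.
    """
    np.random.seed(noise_seed)
    n = v.size
    e_ext = np.zeros(n)
    I = np.zeros(n)
    fired = np.zeros(n, np.bool_)

    for k in range(chunk_ms):
        t = t0 + k

        # --- external stimulation for this step -------------------------
        for i in range(n):
            e_ext[i] = 0.0
        stim_active = pstate[PS_MODE] == MODE_STIM
        if stim_active and stim_amp != 0.0:
            for z in range(input_zone.size):
                e_ext[input_zone[z]] += stim_amp
        punish_active = pstate[PS_PUNISH] > 0
        if punish_active:
            for z in range(punish_targets.size):
                e_ext[punish_targets[z]] += punish_amp
            pstate[PS_PUNISH] -= 1

        # --- total input and neuron update ------------------------------
        synaptic_input(w, exists, fired_prev, is_exc, stp_on, stp_x, stp_u, I)
        if sigma > 0.0:
            for i in range(n):
                I[i] += e_ext[i] + np.random.normal(0.0, sigma)
        else:
            for i in range(n):
                I[i] += e_ext[i]
        izh_update(v, u, pa, pb, pc, pd, I, half_step, fired)
        if stp_on:
            stp_update(stp_x, stp_u, fired, is_exc, stp_U, stp_tau_d, stp_tau_f, 1.0)

        # --- recording ---------------------------------------------------
        sec = k // 1000
        for i in range(n):
            if fired[i]:
                counts_1s[sec, i] += 1
                if record_raster and event_count[0] < raster_t.size:
                    raster_t[event_count[0]] = t
                    raster_i[event_count[0]] = i
                    event_count[0] += 1
        ca = count_zone(fired, zone_a)
        cb = count_zone(fired, zone_b)
        if debug_on:
            debug_rec[k, 0] = ca
            debug_rec[k, 1] = cb
            debug_rec[k, 2] = 1 if stim_active else 0
            debug_rec[k, 3] = 1 if punish_active else 0

        # --- stop condition / trial scheduling ---------------------------
        if pstate[PS_MODE] == MODE_STIM:
            trial_done = False
            satisfied = ca >= a_min and ((not use_b_clause) or cb < b_max)
            if satisfied:
                m = trial_count[0]
                trial_onset[m] = pstate[PS_ONSET]
                trial_rt[m] = t - pstate[PS_ONSET]
                trial_timed_out[m] = False
                trial_count[0] = m + 1
                trial_done = True
            elif t - pstate[PS_ONSET] + 1 >= timeout_ms:
                m = trial_count[0]
                trial_onset[m] = pstate[PS_ONSET]
                trial_rt[m] = timeout_ms
                trial_timed_out[m] = True
                trial_count[0] = m + 1
                trial_done = True
            if trial_done:
                pstate[PS_MODE] = MODE_DELAY
                pstate[PS_DELAY] = delays[pstate[PS_DELAY_IDX] % delays.size]
                pstate[PS_DELAY_IDX] += 1
                pstate[PS_NTRIALS] += 1
        else:
            pstate[PS_DELAY] -= 1
            if pstate[PS_DELAY] <= 0:
                pstate[PS_MODE] = MODE_STIM
                pstate[PS_ONSET] = t + 1

        # --- stimulus (punishment) condition ------------------------------
        if punish_on and cb >= punish_threshold:
            pstate[PS_PUNISH] = punish_duration  # restart on overlap

        # --- plasticity ----------------------------------------------------
        if stdp_on:
            stdp_apply(w, plastic, fired, last_spike, t,
                       stdp_A, stdp_tau, stdp_cutoff, w_max)
        for i in range(n):
            if fired[i]:
                last_spike[i] = t
        if decay_on:
            weight_decay(w, exists, decay_mu)
        for i in range(n):
            fired_prev[i] = fired[i]

        # --- weight snapshots ---------------------------------------------
        if snap_every > 0 and (t + 1) % snap_every == 0:
            s_idx = snap_count[0]
            if s_idx < snaps.shape[0]:
                for jj in range(n):
                    for ii in range(n):
                        snaps[s_idx, jj, ii] = w[jj, ii]
                snap_count[0] = s_idx + 1


@njit(cache=True)
def ray_to_wall(x, y, theta, side):
    """Distance from (x, y) along direction theta to the square [0, side]^2."""
    dx = np.cos(theta)
    dy = np.sin(theta)
    best = 1e18
    if dx > 1e-12:
        tt = (side - x) / dx
        if tt < best:
            best = tt
    elif dx < -1e-12:
        tt = -x / dx
        if tt < best:
            best = tt
    if dy > 1e-12:
        tt = (side - y) / dy
        if tt < best:
            best = tt
    elif dy < -1e-12:
        tt = -y / dy
        if tt < best:
            best = tt
    if best < 0.0:
        best = 0.0
    return best


@njit(cache=True)
def run_robot_chunk(
    # neuron state
    v, u, pa, pb, pc, pd, is_exc,
    # synaptic state
    w, exists, plastic, w_max,
    decay_on, decay_mu,
    stdp_on, stdp_A, stdp_tau, stdp_cutoff, last_spike,
    stp_on, stp_x, stp_u, stp_U, stp_tau_d, stp_tau_f,
    sigma, half_step,
    # zones: left/right sensor input zones, left/right steering output zones
    in_left, in_right, out_left, out_right,
    # stimulation mode: 0 = closed loop (sensor-driven), 1 = constant
    mode, sensitivity, const_amp,
    # arena / body; hull_sensors subtracts the radius from ray distances
    side, radius, speed, sensor_range, sensor_offset, turn_rad, min_dist,
    hull_sensors,
    # carried state
    rstate, ledger, fired_prev,
    t0, chunk_ms, noise_seed,
    # outputs
    near_count_1s, counts_1s,
    record_traj, traj, stim_ms,
):
    """Simulate ``chunk_ms`` steps of the embodied wall-avoidance experiment.

    Per-ms order: sense walls from the current pose -> stimulate the input
    zones (sensor-driven in closed loop, constant otherwise) -> network step
    (inputs, Izhikevich, STP) -> steer by pi/6 per output-zone spike and move
    1 px -> clamp to the arena -> STDP.  ``rstate`` = (x, y, heading) and the
    per-channel stimulation ledger are carried across chunks.
    """
    np.random.seed(noise_seed)
    n = v.size
    e_ext = np.zeros(n)
    I = np.zeros(n)
    fired = np.zeros(n, np.bool_)
    lo = radius
    hi = side - radius

    for k in range(chunk_ms):
        t = t0 + k
        x_pos = rstate[0]
        y_pos = rstate[1]
        heading = rstate[2]

        # --- sensing and input-zone stimulation -------------------------
        if mode == 0:
            d_left = ray_to_wall(x_pos, y_pos, heading + sensor_offset, side)
            d_right = ray_to_wall(x_pos, y_pos, heading - sensor_offset, side)
            if hull_sensors:
                d_left -= radius
                d_right -= radius
            amp_left = 0.0
            amp_right = 0.0
            if d_left <= sensor_range:
                dd = d_left if d_left > min_dist else min_dist
                amp_left = sensitivity / dd
            if d_right <= sensor_range:
                dd = d_right if d_right > min_dist else min_dist
                amp_right = sensitivity / dd
        else:
            amp_left = const_amp
            amp_right = const_amp
        for i in range(n):
            e_ext[i] = 0.0
        if amp_left != 0.0:
            for z in range(in_left.size):
                e_ext[in_left[z]] += amp_left
        if amp_right != 0.0:
            for z in range(in_right.size):
                e_ext[in_right[z]] += amp_right
        delivered = amp_left + amp_right  # per-channel accounting
        ledger[0] += delivered
        stim_ms[k] = delivered

        # --- network step -------------------------------------------------
        synaptic_input(w, exists, fired_prev, is_exc, stp_on, stp_x, stp_u, I)
        if sigma > 0.0:
            for i in range(n):
                I[i] += e_ext[i] + np.random.normal(0.0, sigma)
        else:
            for i in range(n):
                I[i] += e_ext[i]
        izh_update(v, u, pa, pb, pc, pd, I, half_step, fired)
        if stp_on:
            stp_update(stp_x, stp_u, fired, is_exc, stp_U, stp_tau_d, stp_tau_f, 1.0)
        sec = k // 1000
        for i in range(n):
            if fired[i]:
                counts_1s[sec, i] += 1

        # --- steer and move -----------------------------------------------
        n_left = count_zone(fired, out_left)
        n_right = count_zone(fired, out_right)
        heading += turn_rad * (n_left - n_right)
        x_pos += speed * np.cos(heading)
        y_pos += speed * np.sin(heading)
        if x_pos < lo:
            x_pos = lo
        elif x_pos > hi:
            x_pos = hi
        if y_pos < lo:
            y_pos = lo
        elif y_pos > hi:
            y_pos = hi
        rstate[0] = x_pos
        rstate[1] = y_pos
        rstate[2] = heading

        wall_dist = min(min(x_pos, side - x_pos), min(y_pos, side - y_pos))
        if wall_dist < sensor_range:
            near_count_1s[sec] += 1
        if record_traj:
            traj[k, 0] = x_pos
            traj[k, 1] = y_pos
            traj[k, 2] = heading

        # --- plasticity ----------------------------------------------------
        if stdp_on:
            stdp_apply(w, plastic, fired, last_spike, t,
                       stdp_A, stdp_tau, stdp_cutoff, w_max)
        for i in range(n):
            if fired[i]:
                last_spike[i] = t
        if decay_on:
            weight_decay(w, exists, decay_mu)
        for i in range(n):
            fired_prev[i] = fired[i]
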