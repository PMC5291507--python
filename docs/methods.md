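# Methods

## The model

`lsanet` simulates small networks of Izhikevich neurons at a fixed 1 ms
resolution.  Each neuron carries a membrane potential `v` (mV) and a
recovery variable `u`:

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike recorded when `v` reaches 30 mV, followed by the reset
`v <- c`, `u <- u + d`.  Excitatory neurons are regular spiking
(a = 0.02, b = 0.2, c = -65, d = 8), inhibitory neurons fast spiking
(a = 0.1, b = 0.2, c = -65, d = 2).  The per-step input of neuron *i* is

    I_i = sum_j w*_{j,i} f_j  +  e_i  +  m_i

where `f_j` indicates that presynaptic neuron *j* fired on the *previous*
millisecond (one-step synaptic latency, no longer axonal delays), `e_i` is
external stimulation (applied every step while a channel is active, i.e.
1000 Hz), and `m_i` is fresh zero-mean Gaussian noise with standard
deviation `sigma` (mV), drawn independently per neuron and step.

### Integration

Within each millisecond `v` is advanced with two 0.5 ms Euler sub-steps
(`u` once per ms), the published scheme for this model; a single full-step
variant is available via `integrator="full_step"`.  Two numerical guards
apply:

* once `v` crosses the 30 mV peak within a sub-step, integration of `v`
  stops there (the spike is already definite) and `u` is updated with `v`
  capped at the peak.  Without this, densely connected high-weight networks
  (e.g. sweep cells with M >= 60 at w_max = 50) overflow within a single
  millisecond: the quadratic term overshoots, inflates `u`, and the two
  variables feed each other to infinity.
* any non-finite state still aborts the run with `FloatingPointError`.

A deliberate consequence of the 1 ms discretisation: single-neuron firing
rates differ from the continuous ODE by a few spikes per second (e.g. an
RS neuron at constant I = 20 mV fires 42/s here vs 46/s for a dt = 0.01 ms
integration, and fast-spiking neurons saturate well below their ODE rates).
This is a property of the discrete model being simulated, not an
implementation error; tests pin the scheme against an independent
reimplementation instead of the ODE.

## Plasticity

**STDP** (excitatory-to-excitatory connections only) is additive with
amplitude A = 0.1 and time constant tau = 20 ms:
`dw = +A exp(-s/tau)` for pre-before-post (`s = t_post - t_pre > 0`),
`dw = -A exp(s/tau)` for post-before-pre, `dw(0) = 0`.  Pairing is
nearest-spike: each new spike pairs once with the counterpart neuron's most
recent spike.  The pairing window is one time constant (20 ms); pre/post
spikes farther apart do not pair.  The window width matters more than it
may appear: with a much longer window, a tonically firing presynaptic
neuron pairs depressively with a given postsynaptic spike several times
(once per presynaptic spike) but potentiates only once per postsynaptic
spike, which makes weight growth onto rarely firing targets impossible and,
in the three-neuron experiments, prevents the indirect pathway from ever
establishing.  Weights are clipped to [0, w_max] after every update; w_max
is a per-experiment configuration value (10 for the fully connected
selective-learning networks, 50 for the sparse networks, 20 for the STP
networks), never hard-coded.

**Decay** multiplies every existing weight by (1 - mu), mu = 5e-7, once per
millisecond.  It is enabled in the 100-neuron protocol experiments and
disabled in the 3-neuron demonstrations and the robot runs.  By default
decay applies to inhibitory weights too ("all the weights"); tests pin only
the excitatory behaviour.

**Short-term plasticity** follows the depression/facilitation model with
per-excitatory-neuron variables x (resources) and u (release probability):

    dx/dt = (1 - x)/tau_d - u x f        tau_d = 200 ms
    du/dt = (U - u)/tau_f + U (1 - u) f  tau_f = 600 ms,  U = 0.2

integrated with the same 1 ms Euler clock (both derivatives evaluated at
the current state).  The transmitted weight is `w* = u x w` on excitatory
rows (onto excitatory and inhibitory targets alike); inhibitory rows are
not modulated.  At rest `u x -> 0.2`; under sustained firing depression
dominates, which is what suppresses network-wide bursts.

## Protocols

A trial starts with stimulation of the input zone (amplitude `e` mV every
millisecond) and ends when the stop condition holds in a single 1 ms bin —
at least `a_min` spikes in output zone A and, for selective learning, fewer
than `b_max` spikes in output zone B *in the same bin* — or after a 10 s
timeout.  The reaction time is the delay from onset to the satisfying bin.
Stimulation then pauses for a uniformly random integer delay of 1000 to
2000 ms.  The optional stimulus (punishment) condition is evaluated every
millisecond independently of the trial state: when zone B reaches its spike
threshold, all excitatory neurons outside zone B are stimulated for the
next 10 ms, and a re-trigger restarts the 10 ms window.  The punishment
amplitude equals the experiment's stimulation amplitude (the reference
experiments print no separate value).

The per-millisecond order of operations is: external-input assembly,
synaptic + noise summation, neuron update, STP update, recording, stop /
stimulus condition checks and trial scheduling, STDP, decay.

**Learning criterion.**  The learning index is the earliest trial from
which every subsequent reaction time stays below 4000 ms (pure suffix
scan); the learning time is the simulated time at that trial's onset, and
the attained reaction time is the mean over all post-learning trials.
A run counts as *successful* only if the sustained suffix contains at
least 5 trials: noise-driven networks produce chance sub-4000 ms responses
in roughly a quarter of trials, so one or two lucky trials at the end of
the budget are not evidence that the limit is being "kept" (and the
no-stimulation control must score a strict 0%, as reported).

**Zone statistics.**  Rates are computed from per-neuron spike counts in
1 s bins.  Learnability is the output zone's mean per-neuron rate (Hz) in
the last 100 s minus the first 100 s of a 500 s run.

## Experiment presets and chosen problem sizes

* `selective_learning` — fully connected 100-neuron network (80E/20I,
  initial |w| ~ U(0,5)), e = 1 mV, sigma = 3 mV, w_max = 10, decay on,
  stop condition 4/4, budget 400 s.  The no-stimulation control is the same
  configuration with the external channel disabled.
* `sparse_steering` — 20 random output connections per neuron (drawn with
  replacement, so realised out-degree <= 20), |w| ~ U(0,10), w_max = 50,
  e = 10 mV, sigma = 5 mV, stop threshold 1 (no B clause), punishment
  threshold 1; 500 s runs (the run length for the steering figures is not
  printed; 500 s matches the sweep protocol).
* `stp_selective` — fully connected with STP, all input-zone to output-zone
  weights removed, w_max = 20, e = 10 mV, sigma = 3 mV, stop 4/4,
  punishment threshold 1.
* `chain3_*` — three excitatory neurons, all six connections, w_max = 10,
  sigma = 3 mV, no decay, e = 20 mV.  The drive is chosen so the input
  neuron fires every ~25 ms, inside the STDP window — the mechanism
  requires pre-spikes shortly before the stop-condition spike.  The demos
  use defined initial states (weights 2.5 throughout; the direct weight
  starts at 1.0 in the reinforcement variant and is removed in the indirect
  variant), with seeds varying noise and delays.  Durations: 1000 s
  (reinforcement, pruning) and 4000 s (indirect pathway, which grows an
  order of magnitude more slowly).
* `sweep` — sparse topology with |w| = 5 + U(-v, v) per drawn connection
  (sign preserved), stop condition only, 500 s, learnability as above.
* `robot_*` — 100-neuron STP network in `stp_selective` style (|w| ~ U(0,5),
  w_max = 20, sigma = 3 mV, no decay, direct input-to-output connections
  kept), four 10-neuron zones (left/right sensor inputs, left/right
  steering outputs).  Arena 1000 px square, robot radius 25 px, speed
  1 px/ms, sensors at +-pi/4 with 80 px range, steering pi/6 per output
  spike, position clamped component-wise at the walls with heading
  unchanged.  Sensor input is sensitivity/distance per millisecond, with
  the distance measured along the sensor ray **from the robot's hull**
  (ray length minus radius, clamped at 1 px).  Hull-based distance is the
  package default because the robot's centre can never get closer than its
  own radius to a wall, so a centre-based reading is bounded away from
  small values and delivers too little stimulation for any closed-loop
  learning to occur; a centre-based mode is available via
  `sensor_distance_mode="ray_center"`.  Robot runs last 1000 s (learning
  onset is at ~500-700 s, so shorter runs have not yet separated the
  conditions); wall proximity is the fraction of milliseconds with the
  nearest wall closer than the 80 px sensor range, reported over the final
  300 s.

## Randomness and reproducibility

One master seed fans out through named `SeedSequence` substreams (topology,
zones, inter-trial delays, per-chunk noise, robot pose), so changing one
stochastic component leaves the others reproducible.  Runs execute in
chunks (default 10 s of simulated time); the in-kernel noise generator is
reseeded per chunk from the (master, chunk-index) pair, which makes
snapshot/resume at chunk boundaries bit-exact — two runs of any preset with
the same seed produce byte-identical artifacts.

## What the simulations do and do not show

All inputs are generated by the simulator itself; there is no external
data.  The networks are small (100 neurons), fully or sparsely connected
without spatial structure, with instantaneous (next-millisecond) synapses
and a single STDP rule; none of the biological features of cultured
networks (conduction delays, synaptic failure, heterogeneous cell
parameters, development) are modelled.  Passing tests therefore show that
the stimulation-avoidance principle — remove stimulation when the desired
pattern occurs, deliver it when the undesired pattern occurs — steers
*this* model class, not that it quantitatively predicts any biological
preparation.

Two reference quantities are known not to reproduce under the
package's defaults and are reported as computed: the plain open-loop robot
control barely steers (its near-wall fraction stays ~93% instead of ~64%),
because with U(0,5) initial weights and STP the constant input-zone drive
does not propagate to the output zones; and the closed-loop robot receives
~4.6 mV/ms of sensor stimulation in its pre-learning phase (printed
reference: 1.54 mV/ms), because the hull-based sensor reads distances down
to the 1 px clamp while the robot is pressed against a wall.  Raising the
initial weight range reproduces the open-loop figure but collapses the
matched-stimulation control (the study's central feedback-vs-intensity
contrast), so the defaults keep the U(0,5) initialisation.
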