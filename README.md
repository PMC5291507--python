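# lsanet

Learning by stimulation avoidance in spiking neural networks: a simulator
for closed-loop stimulation experiments on Izhikevich networks with
spike-timing-dependent plasticity (STDP), and for an embodied
wall-avoidance robot controlled by such a network.

The scientific question the package addresses: can a random recurrent
spiking network be *steered* purely by the timing of an external
stimulus — applying a focal stimulation until a desired firing pattern
appears, then removing it — without any reward signal or supervised rule?
With plain Hebbian STDP, firing patterns whose occurrence terminates the
stimulation are strengthened and patterns that trigger stimulation are
weakened, so the network learns to produce the desired output quickly
("stimulation avoidance").  The package is written for computational
neuroscientists who want to reproduce, probe or extend that family of
closed-loop experiments: selective learning of output-zone activity,
synapse reinforcement and pruning in a minimal 3-neuron circuit,
burst-suppression by noise or by short-term plasticity (STP), a
connectivity/weight-variance sweep, and sensory-motor wall-avoidance
learning by a simulated robot.

## Model

Neurons follow the two-variable quadratic model

    v' = 0.04 v² + 5 v + 140 − u + I,      u' = a (b v − u),

with spike at v ≥ 30 mV, then v ← c, u ← u + d (regular-spiking parameters
for the 80 excitatory neurons, fast-spiking for the 20 inhibitory ones;
1 ms steps).  Per-step input is I = Σ_j w*_{j,i} f_j + e + m: last-step
presynaptic spikes, external stimulation e, Gaussian noise m (σ per
experiment).  Excitatory→excitatory weights evolve by additive STDP

    Δw(s) = ± A e^(−|s|/τ),   A = 0.1,  τ = 20 ms,  s = t_post − t_pre,

clipped to [0, w_max], with optional global decay w ← (1 − μ) w
(μ = 5·10⁻⁷) and optional Tsodyks-style short-term plasticity
w* = u x w (U = 0.2, τ_d = 200 ms, τ_f = 600 ms) that suppresses global
bursts.  Training alternates stimulation-on trials (stopped by the desired
output pattern or a 10 s timeout) with 1–2 s pauses; an optional
punishment rule stimulates the whole excitatory network for 10 ms whenever
the undesired output zone fires.  See `docs/methods.md` for every rule,
default and design choice.

## Worked example

```python
from lsanet import run_preset

res = run_preset("selective_learning", seed=1)
m = res.metrics
print("trials:", m.n_trials)
print("success:", m.success)
print("learning_time_s:", m.learning_time_s)
print("attained_reaction_time_ms:", round(m.attained_reaction_time_ms, 1))
```

prints

```
trials: 170
success: True
learning_time_s: 136.433
attained_reaction_time_ms: 490.3
```

i.e. over a 400 s budget this network ran 170 stimulation trials; from
t ≈ 136 s onward the delay between stimulation onset and the desired
output pattern (≥ 4 spikes in output zone A and < 4 in zone B in the same
millisecond) stayed below 4 s for the rest of the run, with a mean
post-learning reaction time of 490 ms.  The minimal-circuit demos work the
same way — `run_preset("chain3_prune", seed=0)` drives the direct
input→output weight from 2.5 to 0.0 because the output neuron's spiking
*starts* stimulation there, so the network prunes the synapse that causes
stimulation.

The same experiments are available from the shell:

```
lsanet run selective_learning --seed 1 --out out/sel1
lsanet sweep --m-values 5,25,60,120 --v-values 1,3 --reps 5 --out out/sweep.csv
lsanet robot --mode closed --sensitivity 8 --duration-ms 1000000 --seed 0 --out out/robot
```

Each run writes `config.json` (exact echo; re-running it reproduces the
results bit-for-bit), `trials.csv`, `metrics.json`, and optionally a spike
raster (`time_ms<TAB>neuron_id`) and weight snapshots.

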