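# dynsynrl

Reward-modulated learning of **hidden dynamic-synapse parameters** in a
spiking network, benchmarked on a temporally coded XOR task.

Most reinforcement-learning rules for spiking networks tune synaptic
*weights*. Some biophysical synapse models, however, have no scalar weight
to tune — their response is shaped by hidden kinetic parameters. This
package implements and dissects a framework in which a leaky
integrate-and-fire (LIaF) network with Tsodyks–Markram (TM) short-term
plasticity learns by adjusting those hidden parameters — the utilization
increment `U_SE`, the recovery constant `τ_rec`, and the facilitation
constant `τ_fac` — from a scalar reward, leaving the static weight `A`
untouched. It is intended for computational neuroscientists who want a
reproducible, testable reference implementation of this class of rule.

## Model

Neurons follow `τ_V dV/dt = V_rest − V + EPSP(t)` with threshold/reset and
a 2-ms absolute refractory period. Each synapse carries TM dynamics

    dr/dt = (1 − r)/τ_rec − u·r·δ(t − t_i)
    du/dt = (U_SE − u)/τ_fac + U_SE·(1 − u)·δ(t − t_i)

with postsynaptic drive `A·u⁺·r` per presynaptic spike and dynamic
strength `S = r·u`. Two Poisson inputs (50 Hz, 200-ms episodes, 1-ms grid)
feed a hidden LIaF layer and one output neuron; the target is the per-bin
XOR of the binned (W = 5 ms) inputs. After each episode the binned output
F and reference G are compared with the van Rossum distance
`D = (1/τ_c)∫(f − g)² dt` (τ_c = 15 ms, evaluated exactly in closed form),
the reward `Rwd = exp(−α·D)` and TD error `δ = μ(Rwd_prev − Rwd_curr)` are
formed, and the input→hidden synapses update multiplicatively,
`Δm = η·m·(signed error term)`, η = 0.01, μ = 7, α = 0.01. Three readings
of the sign handling are provided (`fixed`, `adaptive`, `hebbian`); see
`docs/methods.md` for why `adaptive` is the default and what the rule can
and cannot achieve under fresh-input episodes.

## Worked example

Run the default experiment (7 hidden neurons, 300 episodes) and summarize:

```bash
dynsynrl run --out demo_run --seed 7
```

prints (numbers from this exact command):

```
{"distance": {"mean": 4.187024037042094, "sd": 2.025133901894006},
 "crosscorr": {"mean": 0.6247188283140274, "sd": 0.1227791009549463},
 "hit_rate_binned": {"mean": 74.35, "sd": 8.759979731595227}}
results written to demo_run
```

Read: over the final 50 episodes, the binned network output sits at a mean
van Rossum distance of ≈4.19 (bin units) from the XOR reference, their
Gaussian-smoothed maximum cross-correlation is ≈0.62, and ≈74 % of the 40
bins agree. `demo_run/` now contains `episodes.csv` (per-episode measures),
`parameters.csv` (synaptic parameter trajectories), `strength.csv`
(per-episode time-averaged S per synapse), a `config.yaml` echo that
reproduces the run bitwise, and `manifest.json` (seed provenance). Add
`--plots` for learning-curve, parameter-trajectory, and strength-course
PNGs. Other subcommands: `dynsynrl sweep --windows 4,5,7` (window sweep at
fixed binned length), `dynsynrl summarize <dir>`, and `dynsynrl metrics
<a.trains> <b.trains>` for comparing serialized spike-train files.

Library use mirrors the CLI:

```python
from dynsynrl import ExperimentConfig, LearningConfig, run_training, summarize

result = run_training(ExperimentConfig(n_hidden=7, seed=7), LearningConfig())
stats = summarize(result.records, last_k=50, network=result.network)
```

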