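# Methods

`dynsynrl` simulates a small feed-forward spiking network whose synapses are
Tsodyks–Markram (TM) dynamic synapses, and trains the *hidden* synaptic
parameters — not the synaptic weights — with an episodic, reward-modulated
Hebbian rule. The benchmark task is a temporally coded XOR: the network
should reproduce, bin by bin, the XOR of its two Poisson input trains.

## Models

**Neuron.** Leaky integrate-and-fire:
`tau_V dV/dt = V_rest − V + EPSP(t)`, with `tau_V = 20 ms`, `V_rest = 0 mV`,
`V_th = 50 mV`, and an absolute refractory period `tau_refr = 2 ms` during
which V is clamped at rest. The two input neurons are pure relays that emit
their assigned stimulus trains; only hidden and output neurons integrate.

**Synapse.** TM short-term plasticity with resource fraction `r`
(depression; recovery constant `tau_rec`) and utilization `u`
(facilitation; baseline `U_SE`, relaxation constant `tau_fac`). At a
presynaptic spike, facilitation is applied before release
(`u+ = u + U_SE (1 − u)`, `release = u+ · r`, `r+ = r − u+ · r`), and the
postsynaptic drive is `A · release`, with `A < 0` for inhibitory synapses.
The dynamic synaptic strength is `S = r · u`.

**Integration.** Between spikes all state equations are linear, so `r`,
`u`, and `V` are advanced with their exact exponential solutions at the
1-ms grid; spike jumps are applied at step boundaries. Within one step:
decay all states, deliver spikes emitted at the previous step (one-step
synaptic latency), sum the drives, test thresholds. This removes Euler
error at the coarse grid entirely; the test suite verifies agreement with
a dt = 0.001 ms Euler integration to 1e-3 and with closed forms to 1e-9.

**Topology.** 2 inputs → fully connected hidden layer (default 7 neurons)
→ 1 output. Exactly two input→hidden synapses and one hidden→output
synapse are made inhibitory, drawn once per run from a dedicated random
substream and fixed thereafter.

## Task and measures

Each 200-ms episode draws two fresh 50-Hz Poisson trains (Bernoulli
per 1-ms step). Inputs are binned with non-overlapping windows of
`W = 5 ms` (a bin is high iff it contains a spike); the reference is the
per-bin XOR, realized as a spike train with one spike at each high bin's
centre (so it re-bins to the reference exactly). Performance measures per
episode, computed between binned output F and binned reference G:

- **van Rossum distance** `D = (1/tau_c) ∫ (f − g)^2 dt` with causal
  unit-jump exponential filters, `tau_c = 15 ms` converted to bin units
  (`tau_c / W` bins). The integral is evaluated in closed form (pairwise
  exponential kernel sums), which is exact; a trapezoidal evaluator is
  included for validation. Under this normalization a lone unpaired spike
  costs exactly 1/2 regardless of `tau_c`, and a displaced spike costs
  `1 − exp(−Δt/tau_c)`.
- **Maximum cross-correlation** X: both binned sequences smoothed with a
  Gaussian of width 1 bin (a free choice of this package; exposed in config),
  then the maximum over lags (up to half the sequence length) of the
  overlap-normalized Pearson coefficient.
- **Hit rates**: percent of agreeing positions (ones and zeros) at 1-ms
  and at bin resolution.

The reward is `Rwd = exp(−alpha · D(F,G))` with `alpha = 0.01`, and the
temporal-difference error between consecutive episodes is
`delta_Rwd = mu (Rwd_prev − Rwd_curr)` with `mu = 7` (trace decay fixed at
`lambda = 1`).

## Learning rule

Only input→hidden synapses are eligible. Each carries its own copy of
`(U_SE, tau_rec, tau_fac)`; updates are multiplicative,
`Δm = eta · m · (signed error term)` with `eta = 0.01`, clipped to
`U_SE ∈ [0.01, 1]`, `tau_rec, tau_fac ∈ [1, 1000] ms`; the weight `A` is
never trained. Initial values are `U_SE = 0.5`, `tau_rec = 100 ms`,
`tau_fac = 50 ms`.

How the sign of the TD error maps onto the direction of each parameter's
change is genuinely open, so three readings are implemented
(`learning.update_rule`):

- `fixed`: `Δm = sign_m · eta · m · delta_Rwd` with the sign table
  `sign(U_SE) = sign(tau_fac) = −1`, `sign(tau_rec) = +1` (facilitation
  strengthens when the reward improved). This rule telescopes: summing
  over a run, `Δ log m ≈ sign_m · eta · mu · (Rwd_first − Rwd_last)`, so
  the net parameter change over any run is bounded by ~e^±0.07. It can
  therefore never converge to new values or forget its initialization.
- `adaptive` (default): direction-memory hill climbing. Each synapse
  keeps a direction state on the facilitation axis; a worsened reward
  (`delta_Rwd > 0`) reverses it, and the step is `eta · m · |delta_Rwd|`
  along it (facilitation parameters with the direction, `tau_rec`
  against it). This is the only reading under which sustained parameter
  drift is possible at all, which is why it is the default.
- `hebbian`: the fixed rule gated per synapse by a signed eligibility
  vote — presynaptic spikes in reference-high bins vote +1 (a
  postsynaptic spike was desired), spikes in reference-low bins −1.

The first episode only seeds the reward state; per-episode relative
changes are bounded by `eta · mu` (7 % with defaults), which the test
suite asserts on every logged update.

## Amplitude calibration

The nominal `A = 7×10⁻⁴` cannot drive a 50-mV threshold (the largest
possible single-spike drive is `A · 1` ≪ `V_th`), so the default amplitude
is a package calibration: `|A| = 5500` makes the untrained hidden and
output neurons fire at roughly the 50-Hz input rate, inside a
physiological 10–100 Hz band. The literal value remains available via
`synapse.literal_amplitude: true` (the network is then silent).

## Synthetic inputs: what they do and do not emulate

Stimuli are memoryless Bernoulli-thinned Poisson trains at exactly one
spike per ms maximum; 600 fresh trains per run are consumed once, so no
episode repeats an input. This matches the stated protocol but carries no
serial correlation, rate drift, or refractory structure of real afferents.
Passing tests therefore demonstrate properties of the model under ideal
stationary drive, not robustness to realistic input statistics.

## Numerical choices and degenerate inputs

- Episodes are independent trials: synaptic states and membrane
  potentials reset to rest (`r = 1`, `u = U_SE`, `V = V_rest`) at episode
  start.
- Identical-input episodes (near-empty XOR target) are allowed; the
  cross-correlation of a zero-variance smoothed sequence is defined as 0
  with a warning.
- All randomness flows from one master seed through named substreams
  (input generation, inhibitory assignment), so topology can be held
  fixed while inputs vary; full runs are bitwise reproducible from the
  persisted config.
- Ties in the cross-correlation lag search resolve to the first maximal
  lag; the result is lag-symmetric up to smoothing edge effects.

## Known limitations

The headline learning effect is not attainable under the stated protocol,
and the package makes the reason measurable rather than hiding it. A
parameter-space scan (`eta = 0`) shows a genuine optimum — lowering
`tau_rec` toward ~10 ms roughly halves the converged distance — but
reaching it requires ~2.3 log-units of coherent drift, while the episodic
TD step size is at most `eta · mu · |ΔRwd| ≈ 0.1–0.3 %` per episode and
the reward difference between consecutive episodes is dominated by
input-sampling noise (SD(D) ≈ 1.5 across fresh Poisson episodes, versus a
per-step parameter effect on D of ~10⁻³). Every episodic reading of the
rule is therefore a near-unbiased random walk: over 300 episodes
parameters move a few percent, and last-50 distances are statistically
indistinguishable from `eta = 0` controls. A near-noiseless reward
difference (for example, repeating the same input pair across episodes)
would restore coherent hill climbing, but contradicts the fresh-input
protocol this package implements. The acceptance checks that encode the
reference converged magnitudes are accordingly expected to fail, and the
quantities are reported as computed.
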