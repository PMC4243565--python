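# Methods

## Model

The network is a vector `x^t ∈ {0,1}^N` of binary neurons in discrete time,
optionally extended by `N_ext` external input neurons at trailing indices
whose states are copied from a stimulus stream, never sampled. Each
recurrent neuron receives the membrane input

```
s_i^t = Σ_{j≠i} w_ij x_j^t − h_i
```

and fires at the next step independently with probability
`p(x_i^{t+1}=1 | x^t) = p_max σ(s_i^t)`, with σ the logistic function and
`p_max ∈ (0,1]` the maximal transmission probability. There are no
self-connections (the recurrent diagonal of `w` is structurally zero) and
no sign constraint on weights: a single model neuron may make both
excitatory and inhibitory synapses. A noisy leaky integrate-and-fire
simulation (`lif_fi_curve`) reproduces the standard justification for this
transfer: the f–I curve of an LIF neuron with Wiener noise is a saturating
sigmoid whose ceiling is set by the refractory period, so `s` plays the
role of an input current and `p_max` of a refractory ceiling. No physical
duration is assigned to one time step; the discrete dynamics stand on
their own.

## Objective

Learning ascends an approximate information-retention objective
(natural-log units internally; the reported `I_gauss` is in bits):

- `A1 = Σ_i log I[x_i^t ; x^{t-1}]` — per-neuron predictability. The sum of
  per-neuron information terms lower-bounds the full `I[x^t; x^{t-1}]`
  exactly when neurons are independent, which the next term enforces; the
  logarithm accelerates learning when the terms are small.
- `A2 = κ Σ_{i<j} cov(x_i, x_j)` — pairwise-correlation penalty, equally
  readable as a population-sparseness penalty since
  `Σ_{i<j} x_i x_j = m(m−1)/2` with `m = Σ_i x_i`.
- `A3 = (η/2) Σ_i (E[x_i] − p0)²` — rate control toward the target `p0`.
- `A4 = (ζ/2) Σ_i E[(s_i − s0)²]` — membrane-input fluctuation control
  around the reference `s0 = log(p0/(p_max−p0))`, the input at which a
  neuron fires at exactly `p0`. Without this term, runaway positive and
  negative weights eventually produce near-periodic firing in which the
  pairwise-correlation approximation underlying `A2` breaks down.

The raw coefficients are parameterised by size- and rate-free constants,

```
κ = 2 / ((N−1) c_κ p0²),   η = 1 / (c_η² p0⁴),   ζ = 1 / c_ζ²,
```

so that each penalty term is O(N) and comparable `c` values exert
comparable pressure across system sizes and rates. (The grouping of these
formulas is ambiguous in the source text; this reading is the one under
which the scale-freeness argument goes through, and is fixed throughout.)

## Learning rule

Stochastic-gradient ascent on `A` becomes temporally and synaptically local
through two ingredients:

1. **Eligibility traces.** The score term
   `ψ_i^t = ∂/∂s log p(x_i^{t+1}|s)|_{s_i^t}` equals `1 − σ(s_i^t)` when the
   neuron fires next step and `−p_max σ(1−σ)/(1−p_max σ)` when it stays
   quiescent. It has exactly zero mean under the model's own firing law
   (score-function identity, asserted to machine precision in the tests).
   Every synapse integrates `⟨ψ_i x_j⟩_τ` leakily with constant τ; every
   neuron integrates `⟨ψ_i⟩_τ`.
2. **Global gating.** At each step one scalar `γ1 − γ2 − γ3 − γ4`
   multiplies all traces:
   - `γ1 = Σ_i log[p(x_i^t|x^{t-1})/Z_i] / max(⟨log ...⟩_T, δ)` with `Z_i`
     the slow estimate of the marginal firing probability (its complement
     for quiescent neurons). The `a_prime` variant normalises the
     population sum instead of each neuron's term.
   - `γ2 = κ{m(m−1)/2 − (⟨m⟩_T − p0) m}`,
   - `γ3 = η Σ_i (⟨p_max σ(s_i)⟩_T − p0) x_i`,
   - `γ4 = (ζ/2) Σ_i (s_i − s0)²`.

All slow statistics are leaky averages `⟨q^t⟩_T = q^{t-1}/T + (1−1/T)⟨q^{t-1}⟩_T`,
zero-initialised; the stochastic approximation is exact in the limit
τ → ∞, T/τ → ∞. The update applied at step t is

```
Δw_ij = ε(τ/T)(γ1−γ2−γ3−γ4)⟨ψ_i x_j⟩_τ − ε(ζ/T)(s_i−s0)x_j
Δh_i  = −ε(τ/T)(γ1−γ2−γ3−γ4)⟨ψ_i⟩_τ  + ε(ζ/T)(s_i−s0)
```

with ε held constant (no annealing).

### Step schedule

One step at time t, with `x^t` current and `s^{t-1}` the input that
generated it: (1) compute `s^t`; (2) assemble the γ signals from `x^t`,
`s^{t-1}` (predictability) and slow averages that contain quantities up to
t−1 only (strictly causal); (3) apply the update using traces containing
pairs up to `(ψ^{t-1}, x^{t-1})`; (4) sample `x^{t+1}` from `s^t`;
(5) fold `(ψ^t, x^t)` into the traces; (6) fold step-t quantities into the
slow averages. The compiled kernel and a pure-numpy reference
implementation of this schedule agree to ~1e-15 over hundreds of steps
(tested, including external inputs and the `a_prime` variant).

### Numerical choices

- The singularity at `⟨log p/Z⟩_T = 0` is removed by flooring the
  denominator at δ = 1e-3. The same floor is applied to a cold-start `Z`
  of zero (all averages start at zero, so the first firing step would
  otherwise divide by zero); this removable startup guard affects only the
  first few steps of a run.
- σ is evaluated in a branch that never overflows `exp`.
- No weight or threshold clipping is applied; if any parameter becomes
  non-finite the trainer aborts with the last finite state intact.
- Plasticity masks (`plastic_rows`, `plastic_cols`) restrict updates; in
  input-driven experiments rows run over recurrent neurons and columns
  over recurrent + external neurons, and the designated feedforward
  synapses start at 100 and remain plastic. The γ sums run over a
  configurable scope (all recurrent neurons by default; restricted to the
  recurrent population in the image experiment, where the input cells'
  statistics are i.i.d. by construction). Thresholds follow the same row
  mask as weights.
- RNG: one root seed is split into independent initialization / dynamics /
  stimulus streams. The kernels consume pre-drawn uniforms in (step,
  neuron) order, so trajectories are bit-reproducible, independent of
  chunk size, and unaffected by recording. Snapshots carry all trace
  state and RNG states, making resume bit-identical (tested).

## Stimulus protocols

- **Episodic sequences**: 3 external neurons; within an episode neuron 1
  fires at the first step, neuron 3 at the third, neuron 2 at the fifth,
  each independently with probability 1/2, giving 2³−1 = 7 distinct
  non-silent episode variants; episode onsets are separated by integer
  gaps uniform on [50, 100].
- **Images**: 12×12 patches are drawn i.i.d. per step from whitened images
  (`L(f) = f·exp(−(f/f_c)^4)`, `f_c` = 200 cycles/picture, radial
  frequency on the unshifted FFT grid) and relayed by one ON and one OFF
  cell per pixel with `p(ON) = min(ξ y⁺, 1)`, `p(OFF) = min(ξ y⁻, 1)`.
  The gain ξ = 1.65 produces a ~0.15 population rate on the original
  natural-image ensemble; on other ensembles ξ is calibrated by bisection
  to a requested rate (default 0.15), treated as the population average
  over ON and OFF cells.
- **Synthetic fixture**: Gaussian random-phase images with radial
  amplitude spectrum `|f|^{−1}` (unit variance, zero mean). This
  reproduces the second-order statistic of natural scenes that the
  whitening/encoding pipeline consumes, but none of their phase structure
  (edges, occlusions) — so receptive fields learned on the fixture need
  not be Gabor-like, and tests that pass on it certify the pipeline, not
  natural-image feature extraction.

## Analyses

- `I_gauss = log2|Ĉ| − ½ log2|D̂|` from the covariances of `x^t` and the
  concatenated `(x^t, x^{t-1})`; exact for Gaussian data, and within 15%
  of the enumerated mutual information on weakly coupled networks
  (|w| ≤ 1) at 1e6 samples (tested at N = 5, 6). The estimate carries a
  positive bias that grows as coupling strengthens (bimodal activity) or N
  shrinks: at N = 4 with near-unit weights the systematic gap is ~14%
  even at 1.6e7 samples. Zero-variance neurons are dropped before the
  determinants, and a singular covariance raises rather than returning a
  spurious value.
- **Exact mutual information** by full 2^N enumeration (N ≤ 12): build the
  transition kernel from the dynamics, solve the stationary distribution,
  evaluate the discrete MI in bits. Serves as the oracle for `I_gauss`
  and for the gradient checks.
- **Bursts**: maximal runs of consecutive steps with ≥ 1 spike; size =
  spikes in the run, duration = run length. Runs touching the raster
  boundary are censored (their extent is unknown) and discarded. The
  power-law slope is ordinary least squares on `(log s, log p̂(s))` over
  occupied integer sizes in [1, 50] by default; the source material
  overlays a −3/2 reference line without naming an estimator, so OLS on
  the empirical mass function is a deliberate, simple choice. For an
  *ideal* critical branching process (offspring mixture ½Bin(2,0.4) +
  ½Bin(3,0.4)) this estimator yields −1.41 over sizes 1–50 by exact
  enumeration of the progeny distribution — the pre-asymptotic small-s
  regime flattens the fit relative to the asymptotic −3/2.
- **Censuses**: patterns are exact binary configurations; length-L
  sequences are exact concatenations of L consecutive patterns over a
  sliding window (stride 1). "Repeated" means occurrence > 2 for the
  census convention (configurable; ≥ 2 for raster annotation).
- **CV of ISIs**: population-normalised SD over mean of the inter-spike
  intervals (the printed SD formula in the source is dimensionally
  inconsistent as extracted; the population standard deviation is the
  intended reading). A Bernoulli(p) train has geometric ISIs with
  CV = √(1−p).
- **Shuffle control**: uniform permutation of the off-diagonal recurrent
  weights, preserving the weight multiset, diagonal, thresholds and
  external columns.
- **Spike-triggered averages**: `⟨y_j^{t-1} x_i^t⟩` (patch preceding the
  spike), rescaled per neuron so the pixel mean is exactly 128 and the
  maximal absolute deviation exactly 127 (real-valued gray levels in
  [1, 255]; quantisation to integers happens only at image export).
  Spikeless or flat-STA neurons are flagged degenerate.
- **Strong chains**: breadth-first expansion from root neurons along
  edges `w_ij > 8` (presynaptic j → postsynaptic i) to depth 6 by
  default, labelling nodes with first-reach depth.

## Problem sizes used in the checks

Sizes are chosen so the whole suite runs on one CPU in minutes:

- Gradient agreement: N = 3, 2.5-magnitude uniform random weights, 1e6
  accumulation steps after a 1e5-step warm-up of the slow averages
  (τ = 15, T = 1e4); cosine similarity > 0.9 against a central
  finite-difference gradient of the enumerated objective. The warm-up
  avoids the cold-start transient of the γ1 denominator. With much weaker
  weights the per-neuron information terms fall below δ, the γ1
  normalisation saturates at 1/δ, and the direction degrades — an
  intrinsic property of the floored rule, not an implementation artifact.
- Avalanche exponent: a constructed critical network (50 neurons, each
  driving 2 or 3 targets — in/out degrees balanced by a
  configuration-model pairing — at saturated probability p_max = 0.4;
  branching ratio 1) with spontaneous seeding rate 1e-4 per neuron-step,
  2e7 steps, ≈ 1e5 bursts; fitted slope within −1.5 ± 0.2. The measured
  value (≈ −1.31) sits between the ideal-branching OLS value (−1.41) and
  the merging/collision-flattened regime; rarer seeding no longer changes
  it.
- Learning trend: the avalanche-regime parameter block (N = 50,
  p_max = 0.4, p0 = 0.01, ε = 0.02, c_κ = 30, c_η = 10, c_ζ = 3, τ = 10,
  T = 5e4) run for 1e8 steps (~6 minutes compiled; 5–20× short of the
  full-scale runs). Asserted: Spearman trend of `I_gauss` (logged every
  5e6 steps on rolling 5e4-step windows) > 0.8 with a ≥ 2× rise, and the
  post-learning burst slope strictly closer to −3/2 than at
  initialization. At 1e7 steps the weights have not yet left the
  weak-coupling regime and the avalanche statistics are indistinguishable
  from initialization — the trend needs the longer horizon.
- CV calibration: Bernoulli(0.001), 1e7 steps (≈ 1e4 spikes): CV = 1.00 ±
  0.01; closed form √(1−p) checked at p = 0.1.

## What the synthetic conditions do and do not show

The generators emulate the study conditions (episodic input timing and
probabilities, ON/OFF encoding of whitened patches, independent Bernoulli
baselines), not real recordings: there is no measurement noise, no
electrode subsampling, no non-stationarity, and the fixture images carry
natural second-order but not higher-order statistics. Passing tests
certify that the learning rule and analyses behave as derived under the
model's own assumptions; they do not certify cortical data fits.

## Known limitations

- Full-scale runs (≥ 5e8 steps at the published blocks) are supported but
  take hours; the receptive-field preset at full scale additionally needs
  the original natural-image ensemble for Gabor-like results.
- The enumeration oracles cap at N = 12 (dense 2^N × 2^N kernels).
- `I_gauss` is biased upward for strongly coupled or very small networks;
  use `exact_mutual_information` there.
- Dale's-law-constrained excitatory/inhibitory pairing and continuous-time
  extensions of the rule are out of scope.
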