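# infomaxnet

Recurrent Infomax learning in stochastic binary networks: a simulator,
stimulus protocols, and spike-train analyses.

## The problem

Cortical circuits show characteristic spontaneous and evoked activity —
repeats of precise firing sequences, neuronal avalanches with power-law size
statistics, replay of stimulus-evoked sequences, and simple-cell-like
receptive fields. One candidate organising principle behind all of these is
*Infomax on recurrent networks*: synapses change so that the network state
retains as much information as possible about its own immediately preceding
state,

```
max_{w, h}  I[x^t ; x^{t-1}]    subject to  E[x_i^t] = p0.
```

The scientific content of this package is a *biologically local* learning
rule for that objective. Each neuron is binary, fires with probability
`p_max · σ(s_i)` where `s_i = Σ_{j≠i} w_ij x_j − h_i`, and every synapse
maintains a leaky eligibility trace `⟨ψ_i x_j⟩_τ` of a purely local score
term ψ (the derivative of the log firing likelihood with respect to the
membrane input). Learning is the trace gated by one global scalar assembled
from four population signals:

```
Δw_ij = ε (τ/T)(γ1 − γ2 − γ3 − γ4) ⟨ψ_i x_j⟩_τ − ε (ζ/T)(s_i − s0) x_j
Δh_i  = −ε (τ/T)(γ1 − γ2 − γ3 − γ4) ⟨ψ_i⟩_τ  + ε (ζ/T)(s_i − s0)
```

γ1 rewards better-than-marginal predictability, γ2 penalises population
synchrony (pairwise correlation / sparseness), γ3 pins mean rates to `p0`,
and γ4 confines membrane-input fluctuations around the reference
`s0 = log(p0/(p_max − p0))`. The rule is a stochastic-gradient ascent on an
approximate objective `A = A1 − A2 − A3 − A4` (per-neuron information,
correlation, rate and fluctuation terms), and has the same structure as
reward-modulated STDP: an STDP-like synaptic trace times a diffusely
broadcast modulatory factor.

The package provides, as tested library code:

- **network core** — the stochastic binary dynamics, compiled simulation
  loops, and a leaky integrate-and-fire f–I check that motivates the
  sigmoid transfer;
- **learning** — the objective terms, global signals, eligibility traces,
  the per-step update (standard and population-normalised `a_prime`
  variants), a chunked trainer with bit-exact snapshots/resume, and exact
  enumeration oracles (stationary chain, mutual information, objective
  gradients) for tiny networks;
- **stimuli** — the 3-neuron episodic sequence protocol, frequency-domain
  image whitening `L(f) = f·exp(−(f/f_c)^4)`, i.i.d. patch sampling, ON/OFF
  relay-cell encoding, and a synthetic 1/f image fixture so no external
  data is needed;
- **analyses** — the Gaussian information estimate
  `I_gauss = log2|Ĉ| − ½log2|D̂|`, avalanche detection and power-law slope
  fits, exact pattern/sequence censuses, autocorrelograms, CV of
  inter-spike intervals, weight-shuffle controls, spike-triggered averages
  with the fixed gray-level rescaling, and strong-chain extraction;
- **presets + CLI** — the published parameter blocks for each experiment,
  runnable at full or scaled size (`infomaxnet preset avalanches --out ...`).

## Worked example

Information retained by a tiny mutual-excitation loop, measured two ways —
exact enumeration of the stationary chain versus the Gaussian covariance
estimate on a simulated raster:

```python
import numpy as np
import infomaxnet as im
from infomaxnet.analysis import exact_mutual_information, i_gauss
from infomaxnet.network import SynapticParameters

net = im.NetworkConfig(n_neurons=2, p_max=0.95, p0=0.05)
params = SynapticParameters(np.array([[0.0, 1.0], [1.0, 0.0]]), np.full(2, 1.5))
print(f"exact MI:   {exact_mutual_information(params, net):.4f} bits")
raster = im.simulate(params, 1_000_000, rng=np.random.default_rng(0), p_max=net.p_max)
print(f"I_gauss:    {i_gauss(raster, warn_short=False):.4f} bits")
print(f"mean rate:  {raster.spikes.mean():.4f}")
```

prints

```
exact MI:   0.0454 bits
I_gauss:    0.0501 bits
mean rate:  0.2125
```

Each neuron's state carries ~0.05 bits about the previous step (the mutual
excitation makes firing self-predictive), and the Gaussian estimate tracks
the exact value to ~10% — the weakly coupled regime in which it is a valid
surrogate during learning.

Training runs use the same surface:

```python
from infomaxnet import LearningConfig, NetworkConfig
from infomaxnet.learning import InfomaxTrainer

net = NetworkConfig(n_neurons=50, p_max=0.4, p0=0.01)
learn = LearningConfig(epsilon=0.02, c_eta=10.0, c_kappa=30.0, c_zeta=3.0,
                       tau=10.0, T=50000.0)
trainer = InfomaxTrainer(net, learn, seed=1)
metrics = trainer.run(100_000_000, log_every=5_000_000)  # ~6 min compiled
```

On this avalanche-regime configuration the logged `i_gauss` rises
monotonically (0.04 → 6.1 over the run above) as sparse strong connections
form, and the burst-size distribution of the post-learning activity moves
toward the critical `p(s) ∝ s^{-3/2}` law.

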