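# popdim

**Shared-variability dimensionality for neural populations and balanced
spiking-network models.**

When tens of neurons are recorded over hundreds of trials, dimensionality
reduction is used to ask how the population co-fluctuates: how many
characteristic patterns ("modes") of coordinated activity are there, and how
much of each neuron's variability is shared with the rest of the population?
Both answers depend on how many neurons and trials were sampled, and on the
(usually unknown) connectivity of the underlying circuit.  `popdim`
implements the full computational chain needed to study these questions on
self-generated data:

* a **balanced excitatory/inhibitory spiking-network simulator** (leaky
  integrate-and-fire neurons, difference-of-exponentials synapses) in two
  variants: homogeneous connectivity, and clustered excitatory connectivity
  in which within-cluster pairs connect with elevated probability and weight,
  producing slow coordinated rate fluctuations;
* **factor analysis (FA)** of trials × neurons spike-count matrices, fit by
  EM with the latent dimensionality selected by cross-validated likelihood;
* the derived **population metrics** — shared dimensionality, percent shared
  variance, and per-mode variance fractions;
* **principal-angle** comparison of dominant modes across neuron counts, with
  a random-subspace Monte-Carlo baseline;
* **subsampling protocols** (nested neuron sets, disjoint neuron/trial sets,
  cluster-balanced sampling) and scaling curves of the metrics versus neuron
  count, trial count, or cluster representation.

## The model

FA treats the spike-count vector $x \in \mathbb{R}^n$ of one trial (a 1-s bin
of spontaneous activity) as

$$x \sim \mathcal{N}(\mu,\; LL^\top + \Psi),$$

with loading matrix $L \in \mathbb{R}^{n\times m}$ and diagonal $\Psi$.
$LL^\top$ is the covariance **shared** across neurons; $\Psi$ holds each
neuron's **independent** (Poisson-like) variability.  With eigenvalues
$\lambda_1 \ge \dots \ge \lambda_m$ and eigenvectors $u_i$ of $LL^\top$:

* **Shared dimensionality** $d_\text{shared}$ — the smallest number of
  leading modes whose eigenvalues capture 95% of $\mathrm{tr}(LL^\top)$,
  computed after selecting $m$ by cross-validated data likelihood.
* **Percent shared variance** of neuron $k$ —
  $100\, L_k L_k^\top / (L_k L_k^\top + \Psi_k)$, averaged over neurons for
  the population value.
* **Per-mode fractions** — $100\,\lambda_i / \sum_j \lambda_j$ of the shared
  variance, and the per-mode split of percent shared variance
  $100\,\lambda_i u_{ik}^2 / (L_kL_k^\top + \Psi_k)$ averaged over $k$, which
  sums over modes to the per-neuron value exactly.

Mode stability across neuron counts is measured by restricting each fit's
$L$ to a common neuron core, eigendecomposing the restricted $LL^\top$, and
taking principal angles between the spans of the top modes.

## Worked example

```python
import numpy as np
from popdim import (GenerativeFASpec, sample_fa_counts, cv_select_m, fit_fa,
                    shared_dimensionality, percent_shared_variance)

rng = np.random.default_rng(42)
L = rng.standard_normal((80, 3))
spec = GenerativeFASpec(mu=np.full(80, 5.0), L=L, psi=np.einsum("ij,ij->i", L, L))
counts = sample_fa_counts(spec, n_trials=2000, seed=0)

m_star, _ = cv_select_m(counts, m_grid=range(0, 7), seed=0)
model = fit_fa(counts, m_star)
print(m_star, shared_dimensionality(model), percent_shared_variance(model)[1])
```

Running `python examples/02_fit_factor_analysis.py` (this example, fleshed
out) prints:

```
cross-validation selected m = 3 (true rank 3)
d_shared = 3  (modes needed for 95% of shared variance)
percent shared variance = 49.6%  (construction target: 50%)
per-mode share of shared variance: [44.7 32.9 22.4] %
relative Frobenius error of recovered shared covariance: 0.063
```

Cross-validation recovers the generative rank; every neuron was built to
share half its variance, and the estimate lands at 49.6%; the fitted shared
covariance is within 6% of the ground truth.  The other scripts in
`examples/` demonstrate the clustered-network simulator (within-cluster
spike-count covariance 0.75 vs −0.01 between clusters at desk scale), mode
stability (top-mode angles of a 20-neuron fit against a 60-neuron reference
stay below 5°, against a ~39–85° random baseline), and scaling curves.

## Command line

```bash
popdim simulate --preset clustered --duration 300 --conn-seed 1 --dyn-seed 2 --out spikes.tsv
popdim bin --spikes spikes.tsv --bin 1.0 --burn-in 2.0 --out counts.tsv
popdim fit --counts counts.tsv --m-grid auto --seed 0 --out model.json
popdim metrics --model model.json --out metrics.json
```

Every command writes a `*.manifest.json` recording seeds, inputs and a
config hash.  Canonical full-size network configurations ship as presets
(`clustered_paper.json`: 4000 E + 1000 I, 50 clusters of 80,
p_in = 0.4854 / p_out = 0.1942; `nonclustered_paper.json`: homogeneous
p_EE = 0.2).

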