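# Methods

This note documents the models implemented in `popdim`, the numerical
choices behind them, and what the desk-scale experiments do and do not
establish.

## Spiking network model

Each of the $N_E + N_I$ neurons is a leaky integrate-and-fire unit with
normalized voltage (0 = rest, 1 = threshold):

$$\dot V = \frac{\mu - V}{\tau} + I_\text{syn},$$

with $\tau$ = 15 ms (E) / 10 ms (I), threshold 1, reset 0, and a 5 ms
absolute refractory period.  The constant bias $\mu$ is drawn once per
simulation per neuron, uniformly on [1.1, 1.2] (E) or [1.0, 1.05] (I) —
every neuron is intrinsically supra-threshold, and irregular firing arises
from the balance of recurrent excitation and inhibition rather than from
injected noise.  The dynamics are fully deterministic given the
connectivity and initial state; trial-to-trial variability is
self-generated (chaotic), which is the scientific point of the model.

A presynaptic spike at $t_0$ adds $J\,F(t-t_0)$ to the postsynaptic drive,
with the difference-of-exponentials kernel

$$F(t) = \frac{e^{-t/\tau_2} - e^{-t/\tau_1}}{\tau_2 - \tau_1},
\qquad \tau_1 = 1\ \text{ms},\ \tau_2 = 3\ \text{ms (E)} / 2\ \text{ms (I)},$$

which is zero at $t=0$, peaks near 1.6 ms (E), and integrates to exactly 1,
so $J$ is the total charge per spike.  $I_\text{syn}$ carries units of
1/ms so the weight values are used exactly as configured.

**Connectivity.**  Every ordered (post, pre) pair is connected
independently: $p^{EE} = 0.2$, all other class pairs 0.5; weights
$J^{EE}=0.024$, $J^{EI}=-0.045$, $J^{IE}=0.014$, $J^{II}=-0.057$.  The
clustered variant partitions the 4000 excitatory neurons into 50 clusters
of 80 with $p^{EE}_\text{in}=0.4854$, $p^{EE}_\text{out}=0.1942$ (their
pair-count-weighted mean recovers 0.2) and weights
$J^{EE}_\text{in}=0.0456$, $J^{EE}_\text{out}=0.024$.  Self-connections
are disallowed (standard convention).  Connectivity and dynamics use
separate seeds so a single network realization can be simulated repeatedly.

**Numerics** (the source model statement is silent on all of these; each is
configurable):

* Integration: exponential Euler on the membrane leak with forward
  accumulation of the synaptic drive, $dt = 0.05$ ms.  The synaptic filter
  is realized exactly as the difference of two first-order states per
  (neuron × presynaptic class), decayed by exact exponential factors each
  step, so no convolution history is stored and the impulse response is
  exact at the step boundaries.
* $dt$ must divide the refractory period; refractoriness is a hold-at-reset
  until-timestamp.  A spike is registered when $V \ge 1$ at the end of a
  step and assigned that step's time.
* Initial voltages are uniform on [reset, threshold) from the dynamics
  seed; synaptic states start at zero; the first 2 s of every run are
  discarded (burn-in) before binning.
* Identical (network, seed) inputs produce bit-identical spike trains; the
  inner loop is numba-compiled.
* Convergence in $dt$ is verified per-neuron on uncoupled neurons (where
  the interspike interval has the closed form
  $\tau\ln\frac{\mu - V_\text{re}}{\mu - V_\text{th}} + t_\text{ref}$) and
  at the population-mean level for coupled networks — per-neuron
  finite-time rates in a recurrent network are chaotic and not a
  well-posed convergence target.

**Trials.**  A "trial" is one 1-s bin of a single continuous run (no state
reset between trials); bins are half-open and a partial trailing bin is
dropped.  Bin widths of 0.2/0.5/1.0 s are supported.

## Factor analysis

$x \sim \mathcal{N}(\mu, LL^\top + \Psi)$ is fit by EM on the sufficient
statistics (sample mean and covariance), which is algebraically identical
to per-trial EM for this model and makes cross-validation over rank grids
cheap at thousands of trials.  Choices:

* **Initialization**: $L$ from the top-$m$ principal directions of the
  sample covariance scaled by the square root of each eigenvalue's excess
  over the mean variance; $\Psi$ from the sample variances.  The fit is
  deterministic given the data.
* **Convergence**: relative log-likelihood change $< 10^{-8}$ or 3000
  iterations (CV fits use $10^{-6}$/500 — rank comparison does not need
  terminal precision); non-convergence is reported in model metadata.
  The training log-likelihood is non-decreasing across iterations and this
  is asserted in tests.
* **$\Psi$ floor**: $10^{-6}\times$ each neuron's sample variance, which
  prevents Heywood collapse; zero-variance neurons are a hard error (the
  caller screens units instead — see below).
* **Likelihoods** use the matrix-inversion and determinant lemmas, so only
  $m\times m$ systems are solved; correctness is checked against a dense
  multivariate-normal oracle to $10^{-8}$.
* **Raw counts** are analyzed — no square-root transform or z-scoring.

**Model selection**: trials are split at random (seeded) into 4 folds;
$m^*$ maximizes the mean held-out log-likelihood, ties broken toward the
smaller rank.  The default grid is coarse (unit steps to 10, then every 3)
with unit-step refinement around the coarse argmax.  The 95% rule for
$d_\text{shared}$ is applied to the model refit on all trials at $m^*$;
the CV models are discarded.  Cross-validated likelihood curves flatten
when data are abundant, so $m^*$ itself is noisy there — $d_\text{shared}$
is deliberately the more stable summary.

**Unit screening**: FA is undefined for zero-variance units, so analysis
pools exclude units firing below 1 spike/s (`CountMatrix.active_neurons`),
mirroring the usual rate screen applied to array recordings.

## Mode comparison

Fits with different neuron counts live in different spaces, so modes are
compared after restriction: take the rows of $L$ for a common neuron core
(20 by default), eigendecompose the restricted $LL^\top$, keep the top 5
modes, and compute principal angles (arccos of the singular values of
$Q_A^\top Q_B$ after QR orthonormalization with column pivoting — the
restricted reference basis is not orthogonal before this step, and the
choice to orthonormalize is recorded here).  Angles are invariant to
column order, sign, and any rotation within a basis's span; eigenvector
signs are fixed by making each mode's largest-magnitude entry positive for
reproducible serialization.  The "random vectors" baseline is $k$
independent Gaussian vectors in $\mathbb{R}^{20}$ orthonormalized into a
$k$-dimensional subspace (the rotation-invariant ensemble), summarized by
Monte-Carlo mean ± sd per angle index.

## Subsampling protocols

* Neuron sweeps use **nested** subsets (each sample augments the next
  smaller one) drawn from excitatory units only; repeats use 5
  non-overlapping neuron sets crossed with 5 non-overlapping contiguous
  trial blocks (25 repeats) for model networks, or single samples per
  dataset for array-style data.  Standard errors are sd/√reps over the
  declared repeats, and the stored aggregates are recomputable from the
  stored per-repeat values.
* Cluster-representation sweeps draw $50/N$ neurons from each of $N$
  uniformly chosen clusters ($N$ must divide 50).
* Trial-exchangeability checks: per-neuron autocorrelation of the 1-s
  count series (biased estimator, lag 0 ≡ 1), and FA metrics under
  adjacent / skip-1 / skip-2 / random trial samplings of equal size.

## Synthetic data generators

* `sample_fa_counts` inverts the FA model ($z\sim\mathcal N(0,I)$,
  $x = \mu + Lz + \varepsilon$); optional Poissonization uses the Gaussian
  draw, truncated at zero, as a Poisson rate.  This is a crude integer
  emulation — it matches first and (approximately) second moments, not
  higher ones.
* `make_invivo_like_params` builds an 80-neuron, rank-4 parameter set with
  the signature of V1 spontaneous activity: an all-positive first loading
  column ($|\mathcal N(1, 0.5^2)|$ entries, normalized) carrying 70% of
  the shared variance — a population-wide co-fluctuation — with the
  remainder split across random orthogonal columns in a geometric taper,
  and $\Psi$ set per neuron so each neuron's percent shared variance is
  exactly 51.8%.  The targets (first mode > 60%, overall 51.8%) hold by
  construction and are verified through the metrics pipeline, not assumed.
* `toy_network_config(scale)` shrinks the canonical networks for
  desk-scale work (scale 0.1 → 400 E / 100 I, 10 clusters of 40).  The
  within/between probability ratio 2.4995 is preserved and the
  between-cluster probability re-solved so the pair-weighted mean stays
  exactly 0.2.  Weights are multiplied by $\text{scale}^{-1/4}$: with
  unscaled weights the small clustered network loses cluster
  metastability, while the full $1/\sqrt{\text{scale}}$ balanced-network
  scaling over-amplifies pairwise correlations (which already grow as $N$
  shrinks) to the point where even the homogeneous network shows
  detectable shared structure at a few hundred trials.  The quarter-power
  compromise keeps firing rates plausible and preserves the qualitative
  contrast between architectures.  This was chosen once, by sweeping the
  exponent on both architectures, and is a property of the toy generator,
  not a fitted quantity.

## Desk-scale problem sizes and their limits

The packaged experiments (`popdim.experiments`, `scripts/acceptance.py`,
and the test suite) run the scale-0.1 networks for ~300 1-s trials with FA
on 10–40 neurons, generative recovery at 80 neurons × 2000 trials, and
baselines at 10⁴ Monte-Carlo draws.  These sizes were chosen so the entire
chain runs in minutes on one CPU while still exhibiting the qualitative
phenomena of interest: clustered connectivity yields low-dimensional,
high-shared-variance activity whose $d_\text{shared}$ grows with neuron
count and whose within-cluster covariance dominates; homogeneous
connectivity yields no detectable shared structure at the same sampling.

Two caveats.  First, the homogeneous network's shared variance is small
but not exactly zero; with enough trials it becomes detectable (in the
full-size network this takes thousands of trials), so at desk scale the
null result holds for most but not all random seeds — weak structure
(a few percent shared variance) occasionally crosses the detection
threshold.  Second, the toy networks emulate the full-size architecture's
qualitative behavior, not its quantitative values: magnitudes of
$d_\text{shared}$, percent shared variance, and firing rates at scale 0.1
should not be read as predictions for the 4000-neuron network, which can
be run through the identical code paths via the shipped presets when
CPU-hours are available.

The synthetic generators emulate stated statistical structure (moment
structure, dominant-mode geometry, trial exchangeability); they do not
reproduce higher moments, firing-rate heterogeneity, or temporal structure
of real recordings, so passing tests establish correctness of the
estimators and pipeline, not fidelity to any particular dataset.
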