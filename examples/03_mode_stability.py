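"""How stable are the dominant modes as more neurons are analyzed?

Generates counts with block (cluster-like) shared structure, fits FA on
nested 20/40-neuron subsets of a 60-neuron reference, and measures the
principal angles between each subset's top modes and the reference modes,
restricted to a common 20-neuron core.  Small angles mean a small
recording already identifies the directions of shared variability that
generalize to the larger population.
"""

import numpy as np

from popdim import GenerativeFASpec, mode_stability_experiment, sample_fa_counts

rng = np.random.default_rng(7)
n = 60
labels = np.repeat(np.arange(6), 10)
L = np.zeros((n, 6))
L[np.arange(n), labels] = rng.uniform(1.5, 2.5, size=n)
spec = GenerativeFASpec(mu=np.full(n, 5.0), L=L, psi=np.ones(n))
counts = sample_fa_counts(spec, 800, seed=8)

out = mode_stability_experiment(
    counts,
    subset_sizes=[20, 40],
    reference_size=60,
    common_size=20,
    k=5,
    fa_opts={"m_grid": list(range(0, 9))},
    seed=0,
)

for size, group in out["angles"].groupby("subset_size"):
    degs = ", ".join(f"{d:.1f}" for d in group.degrees)
    print(f"{size:>3}-neuron fit vs 60-neuron reference: angles [{degs}] deg")
base = ", ".join(f"{m:.1f}" for m in out["baseline_mean"])
print(f"random-subspace baseline (mean):            [{base}] deg")
print("Angles well below the random baseline: the dominant modes found "
      "with 20 neurons already match the larger population's modes.")
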