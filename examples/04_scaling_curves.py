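"""Scaling of d_shared and percent shared variance with neuron count.

Compares counts with one strong population-wide factor against independent
counts: the shared metrics grow/stabilize with neuron count in the first
case and stay at zero in the second — the signature distinguishing
structured from unstructured population variability.
"""

import numpy as np

from popdim import CountMatrix, scaling_experiment

rng = np.random.default_rng(0)
n_trials, n_neurons = 1200, 40
z = rng.standard_normal((n_trials, 1))
structured = CountMatrix(
    counts=6 + 1.2 * z @ np.ones((1, n_neurons)) + rng.standard_normal((n_trials, n_neurons)),
    neuron_ids=np.arange(n_neurons),
)
independent = CountMatrix(
    counts=6 + rng.standard_normal((n_trials, n_neurons)),
    neuron_ids=np.arange(n_neurons),
)

for name, counts in [("structured", structured), ("independent", independent)]:
    table = scaling_experiment(
        counts,
        axis="neurons",
        grid=[10, 20],
        n_neuron_sets=2,
        n_trial_sets=2,
        fa_opts={"m_grid": [0, 1, 2, 3]},
        seed=0,
    )
    print(f"\n{name} counts:")
    print(table.aggregated.to_string(index=False))

print("\nStructured counts keep d_shared = 1 (one global co-fluctuation) and "
      "high percent shared variance at every neuron count; independent "
      "counts show zero shared structure throughout.")
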