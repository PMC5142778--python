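"""Subsampling protocols, scaling curves, autocorrelation checks."""

import numpy as np
import pandas as pd
import pytest

from popdim.counts import CountMatrix
from popdim.sampling import (
    ScalingTable,
    cluster_balanced_sample,
    count_autocorrelation,
    disjoint_sets,
    nested_neuron_subsets,
    scaling_experiment,
    trial_spacing_check,
)


def gaussian_counts(n_trials=300, n_neurons=40, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_trials, n_neurons)) + 5.0
    return CountMatrix(
        counts=x, neuron_ids=np.arange(n_neurons), cluster_labels=labels
    )


class TestSubsets:
    def test_nested_containment_and_sizes(self):
        sets = nested_neuron_subsets(np.arange(80), [10, 20, 40], seed=1)
        assert [len(s) for s in sets] == [10, 20, 40]
        assert set(sets[0]) < set(sets[1]) < set(sets[2])

    def test_whole_pool(self):
        (s,) = nested_neuron_subsets(np.arange(15), [15], seed=0)
        assert set(s) == set(range(15))

    def test_nonincreasing_sizes_rejected(self):
        with pytest.raises(ValueError):
            nested_neuron_subsets(np.arange(30), [10, 10], seed=0)

    def test_inclusion_uniformity(self):
        """Over many seeded draws each neuron appears at size 10 from a pool
        of 80 with frequency 1/8 within 4 SE."""
        hits = np.zeros(80)
        reps = 1000
        for s in range(reps):
            hits[nested_neuron_subsets(np.arange(80), [10], seed=s)[0]] += 1
        p = 10 / 80
        se = np.sqrt(p * (1 - p) / reps)
        assert np.all(np.abs(hits / reps - p) < 4 * se)

    def test_disjoint_partition(self):
        sets = disjoint_sets(np.arange(400), 5, 80, seed=2)
        union = np.concatenate(sets)
        assert len(union) == 400 and len(set(union.tolist())) == 400
        with pytest.raises(ValueError):
            disjoint_sets(np.arange(100), 5, 30, seed=0)


class TestClusterBalancedSample:
    labels = np.repeat(np.arange(50), 8)  # 400 neurons, 50 clusters of 8

    @pytest.mark.parametrize("n_rep,per", [(50, 1), (10, 5), (1, 50)])
    def test_representation_counts(self, n_rep, per):
        if per > 8:  # a cluster of 8 cannot supply 50 neurons
            with pytest.raises(ValueError, match="fewer"):
                cluster_balanced_sample(self.labels, n_rep, seed=0)
            return
        idx = cluster_balanced_sample(self.labels, n_rep, seed=0)
        assert len(idx) == 50
        chosen = self.labels[idx]
        assert len(np.unique(chosen)) == n_rep
        assert np.all(np.bincount(chosen)[np.unique(chosen)] == per)

    def test_nondivisor_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            cluster_balanced_sample(self.labels, 3, seed=0)


class TestScalingExperiment:
    def test_independent_data_yields_zero_everywhere(self):
        counts = gaussian_counts(n_trials=1200, n_neurons=40)
        table = scaling_experiment(
            counts,
            axis="neurons",
            grid=[10, 20],
            n_neuron_sets=2,
            n_trial_sets=1,
            fa_opts={"m_grid": [0, 1, 2]},
            seed=0,
        )
        assert np.all(table.per_repeat.d_shared == 0)
        assert np.all(table.per_repeat.percent_shared == 0)

    def test_se_recomputation_matches(self):
        counts = gaussian_counts(n_trials=400, n_neurons=30)
        table = scaling_experiment(
            counts,
            axis="trials",
            grid=[50, 100],
            n_neuron_sets=2,
            n_trial_sets=2,
            fixed=10,
            fa_opts={"m_grid": [0, 1]},
            seed=0,
        )
        re_agg = ScalingTable.aggregate(table.per_repeat)
        pd.testing.assert_frame_equal(re_agg, table.aggregated)
        assert set(table.per_repeat.grid_value) == {50, 100}
        # SE definition: sd/sqrt(reps)
        g = table.per_repeat[table.per_repeat.grid_value == 50]
        manual = g.d_shared.std(ddof=1) / np.sqrt(len(g))
        row = table.aggregated[table.aggregated.grid_value == 50]
        assert row.d_shared_se.iloc[0] == pytest.approx(manual, nan_ok=True)

    def test_correlated_data_detected(self):
        """A strong one-factor structure yields d_shared 1 at every grid value."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal((400, 1))
        x = 5 + z @ np.ones((1, 30)) * 1.5 + rng.standard_normal((400, 30))
        counts = CountMatrix(counts=x, neuron_ids=np.arange(30))
        table = scaling_experiment(
            counts,
            axis="neurons",
            grid=[6, 12],
            n_neuron_sets=2,
            n_trial_sets=1,
            fa_opts={"m_grid": [0, 1, 2]},
            seed=0,
        )
        assert np.all(table.per_repeat.d_shared == 1)


class TestClusterRepresentationSweep:
    def test_dshared_grows_with_cluster_representation(self):
        """Counts with per-cluster co-fluctuations: representing more
        clusters in a fixed-size sample reveals more shared dimensions."""
        rng = np.random.default_rng(12)
        n_clusters, per = 10, 20
        n = n_clusters * per
        labels = np.repeat(np.arange(n_clusters), per)
        z = rng.standard_normal((600, n_clusters))
        L = np.zeros((n, n_clusters))
        L[np.arange(n), labels] = 2.0
        x = 6 + z @ L.T + rng.standard_normal((600, n))
        counts = CountMatrix(
            counts=x, neuron_ids=np.arange(n), cluster_labels=labels
        )
        table = scaling_experiment(
            counts,
            axis="clusters_represented",
            grid=[1, 5, 10],
            n_neuron_sets=2,
            n_trial_sets=1,
            fixed=20,
            fa_opts={"m_grid": list(range(0, 12))},
            seed=0,
        )
        agg = table.aggregated.set_index("grid_value").d_shared_mean
        assert agg[1] < agg[5] <= agg[10]
        assert agg[10] == pytest.approx(10, abs=1)


class TestAutocorrelation:
    def test_lag_zero_is_one_and_white_noise_flat(self):
        counts = gaussian_counts(n_trials=2000, n_neurons=30, seed=4)
        summary, acf = count_autocorrelation(counts, max_lag=10)
        assert np.all(acf[0] == 1.0)
        nonzero = summary[summary.lag > 0]
        assert np.all(np.abs(nonzero["mean"]) < 3 * nonzero["se"] + 0.05)

    def test_ar1_recovered(self):
        """Injected AR(1) with rho = 0.5 shows up at lag 1."""
        rng = np.random.default_rng(5)
        t, n, rho = 4000, 20, 0.5
        x = np.zeros((t, n))
        eps = rng.standard_normal((t, n))
        for i in range(1, t):
            x[i] = rho * x[i - 1] + eps[i]
        counts = CountMatrix(counts=x + 10, neuron_ids=np.arange(n))
        summary, _ = count_autocorrelation(counts, max_lag=3)
        lag1 = summary[summary.lag == 1]
        assert abs(lag1["mean"].iloc[0] - rho) < 3 * lag1["se"].iloc[0] + 0.02

    def test_constant_neuron_excluded(self):
        x = np.random.default_rng(6).standard_normal((100, 3))
        x[:, 1] = 4.0
        counts = CountMatrix(counts=x, neuron_ids=np.arange(3))
        summary, acf = count_autocorrelation(counts, max_lag=2)
        assert np.all(np.isnan(acf[:, 1]))
        assert np.isfinite(summary["mean"]).all()


class TestTrialSpacing:
    def test_exchangeable_data_indistinguishable_and_deterministic(self):
        counts = gaussian_counts(n_trials=1300, n_neurons=20, seed=7)
        out1 = trial_spacing_check(
            counts, n_trials=400, fa_opts={"m_grid": [0, 1]}, seed=0
        )
        out2 = trial_spacing_check(
            counts, n_trials=400, fa_opts={"m_grid": [0, 1]}, seed=0
        )
        pd.testing.assert_frame_equal(out1, out2)
        # independent Gaussian counts: no shared structure under any sampling
        assert np.all(out1.d_shared == 0)
        assert set(out1.sampling) == {"skip_0s", "skip_1s", "skip_2s", "random"}
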