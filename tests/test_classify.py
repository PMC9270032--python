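"""Group-aware splits, Pearson handling, SVM experiment determinism."""

import numpy as np
import pytest

from cnscensus.classify import (SplitPlan, hyperparameter_grid,
                                make_group_splits, pearson, run_experiment,
                                run_split)
from cnscensus.core import (ConfigurationError, ExperimentConfig, KernelGram,
                            ParameterError)


def _animals(n_f=8, n_m=8):
    return ([(f"F{i}", "female") for i in range(n_f)]
            + [(f"M{i}", "male") for i in range(n_m)])


def _separable_gram(n_f=8, n_m=8, repeats=5, noise=0.05, seed=0):
    """Items cluster by class in a latent feature; linear kernel on it."""
    rng = np.random.default_rng(seed)
    feats, groups, labels = [], [], []
    for aid, cls in _animals(n_f, n_m):
        centre = 1.0 if cls == "female" else -1.0
        for _ in range(repeats):
            feats.append([centre + rng.normal(0, noise), rng.normal()])
            groups.append(aid)
            labels.append(cls)
    x = np.asarray(feats)
    k = x @ x.T
    gram = KernelGram(matrix=0.5 * (k + k.T),
                      item_ids=[f"i{j}" for j in range(len(groups))],
                      group_ids=groups)
    return gram, labels


class TestSplits:
    def test_partition_sizes_and_disjointness(self):
        plans = make_group_splits(_animals(16, 15), 6, 50, seed=1)
        assert len(plans) == 50
        for p in plans:
            assert len(p.train_animals) == 12
            assert len(p.test_animals) == 19
            assert not p.train_animals & p.test_animals

    def test_item_counts_with_100_subsamples(self):
        """16+15 animals with 100 subsamples each split 6+6 -> 1200 train
        and 1900 test items."""
        plans = make_group_splits(_animals(16, 15), 6, 1, seed=0)
        assert 100 * len(plans[0].train_animals) == 1200
        assert 100 * len(plans[0].test_animals) == 1900

    def test_zero_splits_empty(self):
        assert make_group_splits(_animals(), 6, 0, seed=0) == []

    def test_deterministic(self):
        a = make_group_splits(_animals(), 6, 10, seed=3)
        b = make_group_splits(_animals(), 6, 10, seed=3)
        assert [p.train_animals for p in a] == [p.train_animals for p in b]

    def test_insufficient_animals_raise(self):
        with pytest.raises(ConfigurationError):
            make_group_splits(_animals(6, 8), 6, 1, seed=0)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitPlan(frozenset({"a"}), frozenset({"a", "b"}), 0)


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84))

    def test_constant_input_flagged_as_zero(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            pearson([1, 2], [1, 2, 3])


class TestRunSplit:
    def test_perfectly_separable_kernel_gives_rho_one(self):
        gram, labels = _separable_gram()
        plan = make_group_splits(_animals(), 6, 1, seed=5)[0]
        rho_true, _ = run_split(gram, labels, plan, c=10.0, control_seed=1)
        assert rho_true == pytest.approx(1.0)

    def test_control_seed_changes_control_only(self):
        gram, labels = _separable_gram()
        plan = make_group_splits(_animals(), 6, 1, seed=5)[0]
        r1 = run_split(gram, labels, plan, 10.0, control_seed=1)
        r2 = run_split(gram, labels, plan, 10.0, control_seed=2)
        assert r1[0] == r2[0]


class TestExperiment:
    def test_deterministic_given_master_seed(self):
        gram, labels = _separable_gram()
        cfg = ExperimentConfig(subsample_size=1, subsample_repeats=1,
                               n_splits=8, master_seed=42)
        a = run_experiment(gram, labels, cfg)
        b = run_experiment(gram, labels, cfg)
        np.testing.assert_array_equal(a.per_split, b.per_split)

    def test_single_split_overlap_binary(self):
        gram, labels = _separable_gram()
        cfg = ExperimentConfig(subsample_size=1, subsample_repeats=1,
                               n_splits=1, master_seed=0)
        res = run_experiment(gram, labels, cfg)
        assert res.overlap_fraction in (0.0, 1.0)

    def test_strong_signal_beats_control(self):
        gram, labels = _separable_gram()
        cfg = ExperimentConfig(subsample_size=1, subsample_repeats=1,
                               n_splits=40, master_seed=7)
        res = run_experiment(gram, labels, cfg)
        assert res.overlap_fraction < 0.05
        assert res.rho_true.mean() > 0.9

    def test_label_permutation_within_animal_is_inert(self):
        """No-leakage: items of one animal are interchangeable, so
        permuting them never changes split membership or results."""
        gram, labels = _separable_gram(repeats=3)
        cfg = ExperimentConfig(subsample_size=1, subsample_repeats=1,
                               n_splits=5, master_seed=3)
        base = run_experiment(gram, labels, cfg)
        # Permute the three items of animal F0 (indices 0..2).
        perm = np.arange(len(labels))
        perm[[0, 1, 2]] = [2, 0, 1]
        gram2 = KernelGram(matrix=gram.matrix[np.ix_(perm, perm)],
                           item_ids=[gram.item_ids[i] for i in perm],
                           group_ids=[gram.group_ids[i] for i in perm])
        permuted = run_experiment(gram2, [labels[i] for i in perm], cfg)
        np.testing.assert_allclose(base.per_split, permuted.per_split,
                                   atol=1e-12)

    def test_null_kernel_is_chance_level(self):
        """Pure-noise kernels: the overlap fraction, averaged over
        independent kernel draws (a single 16-animal draw carries chance
        structure of its own), is consistent with one half."""
        rng = np.random.default_rng(0)
        groups = [f"{'F' if i < 8 else 'M'}{i % 8}" for i in range(16)
                  for _ in range(5)]
        labels = ["female" if g.startswith("F") else "male" for g in groups]
        overlaps = []
        for draw in range(4):
            x = rng.normal(size=(80, 4))
            k = x @ x.T
            gram = KernelGram(matrix=0.5 * (k + k.T),
                              item_ids=[str(i) for i in range(80)],
                              group_ids=groups)
            cfg = ExperimentConfig(subsample_size=1, subsample_repeats=1,
                                   n_splits=100, master_seed=13 + draw)
            overlaps.append(run_experiment(gram, labels, cfg).overlap_fraction)
        assert 0.35 < np.mean(overlaps) < 0.65


class TestGrid:
    def test_single_cell_and_determinism(self):
        gram, labels = _separable_gram()

        def builder(sigma):
            return gram

        df = hyperparameter_grid(builder, labels, [10.0], [0.01], seed=1)
        assert len(df) == 1
        df2 = hyperparameter_grid(builder, labels, [10.0, 10.0], [0.01],
                                  seed=1)
        assert df2.iloc[0]["rho_test"] == df2.iloc[1]["rho_test"]

    def test_separable_kernel_reaches_high_correlation(self):
        gram, labels = _separable_gram()
        df = hyperparameter_grid(lambda s: gram, labels, [0.1, 10.0],
                                 [0.01, 1.0], seed=2)
        assert df["rho_test"].max() >= 0.8
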