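"""Leakage-avoiding SVM classification with randomized-label controls.

The experiment asks whether a kernel over per-subsample summaries can
recover the sex of the animal a subsample came from.  Because every
animal contributes many subsampled items, train/test splits are made at
the *animal* level: all items of an animal land wholly in train or wholly
in test, so no information leaks between the sets through shared parent
clouds.

Per split, a soft-margin SVM on the precomputed kernel is trained twice:
once against the animals' true sexes and once against sexes assigned by a
fair coin (redrawn independently every split, at animal level).  The
Pearson correlation between predicted and target labels on the test items
gives one (rho_true, rho_control) pair per split; the fraction of splits
where the control beats the truth is the experiment's significance
summary (the "overlap fraction").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import (ConfigurationError, ExperimentConfig, KernelGram,
                   ParameterError, SplitExperimentResult)

__all__ = [
    "SplitPlan",
    "make_group_splits",
    "pearson",
    "run_split",
    "run_experiment",
    "hyperparameter_grid",
]

log = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """Animal-level train/test partition for one split."""

    train_animals: frozenset
    test_animals: frozenset
    split_seed: int

    def __post_init__(self) -> None:
        if self.train_animals & self.test_animals:
            raise ConfigurationError("train and test animals must be disjoint")


def _encode_labels(labels) -> np.ndarray:
    """Map a two-class label sequence to -1/+1 (sorted unique order)."""
    arr = np.asarray(labels)
    classes = np.unique(arr)
    if classes.size != 2:
        raise ConfigurationError(
            f"expected exactly 2 classes, got {classes.tolist()}")
    return np.where(arr == classes[1], 1.0, -1.0)


def _animal_classes(gram: KernelGram, y: np.ndarray) -> dict:
    """Per-animal class, validating that items of an animal agree."""
    out: dict = {}
    for g, label in zip(gram.group_ids, y):
        if g in out and out[g] != label:
            raise ConfigurationError(
                f"animal {g!r} carries items with conflicting labels")
        out[g] = label
    return out


def make_group_splits(animals, n_train_per_class: int, n_splits: int,
                      seed: int) -> list[SplitPlan]:
    """Random animal-level splits: n_train_per_class per class in train.

    ``animals`` is a sequence of (animal_id, class) pairs.  Deterministic
    for a fixed seed.
    """
    if n_splits < 0:
        raise ParameterError("n_splits must be >= 0")
    by_class: dict = {}
    for animal_id, cls in animals:
        by_class.setdefault(cls, []).append(animal_id)
    if len(by_class) != 2:
        raise ConfigurationError("need exactly two classes of animals")
    for cls, ids in by_class.items():
        if len(ids) <= n_train_per_class:
            raise ConfigurationError(
                f"class {cls!r} has {len(ids)} animals; need more than "
                f"{n_train_per_class} to leave a test set")
    rng = np.random.default_rng(seed)
    all_ids = frozenset(a for ids in by_class.values() for a in ids)
    plans = []
    for _ in range(n_splits):
        train: set = set()
        for ids in by_class.values():
            train.update(rng.choice(sorted(ids), size=n_train_per_class,
                                    replace=False))
        plans.append(SplitPlan(
            train_animals=frozenset(train),
            test_animals=all_ids - train,
            split_seed=int(rng.integers(2**31))))
    return plans


def pearson(x, y) -> float:
    """Product-moment correlation; 0 (with a logged flag) if either input
    is constant, so null-model runs cannot crash on degenerate splits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ParameterError("pearson needs two equal-length vectors, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("pearson undefined for constant input; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _fit_predict(k_train, y_train, k_test_train, c: float,
                 decision_values: bool) -> np.ndarray:
    if np.unique(y_train).size < 2:
        # Single-class training target (possible under the fair-coin
        # control): the classifier degenerates to a constant predictor.
        return np.full(k_test_train.shape[0], y_train[0])
    svc = SVC(C=c, kernel="precomputed")
    svc.fit(k_train, y_train)
    if decision_values:
        return svc.decision_function(k_test_train)
    return svc.predict(k_test_train)


def run_split(gram: KernelGram, labels, plan: SplitPlan, c: float,
              control_seed: int,
              decision_values: bool = False) -> tuple[float, float]:
    """One split: true-label and control (randomized-label) correlations.

    The classifier output correlated with the targets is the predicted
    class encoded +-1 (or the decision value if ``decision_values``).
    """
    if c <= 0:
        raise ParameterError("SVM regularizer c must be > 0")
    y = _encode_labels(labels)
    groups = np.asarray(gram.group_ids)
    known = plan.train_animals | plan.test_animals
    if not set(groups) <= known:
        raise ConfigurationError("gram contains animals absent from the plan")
    train = np.isin(groups, sorted(plan.train_animals))
    test = np.isin(groups, sorted(plan.test_animals))
    k = gram.matrix
    k_train = k[np.ix_(train, train)]
    k_test_train = k[np.ix_(test, train)]

    pred = _fit_predict(k_train, y[train], k_test_train, c, decision_values)
    rho_true = pearson(pred, y[test])

    # Control: each animal gets a fair-coin sex, all its items inherit it.
    rng = np.random.default_rng(control_seed)
    animal_ids = sorted({*plan.train_animals, *plan.test_animals})
    coin = dict(zip(animal_ids, rng.choice([-1.0, 1.0], size=len(animal_ids))))
    y_ctrl = np.array([coin[g] for g in groups])
    pred_ctrl = _fit_predict(k_train, y_ctrl[train], k_test_train, c,
                             decision_values)
    rho_control = pearson(pred_ctrl, y_ctrl[test])
    return rho_true, rho_control


def run_experiment(gram: KernelGram, labels, cfg: ExperimentConfig,
                   decision_values: bool = False) -> SplitExperimentResult:
    """The full split experiment: ``cfg.n_splits`` (rho_true, rho_control).

    Deterministic for a fixed ``cfg.master_seed``: split membership and the
    per-split control coins all derive from it via a counter-based scheme.
    """
    y = _encode_labels(labels)
    animal_class = _animal_classes(gram, y)
    animals = sorted(animal_class.items())
    split_seed = int(np.random.SeedSequence(
        entropy=cfg.master_seed, spawn_key=(0,)).generate_state(1)[0] % 2**31)
    plans = make_group_splits(animals, cfg.train_animals_per_class,
                              cfg.n_splits, seed=split_seed)
    rows = np.empty((len(plans), 2))
    for i, plan in enumerate(plans):
        control_seed = int(np.random.SeedSequence(
            entropy=cfg.master_seed,
            spawn_key=(1, i)).generate_state(1)[0] % 2**31)
        rows[i] = run_split(gram, labels, plan, cfg.svm_regularizer_c,
                            control_seed, decision_values=decision_values)
    return SplitExperimentResult(per_split=rows)


def hyperparameter_grid(gram_builder, labels, c_values, sigma_values,
                        seed: int, n_train_per_class: int = 6):
    """Held-out correlation for every (c, sigma) pair on one fixed split.

    ``gram_builder(sigma)`` must return the :class:`KernelGram` for that
    bandwidth.  Returns a pandas DataFrame with columns c, sigma, rho_test.
    """
    import pandas as pd

    c_values = list(c_values)
    sigma_values = list(sigma_values)
    if not c_values or not sigma_values:
        raise ParameterError("hyperparameter grids must be non-empty")
    rows = []
    plan = None
    for sigma in sigma_values:
        gram = gram_builder(sigma)
        y = _encode_labels(labels)
        if plan is None:
            animals = sorted(_animal_classes(gram, y).items())
            plan = make_group_splits(animals, n_train_per_class, 1,
                                     seed=seed)[0]
        groups = np.asarray(gram.group_ids)
        train = np.isin(groups, sorted(plan.train_animals))
        test = np.isin(groups, sorted(plan.test_animals))
        for c in c_values:
            pred = _fit_predict(gram.matrix[np.ix_(train, train)], y[train],
                                gram.matrix[np.ix_(test, train)], c, False)
            rows.append((c, sigma, pearson(pred, y[test])))
    return pd.DataFrame(rows, columns=["c", "sigma", "rho_test"])
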