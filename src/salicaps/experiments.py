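"""Reproducible end-to-end experiments at desk scale.

The full-size model (8 lanes, 1000-position inputs, 10 bagging iterations
over a real profile dataset) is out of reach without the original profile
data; these experiments exercise the identical pipeline on the synthetic
motif-implanted dataset at a scale that runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from salicaps.metrics import roc_and_auc
from salicaps.network import LaneConfig, NetworkConfig
from salicaps.synthetic import SyntheticConfig, generate
from salicaps.training import (
    BaggingConfig,
    EnsembleModel,
    TrainConfig,
    ensemble_predict,
    train_ensemble,
)

#: Scaled-down network used by the synthetic learnability benchmark: two
#: lanes whose kernel sizes (9, 15) bracket the 12-residue implanted motif,
#: with the primary grid strided by 2 to keep routing cheap at desk scale.
SCALED_DOWN_KERNELS = (9, 15)


def scaled_down_network(input_len: int = 100) -> NetworkConfig:
    return NetworkConfig(
        lanes=tuple(
            LaneConfig(kernel_size=k, primary_stride=2)
            for k in SCALED_DOWN_KERNELS
        ),
        input_len=input_len,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    auc: float
    n_train: int
    n_test: int
    model: EnsembleModel


def synthetic_learnability(
    seed: int,
    n_bags: int = 3,
    max_epochs: int = 20,
    input_len: int = 100,
    test_fraction: float = 0.2,
) -> BenchmarkResult:
    """Train a scaled-down ensemble on the default synthetic dataset.

    Generates the default 100-positive / 500-negative motif-implanted
    dataset, holds out a stratified ``test_fraction``, trains an ``n_bags``-
    member bagging ensemble of the scaled-down two-lane network, and returns
    the held-out ROC-AUC.
    """
    dataset = generate(SyntheticConfig(seed=seed))
    labeled = dataset.to_labeled(input_len=input_len)

    rng = np.random.default_rng(seed + 1000)
    pos = np.flatnonzero(labeled.labels == 1)
    neg = np.flatnonzero(labeled.labels == 0)
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_pos_test = int(round(test_fraction * len(pos)))
    n_neg_test = int(round(test_fraction * len(neg)))
    test = labeled.subset(np.concatenate([pos[:n_pos_test], neg[:n_neg_test]]))
    train = labeled.subset(np.concatenate([pos[n_pos_test:], neg[n_neg_test:]]))

    positives = train.subset(np.flatnonzero(train.labels == 1))
    negatives = train.subset(np.flatnonzero(train.labels == 0))
    cfg = BaggingConfig(
        iterations=n_bags,
        bag_size=len(positives),
        seed=seed,
        train=TrainConfig(max_epochs=max_epochs),
    )
    model = train_ensemble(positives, negatives, scaled_down_network(input_len), cfg)
    probs = ensemble_predict(model, test.inputs)
    _, _, auc = roc_and_auc(probs[:, 1], test.labels)
    return BenchmarkResult(
        auc=float(auc), n_train=len(train), n_test=len(test), model=model
    )
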