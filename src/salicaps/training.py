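"""Bagging-ensemble training for the class-imbalanced secretion task.

Positive (saliva-secretory) proteins are scarce relative to negatives, so a
single model trained on the raw data is dominated by the majority class.
Bagging restores balance: each of T iterations pairs the full positive set
with a fresh random subset of n negatives drawn without replacement, trains
an independent network on that balanced bag, and the ensemble prediction is
the arithmetic mean of the member softmax outputs.

Members are optimized with Adam (learning rate 0.001, first/second moment
decay 0.9/0.999) on cross-entropy loss plus an L2 weight penalty, with early
stopping on validation cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from salicaps.network import (
    NetworkConfig,
    forward_with_cache,
    init_params,
    loss_and_grads,
)


@dataclass
class LabeledDataset:
    """Encoded inputs with binary labels and protein ids."""

    inputs: np.ndarray  # (N, input_len, 20)
    labels: np.ndarray  # (N,) in {0, 1}
    ids: list[str]

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.inputs) == len(self.labels) == len(self.ids)):
            raise ValueError("inputs, labels and ids must have equal lengths")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            inputs=self.inputs[idx],
            labels=self.labels[idx],
            ids=[self.ids[i] for i in idx],
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and stopping settings for one ensemble member."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    l2_coefficient: float = 1e-4
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        for name in (
            "learning_rate", "beta1", "beta2", "batch_size", "max_epochs",
            "early_stop_patience",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.l2_coefficient < 0.0:
            raise ValueError("l2_coefficient must be >= 0")


@dataclass(frozen=True)
class BaggingConfig:
    """Bagging settings: T iterations of n negatives each."""

    iterations: int = 10
    bag_size: int = 350
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")


class BagSizeError(ValueError):
    """Raised when the negative pool is smaller than the requested bag size."""


def make_bags(
    positives: Sequence, negatives: Sequence, cfg: BaggingConfig
) -> list[tuple[list, list]]:
    """Draw T balanced bags of (positives, sampled negatives).

    Every bag contains the full positive set (or ``bag_size`` positives drawn
    without replacement if more exist) plus ``bag_size`` negatives drawn
    without replacement, resampled independently per bag.  Reproducible under
    ``cfg.seed``.
    """
    positives = list(positives)
    negatives = list(negatives)
    if len(positives) < 1:
        raise ValueError("at least one positive sample is required")
    if len(negatives) < cfg.bag_size:
        raise BagSizeError(
            f"need at least bag_size={cfg.bag_size} negatives, "
            f"got {len(negatives)}"
        )
    rng = np.random.default_rng(cfg.seed)
    bags = []
    for _ in range(cfg.iterations):
        if len(positives) > cfg.bag_size:
            pos_idx = rng.choice(len(positives), size=cfg.bag_size, replace=False)
            bag_pos = [positives[i] for i in pos_idx]
        else:
            bag_pos = list(positives)
        neg_idx = rng.choice(len(negatives), size=cfg.bag_size, replace=False)
        bags.append((bag_pos, [negatives[i] for i in neg_idx]))
    return bags


def kfold_split(
    labels: Sequence[int] | LabeledDataset, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions as (train_idx, validation_idx) pairs."""
    if isinstance(labels, LabeledDataset):
        labels = labels.labels
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, val) for train, val in skf.split(np.zeros(len(labels)), labels)
    ]


class Adam:
    """Plain Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.lr = cfg.learning_rate
        self.b1 = cfg.beta1
        self.b2 = cfg.beta2
        self.eps = 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def _stratified_holdout(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (train, validation), stratified by label."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.asarray(sorted(train_idx)), np.asarray(sorted(val_idx))


def evaluate_loss(
    dataset: LabeledDataset,
    net: NetworkConfig,
    params: dict[str, np.ndarray],
    batch_size: int = 64,
) -> float:
    """Mean cross-entropy of a parameter set on a dataset (dropout off)."""
    total = 0.0
    for start in range(0, len(dataset), batch_size):
        xb = dataset.inputs[start : start + batch_size]
        yb = dataset.labels[start : start + batch_size]
        probs, _ = forward_with_cache(xb, net, params, train=False)
        total += -np.sum(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
    return float(total / len(dataset))


def train_member(
    bag: LabeledDataset,
    net: NetworkConfig,
    cfg: TrainConfig,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train one ensemble member on a balanced bag.

    A stratified ``validation_fraction`` holdout monitors cross-entropy;
    training halts at ``max_epochs`` or after ``early_stop_patience`` epochs
    without validation improvement, returning the best-validation weights.

    Returns (params, history) where history holds one record per epoch with
    train and validation loss.
    """
    if len(bag) == 0:
        raise ValueError("bag is empty")
    if len(np.unique(bag.labels)) < 2:
        raise ValueError("bag must contain both classes")
    if net.l2_coefficient != cfg.l2_coefficient:
        net = NetworkConfig(**{**net.to_dict(), "lanes": net.lanes,
                               "l2_coefficient": cfg.l2_coefficient})
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _stratified_holdout(
        bag.labels, cfg.validation_fraction, rng
    )
    train_set, val_set = bag.subset(train_idx), bag.subset(val_idx)

    params = init_params(net, rng, dtype=np.dtype(cfg.dtype))
    optimizer = Adam(params, cfg)
    best_params = {k: v.copy() for k, v in params.items()}
    best_val = np.inf
    stale = 0
    history: list[dict] = []
    n_train = len(train_set)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, grads, _ = loss_and_grads(
                train_set.inputs[batch], train_set.labels[batch],
                net, params, train=True, rng=rng,
            )
            optimizer.step(params, grads)
            epoch_loss += loss * len(batch)
        val_loss = evaluate_loss(val_set, net, params)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n_train,
             "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    return best_params, history


@dataclass
class EnsembleModel:
    """A trained bagging ensemble: member weights plus shared configuration."""

    config: NetworkConfig
    members: list[dict[str, np.ndarray]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")

    def predict(self, inputs: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return ensemble_predict(self, inputs, batch_size=batch_size)

    def save(self, path: str | Path) -> None:
        """Persist all members and the config in one .npz container."""
        arrays: dict[str, np.ndarray] = {}
        for i, member in enumerate(self.members):
            for k, v in member.items():
                arrays[f"member{i}/{k}"] = v
        meta = {
            "config": self.config.to_dict(),
            "n_members": len(self.members),
            "metadata": self.metadata,
        }
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = NetworkConfig.from_dict(meta["config"])
            members = []
            for i in range(meta["n_members"]):
                prefix = f"member{i}/"
                members.append(
                    {
                        k[len(prefix):]: data[k]
                        for k in data.files
                        if k.startswith(prefix)
                    }
                )
        return cls(config=config, members=members, metadata=meta["metadata"])


def ensemble_predict(
    model: EnsembleModel, inputs: np.ndarray, batch_size: int = 64
) -> np.ndarray:
    """Mean of member softmax outputs; shape (N, 2), rows sum to 1."""
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim == 2:
        inputs = inputs[None]
    total = np.zeros((len(inputs), model.config.n_classes))
    for member in model.members:
        for start in range(0, len(inputs), batch_size):
            xb = inputs[start : start + batch_size]
            probs, _ = forward_with_cache(xb, model.config, member, train=False)
            total[start : start + batch_size] += probs
    return total / len(model.members)


def train_ensemble(
    positives: LabeledDataset,
    negatives: LabeledDataset,
    net: NetworkConfig,
    cfg: BaggingConfig,
) -> EnsembleModel:
    """Full bagging pipeline: draw T balanced bags and train one member each.

    Per-member training seeds are fanned out deterministically from
    ``cfg.seed``.
    """
    pos_idx = list(range(len(positives)))
    neg_idx = list(range(len(negatives)))
    bags = make_bags(pos_idx, neg_idx, cfg)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.iterations)
    members = []
    compositions = []
    for t, (bag_pos, bag_neg) in enumerate(bags):
        bag = LabeledDataset(
            inputs=np.concatenate(
                [positives.inputs[bag_pos], negatives.inputs[bag_neg]]
            ),
            labels=np.concatenate(
                [positives.labels[bag_pos], negatives.labels[bag_neg]]
            ),
            ids=[positives.ids[i] for i in bag_pos]
            + [negatives.ids[i] for i in bag_neg],
        )
        params, _ = train_member(bag, net, cfg.train, seed=int(seeds[t] % 2**31))
        members.append(params)
        compositions.append(
            {"positives": list(map(int, bag_pos)),
             "negatives": list(map(int, bag_neg))}
        )
    return EnsembleModel(
        config=net,
        members=members,
        metadata={"seed": cfg.seed, "bags": compositions},
    )
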