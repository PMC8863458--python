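"""End-to-end optimization of the hybrid network.

The objective is the mean cross-entropy over the batch plus an l2 penalty
``lambda * sum(w**2)`` over convolution and dense weights (batch-norm
scale/shift and biases are exempt).  Optimization uses Adam with an initial
learning rate of 0.005 halved every 20 epochs, batch size 6, and a maximum of
100 epochs; the final-epoch model is the evaluated model (no early stopping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import InvalidInputError, NumericalError
from .architecture import BRANCH_ORDER, ArchConfig, HybridNetwork, stack_hybrids
from .nn import Adam, Param, softmax
from .transforms import HybridInput

__all__ = ["TrainConfig", "TrainRecord", "loss", "learning_rate_at", "train_model"]

_CLIP = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and regularization strength."""

    batch_size: int = 6
    max_epochs: int = 100
    initial_lr: float = 0.005
    lr_halving_period_epochs: int = 20
    l2_lambda: float = 1e-4
    optimizer: str = "Adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.lr_halving_period_epochs) < 1:
            raise InvalidInputError("batch size, epochs and halving period must be >= 1")
        if self.initial_lr <= 0 or self.l2_lambda < 0:
            raise InvalidInputError("initial_lr must be > 0 and l2_lambda >= 0")


@dataclass
class TrainRecord:
    """Per-epoch training trace plus the trained model."""

    losses: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    clip_events: int = 0
    config: TrainConfig | None = None
    model: HybridNetwork | None = None


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant halving schedule: lr(e) = lr0 * 0.5**floor(e/period)."""
    return config.initial_lr * 0.5 ** (epoch // config.lr_halving_period_epochs)


def loss(
    probabilities: np.ndarray,
    labels: np.ndarray,
    weights: list[Param] | list[np.ndarray] | None = None,
    l2_lambda: float = 1e-4,
) -> float:
    """Regularized cross-entropy: mean over the batch plus lambda * sum(w**2).

    Probabilities below 1e-12 at the true class are clipped before the log.
    ``weights`` may be ``Param`` objects (only those marked ``regularized``
    contribute) or plain arrays (all contribute).
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    y = np.asarray(labels, dtype=np.int64).ravel()
    if p.shape[0] != y.size:
        raise InvalidInputError("probabilities and labels disagree in length")
    p_true = np.clip(p[np.arange(y.size), y], _CLIP, None)
    ce = float(-np.mean(np.log(p_true)))
    reg = 0.0
    if weights is not None:
        for w in weights:
            if isinstance(w, Param):
                if w.regularized:
                    reg += float(np.sum(w.value.astype(np.float64) ** 2))
            else:
                reg += float(np.sum(np.asarray(w, dtype=np.float64) ** 2))
    return ce + l2_lambda * reg


def _l2_sum(params: list[Param]) -> float:
    return sum(float(np.sum(p.value.astype(np.float64) ** 2))
               for p in params if p.regularized)


def train_model(
    train_set: list[HybridInput] | dict[str, np.ndarray],
    labels: np.ndarray,
    config: TrainConfig | None = None,
    branches: tuple[str, ...] = BRANCH_ORDER,
    model: HybridNetwork | None = None,
    arch: ArchConfig | None = None,
) -> TrainRecord:
    """Jointly optimize all branches and the head on a labeled training set.

    ``train_set`` is either a list of ``HybridInput`` (sharing one transform
    config) or pre-stacked batch tensors keyed by branch name.  All
    randomness (weight init, epoch shuffling) derives from ``config.seed``;
    identical seeds and data reproduce the record exactly.
    """
    config = config or TrainConfig()
    y = np.asarray(labels, dtype=np.int64).ravel()
    if np.unique(y).size < 2:
        raise InvalidInputError("training set must contain both classes")
    if model is None:
        model = HybridNetwork(branches=branches, arch=arch, seed=config.seed)
    arrays = (
        stack_hybrids(train_set, model.branch_names)
        if not isinstance(train_set, dict)
        else {k: train_set[k] for k in model.branch_names}
    )
    n = y.size
    if any(a.shape[1] != n for a in arrays.values()):
        raise InvalidInputError("inputs and labels disagree in sample count")

    params = model.params()
    reg_params = [p for p in params if p.regularized]
    opt = Adam(params, config.adam_beta1, config.adam_beta2, config.adam_eps)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    lam = config.l2_lambda
    record = TrainRecord(config=config, model=model)

    for epoch in range(config.max_epochs):
        lr = learning_rate_at(epoch, config)
        perm = shuffle_rng.permutation(n)
        epoch_ce = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = {k: np.ascontiguousarray(a[:, idx]) for k, a in arrays.items()}
            yb = y[idx]
            logits = model.forward(xb, training=True)
            p = softmax(logits.astype(np.float64))
            p_true = p[np.arange(yb.size), yb]
            record.clip_events += int(np.sum(p_true < _CLIP))
            batch_ce = -np.log(np.clip(p_true, _CLIP, None))
            epoch_ce += float(batch_ce.sum())
            epoch_correct += int(np.sum((p[:, 0] <= p[:, 1]).astype(np.int64) == yb))
            # d(mean CE)/dlogits for softmax cross-entropy
            dlogits = p.copy()
            dlogits[np.arange(yb.size), yb] -= 1.0
            dlogits /= yb.size
            model.backward(dlogits.astype(np.float32))
            for pm in reg_params:
                pm.grad += (2.0 * lam) * pm.value
            opt.step(lr)
        total = epoch_ce / n + lam * _l2_sum(reg_params)
        if not np.isfinite(total):
            raise NumericalError(
                f"non-finite loss at epoch {epoch} (cross-entropy {epoch_ce / n})"
            )
        record.losses.append(total)
        record.accuracies.append(epoch_correct / n)
        record.learning_rates.append(lr)
    return record
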