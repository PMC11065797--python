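"""Training loop: MSE loss, Adam, exponential LR decay, early stopping.

One independent model is trained per view count; the returned weights are
always those of the minimum-validation-loss epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from sparsect.model.config import UNetConfig
from sparsect.model.layers import DTYPE, Adam
from sparsect.model.unet import ResidualModel, build_model
from sparsect.preprocessing import ResidualPair


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    batch_size: int = 6
    lr0: float = 0.001
    lr_decay_rate: float = 0.1  # lr_n = lr0 * exp(-rate * n)
    early_stopping_patience: int = 5
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def lr_at_epoch(epoch_index: int, config: TrainConfig = TrainConfig()) -> float:
    """Closed-form exponential schedule: lr0 * exp(-0.1 * n), n = 0 first epoch."""
    if epoch_index < 0:
        raise ValueError("epoch_index must be >= 0")
    return config.lr0 * float(np.exp(-config.lr_decay_rate * epoch_index))


def _stack(pairs: Sequence[ResidualPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.sparse for p in pairs]).astype(DTYPE)[:, None]
    y = np.stack([p.residual_label for p in pairs]).astype(DTYPE)[:, None]
    return x, y


def _eval_loss(model: ResidualModel, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        pred = model.forward(xb, training=False)
        total += float(np.sum((pred - yb) ** 2))
        n += yb.size
    return total / n


def train(
    model: ResidualModel,
    train_pairs: Sequence[ResidualPair],
    val_pairs: Sequence[ResidualPair],
    config: TrainConfig = TrainConfig(),
) -> tuple[ResidualModel, TrainHistory]:
    """Minimize MSE with Adam; return the best-validation-epoch weights.

    Halts at ``max_epochs`` or once validation loss has not improved by
    more than ``min_delta`` for ``early_stopping_patience`` consecutive
    epochs. Raises on an empty training set or a non-finite loss.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    if len(val_pairs) == 0:
        raise ValueError("empty validation set")
    train_subjects = {p.subject_id for p in train_pairs}
    val_subjects = {p.subject_id for p in val_pairs}
    if train_subjects & val_subjects:
        raise ValueError(
            f"subjects shared between train and validation: {sorted(train_subjects & val_subjects)}"
        )

    x_tr, y_tr = _stack(train_pairs)
    x_va, y_va = _stack(val_pairs)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.layers)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    since_improvement = 0

    for epoch in range(config.max_epochs):
        lr = lr_at_epoch(epoch, config)
        perm = rng.permutation(len(x_tr))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, training=True)
            diff = pred - yb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.backward((2.0 / diff.size) * diff.astype(DTYPE))
            optimizer.step(lr)
            epoch_loss += loss * yb.size
            seen += yb.size

        val = _eval_loss(model, x_va, y_va, config.batch_size)
        history.train_loss.append(epoch_loss / seen)
        history.val_loss.append(val)
        history.learning_rate.append(lr)

        if val < best_val - config.min_delta:
            best_val = val
            history.best_epoch = epoch
            best_state = model.state_dict()
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.early_stopping_patience:
                history.stopped_early = True
                break

    model.load_state_dict(best_state)
    return model, history


def train_all_views(
    pairs_by_view: dict[int, tuple[Sequence[ResidualPair], Sequence[ResidualPair]]],
    view_counts: Sequence[int],
    model_config: UNetConfig,
    train_config: TrainConfig = TrainConfig(),
) -> dict[int, tuple[ResidualModel, TrainHistory]]:
    """Train one independently initialized model per view count.

    ``pairs_by_view`` maps view count -> (train_pairs, val_pairs). Seeds are
    offset per view so runs are reproducible yet independent.
    """
    missing = [v for v in view_counts if v not in pairs_by_view]
    if missing:
        raise ValueError(f"no residual pairs for view levels: {missing}")
    out: dict[int, tuple[ResidualModel, TrainHistory]] = {}
    for v in view_counts:
        tr, va = pairs_by_view[v]
        mcfg = UNetConfig(
            **{
                **model_config.__dict__,
                "seed": model_config.seed + int(v),
            }
        )
        tcfg = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + int(v)})
        model = build_model(mcfg)
        out[v] = train(model, tr, va, tcfg)
    return out
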