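"""Two-stage training, early stopping, and the split/trial protocol.

Stage 1 trains each enabled path independently: every path gets its own
temporary sum-readout plus affine head, and only that path's layer
parameters (and temporary head) are optimized.  Stage 2 freezes all path
parameters and trains the aggregator and the final head.  Both stages
minimize mean squared error on minibatches of 16 by default and stop when
the monitored loss has not improved by at least ``min_delta`` for
``patience`` successive epochs.

The evaluation protocol splits the data 8:1:1 into train/validation/test,
repeats over independent trials (fresh split and fresh model per trial),
and averages test metrics across trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._tensor import Tensor
from .model import (ModelConfig, MultiPathModel, build_model,
                    forward_tensor, _run_path_stream)
from .molgraph import MolecularGraph
from .paths import glorot

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitSpec", "TrainLog", "Adam", "SGD",
           "split_dataset", "mse_loss", "should_stop",
           "train_stage1", "train_stage2", "train_model", "run_trials"]

Record = tuple[MolecularGraph, float]


@dataclass
class TrainConfig:
    batch_size: int = 16
    optimizer: str = "adam"            # adam | sgd
    learning_rate: float = 3e-3
    patience: int = 10
    min_delta: float = 1e-4
    max_epochs: int = 500
    monitored_loss: str = "validation"  # validation | training
    loss: str = "mse"                   # mse | bce
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.monitored_loss not in ("validation", "training"):
            raise ValueError(f"unknown monitored loss {self.monitored_loss!r}")


@dataclass
class SplitSpec:
    """8:1:1 split protocol; trial t permutes with seed ``base_seed + t``."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_trials: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TrainLog:
    train_losses: list[float] = field(default_factory=list)
    valid_losses: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""
    trained_groups: tuple[str, ...] = ()
    frozen_groups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# optimizers


class Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            # np.asarray keeps 0-d parameters as arrays, not numpy scalars
            p.data = np.asarray(p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class SGD:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data = np.asarray(p.data - self.lr * p.grad)


def _make_optimizer(params: Sequence[Tensor], config: TrainConfig):
    if config.optimizer == "adam":
        return Adam(params, lr=config.learning_rate)
    return SGD(params, lr=config.learning_rate)


# ---------------------------------------------------------------------------
# protocol primitives


def split_dataset(records: Sequence[Record], spec: SplitSpec,
                  trial: int = 0) -> tuple[list[Record], list[Record], list[Record]]:
    """Seeded random split into (train, valid, test) of sizes
    (floor(f_tr * n), floor(f_va * n), remainder)."""
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(spec.base_seed + trial)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.fractions[0] * n))
    n_valid = int(np.floor(spec.fractions[1] * n))
    idx_train = perm[:n_train]
    idx_valid = perm[n_train:n_train + n_valid]
    idx_test = perm[n_train + n_valid:]
    pick = lambda idx: [records[i] for i in idx]
    return pick(idx_train), pick(idx_valid), pick(idx_test)


def mse_loss(pred: Sequence[float], target: Sequence[float]) -> float:
    """Mean squared error (1/n) sum (pred - target)^2."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.size == 0:
        raise ValueError("mse_loss on empty input")
    if pred.shape != target.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def should_stop(loss_history: Sequence[float], patience: int,
                min_delta: float) -> bool:
    """True iff each of the last ``patience`` epochs improved the running
    best by less than ``min_delta``."""
    if not len(loss_history):
        raise ValueError("empty loss history")
    if len(loss_history) < patience:
        return False
    best = np.inf
    improvements: list[float] = []
    for loss in loss_history:
        improvements.append(best - loss)
        best = min(best, loss)
    return all(imp < min_delta for imp in improvements[-patience:])


# ---------------------------------------------------------------------------
# fitting machinery


def _scaled_targets(model: MultiPathModel, records: Sequence[Record]) -> np.ndarray:
    y = np.array([t for _, t in records], dtype=float)
    return (y - model.target_mean) / model.target_std


def _fit_scaler(model: MultiPathModel, train: Sequence[Record],
                config: TrainConfig) -> None:
    if config.standardize and model.config.task == "regression":
        y = np.array([t for _, t in train], dtype=float)
        model.target_mean = float(y.mean())
        model.target_std = float(y.std()) or 1.0
    else:
        model.target_mean, model.target_std = 0.0, 1.0


def _batch_loss(preds: list[Tensor], targets: np.ndarray,
                kind: str) -> Tensor:
    total: Tensor | None = None
    for pred, y in zip(preds, targets):
        if kind == "mse":
            term = (pred - float(y)) ** 2
        else:  # bce on the logistic output
            p = pred.sigmoid()
            y = float(y)
            term = -(y * p.log() + (1 - y) * (1 - p).log())
        total = term if total is None else total + term
    return total / float(len(preds))


def _fit(forward_fn: Callable[[MolecularGraph], Tensor],
         params: Sequence[Tensor], train: Sequence[Record],
         valid: Sequence[Record], targets_train: np.ndarray,
         targets_valid: np.ndarray, config: TrainConfig,
         rng: np.random.Generator) -> TrainLog:
    """Minibatch-optimize ``params``; early-stop on the monitored loss."""
    opt = _make_optimizer(params, config)
    log = TrainLog()
    monitored: list[float] = []
    best = np.inf
    best_state: list[np.ndarray] | None = None
    trainable = [p for p in params if p.requires_grad]

    def restore_best() -> None:
        if best_state is not None:
            for p, data in zip(trainable, best_state):
                p.data = data

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train))
        running = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            preds = [forward_fn(train[i][0]) for i in batch]
            loss = _batch_loss(preds, targets_train[batch], config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            running += loss.item() * len(batch)
        train_loss = running / len(train)
        valid_preds = [forward_fn(g).item() for g, _ in valid]
        valid_loss = (mse_loss(valid_preds, targets_valid)
                      if config.loss == "mse" else
                      _bce_metric(valid_preds, targets_valid))
        if not (np.isfinite(train_loss) and np.isfinite(valid_loss)):
            log.stop_epoch, log.stop_reason = epoch, "diverged (non-finite loss)"
            logger.error("training diverged at epoch %d", epoch)
            raise RuntimeError(f"training diverged at epoch {epoch}")
        log.train_losses.append(train_loss)
        log.valid_losses.append(valid_loss)
        monitored.append(valid_loss if config.monitored_loss == "validation"
                         else train_loss)
        if monitored[-1] < best:
            best = monitored[-1]
            best_state = [p.data.copy() for p in trainable]
        if should_stop(monitored, config.patience, config.min_delta):
            log.stop_epoch, log.stop_reason = epoch, "early_stopping"
            restore_best()
            return log
    log.stop_epoch, log.stop_reason = config.max_epochs, "max_epochs"
    restore_best()
    return log


def _bce_metric(raw_preds: Sequence[float], targets: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-np.asarray(raw_preds)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    y = np.asarray(targets)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


# ---------------------------------------------------------------------------
# the two training stages


def _single_path_forward(model: MultiPathModel, path: str,
                         head: tuple[Tensor, Tensor]
                         ) -> Callable[[MolecularGraph], Tensor]:
    W, b = head

    def fn(graph: MolecularGraph) -> Tensor:
        H = _run_path_stream(model, graph, path, Tensor(graph.H_init))
        vec = H.sum(axis=0)
        return (vec.reshape(1, -1) @ W.T + b).reshape(())

    return fn


def train_stage1(model: MultiPathModel, train: Sequence[Record],
                 valid: Sequence[Record],
                 config: TrainConfig) -> dict[str, TrainLog]:
    """Train each enabled path independently with a temporary head.

    Aggregator and final-head parameters are untouched; the temporary heads
    are kept on the model (``temp_heads``) only for inspection and are
    discarded by stage 2.
    """
    _fit_scaler(model, train, config)
    y_train = _scaled_targets(model, train)
    y_valid = _scaled_targets(model, valid)
    logs: dict[str, TrainLog] = {}
    for k, path in enumerate(model.config.paths):
        rng = np.random.default_rng([config.seed, k])
        M = model.config.feature_dim
        head = (glorot(rng, 1, M), Tensor(0.0, requires_grad=True))
        model.temp_heads[path] = head
        params = list(model.path_tensors(path).values()) + list(head)
        log = _fit(_single_path_forward(model, path, head), params,
                   train, valid, y_train, y_valid, config, rng)
        log.trained_groups = (path, f"temp_head/{path}")
        log.frozen_groups = tuple(p for p in model.config.paths if p != path
                                  ) + ("aggregator", "head")
        logs[path] = log
    return logs


def train_stage2(model: MultiPathModel, train: Sequence[Record],
                 valid: Sequence[Record], config: TrainConfig) -> TrainLog:
    """Freeze the paths; train the aggregator and the final head.

    Path parameters are snapshotted before and asserted bitwise unchanged
    after the run.
    """
    if not model.temp_heads:
        logger.warning("stage 2 without a preceding stage 1")
    model.temp_heads = {}
    y_train = _scaled_targets(model, train)
    y_valid = _scaled_targets(model, valid)
    snapshot = {name: t.data.copy()
                for p in model.config.paths
                for name, t in model.path_tensors(p).items()}
    params = list(model.agg_tensors().values()) + list(model.head_tensors().values())
    rng = np.random.default_rng([config.seed, 1000])

    def fn(graph: MolecularGraph) -> Tensor:
        return forward_tensor(model, graph)[0]

    log = _fit(fn, params, train, valid, y_train, y_valid, config, rng)
    for p in model.config.paths:
        for name, t in model.path_tensors(p).items():
            if not np.array_equal(t.data, snapshot[name]):
                raise AssertionError(f"frozen path parameter {name} changed in stage 2")
    log.trained_groups = ("aggregator", "head")
    log.frozen_groups = tuple(model.config.paths)
    return log


def train_model(model: MultiPathModel, train: Sequence[Record],
                valid: Sequence[Record], config: TrainConfig
                ) -> dict[str, TrainLog]:
    """Run both stages; returns per-path stage-1 logs plus the stage-2 log
    under key "stage2"."""
    logs = dict(train_stage1(model, train, valid, config))
    logs["stage2"] = train_stage2(model, train, valid, config)
    return logs


# ---------------------------------------------------------------------------
# multi-trial protocol


def run_trials(records: Sequence[Record], model_config: ModelConfig,
               train_config: TrainConfig, split_spec: SplitSpec):
    """Fresh split + fresh model + two-stage training per trial; returns
    (per-trial results, aggregate mean/std)."""
    from .evaluation import TrialResult, aggregate_trials, evaluate_model

    results: list[TrialResult] = []
    for trial in range(split_spec.n_trials):
        try:
            train, valid, test = split_dataset(records, split_spec, trial)
            cfg = ModelConfig.from_dict({**model_config.to_dict(),
                                         "seed": model_config.seed + trial})
            tcfg_dict = vars(train_config).copy()
            tcfg_dict["seed"] = train_config.seed + trial
            tcfg = TrainConfig(**tcfg_dict)
            model = build_model(cfg)
            train_model(model, train, valid, tcfg)
            results.append(evaluate_model(model, test, trial=trial))
        except Exception as exc:
            raise RuntimeError(f"trial {trial} failed: {exc}") from exc
    return results, aggregate_trials(results)
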