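"""Training, cross-validation and hyperparameter search for cNODE models.

The loss is the mean prediction error over a dataset,

    E(D) = (1/|D|) sum_{(z,p) in D} d(p, phi_theta(z)),

with Bray-Curtis dissimilarity by default.  Gradients are exact
(reverse-mode through the unrolled solver); updates use adaptive-moment
gradient descent (Adam) or plain SGD.

Two training modes are provided.  *Plain* mode runs mini-batch gradient
descent on E.  *Meta* mode treats each mini-batch as an episode split into
support and query sets: the parameters are adapted on the support split by
a few inner SGD steps, the query loss is evaluated at the adapted
parameters, and its gradient drives the outer update of the original
parameters (a first-order MAML-style scheme).  Meta mode targets
generalization to never-seen assemblages; plain mode is the simpler
fallback and both are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._grad import loss_and_grad
from .core import CNODEModel
from .datamodel import MicrobiomeDataset
from .dissimilarity import get_dissimilarity
from .evaluation import EvaluationResult, evaluate

__all__ = [
    "TrainingConfig",
    "MetaSettings",
    "TrainingTrace",
    "bray_curtis",
    "prediction_error",
    "train",
    "meta_episode_update",
    "leave_one_out",
    "hyperparameter_search",
]

# re-export: the default dissimilarity doubles as the public error metric
from .dissimilarity import bray_curtis  # noqa: E402  (after __all__)


@dataclass(frozen=True)
class MetaSettings:
    """Episodic (support/query) adaptation settings for meta mode."""

    inner_steps: int = 1
    inner_lr: float = 0.05
    query_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be >= 0")
        if self.inner_lr <= 0:
            raise ValueError("inner_lr must be positive")
        if not 0.0 < self.query_fraction < 1.0:
            raise ValueError("query_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    epochs: int = 200
    minibatch_size: int = 8
    meta: MetaSettings | None = None
    dissimilarity: str = "bray_curtis"
    seed: int = 0
    optimizer: str = "adam"  # or "sgd"
    early_stopping_patience: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        get_dissimilarity(self.dissimilarity)


@dataclass
class TrainingTrace:
    train_errors: list[float] = field(default_factory=list)
    test_errors: list[float] | None = None

    @property
    def epochs(self) -> int:
        return len(self.train_errors)


def prediction_error(
    model: CNODEModel,
    dataset: MicrobiomeDataset,
    dissimilarity: str = "bray_curtis",
) -> float:
    """Mean dissimilarity between observed and predicted compositions."""
    if dataset.S == 0:
        raise ValueError("empty dataset")
    from .core import predict_batch

    value_fn, _ = get_dissimilarity(dissimilarity)
    Phat = predict_batch(model, dataset.Z)
    return float(np.asarray(value_fn(dataset.P, Phat)).mean())


class _Adam:
    """Minimal adaptive-moment optimizer for one dense matrix."""

    def __init__(self, shape, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, shape, lr: float):
        self.lr = lr

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        return theta - self.lr * grad


def _make_optimizer(name: str, shape, lr: float):
    return _Adam(shape, lr) if name == "adam" else _SGD(shape, lr)


def meta_episode_gradient(
    model: CNODEModel,
    Z: np.ndarray,
    P: np.ndarray,
    settings: MetaSettings,
    rng: np.random.Generator,
    dissimilarity: str,
) -> np.ndarray:
    """First-order meta gradient for one episode.

    The episode is split into support and query subsets; ``inner_steps``
    plain gradient steps adapt a copy of the parameters on the support
    split, and the query-loss gradient at the adapted parameters is
    returned as the outer gradient.  With ``inner_steps=0`` this is exactly
    the plain mini-batch gradient on the query split.
    """
    B = Z.shape[0]
    if B < 2:
        raise ValueError("meta episode needs at least 2 samples")
    n_query = round(settings.query_fraction * B)
    n_query = min(max(n_query, 1), B - 1)
    perm = rng.permutation(B)
    query, support = perm[:n_query], perm[n_query:]

    adapted = model.copy()
    for _ in range(settings.inner_steps):
        _, g = loss_and_grad(adapted, Z[support], P[support], dissimilarity)
        adapted.theta = adapted.theta - settings.inner_lr * g
    _, g_query = loss_and_grad(adapted, Z[query], P[query], dissimilarity)
    return g_query


def meta_episode_update(
    model: CNODEModel,
    episode_Z: np.ndarray,
    episode_P: np.ndarray,
    settings: MetaSettings,
    learning_rate: float,
    rng: np.random.Generator | int = 0,
    dissimilarity: str = "bray_curtis",
) -> CNODEModel:
    """One outer SGD update of ``model`` from a single meta episode."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    g = meta_episode_gradient(
        model, np.asarray(episode_Z), np.asarray(episode_P), settings, rng,
        dissimilarity,
    )
    out = model.copy()
    out.theta = model.theta - learning_rate * g
    return out


def train(
    model: CNODEModel,
    train_set: MicrobiomeDataset,
    config: TrainingConfig,
    test_set: MicrobiomeDataset | None = None,
) -> tuple[CNODEModel, TrainingTrace]:
    """Gradient-based training of a cNODE on (assemblage, composition) pairs.

    Returns a new model (the input is not mutated) and the per-epoch error
    trace; when ``test_set`` is given its error is traced as well.  Fully
    deterministic under ``config.seed``.
    """
    if train_set.S == 0:
        raise ValueError("empty training set")
    if config.minibatch_size > train_set.S:
        raise ValueError(
            f"minibatch_size {config.minibatch_size} exceeds training-set "
            f"size {train_set.S}"
        )
    current = model.copy()
    trace = TrainingTrace(test_errors=[] if test_set is not None else None)
    if config.epochs == 0:
        return current, trace

    Z, P = train_set.Z, train_set.P
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(config.optimizer, current.theta.shape, config.learning_rate)
    best_err = np.inf
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_set.S)
        for start in range(0, train_set.S, config.minibatch_size):
            batch = order[start : start + config.minibatch_size]
            if config.meta is not None and batch.size >= 2:
                grad = meta_episode_gradient(
                    current, Z[batch], P[batch], config.meta, rng,
                    config.dissimilarity,
                )
            else:
                _, grad = loss_and_grad(
                    current, Z[batch], P[batch], config.dissimilarity
                )
            if not np.isfinite(grad).all():
                raise FloatingPointError(
                    f"non-finite gradient at epoch {epoch}, batch start {start}"
                )
            current.theta = opt.step(current.theta, grad)

        epoch_err = prediction_error(current, train_set, config.dissimilarity)
        trace.train_errors.append(epoch_err)
        if test_set is not None:
            trace.test_errors.append(
                prediction_error(current, test_set, config.dissimilarity)
            )
        if config.early_stopping_patience is not None:
            monitored = (
                trace.test_errors[-1] if test_set is not None else epoch_err
            )
            if monitored < best_err - 1e-6:
                best_err = monitored
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stopping_patience:
                    break
    return current, trace


def leave_one_out(
    dataset: MicrobiomeDataset,
    config: TrainingConfig,
    init_seed: int = 0,
) -> EvaluationResult:
    """Leave-one-out cross-validation.

    For each sample k a fresh model is trained on the other S-1 samples and
    the dissimilarity between the held-out composition and its prediction
    is recorded; returns all S errors with quartile summaries.
    """
    if dataset.S < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    from .core import predict

    value_fn, _ = get_dissimilarity(config.dissimilarity)
    errors = []
    for k in range(dataset.S):
        rest = dataset.subset([i for i in range(dataset.S) if i != k])
        fresh = CNODEModel.initialize(dataset.N, seed=init_seed)
        fold_cfg = replace(
            config,
            minibatch_size=min(config.minibatch_size, rest.S),
            seed=config.seed + k,
        )
        try:
            fitted, _ = train(fresh, rest, fold_cfg)
        except FloatingPointError as exc:
            raise FloatingPointError(f"fold {k}: {exc}") from exc
        phat = predict(fitted, dataset[k].z)
        errors.append(float(value_fn(dataset[k].p, phat)))
    return EvaluationResult.from_errors(errors, config.dissimilarity)


def hyperparameter_search(
    dataset: MicrobiomeDataset,
    grid: Sequence[TrainingConfig],
    mode: str = "loocv",
    test_fraction: float = 0.2,
    split_seed: int = 0,
) -> tuple[TrainingConfig, list[dict]]:
    """Pick the configuration minimizing mean prediction error.

    ``mode="loocv"`` scores each configuration by leave-one-out
    cross-validation; ``mode="split"`` uses a single seeded train/test
    split (cheaper).  Ties break toward smaller learning rate, then smaller
    mini-batch size.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if mode not in ("loocv", "split"):
        raise ValueError("mode must be 'loocv' or 'split'")
    summaries: list[dict] = []
    for cfg in grid:
        try:
            if mode == "loocv":
                result = leave_one_out(dataset, cfg)
                mean_err = float(np.mean(result.per_sample_errors))
            else:
                from .io import split_dataset

                d1, d2 = split_dataset(dataset, test_fraction, split_seed)
                cfg_eff = replace(
                    cfg, minibatch_size=min(cfg.minibatch_size, d1.S)
                )
                fitted, _ = train(
                    CNODEModel.initialize(dataset.N, seed=cfg.seed), d1, cfg_eff
                )
                mean_err = prediction_error(fitted, d2, cfg.dissimilarity)
        except FloatingPointError as exc:
            raise FloatingPointError(f"config {cfg}: {exc}") from exc
        summaries.append(
            {
                "config": cfg,
                "mean_error": mean_err,
                "learning_rate": cfg.learning_rate,
                "minibatch_size": cfg.minibatch_size,
            }
        )
    best = min(
        summaries,
        key=lambda s: (s["mean_error"], s["learning_rate"], s["minibatch_size"]),
    )
    return best["config"], summaries
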