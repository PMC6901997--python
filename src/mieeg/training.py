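"""Loss, initialization, optimization and the transfer-learning protocols.

Training minimizes the categorical cross-entropy
:math:`C(p, q) = -\\sum_i p_i \\log q_i` (targets :math:`p`, predicted
distribution :math:`q`) with Adam at learning rate 1e-3, L2 weight decay
1e-7 and mini-batches of 64; convolution weights are initialized from a
standard normal and batch-norm scales at 1.  The best-validation-accuracy
checkpoint is returned (fixed epoch budget, no early stopping, so runs are
bit-reproducible for a given seed).

Cross-subject transfer: a coarse model is pretrained on the pooled trials
of the source subjects, then fine-tuned on the target subject's (possibly
very small) calibration set, optionally mixed with randomly drawn source
trials.  During fine-tuning each sub-network gets its own learning rate —
1/27, 1/9 and 1/3 of the base rate for the feature-extraction,
feature-reduction and classifier groups respectively — so that the early,
general layers move least.  The feature-reduction group of this
architecture happens to have no trainable parameters; its factor is exposed
for variant architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from ._layers import DTYPE, Adam
from .epochs import (
    EpochedDataset,
    ValidationError,
    concatenate_datasets,
    split_dataset,
    stratified_sample,
)
from .model import Model

__all__ = [
    "TrainConfig",
    "LayeredLRPolicy",
    "EpochRecord",
    "TrainHistory",
    "cross_entropy",
    "initialize_weights",
    "train",
    "evaluate",
    "pretrain_pooled",
    "fine_tune",
    "small_sample_protocol",
]


@dataclass
class TrainConfig:
    """Optimizer and loop settings (defaults follow the standard recipe)."""

    base_lr: float = 1e-3
    weight_decay: float = 1e-7
    batch_size: int = 64
    max_epochs: int = 100
    seed: int = 0
    valid_fraction: float = 0.1  # internal split used by the pooled/fine-tune paths

    def __post_init__(self) -> None:
        if not self.base_lr > 0:
            raise ValidationError("base_lr must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")


@dataclass
class LayeredLRPolicy:
    """Per-sub-network learning-rate factors for fine-tuning (1/27, 1/9, 1/3)."""

    fe_factor: float = 1.0 / 27.0
    fr_factor: float = 1.0 / 9.0
    clf_factor: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.fe_factor <= self.fr_factor <= self.clf_factor <= 1:
            raise ValidationError(
                "need 0 < fe_factor <= fr_factor <= clf_factor <= 1, got "
                f"{(self.fe_factor, self.fr_factor, self.clf_factor)}"
            )

    def factors(self) -> dict[str, float]:
        return {
            "feature_extraction": self.fe_factor,
            "feature_reduction": self.fr_factor,
            "classifier": self.clf_factor,
        }


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    valid_loss: float
    valid_accuracy: float


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Index (1-based epoch number) of the best validation accuracy.

        Accuracy ties resolve to the lower validation loss (accuracy on a
        small validation set is coarsely quantized, the loss is not), and
        remaining ties to the earliest epoch.
        """
        best = max(self.records,
                   key=lambda r: (r.valid_accuracy, -r.valid_loss, -r.epoch))
        return best.epoch

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loss and metrics
# ---------------------------------------------------------------------------


def cross_entropy(target_onehot: np.ndarray, predicted_logprob: np.ndarray) -> float:
    """Mean categorical cross-entropy of log-probability predictions.

    ``target_onehot``: [B, n] one-hot rows; ``predicted_logprob``: [B, n]
    rows of log-probabilities.  Returns the batch mean of
    :math:`-\\sum_i p_i \\log q_i`.
    """
    p = np.asarray(target_onehot, dtype=np.float64)
    logq = np.asarray(predicted_logprob, dtype=np.float64)
    if p.shape != logq.shape:
        raise ValidationError(
            f"shape mismatch between targets {p.shape} and predictions {logq.shape}"
        )
    return float(-(p * logq).sum(axis=1).mean())


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes), dtype=np.float64)
    out[np.arange(labels.size), labels] = 1.0
    return out


def evaluate(model: Model, test_ds: EpochedDataset) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true class, columns = predicted)."""
    if test_ds.n_trials == 0:
        raise ValidationError("cannot evaluate on an empty dataset")
    from .model import predict

    pred, _ = predict(model, test_ds)
    acc = float((pred == test_ds.labels).mean())
    cm = confusion_matrix(test_ds.labels, pred, labels=np.arange(test_ds.n_classes))
    return acc, cm


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_weights(model: Model, scheme: str = "paper", seed: int = 0) -> Model:
    """Initialize all weights in place and return the model.

    ``"paper"``: convolution/classifier weights from a standard normal
    (zero mean, unit variance); batch-norm scale 1, shift 0; classifier
    bias 0.  This is an unusually large scale, but the batch norm after
    each convolution keeps activations trainable.
    ``"scaled"``: fan-in-scaled normal (std = 1/sqrt(fan_in)), a
    conventional alternative for ablation.
    """
    if scheme not in ("paper", "scaled"):
        raise ValidationError(f"unknown initialization scheme '{scheme}'")
    rng = np.random.default_rng(seed)
    for name, layer, _ in model.layer_specs:
        for pname, arr in layer.params.items():
            if name.startswith("bn_"):
                layer.params[pname] = (
                    np.ones_like(arr) if pname == "gamma" else np.zeros_like(arr)
                )
            elif pname == "b":
                layer.params[pname] = np.zeros_like(arr)
            else:
                w = rng.standard_normal(arr.shape)
                if scheme == "scaled":
                    fan_in = int(np.prod(arr.shape[1:]))
                    w = w / np.sqrt(max(1, fan_in))
                layer.params[pname] = w.astype(DTYPE)
    for bn in (model.bn_temporal, model.bn_spatial):
        bn.running_mean = np.zeros_like(bn.running_mean)
        bn.running_var = np.ones_like(bn.running_var)
    return model


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _make_optimizer(
    model: Model, cfg: TrainConfig, policy: LayeredLRPolicy | None
) -> Adam:
    factors = policy.factors() if policy else {g: 1.0 for g in
                                               ("feature_extraction", "feature_reduction", "classifier")}
    groups = [
        {"layers": model.layers_by_group(g), "lr_factor": f}
        for g, f in factors.items()
    ]
    return Adam(groups, base_lr=cfg.base_lr, weight_decay=cfg.weight_decay)


def _epoch_loss_and_step(
    model: Model, data: np.ndarray, onehot: np.ndarray, order: np.ndarray,
    batch_size: int, optimizer: Adam, rng: np.random.Generator,
) -> float:
    total, seen = 0.0, 0
    for s in range(0, order.size, batch_size):
        idx = order[s:s + batch_size]
        logp = model.forward(data[idx], training=True, rng=rng)
        p = onehot[idx]
        loss = cross_entropy(p, logp)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: non-finite loss {loss} at step {optimizer.t}"
            )
        model.backward(((-p) / idx.size).astype(DTYPE))
        optimizer.step()
        total += loss * idx.size
        seen += idx.size
    return total / seen


def _valid_metrics(model: Model, ds: EpochedDataset, batch_size: int) -> tuple[float, float]:
    losses, correct = 0.0, 0
    onehot = _onehot(ds.labels, ds.n_classes)
    for s in range(0, ds.n_trials, batch_size):
        logp = model.forward(ds.data[s:s + batch_size], training=False)
        losses += cross_entropy(onehot[s:s + batch_size], logp) * logp.shape[0]
        correct += int((logp.argmax(axis=1) == ds.labels[s:s + batch_size]).sum())
    return losses / ds.n_trials, correct / ds.n_trials


def train(
    model: Model,
    train_ds: EpochedDataset,
    valid_ds: EpochedDataset,
    cfg: TrainConfig,
    policy: LayeredLRPolicy | None = None,
) -> tuple[Model, TrainHistory]:
    """Train in place and return the best-validation checkpoint.

    Mini-batches are reshuffled every epoch from a generator seeded with
    ``cfg.seed``; ``policy`` (if given) assigns per-group learning-rate
    factors, as used for fine-tuning.  The returned model carries the
    weights of the epoch with the highest validation accuracy (ties broken
    by lower validation loss, then earliest epoch); the history records
    per-epoch train loss, validation loss and validation accuracy.
    """
    if train_ds.n_trials == 0:
        raise ValidationError("training set is empty")
    if train_ds.n_classes != model.cfg.n_classes:
        raise ValidationError(
            f"dataset has {train_ds.n_classes} classes, model expects {model.cfg.n_classes}"
        )
    rng = np.random.default_rng(cfg.seed)
    optimizer = _make_optimizer(model, cfg, policy)
    data = np.ascontiguousarray(train_ds.data, dtype=DTYPE)
    onehot = _onehot(train_ds.labels, train_ds.n_classes)
    history = TrainHistory()
    best_key, best_state = (-1.0, -np.inf), None
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train_ds.n_trials)
        train_loss = _epoch_loss_and_step(
            model, data, onehot, order, cfg.batch_size, optimizer, rng
        )
        valid_loss, valid_acc = _valid_metrics(model, valid_ds, cfg.batch_size)
        history.records.append(EpochRecord(epoch, train_loss, valid_loss, valid_acc))
        key = (valid_acc, -valid_loss)
        if key > best_key:
            best_key, best_state = key, model.state_dict()
    model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# transfer learning
# ---------------------------------------------------------------------------


def _sorted_by_subject(datasets: Sequence[EpochedDataset]) -> list[EpochedDataset]:
    # canonical subject order makes pooling invariant to the list order
    return sorted(datasets, key=lambda d: d.meta.subject_id)


def pretrain_pooled(
    source_datasets: Sequence[EpochedDataset],
    model: Model,
    cfg: TrainConfig,
) -> tuple[Model, TrainHistory]:
    """Train a coarse model on the pooled trials of all source subjects.

    Subjects are pooled in canonical (subject-id) order, then a stratified
    ``cfg.valid_fraction`` validation split is carved out for checkpoint
    selection; everything else is a standard :func:`train` run.
    """
    if not source_datasets:
        raise ValidationError("need at least one source dataset")
    pooled = concatenate_datasets(_sorted_by_subject(source_datasets))
    tr, va, _ = split_dataset(
        pooled, (1 - cfg.valid_fraction, cfg.valid_fraction, 0.0),
        seed=cfg.seed, stratified=True,
    )
    return train(model, tr, va, cfg)


def fine_tune(
    coarse: Model,
    target_train: EpochedDataset,
    mix_sources: Sequence[EpochedDataset],
    policy: LayeredLRPolicy,
    cfg: TrainConfig,
    mix_ratio: float = 1.0,
) -> tuple[Model, TrainHistory]:
    """Layered-learning-rate fine-tuning of a copy of the coarse model.

    A stratified ``cfg.valid_fraction`` of the target trials is held out as
    the validation set (calibration is to the target subject, so checkpoint
    selection tracks the target, not the source mixture); the training set
    is the union of the remaining target trials and
    ``round(mix_ratio * n_target)`` source trials drawn (seeded, without
    replacement when possible) from the pooled sources.  Per-group learning
    rates are ``cfg.base_lr`` times the policy factors.  ``coarse`` itself
    is never modified.
    """
    if target_train.n_trials == 0:
        raise ValidationError("target training set is empty")
    if mix_ratio < 0:
        raise ValidationError("mix_ratio must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    target_tr, target_va, _ = split_dataset(
        target_train, (1 - cfg.valid_fraction, cfg.valid_fraction, 0.0),
        seed=cfg.seed, stratified=True,
    )
    if target_va.n_trials == 0:  # tiny calibration sets: keep one trial out
        target_va = target_tr.subset(np.array([0]))
        target_tr = target_tr.subset(np.arange(1, target_tr.n_trials))
    parts = [target_tr]
    n_mix = int(round(mix_ratio * target_train.n_trials))
    if n_mix > 0 and mix_sources:
        pool = concatenate_datasets(_sorted_by_subject(mix_sources))
        replace_draw = n_mix > pool.n_trials
        chosen = rng.choice(pool.n_trials, size=n_mix, replace=replace_draw)
        parts.append(pool.subset(np.sort(chosen)))
    mixture = concatenate_datasets(parts, subject_id=target_train.meta.subject_id)
    model = coarse.copy()
    return train(model, mixture, target_va, cfg, policy=policy)


def small_sample_protocol(
    coarse: Model,
    target_train: EpochedDataset,
    target_test: EpochedDataset,
    policy: LayeredLRPolicy,
    cfg: TrainConfig,
    sample_sizes: Sequence[int] = (10, 20, 50, 100),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    mix_sources: Sequence[EpochedDataset] = (),
    mix_ratio: float = 1.0,
) -> pd.DataFrame:
    """Calibration-set-size sweep: fine-tune on n stratified target trials.

    For each ``n`` and each seed, draws ``n`` stratified trials from the
    target training set, fine-tunes a fresh copy of the coarse model and
    evaluates on the target test set.  Returns one row per ``n`` with the
    mean and standard deviation of accuracy over seeds.
    """
    sample_sizes = [int(n) for n in sample_sizes]
    if max(sample_sizes) > target_train.n_trials:
        raise ValidationError(
            f"largest sample size {max(sample_sizes)} exceeds the "
            f"{target_train.n_trials} available target trials"
        )
    rows = []
    for n in sample_sizes:
        accs = []
        for seed in seeds:
            subset = stratified_sample(target_train, n, seed=seed)
            tuned, _ = fine_tune(
                coarse, subset, mix_sources, policy,
                replace(cfg, seed=int(seed)), mix_ratio=mix_ratio,
            )
            acc, _ = evaluate(tuned, target_test)
            accs.append(acc)
        rows.append(
            {
                "n_samples": n,
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs)),
                "n_seeds": len(accs),
            }
        )
    return pd.DataFrame(rows)
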