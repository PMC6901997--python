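"""Multiscale filter-bank CNN for epoched motor-imagery EEG.

The network has three sub-networks, tagged as parameter groups so transfer
learning can assign each its own learning rate:

``feature_extraction``
    A parallel bank of temporal convolutions with kernel lengths 64, 40, 26
    and 16 samples (multiple temporal scales, i.e. learned band-pass filters
    of different bandwidth), concatenated and batch-normalized, followed by
    a spatial convolution across all electrodes (the learned analogue of a
    CSP spatial filter) and a second batch norm.

``feature_reduction``
    Square -> average-pool (length 75, stride 15) -> log -> dropout.  For
    each spatial filter this computes the log of windowed mean band power,
    the classical log-variance feature of CSP pipelines; it has no trainable
    parameters.

``classifier``
    A convolution whose kernel covers the whole pooled feature map (a fully
    connected layer), followed by log-softmax.

With input ``[B, C, T]`` the output is ``[B, N_C]`` log-probabilities.
:func:`compute_layer_shapes` is the executable twin of the architecture
table: it predicts every layer's output shape and parameter count
analytically, and the built network is checked against it in the tests.

A note on pooled length: with valid padding, pooling length 75 and stride 15
give ``L = (T - 75)//15 + 1`` output samples (71 for T = 1125); the
classifier kernel is sized to this L.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import _layers as L
from .epochs import EpochedDataset, ValidationError

__all__ = [
    "ModelConfig",
    "LayerShape",
    "LayerShapeReport",
    "Model",
    "compute_layer_shapes",
    "build_model",
    "forward",
    "predict",
    "extract_temporal_features",
    "save_checkpoint",
    "load_checkpoint",
    "GROUPS",
]

GROUPS = ("feature_extraction", "feature_reduction", "classifier")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``f_t`` is the number of temporal filters per branch and ``f_s`` the
    number of spatial filters; ``d = f_t / f_s`` may be given instead of
    ``f_s`` (the search-friendly parameterization).  Defaults correspond to
    the best reported setting, F_T = 40, D = 1.
    """

    n_channels: int
    n_times: int
    n_classes: int
    f_t: int = 40
    f_s: int | None = None
    d: float | None = None
    temporal_kernel_lengths: tuple[int, ...] = (64, 40, 26, 16)
    pool_length: int = 75
    pool_stride: int = 15
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        self.temporal_kernel_lengths = tuple(int(k) for k in self.temporal_kernel_lengths)
        if self.f_s is None:
            self.f_s = round(self.f_t / self.d) if self.d is not None else self.f_t
        if self.d is not None and self.f_t != round(self.d * self.f_s):
            raise ValidationError(
                f"inconsistent ratio: f_t={self.f_t} != round(d*f_s)={round(self.d * self.f_s)}"
            )
        if min(self.n_channels, self.n_times, self.n_classes, self.f_t, self.f_s) < 1:
            raise ValidationError("all size parameters must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValidationError(f"dropout_p must be in [0,1), got {self.dropout_p}")
        too_long = [k for k in self.temporal_kernel_lengths if k > self.n_times]
        if too_long:
            raise ValidationError(
                f"temporal kernels {too_long} exceed n_times={self.n_times}"
            )
        if self.pool_length > self.n_times:
            raise ValidationError(
                f"pool_length={self.pool_length} exceeds n_times={self.n_times} (average_pool)"
            )

    @property
    def pooled_length(self) -> int:
        return (self.n_times - self.pool_length) // self.pool_stride + 1

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "n_times": self.n_times,
            "n_classes": self.n_classes,
            "f_t": self.f_t,
            "f_s": self.f_s,
            "d": self.d,
            "temporal_kernel_lengths": list(self.temporal_kernel_lengths),
            "pool_length": self.pool_length,
            "pool_stride": self.pool_stride,
            "dropout_p": self.dropout_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "temporal_kernel_lengths" in d:
            d["temporal_kernel_lengths"] = tuple(d["temporal_kernel_lengths"])
        return cls(**d)


@dataclass(frozen=True)
class LayerShape:
    layer_name: str
    output_shape: tuple[int, ...]
    parameter_count: int


@dataclass
class LayerShapeReport:
    """Ordered per-layer output shapes and parameter counts."""

    layers: list[LayerShape] = field(default_factory=list)

    @property
    def total_parameters(self) -> int:
        return sum(rec.parameter_count for rec in self.layers)

    def __getitem__(self, name: str) -> LayerShape:
        for rec in self.layers:
            if rec.layer_name == name:
                return rec
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "layer": r.layer_name,
                    "output_shape": "x".join(map(str, r.output_shape)),
                    "parameters": r.parameter_count,
                }
                for r in self.layers
            ]
        )


def compute_layer_shapes(cfg: ModelConfig) -> LayerShapeReport:
    """Analytic per-layer output shapes and parameter counts.

    Weight counts: temporal branch ``k * F_T`` (same padding, no bias);
    batch norm ``2 * maps``; spatial ``C * 4F_T * F_S``; classifier
    ``F_S * L * N_C`` weights plus ``N_C`` bias.
    """
    c, t, n_c = cfg.n_channels, cfg.n_times, cfg.n_classes
    f_t, f_s = cfg.f_t, cfg.f_s
    n_branches = len(cfg.temporal_kernel_lengths)
    maps_cat = n_branches * f_t
    report = LayerShapeReport()
    add = report.layers.append
    add(LayerShape("input", (c, t), 0))
    add(LayerShape("reshape", (1, t, c), 0))
    for i, k in enumerate(cfg.temporal_kernel_lengths, start=1):
        add(LayerShape(f"temporal_conv_{i}", (f_t, t, c), k * f_t))
    add(LayerShape("concat", (maps_cat, t, c), 0))
    add(LayerShape("batchnorm_temporal", (maps_cat, t, c), 2 * maps_cat))
    add(LayerShape("spatial_conv", (f_s, t, 1), c * maps_cat * f_s))
    add(LayerShape("batchnorm_spatial", (f_s, t, 1), 2 * f_s))
    add(LayerShape("square", (f_s, t, 1), 0))
    l_out = cfg.pooled_length
    add(LayerShape("average_pool", (f_s, l_out, 1), 0))
    add(LayerShape("log", (f_s, l_out, 1), 0))
    add(LayerShape("dropout", (f_s, l_out, 1), 0))
    add(LayerShape("classifier", (n_c,), f_s * l_out * n_c + n_c))
    return report


class Model:
    """Built network: ordered layers plus parameter-group tags."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        n_branches = len(cfg.temporal_kernel_lengths)
        maps_cat = n_branches * cfg.f_t
        self.temporal = L.FusedTemporalConv(cfg.temporal_kernel_lengths, cfg.f_t)
        self.bn_temporal = L.BatchNorm(maps_cat)
        self.spatial = L.SpatialConv(cfg.f_s, maps_cat, cfg.n_channels)
        self.bn_spatial = L.BatchNorm(cfg.f_s)
        self.to_maps_first = L.TransposeToMapsFirst()
        self.square = L.Square()
        self.pool = L.AvgPoolTime(cfg.pool_length, cfg.pool_stride)
        self.log = L.Log()
        self.dropout = L.Dropout(cfg.dropout_p)
        self.classifier = L.DenseClassifier(cfg.n_classes, cfg.f_s, cfg.pooled_length)
        self.log_softmax = L.LogSoftmax()
        # (name, layer, group); order is the forward order
        self.layer_specs: list[tuple[str, L.Layer, str]] = [
            ("temporal", self.temporal, "feature_extraction"),
            ("bn_temporal", self.bn_temporal, "feature_extraction"),
            ("spatial", self.spatial, "feature_extraction"),
            ("bn_spatial", self.bn_spatial, "feature_extraction"),
            ("to_maps_first", self.to_maps_first, "feature_reduction"),
            ("square", self.square, "feature_reduction"),
            ("pool", self.pool, "feature_reduction"),
            ("log", self.log, "feature_reduction"),
            ("dropout", self.dropout, "feature_reduction"),
            ("classifier", self.classifier, "classifier"),
            ("log_softmax", self.log_softmax, "classifier"),
        ]

    # -- plumbing ---------------------------------------------------------
    def parameters(self) -> Iterator[tuple[str, np.ndarray, str]]:
        """Yield (qualified name, array, group) for every trainable parameter."""
        for name, layer, group in self.layer_specs:
            for pname, arr in layer.params.items():
                yield f"{name}.{pname}", arr, group

    def layers_by_group(self, group: str) -> list[L.Layer]:
        return [layer for _, layer, g in self.layer_specs if g == group and layer.params]

    def n_parameters(self) -> int:
        return sum(arr.size for _, arr, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, arr, _ in self.parameters()}
        for bn_name, bn in (("bn_temporal", self.bn_temporal), ("bn_spatial", self.bn_spatial)):
            state[f"{bn_name}.running_mean"] = bn.running_mean.copy()
            state[f"{bn_name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, _ in self.layer_specs:
            for pname in layer.params:
                layer.params[pname] = state[f"{name}.{pname}"].copy()
        for bn_name, bn in (("bn_temporal", self.bn_temporal), ("bn_spatial", self.bn_spatial)):
            bn.running_mean = state[f"{bn_name}.running_mean"].copy()
            bn.running_var = state[f"{bn_name}.running_var"].copy()

    def copy(self) -> "Model":
        clone = Model(self.cfg)
        clone.load_state_dict(self.state_dict())
        return clone

    # -- compute ----------------------------------------------------------
    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=L.DTYPE)
        if batch.ndim != 3:
            raise ValidationError(f"batch must be [B, C, T], got ndim={batch.ndim}")
        if batch.shape[1] != self.cfg.n_channels:
            raise ValidationError(
                f"channel axis has size {batch.shape[1]}, expected {self.cfg.n_channels}"
            )
        if batch.shape[2] != self.cfg.n_times:
            raise ValidationError(
                f"time axis has size {batch.shape[2]}, expected {self.cfg.n_times}"
            )
        return batch

    def forward(
        self,
        batch: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_hidden: bool = False,
    ):
        """Run the network; returns ``[B, N_C]`` log-probabilities.

        With ``return_hidden`` also returns a dict of named intermediate
        activations (``temporal_features``, ``spatial_out``, ``pooled_log``).
        """
        batch = self._check_batch(batch)
        hidden: dict[str, np.ndarray] = {}
        x = self.temporal.forward(batch, training, rng)        # [B, C, T, 4F_T]
        x = self.bn_temporal.forward(x, training, rng)
        if return_hidden:  # copy: internal buffers are reused between calls
            hidden["temporal_features"] = x.copy()
        x = self.spatial.forward(x, training, rng)             # [B, T, F_S]
        x = self.bn_spatial.forward(x, training, rng)
        x = self.to_maps_first.forward(x, training, rng)       # [B, F_S, T]
        if return_hidden:
            hidden["spatial_out"] = x.copy()
        x = self.square.forward(x, training, rng)
        x = self.pool.forward(x, training, rng)                # [B, F_S, L]
        x = self.log.forward(x, training, rng)
        if return_hidden:
            hidden["pooled_log"] = x.copy()
        x = self.dropout.forward(x, training, rng)
        x = self.classifier.forward(x, training, rng)
        logp = self.log_softmax.forward(x, training, rng)
        if return_hidden:
            return logp, hidden
        return logp

    def backward(self, dlogp: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the log-probabilities."""
        g = dlogp
        for _, layer, _ in reversed(self.layer_specs):
            g = layer.backward(g)


def build_model(cfg: ModelConfig, seed: int = 0, scheme: str = "paper") -> Model:
    """Construct and initialize the network (see ``initialize_weights``)."""
    from .training import initialize_weights  # deferred: avoid import cycle

    model = Model(cfg)
    return initialize_weights(model, scheme=scheme, seed=seed)


def forward(
    model: Model,
    batch: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Functional wrapper around :meth:`Model.forward`."""
    return model.forward(batch, training=training, rng=rng)


def predict(
    model: Model, ds: EpochedDataset, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-mode predictions: (labels, per-class probabilities)."""
    probs = []
    for s in range(0, ds.n_trials, batch_size):
        logp = model.forward(ds.data[s:s + batch_size], training=False)
        probs.append(np.exp(logp))
    prob = np.concatenate(probs, axis=0)
    return prob.argmax(axis=1), prob


def extract_temporal_features(model: Model, trial: np.ndarray) -> np.ndarray:
    """Temporal filter-bank feature maps for one trial.

    Returns the concatenated temporal-convolution outputs after batch
    normalization, shape ``[n_branches * F_T, T, C]`` — the maps plotted in
    feature-visualization figures (time on x, channel on y).
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValidationError(f"trial must be [C, T], got ndim={trial.ndim}")
    _, hidden = model.forward(trial[None], training=False, return_hidden=True)
    maps = hidden["temporal_features"][0]  # [C, T, 4F_T]
    return np.ascontiguousarray(maps.transpose(2, 1, 0))


def save_checkpoint(model: Model, path: str | Path) -> None:
    """Self-describing checkpoint: weights + embedded architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, config_json=np.array(json.dumps(model.cfg.to_dict())), **state)


def load_checkpoint(path: str | Path) -> Model:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as archive:
        cfg = ModelConfig.from_dict(json.loads(str(archive["config_json"])))
        state = {k: archive[k] for k in archive.files if k != "config_json"}
    model = Model(cfg)
    model.load_state_dict(state)
    return model
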