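"""Epoched EEG container and its canonical on-disk interchange format.

The unit of data everywhere in this package is an epoched dataset: a
``[n_trials, n_channels, n_times]`` array of microvolt samples, one integer
class label per trial, and recording metadata (sampling rate, channel names,
subject id).  Trials are time-locked to a task cue, as in cue-based
motor-imagery paradigms.

On disk a dataset is a single ``.npz`` archive holding the data cube, the
label vector and a JSON metadata block, so a dataset round-trips atomically
and bit-exactly.  Adapters for continuous EDF/GDF recordings are a documented
extension point (epoch externally, e.g. with MNE, then construct an
:class:`EpochedDataset`); they are deliberately not part of the core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FormatError",
    "RecordingMeta",
    "EpochedDataset",
    "write_epochs",
    "read_epochs",
    "split_dataset",
    "stratified_sample",
    "concatenate_datasets",
]

LABEL_DTYPE = np.int64


class ValidationError(ValueError):
    """An EpochedDataset (or config) violates one of its invariants."""


class FormatError(ValueError):
    """An on-disk artifact does not conform to the interchange layout."""


@dataclass(frozen=True)
class RecordingMeta:
    """Recording-level metadata attached to an epoched dataset.

    Parameters
    ----------
    sampling_rate_hz:
        Sampling rate in Hz; must be positive.
    channel_names:
        Ordered, unique, non-empty electrode names; its length defines the
        number of channels C.
    unit:
        Amplitude unit of the data, conventionally microvolts (``"uV"``).
    subject_id:
        Identifier of the recorded subject.
    """

    sampling_rate_hz: float
    channel_names: tuple[str, ...]
    unit: str = "uV"
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if not self.sampling_rate_hz > 0:
            raise ValidationError(
                f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}"
            )
        names = self.channel_names
        if len(names) == 0 or any(not n for n in names):
            raise ValidationError("channel_names must be non-empty strings")
        if len(set(names)) != len(names):
            raise ValidationError("channel_names must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class EpochedDataset:
    """Epoched multichannel EEG trials with class labels.

    ``data`` has shape ``[n_trials, n_channels, n_times]`` (microvolts),
    ``labels`` shape ``[n_trials]`` with values indexing ``class_names``.
    """

    data: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...]
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=LABEL_DTYPE)
        self.class_names = tuple(self.class_names)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be [n_trials, n_channels, n_times], got ndim={self.data.ndim}"
            )
        n_trials, n_channels, _ = self.data.shape
        if n_channels != self.meta.n_channels:
            raise ValidationError(
                f"data has {n_channels} channels but meta names {self.meta.n_channels}"
            )
        if self.labels.shape != (n_trials,):
            raise ValidationError(
                f"labels shape {self.labels.shape} does not match {n_trials} trials"
            )
        if len(self.class_names) == 0:
            raise ValidationError("class_names must be non-empty")
        if n_trials and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValidationError(
                f"labels must lie in 0..{len(self.class_names) - 1}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def with_data(self, data: np.ndarray, *, meta: RecordingMeta | None = None) -> "EpochedDataset":
        """Copy of this dataset with ``data`` (and optionally ``meta``) replaced."""
        return EpochedDataset(
            data=data,
            labels=self.labels.copy(),
            class_names=self.class_names,
            meta=meta if meta is not None else self.meta,
        )

    def subset(self, indices: np.ndarray) -> "EpochedDataset":
        """Trial subset, preserving the given index order."""
        indices = np.asarray(indices, dtype=np.intp)
        return EpochedDataset(
            data=self.data[indices],
            labels=self.labels[indices],
            class_names=self.class_names,
            meta=self.meta,
        )


# ---------------------------------------------------------------------------
# interchange format
# ---------------------------------------------------------------------------

_META_KEYS = ("sampling_rate_hz", "channel_names", "unit", "subject_id", "class_names")


def write_epochs(ds: EpochedDataset, path: str | Path) -> None:
    """Write a dataset to a single self-describing ``.npz`` archive.

    The archive holds ``data``, ``labels`` and a ``meta_json`` block with keys
    ``sampling_rate_hz``, ``channel_names``, ``unit``, ``subject_id`` and
    ``class_names``.  ``read_epochs`` reproduces the dataset bit-exactly.
    """
    ds.validate()
    meta = {
        "sampling_rate_hz": ds.meta.sampling_rate_hz,
        "channel_names": list(ds.meta.channel_names),
        "unit": ds.meta.unit,
        "subject_id": ds.meta.subject_id,
        "class_names": list(ds.class_names),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        data=ds.data,
        labels=ds.labels,
        meta_json=np.array(json.dumps(meta)),
    )


def read_epochs(path: str | Path) -> EpochedDataset:
    """Read a dataset written by :func:`write_epochs` and validate it."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends .npz
    with np.load(path, allow_pickle=False) as archive:
        for key in ("data", "labels", "meta_json"):
            if key not in archive:
                raise FormatError(f"archive {path} is missing required entry '{key}'")
        data = archive["data"]
        labels = archive["labels"]
        meta_raw = str(archive["meta_json"])
    try:
        meta = json.loads(meta_raw)
    except json.JSONDecodeError as exc:  # pragma: no cover - defensive
        raise FormatError(f"metadata block of {path} is not valid JSON") from exc
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"metadata of {path} is missing keys {missing}")
    return EpochedDataset(
        data=data,
        labels=labels,
        class_names=tuple(meta["class_names"]),
        meta=RecordingMeta(
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            channel_names=tuple(meta["channel_names"]),
            unit=str(meta["unit"]),
            subject_id=str(meta["subject_id"]),
        ),
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integer allocation of ``n`` items to ``fractions`` (sum 1) with each
    count within one item of exact proportionality."""
    exact = np.asarray(fractions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # hand leftover items to the largest fractional remainders; ties broken
    # by split order (train first) for determinism
    order = np.argsort(-remainder, kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def split_dataset(
    ds: EpochedDataset,
    fractions: tuple[float, float, float],
    seed: int,
    stratified: bool = True,
) -> tuple[EpochedDataset, EpochedDataset, EpochedDataset]:
    """Partition trials into train/validation/test subsets.

    ``fractions`` must be non-negative and sum to 1.  The split is disjoint,
    exhaustive and reproducible for a given ``seed``.  With ``stratified``,
    per-class counts deviate from exact proportionality by less than one
    trial (largest-remainder allocation within each class, seeded shuffle
    breaking ties).  Trial order within each subset follows the original
    dataset order.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValidationError(f"fractions must be three non-negative reals, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got sum={sum(fractions)}")
    rng = np.random.default_rng(seed)
    n_nonzero = sum(f > 0 for f in fractions)

    parts: list[list[np.ndarray]] = [[], [], []]
    if stratified:
        for cls in range(ds.n_classes):
            idx = np.flatnonzero(ds.labels == cls)
            if idx.size == 0:
                continue
            if idx.size < n_nonzero:
                raise ValidationError(
                    f"class '{ds.class_names[cls]}' has {idx.size} trials, "
                    f"fewer than the {n_nonzero} nonzero splits"
                )
            idx = rng.permutation(idx)
            counts = _largest_remainder_counts(idx.size, fractions)
            offsets = np.cumsum(counts)
            parts[0].append(idx[: offsets[0]])
            parts[1].append(idx[offsets[0]: offsets[1]])
            parts[2].append(idx[offsets[1]: offsets[2]])
    else:
        idx = rng.permutation(ds.n_trials)
        counts = _largest_remainder_counts(ds.n_trials, fractions)
        offsets = np.cumsum(counts)
        parts[0].append(idx[: offsets[0]])
        parts[1].append(idx[offsets[0]: offsets[1]])
        parts[2].append(idx[offsets[1]: offsets[2]])

    out = []
    for chunks in parts:
        merged = np.sort(np.concatenate(chunks)) if chunks else np.empty(0, dtype=np.intp)
        out.append(ds.subset(merged))
    return out[0], out[1], out[2]


def stratified_sample(ds: EpochedDataset, n: int, seed: int) -> EpochedDataset:
    """Draw ``n`` trials with per-class counts within one of proportionality.

    Selected indices keep the original trial order; ``n == n_trials`` returns
    the full dataset unchanged (identity of trial order and content).
    """
    if not 0 < n <= ds.n_trials:
        raise ValidationError(f"n must be in 1..{ds.n_trials}, got {n}")
    classes, class_counts = np.unique(ds.labels, return_counts=True)
    if n < classes.size:
        raise ValidationError(
            f"cannot draw {n} trials stratified over {classes.size} classes"
        )
    weights = class_counts / ds.n_trials
    take = _largest_remainder_counts(n, weights)
    # cap at availability (can only matter for very unbalanced sets)
    over = take - class_counts
    while (over > 0).any():  # pragma: no cover - balanced in practice
        surplus = over.clip(min=0).sum()
        take = np.minimum(take, class_counts)
        room = class_counts - take
        order = np.argsort(-room, kind="stable")
        for i in order:
            if surplus == 0:
                break
            add = min(int(room[i]), int(surplus))
            take[i] += add
            surplus -= add
        over = take - class_counts
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for cls, k in zip(classes, take):
        idx = np.flatnonzero(ds.labels == cls)
        chosen.append(rng.permutation(idx)[:k])
    return ds.subset(np.sort(np.concatenate(chosen)))


def concatenate_datasets(
    datasets: Sequence[EpochedDataset], subject_id: str = "pooled"
) -> EpochedDataset:
    """Concatenate trial-wise; channel counts, times and class sets must agree."""
    if not datasets:
        raise ValidationError("need at least one dataset")
    first = datasets[0]
    offenders = [
        d.meta.subject_id
        for d in datasets
        if d.n_channels != first.n_channels
        or d.n_times != first.n_times
        or d.class_names != first.class_names
    ]
    if offenders:
        raise ValidationError(
            f"datasets {offenders} differ in channels, epoch length or class set"
        )
    return EpochedDataset(
        data=np.concatenate([d.data for d in datasets], axis=0),
        labels=np.concatenate([d.labels for d in datasets]),
        class_names=first.class_names,
        meta=replace(first.meta, subject_id=subject_id),
    )
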