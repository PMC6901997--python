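import numpy as np
import pytest

from mieeg.epochs import EpochedDataset, RecordingMeta
from mieeg.model import ModelConfig
from mieeg.preprocessing import PreprocConfig
from mieeg.synthetic import SynthConfig


def make_dataset(n_trials=8, n_channels=3, n_times=50, n_classes=2, seed=0,
                 rate=250.0, subject_id="S0"):
    rng = np.random.default_rng(seed)
    return EpochedDataset(
        data=rng.standard_normal((n_trials, n_channels, n_times)),
        labels=rng.integers(0, n_classes, n_trials),
        class_names=tuple(f"class{i}" for i in range(n_classes)),
        meta=RecordingMeta(
            sampling_rate_hz=rate,
            channel_names=tuple(f"ch{i}" for i in range(n_channels)),
            subject_id=subject_id,
        ),
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture
def tiny_model_config():
    """Smallest architecture that still exercises every layer."""
    return ModelConfig(
        n_channels=3, n_times=60, n_classes=2, f_t=2,
        temporal_kernel_lengths=(8, 6, 4, 2), pool_length=12, pool_stride=6,
        dropout_p=0.5,
    )


def small_synth_config(**overrides):
    """Fast simulator setting used by the training-level tests: 12 channels,
    125 Hz, 2 s epochs."""
    defaults = dict(
        n_channels=12, sampling_rate_hz=125.0, epoch_duration_s=2.0,
        n_trials_per_class=50, erd_onset_s=0.3, erd_duration_s=1.4, seed=0,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def small_preproc_config(**overrides):
    """Preprocessing matched to :func:`small_synth_config` (125 Hz, 2 s)."""
    defaults = dict(target_rate_hz=125.0, epoch_start_s=0.0, epoch_end_s=2.0)
    defaults.update(overrides)
    return PreprocConfig(**defaults)


def small_model_config(n_times, n_channels=12, n_classes=2, f_t=4):
    return ModelConfig(n_channels=n_channels, n_times=n_times,
                       n_classes=n_classes, f_t=f_t)
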