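"""Standard motor-imagery preprocessing chain.

Cue-locked trials are cropped to the analysis window, resampled to a common
rate, band-pass filtered to the sensorimotor band (4-38 Hz by default, which
retains the mu and beta rhythms and rejects drift and line noise), and
standardized causally with exponentially weighted moving statistics.  The
chain order is crop -> resample -> band-pass -> standardize; each step is also
usable on its own.

The band-pass is a 4th-order Butterworth applied forward-backward
(zero-phase), matching common EEG practice: epoch timing is preserved, at the
cost of the squared magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .epochs import EpochedDataset, RecordingMeta, ValidationError

__all__ = [
    "ConfigurationError",
    "PreprocConfig",
    "bandpass_filter",
    "resample_epochs",
    "crop_epochs",
    "exp_moving_standardize",
    "preprocess",
]

_FILTER_ORDER = 4  # Butterworth band-pass order


class ConfigurationError(ValueError):
    """A preprocessing configuration is internally inconsistent."""


@dataclass
class PreprocConfig:
    """Parameters of the preprocessing chain.

    Attributes
    ----------
    hp_cut_hz, lp_cut_hz:
        Band-pass corner frequencies in Hz (high-pass 4, low-pass 38 by
        default).
    target_rate_hz:
        Common sampling rate after resampling (250 Hz).
    epoch_start_s, epoch_end_s:
        Analysis window relative to the trial start; half-open
        ``[start, end)`` so 0-4.5 s at 250 Hz gives exactly 1125 samples.
    ema_decay, ema_eps:
        Decay of the exponentially weighted running mean/variance and the
        variance floor used in standardization.
    ema_per_trial:
        Whether running statistics restart at each trial (default) or
        continue across the trial axis as if trials were contiguous.
    """

    hp_cut_hz: float = 4.0
    lp_cut_hz: float = 38.0
    target_rate_hz: float = 250.0
    epoch_start_s: float = 0.0
    epoch_end_s: float = 4.5
    ema_decay: float = 0.999
    ema_eps: float = 1e-4
    ema_per_trial: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.hp_cut_hz < self.lp_cut_hz:
            raise ConfigurationError(
                f"need 0 < hp_cut_hz < lp_cut_hz, got {self.hp_cut_hz}, {self.lp_cut_hz}"
            )
        if not self.lp_cut_hz < self.target_rate_hz / 2:
            raise ConfigurationError(
                f"lp_cut_hz={self.lp_cut_hz} must be below the target Nyquist "
                f"{self.target_rate_hz / 2}"
            )
        if not self.epoch_end_s > self.epoch_start_s:
            raise ConfigurationError("epoch_end_s must exceed epoch_start_s")
        if not 0 < self.ema_decay < 1:
            raise ConfigurationError(f"ema_decay must be in (0,1), got {self.ema_decay}")
        if not self.ema_eps > 0:
            raise ConfigurationError("ema_eps must be positive")


def bandpass_filter(ds: EpochedDataset, cfg: PreprocConfig) -> EpochedDataset:
    """Zero-phase Butterworth band-pass along time, per channel and trial."""
    rate = ds.meta.sampling_rate_hz
    if cfg.lp_cut_hz >= rate / 2:
        raise ConfigurationError(
            f"low-pass cutoff {cfg.lp_cut_hz} Hz at or above Nyquist {rate / 2} Hz"
        )
    sos = signal.butter(
        _FILTER_ORDER, [cfg.hp_cut_hz, cfg.lp_cut_hz], btype="bandpass", fs=rate, output="sos"
    )
    out = signal.sosfiltfilt(sos, ds.data, axis=-1)
    return ds.with_data(np.ascontiguousarray(out))


def resample_epochs(ds: EpochedDataset, cfg: PreprocConfig) -> EpochedDataset:
    """Polyphase resample to ``cfg.target_rate_hz`` (downsampling only)."""
    rate = ds.meta.sampling_rate_hz
    target = cfg.target_rate_hz
    if target > rate:
        raise ConfigurationError(
            f"upsampling from {rate} to {target} Hz is not supported"
        )
    if target == rate:
        return ds.with_data(ds.data.copy())
    frac = Fraction(target / rate).limit_denominator(1000)
    out = signal.resample_poly(ds.data, frac.numerator, frac.denominator, axis=-1)
    n_out = int(ds.n_times * target / rate)  # rounded down
    out = np.ascontiguousarray(out[..., :n_out])
    meta = RecordingMeta(
        sampling_rate_hz=target,
        channel_names=ds.meta.channel_names,
        unit=ds.meta.unit,
        subject_id=ds.meta.subject_id,
    )
    return ds.with_data(out, meta=meta)


def crop_epochs(ds: EpochedDataset, cfg: PreprocConfig) -> EpochedDataset:
    """Crop each trial to the half-open window ``[epoch_start_s, epoch_end_s)``."""
    rate = ds.meta.sampling_rate_hz
    i0 = round(cfg.epoch_start_s * rate)
    i1 = round(cfg.epoch_end_s * rate)
    if i1 <= i0:
        raise ValidationError(f"degenerate window [{cfg.epoch_start_s}, {cfg.epoch_end_s})")
    if i0 < 0 or i1 > ds.n_times:
        raise ValidationError(
            f"window [{i0}, {i1}) samples exceeds trial length {ds.n_times}"
        )
    return ds.with_data(ds.data[..., i0:i1].copy())


def exp_moving_standardize(ds: EpochedDataset, cfg: PreprocConfig) -> EpochedDataset:
    """Causal standardization by exponentially weighted moving statistics.

    Per channel, with decay :math:`d`: the running mean is
    :math:`m_t = d\\,m_{t-1} + (1-d)\\,x_t` (seeded with the first sample) and
    the running variance is the analogous average of squared deviations
    (seeded with 0); the output is
    :math:`(x_t - m_t)/\\sqrt{\\max(v_t, \\epsilon)}`.  A constant channel
    therefore maps exactly to zero, and the output is invariant to amplitude
    rescaling wherever the variance is above the floor.

    Statistics restart per trial unless ``cfg.ema_per_trial`` is false, in
    which case trials are treated as a contiguous recording (in trial order).
    """
    if not np.all(np.isfinite(ds.data)):
        raise ValidationError("input contains non-finite values")
    d = cfg.ema_decay
    x = ds.data.astype(np.float64, copy=False)
    if cfg.ema_per_trial:
        series = x  # [n_trials, n_channels, T]
    else:
        series = x.transpose(1, 0, 2).reshape(1, ds.n_channels, -1)
    out = np.empty_like(series)
    m = series[..., 0].copy()
    v = np.zeros_like(m)
    for t in range(series.shape[-1]):
        xt = series[..., t]
        m = d * m + (1 - d) * xt
        dev = xt - m
        v = d * v + (1 - d) * dev * dev
        out[..., t] = dev / np.sqrt(np.maximum(v, cfg.ema_eps))
    if not cfg.ema_per_trial:
        out = out.reshape(ds.n_channels, ds.n_trials, -1).transpose(1, 0, 2)
    return ds.with_data(np.ascontiguousarray(out))


def preprocess(ds: EpochedDataset, cfg: PreprocConfig | None = None) -> EpochedDataset:
    """Full chain: crop -> resample -> band-pass -> standardize."""
    cfg = cfg or PreprocConfig()
    ds = crop_epochs(ds, cfg)
    ds = resample_epochs(ds, cfg)
    ds = bandpass_filter(ds, cfg)
    ds = exp_moving_standardize(ds, cfg)
    return ds
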