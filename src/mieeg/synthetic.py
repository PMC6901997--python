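"""Synthetic motor-imagery EEG with class-conditional ERD/ERS.

The simulator produces epoched multichannel trials whose class information
lives where it does in real sensorimotor EEG: in band-power modulation of
the mu (8-12 Hz) and beta (16-26 Hz) rhythms on lateralized channel groups.
Each trial is a superposition of

* band-limited :math:`1/f^{\\alpha}` background noise on every channel,
* a mu and a beta oscillator (amplitude-modulated sinusoids with per-trial
  frequency drawn inside the band and per-channel random phase), present on
  all channels at a base amplitude,
* an event-related (de)synchronization window during which the oscillator
  amplitude on the trial's class-specific channel group is multiplied by
  the class gain (gain < 1 = ERD, > 1 = ERS), with short raised-cosine
  ramps at the window edges.

Oscillators are explicit sinusoids rather than filtered noise so that
band-power expectations have closed forms (a unit-amplitude sinusoid has
mean square 1/2), which the test oracles rely on.  Inter-subject
variability is modelled by per-subject perturbations of amplitude,
oscillator frequency, channel-group position and noise level — the kind of
shift that makes cross-subject decoding hard in practice.  The simulator
makes no attempt at biophysical realism (no volume conduction, no
artifacts); what it shares with real motor-imagery EEG is the statistical
contrast that the decoder is supposed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .epochs import EpochedDataset, RecordingMeta, ValidationError

__all__ = [
    "ClassSpec",
    "SynthConfig",
    "SubjectShift",
    "generate_dataset",
    "generate_subject_family",
    "bandpower",
]

_RAMP_S = 0.1  # raised-cosine ramp at the ERD window edges


@dataclass(frozen=True)
class ClassSpec:
    """One imagery class: its name, modulated channel group and band gains."""

    name: str
    channels: tuple[int, ...]
    mu_gain: float = 0.4
    beta_gain: float = 0.5


def _default_class_specs(n_channels: int) -> tuple[ClassSpec, ...]:
    half = n_channels // 2
    return (
        ClassSpec("left", tuple(range(half))),
        ClassSpec("right", tuple(range(half, n_channels))),
    )


@dataclass
class SynthConfig:
    """Generative parameters of the ERD/ERS simulator.

    Amplitudes are in microvolts; defaults mimic a 22-channel cue-based
    motor-imagery paradigm at 250 Hz with a 4.5 s epoch: ~10 uV rms pink
    background, 6 uV mu and 3 uV beta oscillations, and a strong
    contralateral ERD (mu power x0.16) between 0.5 and 3.5 s post-cue.
    """

    n_channels: int = 22
    sampling_rate_hz: float = 250.0
    epoch_duration_s: float = 4.5
    n_trials_per_class: int = 100
    class_specs: tuple[ClassSpec, ...] | None = None
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (16.0, 26.0)
    base_mu_amp: float = 6.0
    base_beta_amp: float = 3.0
    noise_exponent: float = 1.0
    noise_amp: float = 10.0
    erd_onset_s: float = 0.5
    erd_duration_s: float = 3.0
    seed: int = 0
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if self.class_specs is None:
            self.class_specs = _default_class_specs(self.n_channels)
        else:
            self.class_specs = tuple(self.class_specs)
        nyquist = self.sampling_rate_hz / 2
        for band in (self.mu_band, self.beta_band):
            if not 0 < band[0] < band[1] < nyquist:
                raise ValidationError(f"band {band} must lie within (0, {nyquist}) Hz")
        for spec in self.class_specs:
            if spec.mu_gain <= 0 or spec.beta_gain <= 0:
                raise ValidationError(f"class '{spec.name}' gains must be positive")
            bad = [c for c in spec.channels if not 0 <= c < self.n_channels]
            if bad:
                raise ValidationError(
                    f"class '{spec.name}' channel indices {bad} out of range "
                    f"0..{self.n_channels - 1}"
                )

    @property
    def n_times(self) -> int:
        return round(self.epoch_duration_s * self.sampling_rate_hz)


@dataclass(frozen=True)
class SubjectShift:
    """Ranges of the per-subject perturbations drawn by
    :func:`generate_subject_family`.

    ``amplitude_scale`` and ``noise_scale`` are maximal multiplicative
    factors (each subject draws log-uniformly from ``[1/s, s]``);
    ``frequency_jitter_hz`` shifts both oscillator bands by a uniform draw
    from ``[-j, +j]``; ``channel_group_rotation`` rotates the class channel
    groups by an integer offset drawn from ``[-r, +r]`` (cyclic).
    """

    amplitude_scale: float = 1.5
    frequency_jitter_hz: float = 1.0
    channel_group_rotation: int = 2
    noise_scale: float = 1.3

    def __post_init__(self) -> None:
        if self.amplitude_scale <= 0 or self.noise_scale <= 0:
            raise ValidationError("amplitude_scale and noise_scale must be > 0")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int,
                exponent: float, amp: float) -> np.ndarray:
    """1/f^exponent noise, unit-normalized per channel then scaled to ``amp`` rms."""
    white = rng.standard_normal((n_channels, n_times))
    if amp == 0:
        return np.zeros((n_channels, n_times))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n_times, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return amp * shaped / std


def _erd_envelope(cfg: SynthConfig, gain: float) -> np.ndarray:
    """Amplitude envelope over the epoch: 1 outside the ERD window, ``gain``
    inside, raised-cosine ramps of 0.1 s at the edges."""
    t = np.arange(cfg.n_times) / cfg.sampling_rate_hz
    env = np.ones(cfg.n_times)
    t0 = cfg.erd_onset_s
    t1 = min(cfg.erd_onset_s + cfg.erd_duration_s, cfg.epoch_duration_s)
    ramp = min(_RAMP_S, (t1 - t0) / 2) if t1 > t0 else 0.0
    if ramp > 0:
        inside = (t >= t0) & (t < t1)
        env[inside] = gain
        rise = (t >= t0) & (t < t0 + ramp)
        env[rise] = 1 + (gain - 1) * 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / ramp))
        fall = (t >= t1 - ramp) & (t < t1)
        env[fall] = gain + (1 - gain) * 0.5 * (1 - np.cos(np.pi * (t[fall] - (t1 - ramp)) / ramp))
    return env


def generate_dataset(cfg: SynthConfig) -> EpochedDataset:
    """Simulate one subject's epoched dataset (balanced classes, seeded)."""
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.class_specs)
    n_trials = n_classes * cfg.n_trials_per_class
    t = np.arange(cfg.n_times) / cfg.sampling_rate_hz
    labels = np.repeat(np.arange(n_classes), cfg.n_trials_per_class)
    labels = labels[rng.permutation(n_trials)]
    data = np.empty((n_trials, cfg.n_channels, cfg.n_times))
    for i, label in enumerate(labels):
        spec = cfg.class_specs[label]
        trial = _pink_noise(rng, cfg.n_channels, cfg.n_times,
                            cfg.noise_exponent, cfg.noise_amp)
        for band, base_amp, gain in (
            (cfg.mu_band, cfg.base_mu_amp, spec.mu_gain),
            (cfg.beta_band, cfg.base_beta_amp, spec.beta_gain),
        ):
            freq = rng.uniform(*band)
            phases = rng.uniform(0, 2 * np.pi, size=cfg.n_channels)
            osc = np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
            amp = np.full((cfg.n_channels, 1), float(base_amp))
            envelope = np.ones((cfg.n_channels, cfg.n_times))
            mod = _erd_envelope(cfg, gain)
            for ch in spec.channels:
                envelope[ch] = mod
            trial += amp * envelope * osc
        data[i] = trial
    meta = RecordingMeta(
        sampling_rate_hz=cfg.sampling_rate_hz,
        channel_names=tuple(f"ch{i:02d}" for i in range(cfg.n_channels)),
        unit="uV",
        subject_id=cfg.subject_id,
    )
    return EpochedDataset(
        data=data,
        labels=labels,
        class_names=tuple(s.name for s in cfg.class_specs),
        meta=meta,
    )


def generate_subject_family(
    cfg: SynthConfig, n_subjects: int, shift: SubjectShift, seed: int
) -> list[EpochedDataset]:
    """Simulate a family of subjects sharing class semantics.

    Each subject draws its own amplitude factor, band shift, channel-group
    rotation and noise factor from the ``shift`` ranges (seeded), plus its
    own trial-level randomness; class names and their meaning are preserved
    across subjects.
    """
    if n_subjects < 2:
        raise ValidationError("a subject family needs n_subjects >= 2")
    rng = np.random.default_rng(seed)
    family = []
    for i in range(n_subjects):
        amp = float(np.exp(rng.uniform(-np.log(shift.amplitude_scale),
                                       np.log(shift.amplitude_scale)))) \
            if shift.amplitude_scale != 1 else 1.0
        noise = float(np.exp(rng.uniform(-np.log(shift.noise_scale),
                                         np.log(shift.noise_scale)))) \
            if shift.noise_scale != 1 else 1.0
        jitter = float(rng.uniform(-shift.frequency_jitter_hz, shift.frequency_jitter_hz))
        rot = int(rng.integers(-shift.channel_group_rotation,
                               shift.channel_group_rotation + 1)) \
            if shift.channel_group_rotation else 0
        specs = tuple(
            ClassSpec(
                name=s.name,
                channels=tuple((c + rot) % cfg.n_channels for c in s.channels),
                mu_gain=s.mu_gain,
                beta_gain=s.beta_gain,
            )
            for s in cfg.class_specs
        )
        sub_cfg = replace(
            cfg,
            class_specs=specs,
            base_mu_amp=cfg.base_mu_amp * amp,
            base_beta_amp=cfg.base_beta_amp * amp,
            noise_amp=cfg.noise_amp * noise,
            mu_band=(cfg.mu_band[0] + jitter, cfg.mu_band[1] + jitter),
            beta_band=(cfg.beta_band[0] + jitter, cfg.beta_band[1] + jitter),
            seed=int(rng.integers(2 ** 31)),
            subject_id=f"S{i + 1:02d}",
        )
        family.append(generate_dataset(sub_cfg))
    return family


def bandpower(
    ds: EpochedDataset, band: tuple[float, float], window: tuple[float, float]
) -> pd.DataFrame:
    """Mean squared band-passed amplitude per trial and channel.

    ``band`` in Hz (must lie below Nyquist), ``window`` in seconds relative
    to the trial start (half-open).  The band filter is an ideal (zero-phase
    Fourier-domain) band selector, so closed-form expectations hold exactly:
    a unit sinusoid inside the band yields 0.5.  Returns a DataFrame with
    one row per trial and one column per channel name.
    """
    rate = ds.meta.sampling_rate_hz
    if not 0 < band[0] < band[1] < rate / 2:
        raise ValidationError(f"band {band} must lie within (0, {rate / 2}) Hz")
    i0, i1 = round(window[0] * rate), round(window[1] * rate)
    if i1 <= i0:
        raise ValidationError(f"empty window {window}")
    if i0 < 0 or i1 > ds.n_times:
        raise ValidationError(f"window {window} exceeds the epoch")
    spec = np.fft.rfft(ds.data, axis=-1)
    freqs = np.fft.rfftfreq(ds.n_times, 1.0 / rate)
    spec[..., (freqs < band[0]) | (freqs > band[1])] = 0.0
    filtered = np.fft.irfft(spec, n=ds.n_times, axis=-1)
    power = (filtered[..., i0:i1] ** 2).mean(axis=-1)
    return pd.DataFrame(power, columns=list(ds.meta.channel_names))
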