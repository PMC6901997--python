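"""Pre-registered simulator experiments.

Two end-to-end studies, fully determined by a single integer seed, sized
to run on one CPU core.  They are what ``scripts/acceptance.py`` and the
heavier integration tests execute; the parameter choices (simulator
conditions, network size, epoch budgets) are discussed in
``docs/methods.md``.

* :func:`run_intra_subject_experiment` — train/validate/test decoding on
  one simulated subject at the simulator's default scale (22 channels,
  250 Hz, 4.5 s; 400/100/100 trials).
* :func:`run_transfer_experiment` — leave-one-subject-out transfer on a
  4-subject family: pretrain a coarse model on three pooled sources,
  measure zero-shot accuracy on the held-out target, then fine-tune with
  layered learning rates across calibration-set sizes 10/20/50/100.
"""

from __future__ import annotations

from .epochs import split_dataset
from .model import ModelConfig, build_model
from .preprocessing import PreprocConfig, preprocess
from .synthetic import SubjectShift, SynthConfig, generate_dataset, generate_subject_family
from .training import (
    LayeredLRPolicy,
    TrainConfig,
    evaluate,
    pretrain_pooled,
    small_sample_protocol,
    train,
)

__all__ = [
    "intra_subject_conditions",
    "transfer_conditions",
    "run_intra_subject_experiment",
    "run_transfer_experiment",
]


def intra_subject_conditions(seed: int) -> tuple[SynthConfig, PreprocConfig, TrainConfig]:
    """Study conditions of the intra-subject experiment.

    Default simulator scale; 600 trials so the standard 400/100/100 split
    is exact; 40 training epochs (validation accuracy typically crosses
    0.9 between epochs 20 and 40 and plateaus).
    """
    synth = SynthConfig(n_trials_per_class=300, seed=seed)
    preproc = PreprocConfig()
    train_cfg = TrainConfig(max_epochs=40, seed=seed)
    return synth, preproc, train_cfg


def run_intra_subject_experiment(seed: int) -> dict:
    """Simulate, preprocess, split 400/100/100, train, evaluate.

    Returns test accuracy, the confusion matrix and the training history.
    """
    synth, preproc, train_cfg = intra_subject_conditions(seed)
    ds = preprocess(generate_dataset(synth), preproc)
    tr, va, te = split_dataset(ds, (400 / 600, 100 / 600, 100 / 600),
                               seed=seed, stratified=True)
    mcfg = ModelConfig(n_channels=ds.n_channels, n_times=ds.n_times,
                       n_classes=ds.n_classes, f_t=4)
    model = build_model(mcfg, seed=seed, scheme="scaled")
    model, history = train(model, tr, va, train_cfg)
    acc, cm = evaluate(model, te)
    return {
        "test_accuracy": acc,
        "confusion_matrix": cm,
        "history": history,
        "model": model,
        "splits": (tr, va, te),
    }


def transfer_conditions(seed: int):
    """Study conditions of the transfer experiment.

    A compact 12-channel / 125 Hz / 2 s family with a strong rhythm
    (9 uV mu vs 9 uV pink noise) so every subject is individually
    decodable, and an inter-subject shift dominated by frequency jitter
    (+-2 Hz) plus channel-group rotation (+-2) and mild amplitude/noise
    factors — a domain shift that moves the subjects apart without
    changing task difficulty.
    """
    synth = SynthConfig(
        n_channels=12, sampling_rate_hz=125.0, epoch_duration_s=2.0,
        n_trials_per_class=120, base_mu_amp=9.0, noise_amp=9.0,
        erd_onset_s=0.3, erd_duration_s=1.4, seed=seed,
    )
    shift = SubjectShift(amplitude_scale=1.15, frequency_jitter_hz=2.0,
                         channel_group_rotation=2, noise_scale=1.1)
    preproc = PreprocConfig(target_rate_hz=125.0, epoch_start_s=0.0, epoch_end_s=2.0)
    # the coarse model deliberately gets a short budget: it is the rough,
    # general starting point that fine-tuning continues from
    pretrain_cfg = TrainConfig(max_epochs=30, seed=seed)
    finetune_cfg = TrainConfig(max_epochs=60, batch_size=32, seed=seed)
    return synth, shift, preproc, pretrain_cfg, finetune_cfg


def run_transfer_experiment(
    seed: int,
    sample_sizes: tuple[int, ...] = (10, 20, 50, 100),
    n_seeds: int = 5,
) -> dict:
    """Pretrain on 3 source subjects, transfer to the 4th.

    Returns the zero-shot coarse accuracy on the target test set, the
    calibration-size sweep table (mean over ``n_seeds`` stratified draws
    per size) and the mean fine-tuned accuracy at 100 calibration trials.
    """
    synth, shift, preproc, pretrain_cfg, finetune_cfg = transfer_conditions(seed)
    family = [preprocess(d, preproc)
              for d in generate_subject_family(synth, 4, shift, seed=seed)]
    target, sources = family[-1], family[:-1]
    mcfg = ModelConfig(n_channels=target.n_channels, n_times=target.n_times,
                       n_classes=target.n_classes, f_t=8)
    coarse = build_model(mcfg, seed=seed, scheme="scaled")
    coarse, pretrain_history = pretrain_pooled(sources, coarse, pretrain_cfg)
    tr, _, te = split_dataset(target, (0.7, 0.0, 0.3), seed=seed, stratified=True)
    zero_shot, _ = evaluate(coarse, te)
    seeds = [seed + 1000 * (i + 1) for i in range(n_seeds)]
    table = small_sample_protocol(
        coarse, tr, te, LayeredLRPolicy(), finetune_cfg,
        sample_sizes=sample_sizes, seeds=seeds, mix_sources=sources,
    )
    fine_tuned_100 = float(
        table.loc[table.n_samples == max(sample_sizes), "mean_accuracy"].iloc[0]
    )
    return {
        "zero_shot_accuracy": zero_shot,
        "small_sample_table": table,
        "fine_tuned_accuracy": fine_tuned_100,
        "coarse_model": coarse,
        "target_splits": (tr, te),
        "sources": sources,
        "pretrain_history": pretrain_history,
    }
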