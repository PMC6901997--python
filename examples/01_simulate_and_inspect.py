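"""Simulate motor-imagery EEG and verify its class-dependent band power.

Generates one synthetic subject (two classes, ERD of the mu rhythm on
lateralized channel groups) and prints the mu-band power during the ERD
window for each class on each channel group.  The class with the imagined
movement shows suppressed (desynchronized) mu power on its own group.
"""

import numpy as np

from mieeg import SynthConfig, bandpower, generate_dataset

cfg = SynthConfig(n_channels=12, sampling_rate_hz=125.0, epoch_duration_s=2.0,
                  n_trials_per_class=50, erd_onset_s=0.3, erd_duration_s=1.4, seed=0)
ds = generate_dataset(cfg)
print(f"dataset: {ds.n_trials} trials x {ds.n_channels} channels x {ds.n_times} samples, "
      f"classes {ds.class_names}")

power = bandpower(ds, band=(8.0, 12.0), window=(0.3, 1.7))  # mu band, ERD window
first_half = power.iloc[:, :6].mean(axis=1)
second_half = power.iloc[:, 6:].mean(axis=1)
for cls, name in enumerate(ds.class_names):
    sel = ds.labels == cls
    print(f"class '{name}': mu power ch0-5 = {first_half[sel].mean():7.2f} uV^2, "
          f"ch6-11 = {second_half[sel].mean():7.2f} uV^2")
print("-> the modulated group of each class carries roughly half the mu-band "
      "power (amplitude gain 0.4 on the rhythm, diluted by the background "
      "noise inside the band) - the contrast a decoder must find.")
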