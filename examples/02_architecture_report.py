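"""Print the analytic layer-by-layer report of the network.

For the canonical configuration (22 channels, 1125 time points, 4 classes,
40 temporal filters per branch, D = 1) the report lists every layer's
output shape and parameter count: the four multiscale temporal branches
(kernels 64/40/26/16 -> 2560/1600/1040/640 weights), the spatial
convolution over all electrodes (140800 weights), the parameter-free
square -> average-pool -> log band-power reduction, and the convolutional
classifier over the 71 pooled time steps.
"""

from mieeg import ModelConfig, build_model, compute_layer_shapes

cfg = ModelConfig(n_channels=22, n_times=1125, n_classes=4, f_t=40, d=1.0)
report = compute_layer_shapes(cfg)
print(report.to_frame().to_string(index=False))
print(f"\ntotal parameters: {report.total_parameters}")

model = build_model(cfg, seed=0)
assert model.n_parameters() == report.total_parameters
print("built network parameter count matches the analytic report.")
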