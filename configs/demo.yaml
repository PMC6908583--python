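# Shipped demo pipeline: small, CPU-friendly end-to-end run on the two
# default synthetic texture classes.  Re-running this config reproduces
# byte-identical model fingerprints and reports.
schema_version: 1
seed: 42
out_dir: edgegan_demo
tile_size: 32
edge: sigma_2
metric: mse
n_train_tiles: 30
n_test_tiles: 10
generator:
  depth: 2
  base_filters: 8
discriminator:
  conv_stages: 2
  base_filters: 8
training:
  epochs: 2
  batch_size: 4
  learning_rate: 0.001
hpf:
  count: 4
  size: [96, 96]
  n_windows: 20
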