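# Full model at the clinical working resolution (224x224).
# Channel widths and module knobs are the budget-calibrated defaults;
# see scripts/calibrate_budget.py and docs/methods.md.
model:
  in_channels: 1
  num_classes: 2
  base_channels: [22, 66, 138, 218, 282]
  dilation_rates: [1, 6, 12, 18]
  masg_channels: 340
  attention_reduction: 6
  sava_reduction: 4
  cag_kernel: 9
  cag_expansion: 15
  cag_grid: 13
  lambda_aux: 0.4
  bda: true
  cag: true
  masg: true
  input_size: [224, 224]
  seed: 0

train:
  epochs: 100
  batch_size: 8
  lr0: 0.01
  momentum: 0.9
  weight_decay: 5.0e-5
  resize: [224, 224]
  split_ratios: [0.8, 0.1, 0.1]
  seed: 0
  loss_config: ce+dice+aux
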