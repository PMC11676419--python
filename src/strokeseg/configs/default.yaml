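# Default run configuration.
#
# The training recipe follows the reference hyper-parameters (3x3 kernels,
# batch 8, ReLU activations, dropout 0.2, learning rate 1e-4, Adam, 100
# epochs, BCE-Dice loss).  The model widths are the calibrated schedule found
# by scripts/calibrate_widths.py: with them the flagship variant counts
# 13,662,913 parameters (13,649,473 trainable + 13,440 batch-norm running
# statistics).

loss: bce_dice
batch_size: 8
learning_rate: 1.0e-4
optimizer: adam
epochs: 100
seed: 0
train_fraction: 0.8
split_by_subject: true

target_size: 192
fg_threshold: 0.02
augmentation_factor: 3

model:
  variant: transformer_dil_denseunet
  stem_width: 82
  dilated_channels: 110
  dilation_rates: [2, 4, 8]
  dense_layers: 4
  growth: 17
  compression: 0.5
  heads: 4
  embed_dim: 260
  ffn_dim: 4057
  patch_schedule: [1, 2, 4]
  dropout: 0.2
  norm_placement: post
  input_channels: 1
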