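# Demo training configuration: small model on generated phantoms.
# For DRIVE/CHASEDB1-style directories replace `data.phantoms` with
#   data: {dir: /path/to/dataset, layout: drive}
# and raise model.img_size/embed_dim/depths to the full-scale defaults
# (448, 96, [2, 2, 2]).

initial_lr: 0.05
max_epoch: 10
batch_size: 2
seed: 0
val_fraction: 0.25
haus_warmup_epochs: 4
out_dir: runs/demo

model:
  img_size: 112
  embed_dim: 12
  depths: [1, 1, 1]
  heads: [2, 2, 2]
  window: 7
  alpha: 1.0
  beta: 1.0
  enable_ctcm: true
  enable_pthm: true

loss:
  omega1: 10.0
  omega2: 10.0
  omega3: 1.0

data:
  phantoms:
    n: 6
    depth: 6
    seed: 0
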