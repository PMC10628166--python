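# Desk-scale study configuration: one global seed reproduces every stage.
seed: 1

cohort:
  # ~60 cells per status group; T1 is split into survivors and non-survivors
  cells_per_group: 60
  base_phantom:
    cell_radius_um: [2.0, 2.0, 2.0]
    grid_shape: [40, 40, 40]
    voxel_spacing_um: [0.2, 0.2, 0.2]
    cytoplasm_ri: 1.356
    nucleus_ri: 1.385
    medium_ri: 1.337
    noise_sd: 0.002

qc: {}

morphometry: {}

shells:
  n_shells: 8
  restrict_to_cell: false

stats:
  correlation_mode: timepoint_means

classifier:
  task: diagnosis
  preprocess:
    resize_target: [16, 16, 16]
  model:
    n_blocks: 4
    total_layers: 8
    growth: 4
  train:
    lr0: 0.05
    max_epochs: 12
    patience: 8
  eval:
    cells: [1, 2, 3, 4, 5]
    iterations: 1000
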