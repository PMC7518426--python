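# Desk-scale configuration: identical architecture and optimizer schedule to
# the reference, with sizes reduced so the whole cascade trains on one CPU in
# minutes. These are the settings the test suite exercises.
seed: 0
network:
  base_width: 8
train:
  steps: 2000
  batch_size: 1
  patch_size: 32
  steps_bone: 700
  refine_steps: 400
  steps_vessel: 500
  steps_repair: 600
patch:
  patch_size: 64
  stride: 48
cascade:
  min_component_size: 8
  target_spacing: null   # phantoms are generated at the target grid already
phantom:
  shape: [64, 64, 64]
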