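# Full-scale reference configuration: the optimizer schedule, augmentation
# bounds, architecture, and patching used at clinical scale. Desk-scale runs
# (tests, demos) override the sizes; see configs/desk.yaml.
seed: 0
network:
  base_width: 32
  levels: 4            # four convolutional downsampling + four upsampling units
  n_blocks: 8          # eight bottleneck-residual blocks
  negative_slope: 0.1  # LeakyReLU slope
train:
  momentum: 0.9
  weight_decay: 0.0001
  learning_rate: 0.01
  lr_decay: 0.99995    # multiplicative, applied after every step
  steps: 200000
  batch_size: 1
  patch_size: 256
  centerline_weight_factor: 2.0
  steps_bone: 200000
  refine_steps: 100000
  steps_vessel: 200000
  steps_repair: 100000
augment:
  allow_flip: true
  max_rotation_deg: 25.0
  max_shift: 20
  occlusion_size_range: [4, 12]
  occlusion_prob: 0.5
  noise_sigma: 10.0
  expansion_factor: 5   # a dataset of size N expands to 5N
patch:
  patch_size: 256       # cubic inference patches
  stride: 192
  reduce: mean
cascade:
  region_fractions: [0.3333333333333333, 0.6666666666666666]
  threshold: 0.5
  intensity_scale: 300.0
  background_fill: 40.0
  corridor_radius: 5
  min_component_size: 27
  target_spacing: 0.5   # mm, isotropic
phantom:
  shape: [256, 256, 256]
  region_z_fractions: [0.3333333333333333, 0.6666666666666666]
  aorta_radius_range: [16.0, 22.0]
  carotid_radius_range: [8.0, 11.0]
  intracranial_radius_range: [4.0, 6.5]
  intracranial_depth: 3
  background_intensity: 40.0
  vessel_intensity: 250.0
  bone_intensity: 300.0
  noise_sigma: 15.0
  skull_thickness: 10.0
  bone_vessel_clearance: 8.0
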