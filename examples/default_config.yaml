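augment:
  noise_sigma_hu:
  - 0.0
  - 10.0
  smooth_sigma_mm:
  - 0.0
  - 0.8
dataset:
  patch_ratio:
  - 1
  - 1
  patch_size: 96
  target_spacing_mm: 0.8
phantom:
  branch_angle_deg: 32.0
  branch_length_mm: 22.0
  hu_lumen: -1000.0
  hu_parenchyma: -850.0
  hu_vessel: 40.0
  hu_wall: -200.0
  length_taper: 0.85
  noise_sigma_hu: 15.0
  radius_taper: 0.8
  root_radius_mm: 4.0
  seed: null
  spacing_mm:
  - 1.0
  - 1.0
  - 1.0
  tree_depth: 5
  vessel_offset_mm: 10.0
  vessel_radius_ratio: 0.7
  volume_shape:
  - 112
  - 112
  - 112
  wall_thickness_mm: 1.0
plugs:
  allow_truncation: true
  eligible_diameter_mm:
  - 1.0
  - 20.0
  length_range_mm:
  - 2.0
  - 20.0
  max_phenotype_resamples: 50
  max_seed_attempts: 200
  mural_adherent: true
  occlusion_range:
  - 0.35
  - 1.0
plugs_per_scan: 50
seed: 0
transfer:
  caliber_rel_tolerance: 0.5
  depth_tolerance_mm: 0.5
  min_companion_voxels: 10
  search_radius_mm: 20.0
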