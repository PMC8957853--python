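# Default study conditions: 10 subjects (5 female / 5 male), paired
# bilateral MGB subdivisions + LGB, coronal sectioning on a 0.3 mm lattice.
cohort:
  n_subjects: 10
  volume_cv: 0.25            # ~two-fold inter-subject volume variability
  position_jitter_sd: 0.3    # mm, per-structure biological position spread
  transform_jitter:
    rotation_sd_deg: 2.0
    scale_sd: 0.02
    translation_sd_mm: 1.0
  voxel_size: 0.5            # mm, subject label grids
  seed: 0

# The microtome design is 20 um sections, every 15th delineated
# (d = 0.3 mm). The synthetic elementary section is 0.1 mm (one stands for
# five 20 um sections); sampling every 3rd preserves the 0.3 mm lattice.
sectioning:
  thickness_mm: 0.1
  interval: 3
  offset: random             # seeded uniform draw in [0, interval) per subject
  fine_voxel_size: [0.25, 0.1, 0.25]   # delineation raster, mm

volumetry:
  normalization: proportion  # or 'rescaled' (x cohort-mean brain volume)

stats:
  n_iter: 10000
  seed: 7
  sidedness: two
  sex_unit: hemisphere       # or 'subject_sum'

probmap:
  voxel_size: 1.0            # mm, reference grid
  origin: [-40.0, -44.0, -24.0]
  shape: [80, 38, 32]
  threshold: 50
  reconstruction: shape_based

mesh:
  voxel_size: 0.25
  smooth_iters: 10
  smooth_step: 0.1

output_dir: scratch/pipeline_out
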