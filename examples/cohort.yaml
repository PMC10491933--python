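# Two-group synthetic cohort: control-like walls vs higher, more variable
# wall RI with localized breaks. All lengths in μm.
optical:
  wavelength: 0.72          # illumination wavelength
  slice_thickness_dz: 3.2   # optical-section thickness
  pixel_size: 0.5
  medium_ri_nm: 1.3440
  numerical_aperture: 0.6
  tikhonov_alpha: 0.001     # convention, not a measured system value
  z_step: 1.0

groups:
  - label: AS
    n_animals: 3
    n_vessels: 2
    base:
      volume_shape: [33, 128, 128]
      lumen_radius: 11.0
      wall_thickness: 4.0
      cell_radius: 3.0
      cell_delta_n: 0.015
      target_fill_fraction: 30.0
      fiber_density: 5.0
      fiber_length: 40.0      # long, continuous fibers
      noise_photon_budget: 100000
    param_means: {wall_delta_n: 0.020}
    param_sds: {wall_delta_n: 0.002}
  - label: SS
    n_animals: 3
    n_vessels: 2
    base:
      volume_shape: [33, 128, 128]
      lumen_radius: 11.0
      wall_thickness: 4.0
      cell_radius: 3.0
      cell_delta_n: 0.015
      target_fill_fraction: 30.0
      fiber_density: 10.0
      fiber_length: 10.0      # short, fragmented fibers
      break_arc: [-0.5, 0.5]
      break_length: 30.0
      noise_photon_budget: 100000
    param_means: {wall_delta_n: 0.030}
    param_sds: {wall_delta_n: 0.003}

seed: 0
outdir: scratch/cohort_run
unit: animal        # per-animal means are the independent observations
alpha_level: 0.05
diameter_threshold: 20.0   # strict >
profile_window: 20.0
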