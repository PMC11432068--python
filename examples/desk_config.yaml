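# Desk-scale PD-OCT pipeline configuration.
# Spectral geometry matches the clinical instrument (1060 nm / 100 nm FWHM /
# 400 kHz); volume dimensions are reduced so the full pipeline runs in
# seconds.  Depth pixel is ~2.8 um; layers must fit the unambiguous range
# implied by samples_per_ascan (~720 um at 512 samples).
seed: 7
output_dir: pdoct-out

source:
  center_wavelength_nm: 1060.0
  fwhm_bandwidth_nm: 100.0
  ascan_rate_hz: 400000.0
  samples_per_ascan: 512
  sweep_nonlinearity: [1.0, 0.05]
  dispersion_a2: 20.0
  dispersion_a3: 0.0

protocol:
  samples_per_ascan: 512
  alines_per_bscan: 96
  bscans_per_volume: 16
  fov_degrees: 55.0

phantom:
  axial_extent_um: 560.0
  layers:
    - {name: inner_retina, top_depth_um: 60.0, bottom_depth_um: 250.0, scatterer_density: 20.0, reflectivity: 0.3, depolarization_p: 0.0}
    - {name: rpe, top_depth_um: 250.0, bottom_depth_um: 285.0, scatterer_density: 10.0, reflectivity: 1.0, depolarization_p: 0.85}
    - {name: choroid, top_depth_um: 285.0, bottom_depth_um: 500.0, scatterer_density: 25.0, reflectivity: 0.5, depolarization_p: 0.3}

noise:
  noise_sigma_h: 0.3
  noise_sigma_v: 0.3

recon:
  dispersion: matched   # 'auto' estimates (a2, a3) by sharpness optimization
  dc: bscan-mean

polarimetry:
  kernel: [3, 5]          # lateral x axial
  dopu_threshold: 0.8
  median_kernel: [3, 5, 3]  # lateral x axial x frames
  noise_region_fraction: 0.1
  noise_correct: true

contrast:
  enface:
    - {source: dopu, layer: rpe, mode: min}
    - {source: dopu, layer: choroid, mode: min}
    - {source: intensity, layer: inner_retina, mode: mean}
  composite_bscan: middle
  composite_alpha: 0.6
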