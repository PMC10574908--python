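# Gd2O2S:Tb / CMOS dual-scintillator detector profiles.
# sigma_lsf is the Gaussian LSF width in pixels from slit MTF measurement;
# alpha/beta are the Poisson gain and Gaussian sd of the mean-variance
# noise-level function fitted on flat frames.
detector1:
  scintillator_thickness_um: 84
  pixel_size_um: 48
  matrix: [512, 1024]
  adc_bits: 12
  sigma_lsf: 1.79
  alpha: 0.37
  beta: 9.12
detector2:
  scintillator_thickness_um: 96
  pixel_size_um: 48
  matrix: [512, 1024]
  adc_bits: 12
  sigma_lsf: 2.61
  alpha: 0.29
  beta: 7.10
detector3:
  scintillator_thickness_um: 140
  pixel_size_um: 48
  matrix: [512, 1024]
  adc_bits: 12
  sigma_lsf: 5.13
  alpha: 0.08
  beta: 3.31
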