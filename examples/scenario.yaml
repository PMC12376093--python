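# A weak-signal single-band scenario: carboxyl stretch at 1623 cm^-1,
# true mu^2 = 0.200 D^2, curved solvent background, realistic noise.
bands:
  - {center: 1623, fwhm: 24, mu2: 0.200, shape: pseudo_voigt, amplitude_scale: 0.05}
calibrant: {center: 1623, fwhm: 12, mu2: 0.200, shape: gaussian}
baseline_coeffs: [0.025, 0.04, -0.015]
noise_sd_od: 3.7e-4
noise_sd_2d: 2.0e-5
pump: {kind: gaussian, center: 1610, fwhm: 120}
axis: [1500, 1750, 1.0]
seed: 0
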