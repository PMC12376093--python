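# Aggregation kinetics: bulk beta-sheet mode plus one isotope-labeled
# residue whose dipole strength ramps 0.13 -> 0.26 D^2 sigmoidally.
bands:
  - {center: 1623, fwhm: 16, mu2: 0.26, shape: gaussian, amplitude_scale: 0.1}
  - {center: 1582, fwhm: 12, mu2: 0.13, shape: gaussian, amplitude_scale: 0.1}
calibrant: {center: 1623, fwhm: 12, mu2: 0.200, shape: gaussian}
baseline_coeffs: [0.01, 0.02, -0.005]
noise_sd_od: 2.0e-4
noise_sd_2d: 1.0e-5
pump: {kind: gaussian, center: 1610, fwhm: 120}
seed: 0
kinetics:
  n_frames: 60
  cadence_s: 66.0
  mu2_trajectories:
    - {kind: sigmoid, start: 0.26, end: 0.31, t_mid: 1980, tau: 400}
    - {kind: sigmoid, start: 0.13, end: 0.26, t_mid: 1980, tau: 400}
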