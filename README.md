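# tdskit

Automated transition-dipole-strength (TDS) analysis for two-dimensional
infrared (2D IR) and FTIR spectroscopy of proteins.

## The problem

The transition dipole strength of a vibrational mode — |μ|², in debye²
(D²) — reports on vibrational coupling and therefore on protein secondary
structure in ways that frequency alone cannot: a localized amide I′ mode
sits near 0.12 D², α-helices at 0.26–0.55 D², and β-sheets anywhere from
0.25 to 1.25 D² depending on their size and order. 2D IR gives access to
these values through the ratio of nonlinear to linear signals,

```
d(ω) = [ΔOD_sample(ω,ω) / OD_sample(ω)]
       / [ΔOD_cal(ω_max,ω_max) / OD_cal(ω_max)]
       · |μ|²_cal · I_pump(ω_max) / I_pump(ω)
```

where ΔOD(ω,ω) is the diagonal slice of the 2D IR surface (∝ μ⁴), OD is
the linear optical density from the probe transmission (∝ μ²), the
calibrant is a small molecule of independently known dipole strength, and
the last factor corrects for the non-flat pump envelope. For FTIR-accessible
(uncoupled) modes the dipole strength follows directly from the extinction
spectrum:

```
D = 9.184 × 10⁻³ ∫ ε(ν)/ν dν        [D², ε in M⁻¹cm⁻¹, ν in cm⁻¹]
```

The practical obstacle is the division by OD: any error in the linear-OD
baseline — and any zero-crossing of the corrected OD — poisons d(ω).
tdskit automates that correction with airPLS (adaptive iteratively
reweighted penalized least squares): a Whittaker smoother alternated with
residual-driven reweighting that pulls the fitted baseline under the peaks
without manual region exclusion, plus optional Savitzky–Golay noise
filtering for weak signals. This makes TDS analysis workable down to
single isotope-labeled residues (¹³C¹⁸O labels red-shift one backbone
carbonyl by ~55 cm⁻¹, isolating it from the bulk band) and through entire
amyloid-aggregation time courses.

It is written for 2D IR practitioners: the library mirrors the analysis
steps (baseline → ratio → calibrant scaling → pump normalization →
readout), and a `tds` command-line tool wraps them for shell use. A
synthetic forward model with embedded ground-truth μ² values makes every
pipeline stage testable without instrument data.

## Worked example

A synthetic weak-signal measurement (the 10 mM rung of the l-serine
validation ladder: one carboxyl band, true μ² = 0.200 D², apex OD 0.01 on
a curved background five times larger, realistic noise):

```python
import tdskit as tk

ds = tk.generate(tk.serine_ladder_config(10, seed=0))
corrected, info = tk.correct_baseline(ds.od, "airpls", lam=3e5)
cal = tk.calibrant_reference_from_spectra(
    ds.calibrant_delta_od, ds.calibrant_od, mu2=0.200, omega_max="auto")
tds = tk.compute_tds(ds.delta_od_diag, corrected, cal)
d = tk.tds_at(tds, 1623.0)
rep = tk.snr(corrected, (1600.0, 1650.0), (1500.0, 1560.0))
print(f"airPLS: {info.iterations} iterations, converged={info.converged}")
print(f"corrected-OD SNR (RMS): {rep.snr:.1f}")
print(f"TDS at {d.frequency:.0f} cm^-1: {d.value:.3f} D^2  "
      f"({tk.percent_error(d.value, 0.200):.1f}% from the 0.200 D^2 reference)")
```

prints

```
airPLS: 4 iterations, converged=True
corrected-OD SNR (RMS): 31.6
TDS at 1623 cm^-1: 0.201 D^2  (0.7% from the 0.200 D^2 reference)
```

The readout lands within 1% of the embedded truth for this draw; across
many noise realizations the mean absolute error at this signal level is a
few percent (single draws can be off by ~10% — the readout at the band
maximum carries the full point noise of the OD there; see
`docs/methods.md`). The same pipeline runs from the shell:

```
tds synth --config examples/scenario.yaml --out data/
tds 2dir --diag data/diag.tsv --od data/od.tsv \
    --calibrant-od data/calibrant_od.tsv --calibrant-diag data/calibrant_delta.tsv \
    --mu2 0.200 --baseline airpls --lam 3e5 --out tds.tsv
```

Kinetics experiments use `tds kinetics --dir frames/ --frequency 1582
--window 15 ...`, which averages 15-frame blocks (~16.5 min at the 66 s
cadence), places each point at its window midpoint, and reads a TDS or
intensity trace at the requested wavenumber.

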