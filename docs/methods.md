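# Methods

This note records the models, conventions and numerical choices behind
tdskit, and what the synthetic validation does and does not demonstrate.

## Signal model and the calibrated TDS ratio

The package treats three measured objects on a common wavenumber axis
(cm⁻¹, strictly increasing everywhere in the code):

* the linear optical density OD(ω), obtained from the probe transmission
  (`transmission_to_od`) with optional solvent subtraction, scaling with the
  transition dipole strength as μ²;
* the diagonal slice ΔOD(ω, ω) of the 2D IR surface, scaling as μ⁴.
  Diagonal fundamentals are bleaches, so readers accept either sign and
  `extract_diagonal` returns magnitudes, erroring only when a slice mixes
  signs beyond 1% of its peak amplitude (an ambiguous sign convention is a
  data problem, not something to guess about);
* the pump intensity envelope I_pump(ω), strictly positive wherever used.

The calibrated dipole-strength spectrum is

d(ω) = [ΔOD_s(ω,ω)/OD_s(ω)] / [ΔOD_cal(ω_max,ω_max)/OD_cal(ω_max)] · μ²_cal · I_pump(ω_max)/I_pump(ω).

Two conventions matter and are fixed deliberately:

* **ω_max is the calibrant's band maximum**, i.e. the frequency where the
  reference ratio is evaluated — not the maximum of the pump envelope. The
  pump factor is exactly 1 at ω_max, so pump normalization is a strict
  no-op for a flat pump and for readouts at the calibrant frequency.
* **Division guard.** Points where the corrected OD falls below a floor
  (default 1% of its maximum) are *masked*, never clipped or filled:
  near-zero OD is exactly where ratio artifacts explode, and the mask keeps
  that failure explicit through every downstream operation (masked readouts
  raise; masked kinetics windows become NaN points, not dropped ones).

Interpolation is linear (bilinear in 2D) and never extrapolates; all
resampling errors are therefore boundable by second-derivative bounds,
which the tests exercise.

## airPLS baseline correction

The baseline z minimizes Σ wᵢ(sᵢ−zᵢ)² + λ Σ(Δ²z)², solved exactly as the
banded system (W + λDᵀD)z = Ws (sparse Cholesky via SuperLU). Iteration t
re-weights from the residual d = s − z:

* wᵢ = 0 where sᵢ ≥ zᵢ (peaks exert no upward pull),
* wᵢ = exp(t·|dᵢ|/‖d⁻‖₁) where sᵢ < zᵢ,

starting from unit weights, stopping when ‖d⁻‖₁ < 0.001·‖s‖₁ (0.1% of the
signal vector) or after `max_iter` (default 15) sweeps. The difference
order is fixed at 2.

Parameters that matter:

* **λ (dimensionless, default 1e5 in `correct_baseline`).** Sets the
  baseline's stiffness; the resolution-like length scale is ≈ λ^¼ grid
  points. Heuristic: λ should make the baseline stiff across one band
  width but compliant across the background's curvature. For the reference
  validation conditions (FWHM ≈ 24 cm⁻¹ bands on a 1 cm⁻¹ grid, gently
  curved solvent background) λ = 3×10⁵ (`SERINE_LAMBDA`) is used; raise λ
  for noisier data. The defaults are package choices, not literature
  values — published airPLS work adjusts λ per signal strength without
  reporting numbers.
* **Termination ratio (0.001).** Two consequences worth knowing. First,
  the criterion is relative to ‖s‖₁, so it is *not* shift-invariant: the
  same band on a larger offset terminates earlier. Second, near
  termination ‖d⁻‖₁ is small and the exponential weights become extreme;
  one extra iteration can drop the baseline by several noise standard
  deviations toward the lower noise envelope. This is canonical airPLS
  behavior and is the dominant error tail in the weak-signal regime (see
  "Validation results" below). The iteration map itself is exactly
  shift-equivariant at fixed iteration count, which is what the tests pin.

Savitzky–Golay filtering (third-order, 15-point windows by default)
implements the moving least-squares polynomial exactly; edge points are
fitted over the truncated available window (order capped at the point
count minus one) rather than padding with fabricated data. It reproduces
polynomials up to its order exactly, edges included. Smoothing applies
only to the linear OD, before baseline estimation, and only on request —
TDS spectra themselves are never smoothed, since oversmoothing can erase
real fine structure.

The manual comparison pathway (`polynomial_baseline`) fits an unweighted
polynomial to user-chosen flanking ranges only, the traditional approach
the automated one is benchmarked against.

## FTIR dipole strengths

D = 9.184×10⁻³ ∫ ε(ν)/ν dν by trapezoid over located bounds, with the
band endpoints interpolated so the integral is exact for piecewise-linear
integrands. Bounds come from the smoothed first derivative, walking
outward from the band maximum: a bound is the first zero-crossing
indicating return to background (the valley against a neighbor), or the
first point of a 3-point run with |derivative| below 1% of the in-band
maximum — whichever comes first. The crossing at the maximum itself is
excluded by requiring the derivative to exceed the threshold once on each
side before a bound can fire. For an isolated band on a flat baseline the
derivative's only zero is at the maximum, so the threshold rule is the
operative one; both the fraction and the run length are exposed
parameters, and the procedure is deterministic (ties between candidate
maxima break toward lower wavenumber). Replicate summaries report the
sample (n−1) standard deviation, with the population value alongside,
because published summary tables do not always state their convention.

## Statistics and quality control

* **SNR** = (max in a signal window) / (sd of a linearly detrended noise
  window, n−1), an RMS convention. Instrument practice often quotes
  peak-to-peak noise instead, ≈ 6× the RMS value for Gaussian noise; the
  package's quoted "peak-to-peak SNR" for the synthetic ladder uses that
  6σ equivalence. Windows are user-chosen, must be disjoint, and the noise
  window needs ≥ 10 points.
* **Percent error** = 100·|measured − reference|/|reference|.
* **Grubbs' test** (two-sided, single outlier): G = max|vᵢ − mean|/sd with
  critical value ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) quantile of
  Student's t with n−2 degrees of freedom. Critical values reproduce
  published α = 0.05 tables for n = 3–10 to 10⁻³.

## Kinetics

Frames are stamped at the midpoint of their acquisition; 15-frame blocks
at the 66 s cadence therefore span 16.5 min and their averages sit at 495 s
past the window start. Windows are non-overlapping by default (stride =
window) so every frame contributes exactly once; a trailing partial window
is dropped. TDS traces rerun the full per-window pipeline (baseline →
ratio → calibration → readout at the nearest axis point); the calibrant
reference is computed once per experiment, not per window. Any dead time
before the first frame is carried as a series-level start offset
(default 0).

## The synthetic forward model

Unit-maximum lineshapes g_k (Gaussian / Lorentzian / pseudo-Voigt,
default η = 0.5) with a concentration-like amplitude c_k give

* OD(ω) = Σ c_k μ_k² g_k(ω) + background + noise,
* ΔOD(ω,ω) = κ I_pump(ω) Σ μ_k² · c_k μ_k² g_k(ω) + noise,

so the μ²/μ⁴ scaling is built in and the calibrated ratio inverts the
model *exactly* at isolated band maxima: with zero noise the pipeline
returns each μ_k² to 1e−9 under any pump (normalization on), and the
result is invariant to c_k (the computational content of
concentration-independence). Any recovery error therefore measures the
analysis — chiefly the baseline step — not the construction. The
calibrant pair is always generated noiseless and baseline-free to isolate
sample-side processing. Noise is additive white Gaussian, seeded (PCG64),
independent between OD and diagonal and between frames; bands closer than
half a FWHM trigger a warning because the truth at their maxima becomes a
μ²-weighted mixture. The background is a polynomial in the normalized
axis coordinate so coefficients stay O(1). The optional full 2D surface
is phenomenological — κ I_pump(p) Σ μ⁴ c √(g(p)g(q)) — built only so its
diagonal reproduces the 1D model; it is not an excitonic simulation.

What this does **not** emulate: correlated noise and slow baseline drift,
solvent absorption of the pump, anharmonic (overtone) peak pairs off the
diagonal, session-to-session intensity drift between sample and calibrant,
and scattering artifacts. Passing the synthetic suites shows the analysis
chain is correct and numerically stable under the stated noise model; it
does not certify performance against structured noise.

### Reference validation conditions

Two scenarios are frozen in `synth` so tests and the acceptance script
mean the same thing by "the study":

* **Concentration ladder** (`serine_ladder_config`): one pseudo-Voigt
  carboxyl band at 1623 cm⁻¹ (FWHM 24, μ² = 0.200 D²), apex OD 0.04 /
  0.02 / 0.01 / 0.005 for 40 / 20 / 10 / 5 mM, quadratic background
  rising 0.025 → 0.05 OD, fixed RMS noise 3.7×10⁻⁴ OD (peak-to-peak SNR
  ≈ 18 / 9 / 4.5 / 2.25), flat pump, noiseless Gaussian calibrant at the
  same frequency. Analysis uses airPLS with λ = 3×10⁵ and reads d(ω) at
  the 1623 cm⁻¹ axis point.
* **Aggregation experiment** (`aggregation_demo_config`): Gaussian bands
  for the bulk β-sheet mode (1623 cm⁻¹, FWHM 16) and a single labeled
  residue (1582 cm⁻¹, FWHM 12), μ² following logistic ramps 0.26 → 0.31
  and 0.13 → 0.26 D² (midpoint 4455 s, time constant 600 s; concentration
  held constant so the OD grows only through μ²), Gaussian pump (center
  1610, FWHM 120), 135 frames at 66 s. Gaussian lineshapes keep the
  41 cm⁻¹-separated band maxima uncontaminated, the stated precondition
  for truth-recovery tests.

### Validation results the suites compute

Mean absolute TDS recovery error over the 40–10 mM ladder is ≈ 2%
(20 seeds per rung), with single draws occasionally off by ~10% at the
weakest rung — the readout at the band maximum carries the full OD point
noise there, plus the termination-sensitivity tail described above.
Windowed kinetics traces recover the logistic endpoints to well under 5%.
The sizes (20 and 10 seeds, 135 frames, 251-point axes) are the package's
validation choices; everything scales by configuration.

## Known limitations

* airPLS inherits the canonical algorithm's offset bias: the converged
  baseline rides somewhat below the true background (toward the lower
  noise envelope), biasing d(ω) slightly low; in real workflows this
  partially cancels when the calibrant is processed the same way, which
  the isolated-calibrant validation deliberately does not do.
* No automatic λ selection; no arPLS/ALS variants; no wavelet baselines.
* Peak-bound location is built for isolated or pairwise-overlapping bands,
  not for dense multiplets (no deconvolution).
* Kinetic model fitting (lag times, growth rates) is out of scope; traces
  are produced, not fitted.
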