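"""Synthetic spectra with embedded ground-truth dipole strengths.

The generator's forward model is chosen so the TDS pipeline inverts it
exactly. With unit-maximum lineshapes g_k and a concentration-like amplitude
scale c_k, each band contributes

    A_k(ω) = c_k * μ_k² * g_k(ω)          to the linear OD   (μ² scaling)
    κ * I_pump(ω) * μ_k² * A_k(ω)          to the 2D diagonal (μ⁴ scaling)

so OD(ω) = Σ A_k + baseline + noise and ΔOD(ω,ω) = κ I_pump Σ μ_k² A_k +
noise. At an isolated band maximum the ratio ΔOD/OD (after perfect baseline
removal) equals κ I_pump(ω_k) μ_k²; dividing by the calibrant's ratio κ
I_pump(ω_max) μ_cal², multiplying by μ_cal² and applying the pump factor
returns μ_k² identically — so any recovery error measures the analysis, not
the construction. The calibrant pair is always generated noiseless and
baseline-free so that sample-side processing is isolated.

Noise is additive white Gaussian (independently on OD and diagonal; the
instruments' detector noise has no documented colour model). Everything is
deterministic given the seed (numpy PCG64 via ``default_rng``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ParameterError, SizeError
from .kinetics import SpectrumSeries
from .spectra_io import Spectrum1D, Spectrum2D

_4LN2 = 4.0 * math.log(2.0)


def lineshape(axis: np.ndarray, center: float, fwhm: float, shape: str, eta: float = 0.5):
    """Unit-maximum Gaussian / Lorentzian / pseudo-Voigt profile."""
    x = np.asarray(axis, dtype=float)
    g = np.exp(-_4LN2 * (x - center) ** 2 / fwhm**2)
    if shape == "gaussian":
        return g
    lor = 1.0 / (1.0 + (2.0 * (x - center) / fwhm) ** 2)
    if shape == "lorentzian":
        return lor
    if shape == "pseudo_voigt":
        return eta * lor + (1.0 - eta) * g
    raise ParameterError(f"unknown lineshape {shape!r}")


@dataclass
class BandSpec:
    """One absorption band with its ground-truth dipole strength.

    ``amplitude_scale`` plays the role of concentration: the band's apex OD is
    ``amplitude_scale * mu2`` (lineshapes are normalized to unit maximum, so
    the apex is set directly).
    """

    center: float
    fwhm: float
    mu2: float
    shape: str = "pseudo_voigt"
    eta: float = 0.5
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ParameterError("fwhm must be > 0")
        if self.mu2 < 0:
            raise ParameterError("mu2 must be >= 0")
        if not (0.0 <= self.eta <= 1.0):
            raise ParameterError("eta must be in [0, 1]")
        if self.amplitude_scale < 0:
            raise ParameterError("amplitude_scale must be >= 0")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        return lineshape(axis, self.center, self.fwhm, self.shape, self.eta)


@dataclass
class PumpSpec:
    """Pump-pulse intensity envelope: flat, or a Gaussian of given center/FWHM."""

    kind: str = "flat"
    center: float | None = None
    fwhm: float | None = None
    amplitude: float = 1.0

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        if self.kind == "flat":
            return np.full_like(axis, self.amplitude, dtype=float)
        if self.kind == "gaussian":
            if self.center is None or self.fwhm is None:
                raise ParameterError("gaussian pump needs center and fwhm")
            return self.amplitude * np.exp(-_4LN2 * (axis - self.center) ** 2 / self.fwhm**2)
        raise ParameterError(f"unknown pump kind {self.kind!r}")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``baseline_coeffs`` are polynomial coefficients (constant first) in the
    normalized coordinate x = (ω - lo)/(hi - lo), so coefficients stay O(1)
    regardless of the spectral window. ``kappa`` is the instrument constant
    linking linear and 2D signal scales.
    """

    bands: list[BandSpec] = field(default_factory=list)
    baseline_coeffs: tuple = ()
    noise_sd_od: float = 0.0
    noise_sd_2d: float = 0.0
    pump: PumpSpec = field(default_factory=PumpSpec)
    axis: tuple[float, float, float] = (1500.0, 1750.0, 1.0)
    kappa: float = 1.0
    seed: int = 0
    calibrant: BandSpec = field(
        default_factory=lambda: BandSpec(center=1623.0, fwhm=12.0, mu2=0.200, shape="gaussian")
    )

    def __post_init__(self) -> None:
        lo, hi, step = self.axis
        if step <= 0 or hi <= lo:
            raise ParameterError("axis must be (lo, hi, step) with step > 0, hi > lo")
        if self.noise_sd_od < 0 or self.noise_sd_2d < 0:
            raise ParameterError("noise sds must be >= 0")
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")

    def make_axis(self) -> np.ndarray:
        lo, hi, step = self.axis
        ax = np.arange(lo, hi + 0.5 * step, step)
        if ax.size < 3:
            raise SizeError("axis has fewer than 3 points")
        return ax


@dataclass
class SynthDataset:
    """Mutually consistent spectra plus the ground truth behind them."""

    od: Spectrum1D
    delta_od_diag: Spectrum1D
    pump: Spectrum1D
    calibrant_od: Spectrum1D
    calibrant_delta_od: Spectrum1D
    truth: list[tuple[float, float]]  # (center, mu2) per band
    od_clean: Spectrum1D
    delta_od_diag_clean: Spectrum1D
    spectrum2d: Spectrum2D | None = None
    config: SynthConfig | None = None


def _check_overlap(bands: Sequence[BandSpec]) -> None:
    for i, a in enumerate(bands):
        for b in bands[i + 1 :]:
            if abs(a.center - b.center) < 0.5 * max(a.fwhm, b.fwhm):
                warnings.warn(
                    f"bands at {a.center} and {b.center} cm^-1 overlap strongly; "
                    "the truth at their maxima is a mu^2-weighted mixture",
                    stacklevel=3,
                )


def generate(config: SynthConfig, make_2d: bool = False) -> SynthDataset:
    """Generate one dataset; deterministic given ``config.seed``."""
    if not config.bands:
        raise ParameterError("config.bands must be nonempty")
    _check_overlap(config.bands)
    ax = config.make_axis()
    lo, hi, _ = config.axis
    x = (ax - lo) / (hi - lo)
    background = (
        np.polynomial.polynomial.polyval(x, np.asarray(config.baseline_coeffs, dtype=float))
        if len(config.baseline_coeffs)
        else np.zeros_like(ax)
    )
    pump_vals = config.pump.evaluate(ax)
    profiles = [b.profile(ax) for b in config.bands]
    od_bands = np.sum(
        [b.amplitude_scale * b.mu2 * g for b, g in zip(config.bands, profiles)], axis=0
    )
    dd_clean = config.kappa * pump_vals * np.sum(
        [b.mu2 * b.amplitude_scale * b.mu2 * g for b, g in zip(config.bands, profiles)],
        axis=0,
    )
    od_clean = od_bands + background
    rng = np.random.default_rng(config.seed)
    od_vals = od_clean + (
        rng.normal(0.0, config.noise_sd_od, ax.size) if config.noise_sd_od > 0 else 0.0
    )
    dd_vals = dd_clean + (
        rng.normal(0.0, config.noise_sd_2d, ax.size) if config.noise_sd_2d > 0 else 0.0
    )
    dd_vals = np.clip(dd_vals, 0.0, None)  # diagonal magnitudes are nonnegative

    cal = config.calibrant
    g_cal = cal.profile(ax)
    cal_od = cal.amplitude_scale * cal.mu2 * g_cal
    cal_dd = config.kappa * pump_vals * cal.mu2 * cal_od

    spectrum2d = None
    if make_2d:
        # a phenomenological surface whose diagonal reproduces the 1D model:
        # κ I_pump(p) Σ μ⁴ c sqrt(g(p) g(q)), plus per-cell noise
        surf = np.zeros((ax.size, ax.size))
        for b, g in zip(config.bands, profiles):
            surf += b.mu2 * b.amplitude_scale * b.mu2 * np.sqrt(np.outer(g, g))
        surf *= config.kappa * pump_vals[:, None]
        if config.noise_sd_2d > 0:
            surf = surf + rng.normal(0.0, config.noise_sd_2d, surf.shape)
        spectrum2d = Spectrum2D(ax.copy(), ax.copy(), surf, meta={"synthetic": True})

    meta = {"synthetic": True, "seed": config.seed}
    return SynthDataset(
        od=Spectrum1D(ax, od_vals, role="od", meta=dict(meta)),
        delta_od_diag=Spectrum1D(ax, dd_vals, role="delta_od_diag", meta=dict(meta)),
        pump=Spectrum1D(ax, pump_vals, role="pump", meta=dict(meta)),
        calibrant_od=Spectrum1D(ax, cal_od, role="od", meta={**meta, "calibrant": True}),
        calibrant_delta_od=Spectrum1D(
            ax, cal_dd, role="delta_od_diag", meta={**meta, "calibrant": True}
        ),
        truth=[(b.center, b.mu2) for b in config.bands],
        od_clean=Spectrum1D(ax, od_clean, role="od", meta={**meta, "clean": True}),
        delta_od_diag_clean=Spectrum1D(
            ax, dd_clean, role="delta_od_diag", meta={**meta, "clean": True}
        ),
        spectrum2d=spectrum2d,
        config=config,
    )


@dataclass
class KineticsDataset:
    """A synthetic aggregation experiment: per-frame diagonals and ODs."""

    diag_series: SpectrumSeries
    od_series: SpectrumSeries
    pump: Spectrum1D
    calibrant_od: Spectrum1D
    calibrant_delta_od: Spectrum1D
    truth_times: np.ndarray
    truth_mu2: list[np.ndarray]  # one trajectory per band
    config: SynthConfig


def sigmoid_trajectory(start: float, end: float, t_mid: float, tau: float) -> Callable:
    """Logistic interpolation start -> end with midpoint ``t_mid`` and time
    constant ``tau`` (seconds), the canonical amyloid-aggregation shape."""

    def f(t: float) -> float:
        return start + (end - start) / (1.0 + math.exp(-(t - t_mid) / tau))

    return f


# ---------------------------------------------------------------------------
# canonical study scenarios
#
# These encode the package's reference validation conditions; tests and the
# acceptance script share them so "the study" means one thing everywhere.

#: l-serine carboxyl-stretch ladder: apex OD per emulated concentration (mM).
#: The RMS noise floor is fixed by the instrument, so the linear-OD SNR falls
#: with concentration; 3.7e-4 OD corresponds to a peak-to-peak (~6 sigma)
#: SNR of ~4.5 at 10 mM, the regime where TDS analysis starts to degrade.
SERINE_APEX_OD = {40: 0.04, 20: 0.02, 10: 0.01, 5: 0.005}
SERINE_MU2 = 0.200  # D^2, established carboxyl-stretch value
SERINE_NOISE_SD_OD = 3.7e-4
SERINE_NOISE_SD_2D = 2.0e-5
#: smoothness penalty for the ladder analysis (band FWHM ~24 cm^-1 on a 1
#: cm^-1 grid): large enough to resist plunging into single noise points,
#: small enough to follow the solvent background curvature
SERINE_LAMBDA = 3e5


def serine_ladder_config(concentration_mm: int, seed: int = 0) -> SynthConfig:
    """Study conditions for one rung of the l-serine concentration ladder:
    a single carboxyl band (mu^2 = 0.200 D^2) on a gently curved solvent
    background, flat pump, fixed instrument noise."""
    try:
        apex = SERINE_APEX_OD[concentration_mm]
    except KeyError:
        raise ParameterError(
            f"no ladder rung at {concentration_mm} mM (have {sorted(SERINE_APEX_OD)})"
        ) from None
    return SynthConfig(
        bands=[
            BandSpec(1623.0, 24.0, SERINE_MU2, amplitude_scale=apex / SERINE_MU2)
        ],
        baseline_coeffs=(0.025, 0.04, -0.015),
        noise_sd_od=SERINE_NOISE_SD_OD,
        noise_sd_2d=SERINE_NOISE_SD_2D,
        seed=seed,
        calibrant=BandSpec(1623.0, 12.0, SERINE_MU2, shape="gaussian"),
    )


def aggregation_demo_config(seed: int = 0) -> tuple[SynthConfig, list]:
    """Study conditions for the isotope-label aggregation experiment.

    Two amide I' bands: the bulk β-sheet mode at 1623 cm^-1 (mu^2 ramping
    0.26 -> 0.31 D^2) and a single labeled residue red-shifted to 1582 cm^-1
    (0.13 -> 0.26 D^2, disordered -> β-sheet), both following a logistic
    aggregation time course; Gaussian pump envelope; amide-I' calibrant at
    1623 cm^-1 with user-known mu^2 = 0.200 D^2. Returns (config, mu2
    trajectories).
    """
    config = SynthConfig(
        bands=[
            BandSpec(1623.0, 16.0, 0.26, shape="gaussian", amplitude_scale=0.1),
            BandSpec(1582.0, 12.0, 0.13, shape="gaussian", amplitude_scale=0.1),
        ],
        baseline_coeffs=(0.01, 0.02, -0.005),
        noise_sd_od=2.0e-4,
        noise_sd_2d=1.0e-5,
        pump=PumpSpec("gaussian", center=1610.0, fwhm=120.0),
        calibrant=BandSpec(1623.0, 12.0, 0.200, shape="gaussian"),
        seed=seed,
    )
    trajectories = [
        sigmoid_trajectory(0.26, 0.31, 4455.0, 600.0),
        sigmoid_trajectory(0.13, 0.26, 4455.0, 600.0),
    ]
    return config, trajectories


def generate_kinetics(
    config: SynthConfig,
    n_frames: int,
    cadence_s: float,
    mu2_trajectories: Sequence[Callable | None],
    amplitude_trajectories: Sequence[Callable | None] | None = None,
    start_offset_s: float = 0.0,
) -> KineticsDataset:
    """Frame-wise datasets with time-varying μ² (and optionally amplitudes).

    Frame i is stamped at the midpoint of its acquisition,
    ``start_offset_s + (i + 0.5) * cadence_s``. Noise is seeded independently
    per frame from the parent seed, so the whole series is reproducible.
    """
    if n_frames < 1:
        raise SizeError("need at least one frame")
    if len(mu2_trajectories) != len(config.bands):
        raise ParameterError("one mu2 trajectory (or None) per band required")
    if amplitude_trajectories is not None and len(amplitude_trajectories) != len(config.bands):
        raise ParameterError("one amplitude trajectory (or None) per band required")
    times = start_offset_s + (np.arange(n_frames) + 0.5) * cadence_s
    child_seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=n_frames)
    diag_frames: list[Spectrum1D] = []
    od_frames: list[Spectrum1D] = []
    truth_mu2 = [np.empty(n_frames) for _ in config.bands]
    pump = cal_od = cal_dd = None
    for i, t in enumerate(times):
        bands = []
        for k, base in enumerate(config.bands):
            mu2 = mu2_trajectories[k](t) if mu2_trajectories[k] is not None else base.mu2
            amp = base.amplitude_scale
            if amplitude_trajectories is not None and amplitude_trajectories[k] is not None:
                amp = amplitude_trajectories[k](t)
            bands.append(replace(base, mu2=mu2, amplitude_scale=amp))
            truth_mu2[k][i] = mu2
        ds = generate(replace(config, bands=bands, seed=int(child_seeds[i])))
        diag_frames.append(ds.delta_od_diag)
        od_frames.append(ds.od)
        if pump is None:
            pump, cal_od, cal_dd = ds.pump, ds.calibrant_od, ds.calibrant_delta_od
    diag_series = SpectrumSeries(times, diag_frames, cadence=cadence_s, start_offset=start_offset_s)
    od_series = SpectrumSeries(times.copy(), od_frames, cadence=cadence_s, start_offset=start_offset_s)
    return KineticsDataset(
        diag_series=diag_series,
        od_series=od_series,
        pump=pump,
        calibrant_od=cal_od,
        calibrant_delta_od=cal_dd,
        truth_times=times,
        truth_mu2=truth_mu2,
        config=config,
    )
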