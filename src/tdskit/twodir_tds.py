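"""Transition-dipole-strength spectra from 2D IR / linear OD ratios.

The TDS spectrum is assembled from the ratio of the 2D IR diagonal slice to
the baseline-corrected linear OD, scaled to absolute units by a calibrant of
known dipole strength and optionally corrected for the non-flat intensity
envelope of the pump pulses:

    d(ω) = [ΔOD_sample(ω,ω) / OD_sample(ω)]
           / [ΔOD_cal(ω_max,ω_max) / OD_cal(ω_max)]
           * |μ|²_cal * I_pump(ω_max) / I_pump(ω)

ω_max is the calibrant's band maximum — the frequency at which its reference
ratio is taken — not the maximum of the pump envelope; the two coincide only
by accident. The pump factor is exactly 1 at ω_max and is a no-op for flat
pumps, which is why it is traditionally neglected when the calibrant sits
within ~20 cm^-1 of the mode of interest.

Division by a near-zero corrected OD produces large artifacts, so points
where the corrected OD falls below ``od_floor_fraction`` of its maximum are
masked rather than computed (never clipped): the failure stays explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DataQualityError,
    DomainError,
    EmptyResultError,
    MaskedValueError,
    ParameterError,
    RangeError,
)
from .spectra_io import MaskedSpectrum1D, Spectrum1D, common_axis


@dataclass
class CalibrantReference:
    """A calibrant's band maximum, dipole strength, and reference ratio.

    ``ratio_at_max`` is ΔOD_cal(ω_max, ω_max) / OD_cal(ω_max), the quantity
    that converts a sample's ΔOD/OD ratio into D² units via ``mu2``.
    """

    name: str
    omega_max: float
    mu2: float
    ratio_at_max: float

    def __post_init__(self) -> None:
        if self.mu2 <= 0:
            raise ParameterError("calibrant mu2 must be > 0")
        if self.ratio_at_max <= 0:
            raise DataQualityError("calibrant ratio_at_max must be > 0")


#: Band positions of calibrants used for amide I' work. Dipole strengths are
#: supplied by the user from their own FTIR determinations, except l-serine's
#: carboxyl stretch whose well-documented 0.200 D² serves as a validation
#: constant.
CALIBRANT_BANDS: dict[str, dict] = {
    "nma": {"omega_max": 1623.0, "mu2": None, "note": "N-methylacetamide amide I'"},
    "2h5nba": {
        "omega_max": 1585.0,
        "mu2": None,
        "note": "2-hydroxy-5-nitrobenzaldehyde aromatic stretch",
    },
    "l-serine": {
        "omega_max": 1623.0,
        "mu2": 0.200,
        "note": "carboxyl stretch; documented validation value",
    },
}


class TDSSpectrum(MaskedSpectrum1D):
    """A TDS spectrum d(ω) in D²; masked wherever the OD floor guard fired."""


def ratio_spectrum(
    delta_od_diag: Spectrum1D,
    od_corrected: Spectrum1D,
    od_floor_fraction: float = 0.01,
) -> MaskedSpectrum1D:
    """Pointwise ΔOD/OD with a floor guard on the denominator.

    Points where ``od_corrected < od_floor_fraction * max(od_corrected)`` are
    masked (value 0.0, mask True) instead of divided.
    """
    common_axis(delta_od_diag, od_corrected)
    if od_floor_fraction <= 0:
        raise ParameterError("od_floor_fraction must be > 0")
    dd = delta_od_diag.values
    if np.any(dd < -1e-12):
        raise DomainError("diagonal magnitudes must be nonnegative")
    dd = np.clip(dd, 0.0, None)
    od = od_corrected.values
    od_max = float(od.max())
    if od_max <= 0:
        raise EmptyResultError("corrected OD is nonpositive everywhere")
    floor = od_floor_fraction * od_max
    mask = od < floor
    if mask.all():
        raise EmptyResultError("OD floor guard masked every point")
    vals = np.zeros_like(dd)
    np.divide(dd, od, out=vals, where=~mask)
    return MaskedSpectrum1D(
        delta_od_diag.axis.copy(),
        vals,
        mask,
        role="generic",
        meta={
            "ratio": "delta_od/od",
            "od_floor_fraction": od_floor_fraction,
        },
    )


def calibrant_reference_from_spectra(
    delta_od_cal: Spectrum1D,
    od_cal: Spectrum1D,
    mu2: float,
    omega_max="auto",
    name: str = "custom",
) -> CalibrantReference:
    """Build a :class:`CalibrantReference` from a calibrant's spectra pair.

    ``omega_max="auto"`` locates the maximum of the calibrant OD; otherwise
    the stated frequency is used. The reference ratio is evaluated there by
    linear interpolation.
    """
    common_axis(delta_od_cal, od_cal)
    if mu2 <= 0:
        raise ParameterError("mu2 must be > 0")
    if isinstance(omega_max, str):
        if omega_max != "auto":
            raise ParameterError("omega_max must be a frequency or 'auto'")
        omega = float(od_cal.axis[int(np.argmax(od_cal.values))])
    else:
        omega = float(omega_max)
        if not (od_cal.axis[0] <= omega <= od_cal.axis[-1]):
            raise RangeError(f"omega_max {omega} outside the calibrant axis")
    num = float(np.interp(omega, delta_od_cal.axis, delta_od_cal.values))
    den = float(np.interp(omega, od_cal.axis, od_cal.values))
    if den <= 0 or num <= 0:
        raise DataQualityError("calibrant ΔOD/OD at omega_max is nonpositive")
    return CalibrantReference(name=name, omega_max=omega, mu2=float(mu2), ratio_at_max=num / den)


def pump_norm_factor(pump: Spectrum1D, omega_max: float, target_axis) -> Spectrum1D:
    """The pump-normalization factor I_pump(ω_max)/I_pump(ω) on ``target_axis``."""
    target = np.asarray(target_axis, dtype=float)
    if not (pump.axis[0] <= omega_max <= pump.axis[-1]):
        raise RangeError(f"omega_max {omega_max} outside the pump axis")
    if target.min() < pump.axis[0] or target.max() > pump.axis[-1]:
        raise RangeError("target_axis extends beyond the pump spectrum (no extrapolation)")
    i_max = float(np.interp(omega_max, pump.axis, pump.values))
    i_target = np.interp(target, pump.axis, pump.values)
    if i_max <= 0 or np.any(i_target <= 0):
        raise DomainError("pump intensity must be strictly positive")
    return Spectrum1D(
        target,
        i_max / i_target,
        role="generic",
        meta={"pump_norm_omega_max": omega_max},
    )


def compute_tds(
    sample_delta_od_diag: Spectrum1D,
    sample_od_corrected: Spectrum1D,
    calibrant: CalibrantReference,
    pump: Spectrum1D | None = None,
    normalize_pump: bool = False,
    od_floor_fraction: float = 0.01,
) -> TDSSpectrum:
    """Assemble the TDS spectrum d(ω) from its ingredients.

    Mask propagation: any point masked by the OD floor guard stays masked in
    the result. Sample = calibrant reproduces ``calibrant.mu2`` at ω_max by
    construction, pump or no pump, since the pump factor is 1 there.
    """
    if normalize_pump and pump is None:
        raise ParameterError("normalize_pump=True requires a pump spectrum")
    ratio = ratio_spectrum(sample_delta_od_diag, sample_od_corrected, od_floor_fraction)
    d = ratio.values / calibrant.ratio_at_max * calibrant.mu2
    if normalize_pump:
        factor = pump_norm_factor(pump, calibrant.omega_max, ratio.axis)
        d = d * factor.values
    d[ratio.mask] = 0.0
    return TDSSpectrum(
        ratio.axis.copy(),
        d,
        ratio.mask.copy(),
        role="tds",
        meta={
            "calibrant": calibrant.name,
            "calibrant_omega_max": calibrant.omega_max,
            "calibrant_mu2": calibrant.mu2,
            "pump_normalized": bool(normalize_pump),
            "od_floor_fraction": od_floor_fraction,
        },
    )


def tds_at(
    tds: MaskedSpectrum1D,
    omega: float,
    mode: str = "nearest",
    window: tuple[float, float] | None = None,
    locate_on: Spectrum1D | None = None,
):
    """Read a dipole strength off a TDS spectrum.

    ``mode="nearest"``: value at the axis point nearest ``omega``.
    ``mode="local_max"``: value at the maximum, within ``window``, of
    ``locate_on`` (normally the corrected OD, i.e. the band maximum) or of the
    TDS spectrum itself when no locator is given.
    """
    from .ftir_tds import DipoleStrength  # local import to avoid a cycle

    if mode == "nearest":
        if not (tds.axis[0] <= omega <= tds.axis[-1]):
            raise RangeError(f"omega {omega} outside the TDS axis")
        i = int(np.argmin(np.abs(tds.axis - omega)))
    elif mode == "local_max":
        if window is None:
            raise ParameterError("mode='local_max' requires a window")
        lo, hi = window
        sel = np.nonzero((tds.axis >= lo) & (tds.axis <= hi))[0]
        if sel.size == 0:
            raise RangeError("window contains no axis points")
        ref = locate_on.values if locate_on is not None else tds.values
        if locate_on is not None:
            common_axis(locate_on, Spectrum1D(tds.axis, tds.values))
        i = int(sel[np.argmax(ref[sel])])
    else:
        raise ParameterError(f"unknown readout mode {mode!r}")
    if tds.mask[i]:
        raise MaskedValueError(
            f"TDS at {tds.axis[i]:g} cm^-1 is masked (OD below the floor guard)"
        )
    return DipoleStrength(float(tds.values[i]), "tds_eq2", float(tds.axis[i]))
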