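"""Dipole strength from linear absorption.

For an uncoupled vibration the transition dipole strength (in debye squared)
follows from the extinction-coefficient spectrum via

    D = 9.184e-3 * ∫ ε(ν) / ν dν,

evaluated by trapezoidal integration over the band. Integration bounds are
located from zero-crossings of the (pre-smoothed) first-derivative spectrum,
walking outward from the band maximum; for isolated bands on flat baselines
the only derivative zero is at the maximum itself, so a fallback rule stops
where the derivative magnitude stays below a configurable fraction (default
1%) of its in-band maximum for a run of consecutive points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .baseline import savgol_smooth
from .errors import (
    ConsistencyError,
    DataQualityError,
    NotFoundError,
    ParameterError,
    RangeError,
    SizeError,
)
from .spectra_io import Spectrum1D

#: D^2 per unit of ∫ ε(ν)/ν dν with ε in M^-1 cm^-1 and ν in cm^-1
FTIR_TDS_PREFACTOR = 9.184e-3


@dataclass
class PeakBounds:
    """Integration limits around a band maximum (all in cm^-1)."""

    lo: float
    hi: float
    center: float

    def __post_init__(self) -> None:
        if not (self.lo < self.center < self.hi):
            raise ParameterError(
                f"peak bounds must satisfy lo < center < hi, got "
                f"({self.lo}, {self.center}, {self.hi})"
            )


@dataclass
class DipoleStrength:
    """A dipole strength readout: ``value`` in D^2 at ``frequency`` cm^-1."""

    value: float
    method: str  # "ftir_eq1" or "tds_eq2"
    frequency: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataQualityError("dipole strength must be nonnegative")


def first_derivative(
    spec: Spectrum1D, presmooth: bool = True, sg_window: int = 15, sg_order: int = 3
) -> Spectrum1D:
    """Central-difference first derivative (one-sided at the edges), optionally
    Savitzky-Golay pre-smoothed. The window shrinks automatically for short
    spectra."""
    if len(spec) < 3:
        raise SizeError("need >= 3 points for a derivative")
    y = spec.values
    if presmooth:
        window = min(sg_window, len(spec))
        if window % 2 == 0:
            window -= 1
        if window > sg_order + 1:
            y = savgol_smooth(y, window, min(sg_order, window - 2))
    deriv = np.gradient(y, spec.axis)
    return Spectrum1D(
        spec.axis.copy(), deriv, role="generic", meta={**spec.meta, "derivative": 1}
    )


def _local_maxima(values: np.ndarray, idx: np.ndarray) -> list[int]:
    out = []
    n = values.size
    for i in idx:
        if i == 0 or i == n - 1:
            continue
        if values[i] > values[i - 1] and values[i] >= values[i + 1]:
            out.append(int(i))
    return out


def find_peak_bounds(
    spec: Spectrum1D,
    center_hint: float,
    search_window: tuple[float, float],
    deriv_threshold_frac: float = 0.01,
    flat_run: int = 3,
    presmooth: bool = True,
) -> PeakBounds:
    """Locate a band maximum near ``center_hint`` and its integration bounds.

    Walking outward from the maximum, a bound is set at the first derivative
    zero-crossing that indicates the band has returned to background (the
    valley against a neighboring band), or at the first point of a
    ``flat_run``-long run with ``|derivative| < deriv_threshold_frac`` of the
    in-band derivative maximum — whichever occurs first. The crossing at the
    maximum itself is excluded by requiring the derivative to first exceed the
    threshold on each side ("arming"). Deterministic: ties between candidate
    maxima break toward lower wavenumber.
    """
    lo_w, hi_w = search_window
    if not (spec.axis[0] <= lo_w < hi_w <= spec.axis[-1]):
        raise RangeError("search_window must lie within the spectrum axis")
    if not (lo_w <= center_hint <= hi_w):
        raise RangeError("center_hint must lie inside search_window")
    in_win = np.nonzero((spec.axis >= lo_w) & (spec.axis <= hi_w))[0]
    if in_win.size < 3:
        raise SizeError("search_window contains fewer than 3 points")
    candidates = _local_maxima(spec.values, in_win)
    if not candidates:
        raise NotFoundError("no local maximum inside search_window")
    dist = np.abs(spec.axis[candidates] - center_hint)
    ic = candidates[int(np.argmin(dist))]

    deriv = first_derivative(spec, presmooth=presmooth).values
    dmax = float(np.max(np.abs(deriv[in_win])))
    if dmax == 0.0:
        raise NotFoundError("derivative is identically zero in search_window")
    thresh = deriv_threshold_frac * dmax
    n = len(spec)

    def _walk(direction: int) -> int:
        # descending side: derivative sign is -direction after leaving the apex
        armed = False
        run = 0
        j = ic + direction
        while 0 <= j < n:
            dj = deriv[j]
            if direction * dj <= -thresh:
                armed = True
                run = 0
            elif armed and direction * dj >= 0.0:
                return j  # zero-crossing: band has returned to background
            elif armed and abs(dj) < thresh:
                run += 1
                if run >= flat_run:
                    return j - direction * (flat_run - 1)
            else:
                run = 0
            j += direction
        warnings.warn(
            "peak bound search reached the axis edge; using the edge as the bound",
            stacklevel=3,
        )
        return 0 if direction < 0 else n - 1

    jlo = _walk(-1)
    jhi = _walk(+1)
    jlo = min(jlo, ic - 1)
    jhi = max(jhi, ic + 1)
    return PeakBounds(float(spec.axis[jlo]), float(spec.axis[jhi]), float(spec.axis[ic]))


def dipole_strength_ftir(epsilon: Spectrum1D, bounds: PeakBounds) -> DipoleStrength:
    """Trapezoidal dipole-strength integral of a baseline-corrected extinction
    spectrum (ε in M^-1 cm^-1) over ``[bounds.lo, bounds.hi]``."""
    if bounds.lo < epsilon.axis[0] or bounds.hi > epsilon.axis[-1]:
        raise RangeError("integration bounds outside the spectrum axis")
    inside = (epsilon.axis > bounds.lo) & (epsilon.axis < bounds.hi)
    x = np.concatenate(([bounds.lo], epsilon.axis[inside], [bounds.hi]))
    y = np.concatenate(
        (
            [np.interp(bounds.lo, epsilon.axis, epsilon.values)],
            epsilon.values[inside],
            [np.interp(bounds.hi, epsilon.axis, epsilon.values)],
        )
    )
    integral = float(np.trapezoid(y / x, x))
    value = FTIR_TDS_PREFACTOR * integral
    if value < -1e-9:
        raise DataQualityError(
            f"negative band integral ({value:.3g} D^2): check the baseline correction"
        )
    return DipoleStrength(max(value, 0.0), "ftir_eq1", bounds.center)


@dataclass
class ReplicateSummary:
    """Mean and spread of replicate dipole-strength measurements.

    ``std`` uses the sample (n-1) convention and is ``None`` for a single
    replicate; ``std_pop`` is the population (n) value, reported because
    published summary tables do not always state their convention.
    """

    mean: float
    std: float | None
    std_pop: float | None
    n: int


def average_replicates(values, freq_tol: float = 1.0) -> ReplicateSummary:
    """Average replicate :class:`DipoleStrength` readouts of one mode."""
    vals = list(values)
    if not vals:
        raise SizeError("need at least one replicate")
    method = vals[0].method
    freq = vals[0].frequency
    for v in vals[1:]:
        if v.method != method:
            raise ConsistencyError("replicates mix methods")
        if abs(v.frequency - freq) > freq_tol:
            raise ConsistencyError(
                f"replicates mix frequencies ({v.frequency} vs {freq} cm^-1)"
            )
    arr = np.array([v.value for v in vals], dtype=float)
    n = arr.size
    if n == 1:
        return ReplicateSummary(float(arr[0]), None, None, 1)
    return ReplicateSummary(
        float(arr.mean()), float(arr.std(ddof=1)), float(arr.std(ddof=0)), n
    )
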