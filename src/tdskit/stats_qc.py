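"""Quality metrics and statistical assessments for TDS work.

Signal-to-noise here is the peak height divided by the standard deviation of
a linearly detrended, signal-free noise window (an RMS convention; instrument
vendors often quote peak-to-peak noise instead, roughly 6x larger for
Gaussian noise). Percent errors are reported against an established reference
value, and Grubbs' test flags a single outlier among replicate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import DegeneracyError, DomainError, ParameterError, RangeError, SizeError
from .spectra_io import Spectrum1D


@dataclass
class SNRReport:
    snr: float
    signal_height: float
    noise_sd: float
    signal_window: tuple[float, float]
    noise_window: tuple[float, float]


def snr(
    spec: Spectrum1D,
    signal_window: tuple[float, float],
    noise_window: tuple[float, float],
    allow_zero_noise: bool = False,
) -> SNRReport:
    """Peak height in ``signal_window`` over detrended noise sd in
    ``noise_window`` (disjoint; >= 10 noise points).

    Degenerate (zero-variance) noise raises unless ``allow_zero_noise``, in
    which case the SNR is reported as ``inf``.
    """
    s_lo, s_hi = signal_window
    n_lo, n_hi = noise_window
    for lo, hi, name in ((s_lo, s_hi, "signal"), (n_lo, n_hi, "noise")):
        if lo >= hi:
            raise ParameterError(f"{name}_window must have lo < hi")
        if lo < spec.axis[0] or hi > spec.axis[-1]:
            raise RangeError(f"{name}_window outside the spectrum axis")
    if not (s_hi <= n_lo or n_hi <= s_lo):
        raise ParameterError("signal and noise windows must be disjoint")
    s_sel = (spec.axis >= s_lo) & (spec.axis <= s_hi)
    n_sel = (spec.axis >= n_lo) & (spec.axis <= n_hi)
    if s_sel.sum() < 1:
        raise SizeError("signal_window contains no points")
    if n_sel.sum() < 10:
        raise SizeError("noise_window must contain >= 10 points")
    x = spec.axis[n_sel]
    y = spec.values[n_sel]
    trend = np.polynomial.Polynomial.fit(x, y, 1)(x)
    noise_sd = float(np.std(y - trend, ddof=1))
    height = float(spec.values[s_sel].max())
    if noise_sd == 0.0:
        if not allow_zero_noise:
            raise DegeneracyError("noise window has zero variance (noiseless input?)")
        return SNRReport(math.inf, height, 0.0, signal_window, noise_window)
    return SNRReport(height / noise_sd, height, noise_sd, signal_window, noise_window)


def percent_error(measured: float, reference: float) -> float:
    """100 * |measured - reference| / |reference|."""
    if reference == 0:
        raise DomainError("reference value must be nonzero")
    return 100.0 * abs(measured - reference) / abs(reference)


@dataclass
class GrubbsResult:
    statistic: float
    critical: float
    alpha: float
    outlier_index: int | None
    n: int


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t² / (n - 2 + t²)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise SizeError("Grubbs' test needs n >= 3")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    t = sstats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided, single-outlier Grubbs' test.

    G = max_i |v_i - mean| / sd (sample sd, n-1 divisor); the index of the
    extreme value is reported as an outlier when G exceeds the critical value.
    """
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n < 3:
        raise SizeError("Grubbs' test needs n >= 3")
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        raise DegeneracyError("all values equal: Grubbs' statistic undefined")
    dev = np.abs(v - v.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    crit = grubbs_critical(n, alpha)
    return GrubbsResult(g, crit, alpha, i if g > crit else None, n)
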