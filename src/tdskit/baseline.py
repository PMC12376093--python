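"""Baseline estimation and noise filtering for the linear optical density.

The workhorse is airPLS (adaptive iteratively reweighted penalized least
squares): a Whittaker smoother — the exact solution of the banded system
``(W + lam * D'D) z = W s`` — alternated with residual-driven reweighting that
drives the weights to zero under peaks, so the fitted baseline settles beneath
the bands without any manual region exclusion. Iteration ``t`` uses

    w_i = 0                       where s_i >= z_i
    w_i = exp(t * |s_i - z_i| / |d|_1)   where s_i <  z_i

with ``d`` the negative part of the residual, and terminates when
``|d|_1 < termination_ratio * |s|_1`` (default 0.1%) or after ``max_iter``
sweeps.

A Savitzky-Golay filter (third-order polynomial over 15-point windows by
default) is available for particularly noisy optical densities, and a
range-restricted polynomial fit reproduces the traditional manual baseline
pathway for comparison studies. Smoothing is only ever applied to the linear
OD, never to 2D signals, and only when explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import DegeneracyError, DomainError, ParameterError, SizeError
from .spectra_io import Spectrum1D


@dataclass
class BaselineResult:
    """Fitted baseline plus diagnostics.

    ``lam`` is the Whittaker smoothness penalty (``None`` for polynomial
    baselines, where it does not apply). ``residual_norm_ratio`` is
    ``|d|_1 / |s|_1`` at termination.
    """

    baseline: np.ndarray
    weights: np.ndarray
    iterations: int
    converged: bool
    residual_norm_ratio: float
    lam: float | None
    method: str = "airpls"


def _diff_matrix(n: int, order: int) -> sp.spmatrix:
    D = sp.eye(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return D


def whittaker_weighted(signal, weights, lam: float, diff_order: int = 2) -> np.ndarray:
    """Solve ``min_z sum_i w_i (s_i - z_i)^2 + lam * sum (Δ^order z)^2`` exactly."""
    s = np.asarray(signal, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.ndim != 1 or w.shape != s.shape:
        raise ParameterError("signal and weights must be 1D arrays of equal length")
    if s.size < diff_order + 1:
        raise SizeError(f"need >= {diff_order + 1} points for difference order {diff_order}")
    if not np.all(np.isfinite(s)):
        raise DomainError("signal must be finite")
    if lam <= 0:
        raise ParameterError("lam must be > 0")
    if np.any(w < 0):
        raise ParameterError("weights must be nonnegative")
    if not np.any(w > 0):
        raise DegeneracyError("all weights zero: baseline system is singular")
    n = s.size
    D = _diff_matrix(n, diff_order)
    A = sp.diags(w) + lam * (D.T @ D)
    z = spsolve(A.tocsc(), w * s)
    if not np.all(np.isfinite(z)):
        raise DegeneracyError("singular baseline system (too few weighted points)")
    return z


def airpls(
    signal,
    lam: float,
    max_iter: int = 15,
    termination_ratio: float = 0.001,
    diff_order: int = 2,
) -> BaselineResult:
    """airPLS baseline of ``signal`` with smoothness penalty ``lam``."""
    s = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(s)):
        raise DomainError("signal must be finite")
    if lam <= 0:
        raise ParameterError("lam must be > 0")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    if termination_ratio <= 0:
        raise ParameterError("termination_ratio must be > 0")
    abs_s = float(np.abs(s).sum())
    n = s.size
    if abs_s == 0.0:
        return BaselineResult(
            np.zeros(n), np.ones(n), 1, True, 0.0, lam, method="airpls"
        )
    w = np.ones(n)
    z = np.zeros(n)
    ratio = np.inf
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        z = whittaker_weighted(s, w, lam, diff_order)
        d = s - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        ratio = dssn / abs_s
        if ratio < termination_ratio:
            converged = True
            break
        if t == max_iter:
            break
        w = np.zeros(n)
        w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
    return BaselineResult(z, w, t, converged, ratio, lam, method="airpls")


def savgol_smooth(signal, window_points: int = 15, poly_order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated-window polynomial fits at edges.

    Interior points take the value, at their own position, of the
    least-squares polynomial fitted over the centered window. Near the edges
    the same-order polynomial is fitted over whatever part of the window is
    available rather than padding with fabricated data.
    """
    x = np.asarray(signal, dtype=float)
    if window_points % 2 == 0:
        raise ParameterError("window_points must be odd")
    if window_points <= poly_order:
        raise ParameterError("window_points must exceed poly_order")
    if x.size < window_points:
        raise ParameterError(
            f"signal length {x.size} shorter than window ({window_points})"
        )
    out = savgol_filter(x, window_points, poly_order)
    half = window_points // 2
    idx = np.arange(x.size, dtype=float)
    for i in range(half):
        # order capped so a very short truncated window stays well-posed
        npts = i + half + 1
        order = min(poly_order, npts - 1)
        sel = slice(0, npts)
        coef = np.polynomial.Polynomial.fit(idx[sel], x[sel], order)
        out[i] = coef(idx[i])
        sel = slice(x.size - npts, x.size)
        coef = np.polynomial.Polynomial.fit(idx[sel], x[sel], order)
        out[x.size - 1 - i] = coef(idx[x.size - 1 - i])
    return out


def polynomial_baseline(spec: Spectrum1D, order: int, fit_ranges) -> BaselineResult:
    """Unweighted polynomial fit to the points inside ``fit_ranges`` only,
    evaluated over the full axis — the traditional manual-baseline pathway."""
    if order < 0:
        raise ParameterError("order must be >= 0")
    ranges = list(fit_ranges)
    if not ranges:
        raise ParameterError("fit_ranges must be nonempty")
    sel = np.zeros(len(spec), dtype=bool)
    for lo, hi in ranges:
        if lo >= hi:
            raise ParameterError(f"bad fit range ({lo}, {hi})")
        sel |= (spec.axis >= lo) & (spec.axis <= hi)
    if sel.sum() < order + 1:
        raise DegeneracyError(
            f"{int(sel.sum())} points in fit_ranges; need >= {order + 1} for order {order}"
        )
    poly = np.polynomial.Polynomial.fit(spec.axis[sel], spec.values[sel], order)
    baseline = poly(spec.axis)
    resid = float(np.abs(spec.values[sel] - baseline[sel]).sum())
    total = float(np.abs(spec.values[sel]).sum())
    return BaselineResult(
        baseline=baseline,
        weights=sel.astype(float),
        iterations=1,
        converged=True,
        residual_norm_ratio=resid / total if total > 0 else 0.0,
        lam=None,
        method="polynomial",
    )


def correct_baseline(
    spec: Spectrum1D,
    method: str = "airpls",
    *,
    lam: float = 1e5,
    max_iter: int = 15,
    termination_ratio: float = 0.001,
    order: int = 2,
    fit_ranges=None,
    presmooth: bool = False,
    sg_window: int = 15,
    sg_order: int = 3,
) -> tuple[Spectrum1D, BaselineResult]:
    """Baseline-correct a spectrum: ``corrected = spec - baseline``.

    With ``presmooth=True`` the Savitzky-Golay filter is applied to the signal
    first and the baseline is estimated from (and subtracted from) the
    smoothed signal — the pathway used for very noisy optical densities.
    """
    values = spec.values
    if presmooth:
        values = savgol_smooth(values, sg_window, sg_order)
    if method == "airpls":
        result = airpls(values, lam, max_iter=max_iter, termination_ratio=termination_ratio)
    elif method == "polynomial":
        if fit_ranges is None:
            raise ParameterError("polynomial method requires fit_ranges")
        work = Spectrum1D(spec.axis, values, role=spec.role, meta=dict(spec.meta))
        result = polynomial_baseline(work, order, fit_ranges)
    else:
        raise ParameterError(f"unknown baseline method {method!r}")
    corrected = spec.with_values(
        values - result.baseline,
        baseline_method=result.method,
        baseline_lam=result.lam,
        baseline_iterations=result.iterations,
        baseline_converged=result.converged,
        presmoothed=presmooth,
    )
    return corrected, result
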