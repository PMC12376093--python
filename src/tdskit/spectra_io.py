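"""Spectrum containers and text I/O.

Conventions used throughout the package:

* Axes are wavenumbers in cm^-1, strictly increasing. Readers normalize the
  order; all downstream code can assume it.
* 1D files are two-column delimited text (whitespace or comma), ``#`` starts a
  comment. 2D files are axis-bordered matrices: first row the probe axis,
  first column the pump axis.
* Interpolation is linear (bilinear for 2D) and never extrapolates.
* Invalid points are carried by an explicit boolean mask (True = invalid),
  matching the ``numpy.ma`` convention — never by sentinel values.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import (
    DataQualityError,
    DomainError,
    DuplicateAxisError,
    ParseError,
    RangeError,
    SizeError,
)

ROLES = frozenset({"od", "delta_od_diag", "epsilon", "pump", "tds", "generic"})

#: tolerance used when deciding whether two axes are "the same grid"
_AXIS_ATOL = 1e-9


def _as_axis(axis, min_len: int = 3) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    if a.ndim != 1:
        raise DomainError("axis must be one-dimensional")
    if a.size < min_len:
        raise SizeError(f"axis needs >= {min_len} points, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise DomainError("axis values must be finite")
    if np.any(a <= 0):
        raise DomainError("wavenumber axis must be positive")
    d = np.diff(a)
    if np.any(d == 0):
        raise DuplicateAxisError("duplicate wavenumber on axis")
    if np.any(d < 0):
        raise DomainError("axis must be strictly increasing")
    return a


@dataclass
class Spectrum1D:
    """A wavenumber axis with one value per point.

    ``role`` tags the physical meaning of the values: linear optical density
    (``od``, dimensionless), 2D-diagonal magnitude (``delta_od_diag``),
    extinction coefficient (``epsilon``, M^-1 cm^-1), pump intensity
    (``pump``, arbitrary), transition dipole strength (``tds``, D^2) or
    ``generic``.
    """

    axis: np.ndarray
    values: np.ndarray
    role: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _as_axis(self.axis)
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.axis.shape:
            raise SizeError("values must have the same length as the axis")
        if not np.all(np.isfinite(v)):
            raise DomainError("values must be finite (use a mask for missing points)")
        self.values = v
        if self.role not in ROLES:
            raise DomainError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return self.axis.size

    def with_values(self, values, role: str | None = None, **meta) -> "Spectrum1D":
        """Return a copy with new values (same axis), merging ``meta``."""
        return Spectrum1D(
            self.axis.copy(),
            values,
            role if role is not None else self.role,
            {**self.meta, **meta},
        )


@dataclass
class MaskedSpectrum1D:
    """As :class:`Spectrum1D` plus a validity mask (True = invalid point).

    Operations that combine masked spectra propagate masks: a point invalid
    in any operand is invalid in the result.
    """

    axis: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    role: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _as_axis(self.axis)
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != self.axis.shape or m.shape != self.axis.shape:
            raise SizeError("values and mask must match the axis length")
        if not np.all(np.isfinite(v)):
            raise DomainError("values must be finite (masked points carry 0.0)")
        self.values = v
        self.mask = m
        if self.role not in ROLES:
            raise DomainError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return self.axis.size

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())


@dataclass
class Spectrum2D:
    """A pump x probe ΔOD surface (axes in cm^-1, signal dimensionless)."""

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump_axis = _as_axis(self.pump_axis, min_len=2)
        self.probe_axis = _as_axis(self.probe_axis, min_len=2)
        s = np.asarray(self.signal, dtype=float)
        if s.shape != (self.pump_axis.size, self.probe_axis.size):
            raise SizeError(
                f"signal shape {s.shape} does not match axes "
                f"({self.pump_axis.size}, {self.probe_axis.size})"
            )
        if not np.all(np.isfinite(s)):
            raise DomainError("2D signal must be finite")
        self.signal = s


# ---------------------------------------------------------------------------
# file I/O


def _tokenize(line: str) -> list[str]:
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def read_spectrum1d(path, role: str = "generic") -> Spectrum1D | MaskedSpectrum1D:
    """Read a two-column text spectrum, sorted ascending by wavenumber.

    Rows whose value column is empty (or absent) are read as masked points and
    the result is a :class:`MaskedSpectrum1D`; otherwise a plain
    :class:`Spectrum1D` is returned.
    """
    axis: list[float] = []
    values: list[float] = []
    mask: list[bool] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _tokenize(line)
            if len(tokens) == 2 and tokens[1] == "":
                tokens = tokens[:1]
            if len(tokens) not in (1, 2):
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}")
            try:
                w = float(tokens[0])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad wavenumber {tokens[0]!r}") from None
            if len(tokens) == 1:
                axis.append(w)
                values.append(0.0)
                mask.append(True)
                continue
            try:
                v = float(tokens[1])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad value {tokens[1]!r}") from None
            axis.append(w)
            values.append(v)
            mask.append(False)
    if len(axis) < 3:
        raise SizeError(f"{path}: spectrum needs >= 3 points, got {len(axis)}")
    a = np.asarray(axis)
    order = np.argsort(a, kind="stable")
    a = a[order]
    v = np.asarray(values)[order]
    m = np.asarray(mask)[order]
    if np.any(np.diff(a) == 0):
        raise DuplicateAxisError(f"{path}: duplicate wavenumber on axis")
    meta = {"source": str(path)}
    if m.any():
        return MaskedSpectrum1D(a, v, m, role=role, meta=meta)
    return Spectrum1D(a, v, role=role, meta=meta)


def write_spectrum1d(spec: Spectrum1D | MaskedSpectrum1D, path) -> None:
    """Write a two-column text spectrum with a ``#`` header.

    Masked points are written as rows with an empty value column; the header
    documents the convention.
    """
    mask = getattr(spec, "mask", None)
    lines = ["# tdskit spectrum v1", f"# role: {spec.role}"]
    for k, v in spec.meta.items():
        lines.append(f"# meta {k}: {v}")
    if mask is not None and np.any(mask):
        lines.append("# masked points: value column left empty")
    lines.append("# columns: wavenumber_cm-1\tvalue")
    for i, (w, v) in enumerate(zip(spec.axis, spec.values)):
        if mask is not None and mask[i]:
            lines.append(f"{w:.12g}\t")
        else:
            lines.append(f"{w:.12g}\t{v:.12g}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum2d(path) -> Spectrum2D:
    """Read an axis-bordered matrix file (first row probe axis, first column
    pump axis); axes are sorted ascending with rows/columns permuted along."""
    rows: list[list[str]] = []
    linenos: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(_tokenize(line))
            linenos.append(lineno)
    if len(rows) < 2:
        raise ParseError(f"{path}: matrix file needs a probe-axis row and data rows")
    header = rows[0]
    body = rows[1:]
    width = len(body[0])
    for r, row in enumerate(body):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {linenos[1 + r]}: ragged row ({len(row)} cells, expected {width})"
            )
    # the corner cell is either absent, empty, or a non-numeric label
    if len(header) == width:
        corner = header[0]
        try:
            float(corner)
        except ValueError:
            header = header[1:]
        else:
            raise ParseError(f"{path}: corner cell must be empty or a label, got {corner!r}")
    elif len(header) != width - 1:
        raise ParseError(f"{path}: probe-axis row has {len(header)} cells, expected {width - 1}")

    def _cell(tok: str, i: int, j: int) -> float:
        try:
            return float(tok)
        except ValueError:
            raise ParseError(f"{path}: non-numeric cell {tok!r} at row {i}, column {j}") from None

    probe = np.array([_cell(t, 0, j + 1) for j, t in enumerate(header)])
    pump = np.array([_cell(row[0], i + 1, 0) for i, row in enumerate(body)])
    signal = np.array(
        [[_cell(tok, i + 1, j + 1) for j, tok in enumerate(row[1:])] for i, row in enumerate(body)]
    )
    pi = np.argsort(pump, kind="stable")
    qi = np.argsort(probe, kind="stable")
    return Spectrum2D(pump[pi], probe[qi], signal[np.ix_(pi, qi)], meta={"source": str(path)})


def write_spectrum2d(spec2d: Spectrum2D, path) -> None:
    """Write an axis-bordered matrix file readable by :func:`read_spectrum2d`."""
    lines = ["# tdskit 2D spectrum v1 (pump rows x probe columns, ΔOD cells)"]
    lines.append("pump\\probe\t" + "\t".join(f"{q:.12g}" for q in spec2d.probe_axis))
    for p, row in zip(spec2d.pump_axis, spec2d.signal):
        lines.append(f"{p:.12g}\t" + "\t".join(f"{v:.12g}" for v in row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# axis operations


def _require_inside(points: np.ndarray, lo: float, hi: float, what: str) -> None:
    span = hi - lo
    tol = _AXIS_ATOL * max(abs(lo), abs(hi), span)
    if points.min() < lo - tol or points.max() > hi + tol:
        raise RangeError(
            f"{what}: requested [{points.min():g}, {points.max():g}] outside "
            f"data range [{lo:g}, {hi:g}] (no extrapolation)"
        )


def resample_to_axis(spec: Spectrum1D, target_axis) -> Spectrum1D:
    """Linear interpolation of ``spec`` onto ``target_axis`` (no extrapolation)."""
    target = _as_axis(target_axis)
    _require_inside(target, spec.axis[0], spec.axis[-1], "resample_to_axis")
    vals = np.interp(target, spec.axis, spec.values)
    return Spectrum1D(target, vals, role=spec.role, meta={**spec.meta, "resampled": True})


def common_axis(a: Spectrum1D, b: Spectrum1D) -> None:
    """Raise :class:`RangeError` unless the two spectra share a grid."""
    if len(a) != len(b) or not np.allclose(a.axis, b.axis, rtol=0, atol=_AXIS_ATOL * a.axis[-1]):
        raise RangeError("spectra are not on a common axis; resample_to_axis first")


def extract_diagonal(
    spec2d: Spectrum2D,
    out_axis="probe",
    mixed_sign_tol: float = 0.01,
) -> Spectrum1D:
    """Diagonal slice ΔOD(ω, ω) of a 2D IR surface, returned as magnitudes.

    Diagonal fundamentals in 2D IR are bleaches, so files may carry either
    sign; the slice is rectified to ``|ΔOD|``. If the slice mixes positive and
    negative values beyond ``mixed_sign_tol`` of its peak amplitude the sign
    convention is ambiguous and a :class:`DataQualityError` is raised.
    """
    if isinstance(out_axis, str):
        if out_axis != "probe":
            raise DomainError("out_axis must be an array or 'probe'")
        lo = max(spec2d.pump_axis[0], spec2d.probe_axis[0])
        hi = min(spec2d.pump_axis[-1], spec2d.probe_axis[-1])
        pts = spec2d.probe_axis[(spec2d.probe_axis >= lo) & (spec2d.probe_axis <= hi)]
        if pts.size < 3:
            raise RangeError("pump and probe ranges overlap in fewer than 3 probe points")
    else:
        pts = _as_axis(out_axis)
        _require_inside(pts, spec2d.pump_axis[0], spec2d.pump_axis[-1], "extract_diagonal (pump)")
        _require_inside(pts, spec2d.probe_axis[0], spec2d.probe_axis[-1], "extract_diagonal (probe)")
    interp = RegularGridInterpolator(
        (spec2d.pump_axis, spec2d.probe_axis), spec2d.signal, method="linear", bounds_error=False,
        fill_value=None,
    )
    v = interp(np.column_stack([pts, pts]))
    vmax = np.max(np.abs(v))
    if vmax > 0:
        has_pos = np.any(v > mixed_sign_tol * vmax)
        has_neg = np.any(v < -mixed_sign_tol * vmax)
        if has_pos and has_neg:
            raise DataQualityError(
                "diagonal slice mixes signs beyond tolerance; check the sign convention"
            )
    return Spectrum1D(
        pts, np.abs(v), role="delta_od_diag", meta={**spec2d.meta, "diagonal": True}
    )


def transmission_to_od(sample_intensity: Spectrum1D, reference_intensity: Spectrum1D) -> Spectrum1D:
    """OD = -log10(sample / reference), pointwise, on a common axis."""
    common_axis(sample_intensity, reference_intensity)
    s = sample_intensity.values
    r = reference_intensity.values
    if np.any(s <= 0) or np.any(r <= 0):
        raise DomainError("transmission intensities must be strictly positive")
    return Spectrum1D(
        sample_intensity.axis.copy(),
        -np.log10(s / r),
        role="od",
        meta={**sample_intensity.meta, "from_transmission": True},
    )


def od_to_transmission(od: Spectrum1D, reference_intensity: Spectrum1D) -> Spectrum1D:
    """Inverse of :func:`transmission_to_od` (sample = reference * 10**-OD)."""
    common_axis(od, reference_intensity)
    if np.any(reference_intensity.values <= 0):
        raise DomainError("reference intensity must be strictly positive")
    return Spectrum1D(
        od.axis.copy(),
        reference_intensity.values * 10.0 ** (-od.values),
        role="generic",
        meta=dict(od.meta),
    )


def subtract_solvent(
    sample_od: Spectrum1D, solvent_od: Spectrum1D, scale: float = 1.0
) -> Spectrum1D:
    """Subtract a (scaled) solvent background spectrum from the sample OD."""
    common_axis(sample_od, solvent_od)
    return sample_od.with_values(
        sample_od.values - scale * solvent_od.values,
        solvent_subtracted=True,
        solvent_scale=scale,
        solvent_source=solvent_od.meta.get("source", "<memory>"),
    )
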