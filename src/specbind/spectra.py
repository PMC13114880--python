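"""Spectral data model, file I/O and peak analysis.

The :class:`Spectrum` is the unit carrier for every optical trace in the
package: UV-Vis absorbance and fluorescence emission on a nm axis, FT-IR
absorbance on a cm^-1 axis, and synchronous-fluorescence slices extracted
from an excitation-emission matrix (:class:`EEM`).

Peak positions are refined by a three-point parabola through the discrete
maximum and its neighbours, which resolves sub-grid peak locations (and
hence red/blue shifts of a fraction of the scan step) without assuming a
line shape.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    FlatSignalError,
    InputError,
    MaskError,
    ParseError,
    RangeError,
    SizeError,
)

SPECTRUM_KINDS = ("emission", "absorbance", "ftir", "synchronous")


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace: a strictly increasing axis plus intensities.

    Parameters
    ----------
    axis
        Positions in nm (optical) or cm^-1 (FT-IR); strictly increasing,
        at least 3 points.
    intensity
        Non-negative intensities (absorbance or fluorescence a.u.).
    kind
        One of ``emission``, ``absorbance``, ``ftir``, ``synchronous``.
    meta
        Free-form metadata (temperature_K, delta_lambda_nm, ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if self.kind not in SPECTRUM_KINDS:
            raise InputError(f"unknown spectrum kind {self.kind!r}")
        if axis.ndim != 1 or axis.shape != intensity.shape:
            raise InputError("axis and intensity must be equal-length 1-D arrays")
        if axis.size < 3:
            raise SizeError(f"spectrum needs >= 3 points, got {axis.size}")
        if not np.all(np.diff(axis) > 0):
            raise InputError("axis must be strictly increasing")

    def __len__(self):
        return self.axis.size

    def slice(self, lo: float, hi: float) -> "Spectrum":
        """Return the sub-spectrum with lo <= axis <= hi."""
        sel = (self.axis >= lo) & (self.axis <= hi)
        if sel.sum() < 3:
            raise RangeError(f"window [{lo}, {hi}] covers fewer than 3 points")
        return Spectrum(self.axis[sel], self.intensity[sel], self.kind, dict(self.meta))

    def scaled(self, factor) -> "Spectrum":
        return Spectrum(self.axis, self.intensity * factor, self.kind, dict(self.meta))


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix: intensity[i, j] at (ex_axis[i], em_axis[j])."""

    ex_axis: np.ndarray
    em_axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        ex = np.asarray(self.ex_axis, dtype=float)
        em = np.asarray(self.em_axis, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ex_axis", ex)
        object.__setattr__(self, "em_axis", em)
        object.__setattr__(self, "intensity", z)
        if not (np.all(np.diff(ex) > 0) and np.all(np.diff(em) > 0)):
            raise InputError("EEM axes must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise InputError(
                f"intensity shape {z.shape} does not match axes ({ex.size}, {em.size})"
            )


@dataclass(frozen=True)
class PeakReport:
    """Location and height of one spectral peak.

    ``shift_vs_reference`` is signed: positive means a move to larger axis
    values, i.e. a red shift on a nm axis.
    """

    position: float
    intensity: float
    shift_vs_reference: float | None = None


@dataclass(frozen=True)
class EEMPeak:
    """A local maximum of an EEM at excitation/emission coordinates (nm)."""

    ex: float
    em: float
    intensity: float


@dataclass(frozen=True)
class SynchronousConfig:
    """Wavelength offset for a synchronous slice, delta = em - ex (nm)."""

    delta_lambda: float = 60.0

    def __post_init__(self):
        if self.delta_lambda <= 0:
            raise InputError("delta_lambda must be > 0")


# ---------------------------------------------------------------------------
# file I/O  (2-column CSV/TSV with optional header and '#' comments)
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_spectrum(path, kind: str = "emission") -> "Spectrum":
    """Read a two-column (axis, intensity) CSV or TSV file.

    The delimiter (comma or tab) is sniffed, a single non-numeric header
    row is skipped, and '#' comment lines are ignored.  The axis is sorted
    ascending; duplicate axis values are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return _parse_spectrum(text, kind, name=str(path))


def _parse_spectrum(text: str, kind: str, name: str = "<string>") -> "Spectrum":
    rows = []
    delim = None
    header_skipped = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise ParseError(f"{name}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if not rows and not header_skipped:
                header_skipped = True  # one header row allowed
                continue
            raise ParseError(f"{name}:{lineno}: non-numeric row {line!r}")
    if len(rows) < 3:
        raise SizeError(f"{name}: need >= 3 data points, got {len(rows)}")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ParseError(f"{name}: duplicate axis values")
    return Spectrum(arr[:, 0], arr[:, 1], kind)


def write_spectrum(spectrum: Spectrum, path, delimiter: str = ",") -> None:
    """Write a spectrum in the same 2-column dialect ``read_spectrum`` reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# kind: {spectrum.kind}\n")
        for x, y in zip(spectrum.axis, spectrum.intensity):
            fh.write(f"{x:.12g}{delimiter}{y:.12g}\n")


def read_eem(path) -> EEM:
    """Read a wide-format EEM: first row the em axis, first column the ex axis."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ParseError(f"{path}: EEM file needs a header row and data rows")
    delim = _sniff_delimiter(lines[0])
    reader = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delim))
    try:
        em = np.array([float(v) for v in reader[0][1:]])
        ex, matrix = [], []
        for row in reader[1:]:
            ex.append(float(row[0]))
            matrix.append([float(v) for v in row[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric EEM entry ({exc})")
    return EEM(np.array(ex), em, np.array(matrix))


def write_eem(eem: EEM, path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("ex_em" + delimiter + delimiter.join(f"{v:.12g}" for v in eem.em_axis) + "\n")
        for x, row in zip(eem.ex_axis, eem.intensity):
            fh.write(f"{x:.12g}" + delimiter + delimiter.join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# peak analysis
# ---------------------------------------------------------------------------

def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three points (general, non-uniform x)."""
    coeffs = np.polyfit(x, y, 2)
    a, b, c = coeffs
    if a == 0:  # colinear; keep the grid point
        return x[1], y[1]
    xv = -b / (2 * a)
    yv = c - b * b / (4 * a)
    return float(xv), float(yv)


def peak_position(spectrum: Spectrum, window: tuple[float, float] | None = None) -> PeakReport:
    """Locate the intensity maximum, refined by 3-point parabolic interpolation.

    At an axis boundary no refinement is applied (the grid point is
    reported).  Ties between equal maxima resolve to the smallest axis
    value with a warning.
    """
    sub = spectrum if window is None else spectrum.slice(*window)
    y = sub.intensity
    x = sub.axis
    if np.all(y == y[0]):
        raise FlatSignalError("all intensities equal in window; no peak")
    i = int(np.argmax(y))  # argmax returns the first (leftmost) maximum
    if np.count_nonzero(y == y[i]) > 1:
        warnings.warn("multiple equal maxima; reporting the leftmost", stacklevel=2)
    if 0 < i < len(y) - 1:
        pos, height = _parabolic_vertex(x[i - 1 : i + 2], y[i - 1 : i + 2])
        # a degenerate parabola can place the vertex outside the bracket
        if not (x[i - 1] <= pos <= x[i + 1]):
            pos, height = float(x[i]), float(y[i])
    else:
        pos, height = float(x[i]), float(y[i])
    return PeakReport(position=pos, intensity=height)


def peak_shift(
    reference: Spectrum, test: Spectrum, window: tuple[float, float] | None = None
) -> float:
    """Signed peak displacement, test minus reference.

    Positive values are moves to larger axis positions — a red shift when
    the axis is in nm.
    """
    return peak_position(test, window).position - peak_position(reference, window).position


def eem_peaks(
    eem: EEM,
    scatter_halfwidth_nm: float = 15.0,
    min_separation: float = 10.0,
    rel_threshold: float = 0.05,
) -> list[EEMPeak]:
    """Locate EEM local maxima after masking Rayleigh scatter ridges.

    Cells with |em - ex| <= halfwidth (first order) or |em - 2*ex| <=
    halfwidth (second order) are masked out.  Remaining strict local maxima
    above ``rel_threshold`` times the unmasked maximum (a floor that
    rejects residual scatter-tail wrinkles at the mask boundary) are
    returned sorted by intensity descending; peaks closer than
    ``min_separation`` (Euclidean nm) are merged keeping the stronger.
    """
    if scatter_halfwidth_nm < 0:
        raise InputError("scatter_halfwidth_nm must be >= 0")
    ex = eem.ex_axis[:, None]
    em = eem.em_axis[None, :]
    mask = (np.abs(em - ex) <= scatter_halfwidth_nm) | (
        np.abs(em - 2 * ex) <= scatter_halfwidth_nm
    )
    if mask.all():
        raise MaskError("scatter mask covers the entire matrix")
    z = np.where(mask, -np.inf, eem.intensity)
    padded = np.full((z.shape[0] + 2, z.shape[1] + 2), -np.inf)
    padded[1:-1, 1:-1] = z
    # strict local maximum over the 8-neighbourhood
    centre = padded[1:-1, 1:-1]
    zmax = float(np.max(np.where(mask, -np.inf, eem.intensity)))
    floor = max(rel_threshold * zmax, 0.0)
    is_max = np.isfinite(centre) & (centre > floor)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = padded[1 + di : padded.shape[0] - 1 + di, 1 + dj : padded.shape[1] - 1 + dj]
            is_max &= centre > neigh
    peaks = [
        EEMPeak(float(eem.ex_axis[i]), float(eem.em_axis[j]), float(eem.intensity[i, j]))
        for i, j in zip(*np.nonzero(is_max))
    ]
    peaks.sort(key=lambda p: -p.intensity)
    kept: list[EEMPeak] = []
    for p in peaks:
        if all(np.hypot(p.ex - q.ex, p.em - q.em) >= min_separation for q in kept):
            kept.append(p)
    return kept


def extract_synchronous(eem: EEM, config: SynchronousConfig) -> Spectrum:
    """Slice an EEM along em = ex + delta_lambda.

    Intensities are linearly interpolated along the emission axis at each
    excitation wavelength whose target emission falls inside the em range.
    """
    dl = config.delta_lambda
    targets = eem.ex_axis + dl
    valid = (targets >= eem.em_axis[0]) & (targets <= eem.em_axis[-1])
    if valid.sum() < 3:
        raise RangeError(
            f"delta_lambda={dl} nm leaves fewer than 3 excitation points inside the em axis"
        )
    vals = np.array(
        [
            np.interp(t, eem.em_axis, eem.intensity[i])
            for i, t in zip(np.nonzero(valid)[0], targets[valid])
        ]
    )
    return Spectrum(
        eem.ex_axis[valid], vals, kind="synchronous", meta={"delta_lambda_nm": dl}
    )
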