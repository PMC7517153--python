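"""Shared domain types, delimited-text I/O, and path-level performance metrics.

The package works on pairs of equally sampled time series observed on an
integer time grid ``t = 1..T`` (1-based, inclusive).  A dynamic-correlation
estimate is a :class:`CorrelationPath`: a sequence of values in ``[-1, 1]``
defined from some first time point ``start`` (``start = ws`` for windowed
estimators, ``start = 1`` for DCC) up to ``T``.  Time points where an
estimator cannot produce a value (e.g. a zero-variance window) carry the
undefined marker ``NaN`` and are excluded from all metrics; they serialize
as empty cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class SeriesFormatError(ValueError):
    """Raised when a delimited input file cannot be parsed into a series."""


@dataclass(frozen=True)
class BivariateSeries:
    """A pair of equal-length univariate series on the time grid ``1..T``.

    Parameters
    ----------
    y1, y2 : array-like of shape (T,)
        The two observed series. Must be finite and of identical length
        ``T >= 2``.
    """

    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        y1 = np.asarray(self.y1, dtype=float)
        y2 = np.asarray(self.y2, dtype=float)
        if y1.ndim != 1 or y2.ndim != 1:
            raise ValueError("y1 and y2 must be one-dimensional")
        if y1.shape[0] != y2.shape[0]:
            raise ValueError(
                f"series lengths differ: {y1.shape[0]} vs {y2.shape[0]}"
            )
        if y1.shape[0] < 2:
            raise ValueError("a bivariate series needs at least T = 2 points")
        if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))):
            raise ValueError("series values must be finite (no NaN/Inf)")
        object.__setattr__(self, "y1", y1)
        object.__setattr__(self, "y2", y2)

    @property
    def T(self) -> int:
        return self.y1.shape[0]

    @property
    def times(self) -> np.ndarray:
        """1-based integer time index."""
        return np.arange(1, self.T + 1)

    def as_matrix(self) -> np.ndarray:
        """Return the series as a (T, 2) column-stacked array."""
        return np.column_stack([self.y1, self.y2])

    def centered(self) -> "BivariateSeries":
        """Return a copy with each series centered at its own mean."""
        return BivariateSeries(self.y1 - self.y1.mean(), self.y2 - self.y2.mean())


@dataclass(frozen=True)
class CorrelationPath:
    """A dynamic correlation estimate over times ``start..T``.

    ``rho[k]`` is the estimate at time ``start + k``; NaN marks time points
    where the estimate is undefined.
    """

    start: int
    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 1 or rho.size == 0:
            raise ValueError("rho must be a non-empty one-dimensional sequence")
        if int(self.start) < 1:
            raise ValueError("start must be a positive (1-based) time index")
        defined = rho[~np.isnan(rho)]
        # allow a hair of floating slack before declaring a contract violation
        if defined.size and (defined.min() < -1 - 1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("defined correlation values must lie in [-1, 1]")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "rho", np.clip(rho, -1.0, 1.0))

    @property
    def end(self) -> int:
        return self.start + self.rho.size - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of time points where the estimate is defined."""
        return ~np.isnan(self.rho)

    def value_at(self, t: int) -> float:
        if not (self.start <= t <= self.end):
            raise IndexError(f"time {t} outside path range [{self.start}, {self.end}]")
        return float(self.rho[t - self.start])

    def restrict(self, start: int) -> "CorrelationPath":
        """Return the sub-path from time ``start`` (>= self.start) to the end."""
        if start < self.start:
            raise ValueError(f"cannot extend path backwards to {start}")
        return CorrelationPath(start, self.rho[start - self.start:])


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window width ``ws`` (in samples), used by SW and WGA."""

    ws: int = 15

    def __post_init__(self) -> None:
        if int(self.ws) < 2:
            raise ValueError("window size must be at least 2")
        object.__setattr__(self, "ws", int(self.ws))

    def check_length(self, T: int) -> None:
        if T < self.ws:
            raise ValueError(f"series length T={T} shorter than window ws={self.ws}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    for cand in (",", "\t", ";"):
        if cand in first_line:
            return cand
    return None  # whitespace


def read_series(path, delimiter: str | None = None) -> BivariateSeries:
    """Read a two-column delimited text file into a :class:`BivariateSeries`.

    The first line may be a header; it is skipped if any of its first two
    fields is non-numeric.  Columns beyond the second are ignored.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SeriesFormatError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(lines[0])

    def split(ln: str) -> list[str]:
        return ln.split(delim) if delim else ln.split()

    start_row = 0
    try:
        first = split(lines[0])
        float(first[0]), float(first[1])
    except (ValueError, IndexError):
        start_row = 1  # header line
    rows = []
    for lineno, ln in enumerate(lines[start_row:], start=start_row + 1):
        fields = split(ln)
        if len(fields) < 2:
            raise SeriesFormatError(f"{path}: row {lineno} has fewer than 2 columns")
        vals = []
        for col in (0, 1):
            try:
                vals.append(float(fields[col]))
            except ValueError:
                raise SeriesFormatError(
                    f"{path}: non-numeric value {fields[col]!r} at row {lineno}, "
                    f"column {col + 1}"
                ) from None
        rows.append(vals)
    if len(rows) < 2:
        raise SeriesFormatError(f"{path}: need at least 2 data rows, got {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    return BivariateSeries(arr[:, 0], arr[:, 1])


def write_series(series: BivariateSeries, path, delimiter: str = ",") -> None:
    """Write a series as two delimited columns with full float precision."""
    with open(path, "w") as fh:
        for a, b in zip(series.y1, series.y2):
            fh.write(f"{float(a)!r}{delimiter}{float(b)!r}\n")


def write_path(
    cp: CorrelationPath,
    path,
    lower: Sequence[float] | None = None,
    upper: Sequence[float] | None = None,
) -> None:
    """Write a correlation path as CSV ``time,rho[,lower,upper]``.

    Undefined values are written as empty cells.
    """
    has_ci = lower is not None and upper is not None
    with open(path, "w") as fh:
        fh.write("time,rho,lower,upper\n" if has_ci else "time,rho\n")
        for k, t in enumerate(cp.times):
            cell = "" if np.isnan(cp.rho[k]) else repr(float(cp.rho[k]))
            if has_ci:
                lo = "" if np.isnan(lower[k]) else repr(float(lower[k]))
                hi = "" if np.isnan(upper[k]) else repr(float(upper[k]))
                fh.write(f"{t},{cell},{lo},{hi}\n")
            else:
                fh.write(f"{t},{cell}\n")


def read_path(path) -> CorrelationPath:
    """Read a CSV written by :func:`write_path` back into a path."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    body = lines[1:]  # header
    times, rhos = [], []
    for ln in body:
        fields = ln.split(",")
        times.append(int(fields[0]))
        rhos.append(float(fields[1]) if fields[1] != "" else np.nan)
    return CorrelationPath(times[0], np.asarray(rhos))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mean_abs(cp: CorrelationPath) -> float:
    """Mean of |rho_t| over the defined time points of the path."""
    vals = cp.rho[cp.defined]
    if vals.size == 0:
        raise ValueError("path has no defined values")
    return float(np.mean(np.abs(vals)))


def max_abs(cp: CorrelationPath) -> float:
    """Maximum of |rho_t| over the defined time points of the path."""
    vals = cp.rho[cp.defined]
    if vals.size == 0:
        raise ValueError("path has no defined values")
    return float(np.max(np.abs(vals)))


def mse(cp: CorrelationPath, truth: CorrelationPath) -> float:
    """Mean squared error of the path against the true correlation.

    Averaged over the path's defined time points; the truth must be defined
    at every such point.
    """
    if truth.start > cp.start or truth.end < cp.end:
        raise ValueError(
            f"truth range [{truth.start}, {truth.end}] does not cover the "
            f"path range [{cp.start}, {cp.end}]"
        )
    offset = cp.start - truth.start
    tr = truth.rho[offset : offset + cp.rho.size]
    mask = cp.defined
    if np.any(np.isnan(tr[mask])):
        raise ValueError("truth undefined at a time where the path is defined")
    if not mask.any():
        raise ValueError("path has no defined values")
    return float(np.mean((cp.rho[mask] - tr[mask]) ** 2))
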