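"""Weighted graph algorithm (WGA) for robust dynamic correlation.

Each series of length ``T`` is mapped to a fully connected graph on ``T``
nodes, one per time point.  The edge between times ``t_a`` and ``t_b``
carries the arctangent of the chord slope between the two observations,

    w_ab = arctan( (x(t_b) - x(t_a)) / (t_b - t_a) ),

and the self-weight is zero.  The arctan caps the influence of extreme
values (like the clipping functions of classical robust statistics), which
is what makes the method robust to heavy tails.  Row ``i`` of the weight
matrix is the node-``i`` weight vector ``w_i`` of length ``T``.

With a window of ``ws`` samples ending at time ``i``, the element-wise
median of ``w_{i-ws+1}, ..., w_i`` gives a median weight profile per
series; the dynamic correlation estimate at ``i`` is the Pearson
correlation between the two series' profiles.  The profiles have length
``T`` — they summarize the slope of the windowed points towards *every*
time point — so the estimate blends the local window with global structure.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .base import PairEstimator
from .core import BivariateSeries, CorrelationPath, WindowConfig

# rows of the sliding median computed per chunk to bound peak memory
_CHUNK_ROWS = 256


def edge_weight(xa: float, xb: float, ta: int, tb: int) -> float:
    """Arctan slope weight between observations at two distinct times."""
    if ta == tb:
        raise ValueError("edge weight requires two distinct time points")
    return math.atan((xb - xa) / (tb - ta))


def weight_matrix(x) -> np.ndarray:
    """Full T x T arctan-slope weight matrix of one series.

    Symmetric (numerator and denominator negate together), zero diagonal,
    entries in (-pi/2, pi/2).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a one-dimensional series with T >= 2")
    T = x.size
    t = np.arange(T, dtype=float)
    dx = x[np.newaxis, :] - x[:, np.newaxis]
    dt = t[np.newaxis, :] - t[:, np.newaxis]
    np.fill_diagonal(dt, 1.0)  # avoid 0/0; diagonal forced to zero below
    W = np.arctan(dx / dt)
    np.fill_diagonal(W, 0.0)
    return W


def median_profile(W: np.ndarray, i: int, cfg: WindowConfig = WindowConfig()) -> np.ndarray:
    """Element-wise median of the weight vectors ``w_{i-ws+1} .. w_i``.

    ``i`` is a 1-based time index with ``ws <= i <= T``.  Even window
    counts use the usual midpoint-of-central-order-statistics median.
    """
    T = W.shape[0]
    ws = cfg.ws
    if not ws <= i <= T:
        raise ValueError(f"profile time i={i} outside [ws={ws}, T={T}]")
    return np.median(W[i - ws : i], axis=0)


def _median_profiles(W: np.ndarray, ws: int) -> np.ndarray:
    """All median profiles at once: row k is the profile at time ws + k.

    Odd ws goes through a running median filter (bit-identical to the naive
    per-window ``np.median`` but much faster); even ws uses the naive route
    to keep the midpoint-of-central-order-statistics convention.
    """
    if ws % 2 == 1:
        filt = ndimage.median_filter(W, size=(ws, 1), origin=(ws // 2, 0),
                                     mode="nearest")
        return filt[ws - 1 :]  # rows below ws-1 touch the padded boundary
    windows = sliding_window_view(W, ws, axis=0)  # (T-ws+1, T, ws) view
    n = windows.shape[0]
    out = np.empty((n, W.shape[1]))
    for lo in range(0, n, _CHUNK_ROWS):
        hi = min(lo + _CHUNK_ROWS, n)
        out[lo:hi] = np.median(windows[lo:hi], axis=2)
    return out


def _rowwise_pearson(P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    c1 = P1 - P1.mean(axis=1, keepdims=True)
    c2 = P2 - P2.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", c1, c2)
    v1 = np.einsum("ij,ij->i", c1, c1)
    v2 = np.einsum("ij,ij->i", c2, c2)
    degenerate = (np.ptp(P1, axis=1) == 0) | (np.ptp(P2, axis=1) == 0)
    rho = np.full(num.shape, np.nan)
    ok = ~degenerate
    rho[ok] = num[ok] / np.sqrt(v1[ok] * v2[ok])
    np.clip(rho, -1.0, 1.0, out=rho)
    return rho


def wga_correlation(series: BivariateSeries, cfg: WindowConfig = WindowConfig()) -> CorrelationPath:
    """WGA dynamic correlation path, defined for ``t = ws .. T``.

    The Pearson correlation at each time uses all ``T`` elements of the two
    median profiles.  A constant profile (possible only for discrete or
    artifact data) yields the undefined marker NaN.
    """
    cfg.check_length(series.T)
    P1 = _median_profiles(weight_matrix(series.y1), cfg.ws)
    P2 = _median_profiles(weight_matrix(series.y2), cfg.ws)
    return CorrelationPath(cfg.ws, _rowwise_pearson(P1, P2))


class WeightedGraphCorrelation(PairEstimator):
    """Weighted-graph dynamic correlation estimator.

    Parameters
    ----------
    ws : int, default=15
        Window size (number of consecutive weight vectors whose element-wise
        median forms the profile).

    Attributes
    ----------
    path_ : CorrelationPath
        Estimated dynamic correlation, defined for ``t = ws .. T``.
    rho_ : ndarray of shape (T - ws + 1,)
    start_ : int
    """

    def __init__(self, ws: int = 15):
        self.ws = ws

    def fit(self, X, y=None):
        series = self._validate_pair(X)
        self._set_path(wga_correlation(series, WindowConfig(self.ws)))
        return self
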