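"""Sliding-window (SW) dynamic correlation.

The oldest and simplest estimator of time-varying correlation: slide a
window of ``ws`` consecutive samples along the pair and report the Pearson
correlation within each window.  The estimate at time ``t`` uses the window
``[t - ws + 1, t]`` (the window's right end sits at ``t``), so the path is
defined for ``t = ws .. T``.  Windows where either sub-series is constant
(zero standard deviation) have no defined correlation and are marked NaN.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .base import PairEstimator
from .core import BivariateSeries, CorrelationPath, WindowConfig


def sw_correlation(series: BivariateSeries, cfg: WindowConfig = WindowConfig()) -> CorrelationPath:
    """Windowed Pearson correlation path with right-aligned windows.

    Correlation is normalization-free: the (n-1) vs n convention in the
    window variance cancels in the ratio.
    """
    cfg.check_length(series.T)
    ws = cfg.ws
    w1 = sliding_window_view(series.y1, ws)
    w2 = sliding_window_view(series.y2, ws)
    c1 = w1 - w1.mean(axis=1, keepdims=True)
    c2 = w2 - w2.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", c1, c2)
    v1 = np.einsum("ij,ij->i", c1, c1)
    v2 = np.einsum("ij,ij->i", c2, c2)
    # a window is degenerate iff its values are all equal (exact check)
    degenerate = (np.ptp(w1, axis=1) == 0) | (np.ptp(w2, axis=1) == 0)
    rho = np.full(num.shape, np.nan)
    ok = ~degenerate
    rho[ok] = num[ok] / np.sqrt(v1[ok] * v2[ok])
    np.clip(rho, -1.0, 1.0, out=rho)
    return CorrelationPath(ws, rho)


class SlidingWindowCorrelation(PairEstimator):
    """Sliding-window Pearson correlation estimator.

    Parameters
    ----------
    ws : int, default=15
        Window size in samples.

    Attributes
    ----------
    path_ : CorrelationPath
        Estimated dynamic correlation, defined for ``t = ws .. T``.
    rho_ : ndarray of shape (T - ws + 1,)
    start_ : int

    Examples
    --------
    >>> import numpy as np
    >>> t = np.arange(1, 101)
    >>> X = np.column_stack([np.sin(t / 5), np.sin(t / 5) + 0.1])
    >>> SlidingWindowCorrelation(ws=15).fit(X).rho_.max()
    1.0
    """

    def __init__(self, ws: int = 15):
        self.ws = ws

    def fit(self, X, y=None):
        series = self._validate_pair(X)
        self._set_path(sw_correlation(series, WindowConfig(self.ws)))
        return self
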