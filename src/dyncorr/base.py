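"""Shared scikit-learn estimator plumbing for the correlation estimators."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .core import BivariateSeries


class PairEstimator(BaseEstimator):
    """Base class for estimators operating on a pair of time series.

    ``X`` may be a :class:`~dyncorr.core.BivariateSeries` or an array of
    shape ``(T, 2)`` whose columns are the two series.  Fitting exposes:

    - ``path_`` : the fitted :class:`~dyncorr.core.CorrelationPath`
    - ``rho_`` : the path values (NaN marks undefined points)
    - ``start_`` : 1-based time of the first path value
    """

    def _validate_pair(self, X) -> BivariateSeries:
        if isinstance(X, BivariateSeries):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(
                f"expected a (T, 2) array of paired observations, got {X.shape}"
            )
        return BivariateSeries(X[:, 0], X[:, 1])

    def _set_path(self, path) -> None:
        self.path_ = path
        self.rho_ = path.rho
        self.start_ = path.start

    def fit_transform(self, X, y=None):
        """Fit and return the estimated correlation values ``rho_``."""
        return self.fit(X).rho_
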