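"""Uncertainty quantification for WGA correlation paths.

Naive i.i.d. resampling of a time series destroys its autocovariance, so
bootstrap confidence intervals here use the multivariate linear process
bootstrap (MLPB): estimate the full covariance matrix of the stacked pair
with a tapered, positive-definite estimator, whiten the data with its
Cholesky factor, resample the (approximately) white innovations i.i.d.,
and re-color.  Block-wise application (BootCI) then yields pointwise
percentile intervals for the dynamic correlation path, and a permutation
reference turns those intervals into a pointwise test of "correlation
different from zero".  A closed-form alternative based on Fisher's
z-transformation is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import norm

from .core import BivariateSeries, CorrelationPath, WindowConfig
from .wga import wga_correlation


def trapezoid1(h: int) -> float:
    """Trapezoid taper keeping lags 0 and +-1, zeroing all others."""
    return 1.0 if abs(h) <= 1 else 0.0


def flat(h: int) -> float:
    """No tapering: every lag kept (the naive, inconsistent estimator)."""
    return 1.0


_TAPERS: dict[str, Callable[[int], float]] = {"trapezoid1": trapezoid1, "flat": flat}


@dataclass(frozen=True)
class MLPBConfig:
    """Taper choice and positive-definiteness repair for MLPB."""

    taper: str | Callable[[int], float] = "trapezoid1"
    pd_floor: float = 1e-10

    def taper_fn(self) -> Callable[[int], float]:
        fn = _TAPERS[self.taper] if isinstance(self.taper, str) else self.taper
        if fn(0) != 1.0:
            raise ValueError("taper must satisfy kappa(0) = 1")
        return fn


@dataclass(frozen=True)
class BootCIConfig:
    """Blockwise bootstrap settings: K blocks, B replicates, CI level."""

    K: int | None = None
    B: int = 500
    level: float = 0.95

    def n_blocks(self, T: int) -> int:
        # default: blocks of at least ~50 points
        K = max(1, T // 50) if self.K is None else int(self.K)
        return max(1, min(K, T))


def sample_autocov(series: BivariateSeries, h: int) -> np.ndarray:
    """Lag-h cross/auto-covariance matrix C(h) with 1/T normalization.

    ``C(h)[p, q]`` pairs series ``p`` at time ``t + h`` with series ``q`` at
    time ``t``; ``C(-h) = C(h)'`` by construction.
    """
    T = series.T
    if abs(h) >= T:
        raise ValueError(f"|h| = {abs(h)} must be smaller than T = {T}")
    C = np.vstack([series.y1 - series.y1.mean(), series.y2 - series.y2.mean()])
    if h >= 0:
        lead, lag = C[:, h:], C[:, : T - h]
    else:
        lead, lag = C[:, : T + h], C[:, -h:]
    return (lead @ lag.T) / T


def gamma_jp(
    series: BivariateSeries, cfg: MLPBConfig = MLPBConfig(), layout: str = "series"
) -> np.ndarray:
    """Tapered 2T x 2T covariance estimate of the stacked pair, repaired SPD.

    The (i, j) time-block is ``kappa(i - j) * C(i - j)``.  Assembly happens
    in time-interleaved order (block-Toeplitz); ``layout="series"`` permutes
    to the concatenated [series 1, then series 2] vector layout used by the
    resampling steps, ``layout="interleaved"`` returns the raw block form.
    A ridge ``delta * I`` (delta = pd_floor * trace / (2T), escalated x10 up
    to 6 times) is added until a Cholesky factorization succeeds.
    """
    G, _, _, _ = _gamma_and_chol(series, cfg, layout)
    return G


def _gamma_and_chol(
    series: BivariateSeries, cfg: MLPBConfig, layout: str = "series"
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Tapered covariance, its Cholesky factor, ridge used, eig-repair flag."""
    T = series.T
    kappa = cfg.taper_fn()
    M = np.zeros((T, 2, T, 2))
    idx = np.arange(T)
    for h in range(T):
        k = kappa(h)
        if k == 0.0:
            continue
        Ch = k * sample_autocov(series, h)
        j = idx[: T - h]
        M[j + h, :, j, :] = Ch
        if h > 0:
            M[j, :, j + h, :] = Ch.T
    M = M.reshape(2 * T, 2 * T)
    if layout == "series":
        perm = np.concatenate([2 * idx, 2 * idx + 1])
        M = M[np.ix_(perm, perm)]
    elif layout != "interleaved":
        raise ValueError(f"unknown layout {layout!r}")

    delta = cfg.pd_floor * np.trace(M) / (2 * T)
    ridge = 0.0
    for attempt in range(7):
        try:
            L = np.linalg.cholesky(M + ridge * np.eye(2 * T))
            if ridge:
                M = M + ridge * np.eye(2 * T)
            return M, L, ridge, False
        except np.linalg.LinAlgError:
            ridge = delta if ridge == 0.0 else ridge * 10.0
    # Tapering can leave genuinely negative eigenvalues (common for short
    # series) that no small ridge absorbs; repair by clipping the spectrum
    # at a small positive floor, which preserves the dominant structure.
    w, V = np.linalg.eigh(M)
    floor = max(delta, 1e-6 * float(np.max(w)))
    M = (V * np.maximum(w, floor)) @ V.T
    M = 0.5 * (M + M.T)
    return M, np.linalg.cholesky(M), 0.0, True


class MLPBSampler:
    """Reusable MLPB machinery for one series (factorization cached).

    Attributes
    ----------
    ridge_ : float
        Ridge added to achieve positive definiteness (0 when none needed).
    eig_repaired_ : bool
        True when the ridge escalation failed and the spectrum was clipped
        at a positive floor instead.
    """

    def __init__(self, series: BivariateSeries, cfg: MLPBConfig = MLPBConfig()):
        self.series = series
        self.cfg = cfg
        gamma, L, ridge, repaired = _gamma_and_chol(series, cfg, layout="series")
        self.gamma_ = gamma
        self._L = L
        self.ridge_ = ridge
        self.eig_repaired_ = repaired
        self._means = (series.y1.mean(), series.y2.mean())
        y_vec = np.concatenate([series.y1 - self._means[0], series.y2 - self._means[1]])
        w = solve_triangular(L, y_vec, lower=True)
        self._z = (w - w.mean()) / w.std()

    def resample(self, rng: np.random.Generator) -> BivariateSeries:
        """Draw one bootstrap pair (MLPB steps 4-6)."""
        n = self._z.size
        z_boot = self._z[rng.integers(0, n, n)]
        y_boot = self._L @ z_boot
        T = n // 2
        return BivariateSeries(
            y_boot[:T] + self._means[0], y_boot[T:] + self._means[1]
        )


def mlpb_resample(
    series: BivariateSeries,
    cfg: MLPBConfig = MLPBConfig(),
    seed: int | np.random.Generator = 0,
) -> BivariateSeries:
    """One MLPB bootstrap replicate of the pair (convenience wrapper)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MLPBSampler(series, cfg).resample(rng)


# ---------------------------------------------------------------------------
# BootCI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationBand:
    """Pointwise lower/upper confidence bounds over times start..T."""

    start: int
    lower: np.ndarray
    upper: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.lower.size)


def _block_bounds(T: int, K: int) -> list[tuple[int, int]]:
    """K adjacent blocks of size floor(T/K); the last absorbs the remainder."""
    size = T // K
    bounds = [(k * size, (k + 1) * size) for k in range(K - 1)]
    bounds.append(((K - 1) * size, T))
    return bounds


def boot_paths(
    series: BivariateSeries,
    ws: int = 15,
    mlpb: MLPBConfig = MLPBConfig(),
    boot: BootCIConfig = BootCIConfig(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """B bootstrap WGA paths from blockwise MLPB resampling.

    Returns an array of shape (B, T - ws + 1); row b is the WGA path of the
    b-th recombined bootstrap pair.
    """
    if boot.B < 2:
        raise ValueError("need at least B = 2 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = series.T
    K = boot.n_blocks(T)
    cfg = WindowConfig(ws)
    samplers = [
        MLPBSampler(BivariateSeries(series.y1[lo:hi], series.y2[lo:hi]), mlpb)
        for lo, hi in _block_bounds(T, K)
    ]
    out = np.empty((boot.B, T - ws + 1))
    for b in range(boot.B):
        pieces = [s.resample(rng) for s in samplers]
        pair = BivariateSeries(
            np.concatenate([p.y1 for p in pieces]),
            np.concatenate([p.y2 for p in pieces]),
        )
        out[b] = wga_correlation(pair, cfg).rho
    return out


def boot_ci(
    series: BivariateSeries,
    ws: int = 15,
    mlpb: MLPBConfig = MLPBConfig(),
    boot: BootCIConfig = BootCIConfig(),
    seed: int | np.random.Generator = 0,
) -> CorrelationBand:
    """Pointwise percentile confidence band for the WGA path.

    At each time the (2.5, 97.5) percentiles (at the default 95% level) of
    the B bootstrap paths are taken, with the nearest-rank convention.
    """
    paths = boot_paths(series, ws, mlpb, boot, seed)
    tail = 100.0 * (1.0 - boot.level) / 2.0
    lower = np.nanpercentile(paths, tail, axis=0, method="nearest")
    upper = np.nanpercentile(paths, 100.0 - tail, axis=0, method="nearest")
    return CorrelationBand(ws, lower, upper)


def fisher_z_ci(path: CorrelationPath, T: int, level: float = 0.95) -> CorrelationBand:
    """Closed-form pointwise band via Fisher's z-transformation.

    z_t = arctanh(rho_t) has asymptotic standard error 1/sqrt(T - 3); the
    band is symmetric in z-space and back-transformed with tanh, so it is
    asymmetric in rho-space and always inside (-1, 1).  Values at +-1 are
    clamped to +-(1 - 1e-12) before transforming.
    """
    if T < 4:
        raise ValueError("Fisher z interval needs T >= 4")
    rho = np.clip(path.rho, -(1 - 1e-12), 1 - 1e-12)
    z = np.arctanh(rho)
    half = norm.ppf(0.5 + level / 2.0) / np.sqrt(T - 3)
    return CorrelationBand(path.start, np.tanh(z - half), np.tanh(z + half))


def pointwise_significance(
    series: BivariateSeries,
    ws: int = 15,
    mlpb: MLPBConfig = MLPBConfig(),
    boot: BootCIConfig = BootCIConfig(),
    seed: int | np.random.Generator = 0,
    joint_permutation: bool = False,
) -> np.ndarray:
    """Flag times where dynamic correlation differs from zero at the 5% level.

    Builds the BootCI band for the original pair and for a randomly permuted
    pair (permutation destroys auto- and cross-correlation, so the permuted
    pair's correlation is an estimate of zero); a time point is flagged when
    the two intervals are disjoint (touching intervals are NOT flagged).
    By default each series is permuted independently; with
    ``joint_permutation`` one permutation is applied to both series (this
    preserves contemporaneous pairing and is exposed for exploration only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    band = boot_ci(series, ws, mlpb, boot, rng)
    perm1 = rng.permutation(series.T)
    perm2 = perm1 if joint_permutation else rng.permutation(series.T)
    permuted = BivariateSeries(series.y1[perm1], series.y2[perm2])
    null_band = boot_ci(permuted, ws, mlpb, boot, rng)
    return disjoint(band, null_band)


def disjoint(a: CorrelationBand, b: CorrelationBand) -> np.ndarray:
    """Elementwise strict disjointness of two bands (touching = overlap)."""
    if a.start != b.start or a.lower.size != b.lower.size:
        raise ValueError("bands cover different time ranges")
    return (a.lower > b.upper) | (b.lower > a.upper)
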