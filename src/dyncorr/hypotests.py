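"""Tests of whether an estimated correlation path is truly dynamic.

Null hypothesis: the underlying correlation is static (its variance eta^2
over time is zero); alternative: eta^2 > 0.  Two nonnegative statistics of
the estimated path over t = ws+1 .. T are supported:

- ``kappa2_med``: the sample variance of the path around its *median*
  (a robust variant of the plain variance statistic ``kappa2``),

      kappa2_med = 1/(T - ws - 1) * sum_t (rho_t - rho_med)^2.

- ``zalesky_s``: partition the path into excursion segments between
  crossings of its median; with segment point-counts I_j and peak absolute
  deviations H_j = max |rho_t - rho_med| within segment j,

      S = sum_j I_j^alpha * H_j^beta.

  The recommended defaults are alpha = 0.9, beta = 1; alternatively the
  pair is tuned on a 0.05..1.50 grid (step 0.05) by minimizing the sum of
  squared deviations of bootstrap statistics from the original statistic.

Significance comes from MLPB bootstrap replicates of the original pair:
the statistic is recomputed on each bootstrap WGA path and a 95% interval
is formed (basic bootstrap by default); the null is rejected when the
interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BivariateSeries, CorrelationPath, WindowConfig
from .uncertainty import BootCIConfig, MLPBConfig, boot_paths
from .wga import wga_correlation

GRID = np.round(np.arange(0.05, 1.5001, 0.05), 2)


@dataclass(frozen=True)
class TestResult:
    """A dynamicity test outcome."""

    statistic: float
    boot_stats: np.ndarray
    ci: tuple[float, float]
    reject: bool
    params: tuple[float, float] | None = None


def _path_values(path: CorrelationPath) -> np.ndarray:
    vals = np.asarray(path.rho, dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("test statistics require a fully defined path")
    return vals


def _restrict(path: CorrelationPath, ws: int) -> CorrelationPath:
    """Drop the first path point: statistics run over t = ws+1 .. T."""
    return path.restrict(ws + 1)


def kappa2(path: CorrelationPath) -> float:
    """Sample variance of the path around its mean (divisor n - 1)."""
    vals = _path_values(path)
    if vals.size < 2:
        raise ValueError("need at least 2 path values")
    return float(np.sum((vals - vals.mean()) ** 2) / (vals.size - 1))


def kappa_med(path: CorrelationPath) -> float:
    """Sample variance of the path around its median (divisor n - 1)."""
    vals = _path_values(path)
    if vals.size < 2:
        raise ValueError("need at least 2 path values")
    med = np.median(vals)
    return float(np.sum((vals - med) ** 2) / (vals.size - 1))


def _segments(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-excursion segments: point counts I_j and peak deviations H_j.

    A segment is a maximal run of path points on one side of the median;
    points exactly at the median attach to the preceding segment (to the
    first segment when leading).  Sum of I_j equals the number of points.
    """
    dev = vals - np.median(vals)
    sign = np.sign(dev)
    # carry the previous nonzero sign over exact-median points
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    nz = np.flatnonzero(sign)
    if nz.size == 0:  # constant path: one segment, zero deviation
        return np.array([vals.size], dtype=float), np.array([0.0])
    sign[: nz[0]] = sign[nz[0]]  # leading ties join the first segment
    change = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [sign.size]])
    I = (ends - starts).astype(float)
    H = np.array([np.max(np.abs(dev[s:e])) for s, e in zip(starts, ends)])
    return I, H


def zalesky_s(path: CorrelationPath, alpha: float = 0.9, beta: float = 1.0) -> float:
    """Excursion statistic S = sum_j I_j^alpha H_j^beta (>= 0)."""
    if alpha < 0 or beta <= 0:
        raise ValueError("need alpha >= 0 and beta > 0")
    I, H = _segments(_path_values(path))
    return float(np.sum(I**alpha * H**beta))


def _s_grid(vals: np.ndarray, alphas: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """S over a full (alpha, beta) grid, exploiting that segments are fixed."""
    I, H = _segments(vals)
    A = I[:, None] ** alphas[None, :]          # (J+1, n_alpha)
    B = np.where(H[:, None] > 0, H[:, None] ** betas[None, :], 0.0)
    return np.einsum("ja,jb->ab", A, B)        # (n_alpha, n_beta)


def tune_alpha_beta(
    path: CorrelationPath,
    boot_paths_list,
    criterion: str = "sse_vs_original",
) -> tuple[float, float]:
    """Pick (alpha, beta) on the 0.05..1.50 grid minimizing bootstrap SSE.

    ``criterion="sse_vs_original"`` minimizes sum_b (S_b - S)^2 against the
    original-path statistic; ``"boot_variance"`` minimizes the variance of
    the bootstrap statistics instead.  Ties break to the smallest alpha,
    then the smallest beta.
    """
    boot_list = list(boot_paths_list)
    if len(boot_list) < 2:
        raise ValueError("need at least 2 bootstrap paths for tuning")
    S0 = _s_grid(_path_values(path), GRID, GRID)
    Sb = np.stack([_s_grid(_path_values(bp), GRID, GRID) for bp in boot_list])
    if criterion == "sse_vs_original":
        sse = np.sum((Sb - S0[None]) ** 2, axis=0)
    elif criterion == "boot_variance":
        sse = np.var(Sb, axis=0) * len(boot_list)
    else:
        raise ValueError(f"unknown tuning criterion {criterion!r}")
    flat = int(np.argmin(sse))  # first minimum: smallest alpha, then beta
    return float(GRID[flat // GRID.size]), float(GRID[flat % GRID.size])


_STATISTICS = ("kappa_med", "kappa", "zalesky")


def bootstrap_test(
    series: BivariateSeries,
    ws: int = 15,
    statistic: str = "kappa_med",
    mlpb: MLPBConfig = MLPBConfig(),
    boot: BootCIConfig = BootCIConfig(),
    seed: int | np.random.Generator = 0,
    alpha_beta: tuple[float, float] | None = None,
    interval: str = "basic",
) -> TestResult:
    """Bootstrap test of static vs dynamic correlation on a bivariate pair.

    Computes the chosen statistic on the original WGA path and on B
    blockwise-MLPB bootstrap paths.  ``interval="basic"`` forms the basic
    bootstrap interval from centered deviations d_b = stat_b - stat,
    [stat - q97.5(d), stat - q2.5(d)]; ``interval="literal"`` uses
    [stat - q2.5(stat_b), stat + q97.5(stat_b)] (essentially never contains
    zero for a nonnegative statistic — provided for comparison only).  The
    null of static correlation is rejected when the interval excludes 0.
    For ``statistic="zalesky"``, (alpha, beta) are grid-tuned on the
    bootstrap paths unless supplied.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = _restrict(wga_correlation(series, WindowConfig(ws)), ws)
    rhos = boot_paths(series, ws, mlpb, boot, rng)
    bpaths = [_restrict(CorrelationPath(ws, row), ws) for row in rhos]

    params = None
    if statistic == "kappa_med":
        stat_fn = kappa_med
    elif statistic == "kappa":
        stat_fn = kappa2
    else:
        params = alpha_beta or tune_alpha_beta(path, bpaths)
        def stat_fn(p, _ab=params):
            return zalesky_s(p, *_ab)

    stat = stat_fn(path)
    stats_b = np.array([stat_fn(bp) for bp in bpaths])
    tail = 100.0 * (1.0 - boot.level) / 2.0
    if interval == "basic":
        d = stats_b - stat
        ci = (stat - float(np.percentile(d, 100 - tail, method="nearest")),
              stat - float(np.percentile(d, tail, method="nearest")))
    elif interval == "literal":
        ci = (stat - float(np.percentile(stats_b, tail, method="nearest")),
              stat + float(np.percentile(stats_b, 100 - tail, method="nearest")))
    else:
        raise ValueError(f"unknown interval convention {interval!r}")
    reject = not (ci[0] <= 0.0 <= ci[1])
    return TestResult(stat, stats_b, ci, reject, params)
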