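"""Bivariate dynamic conditional correlation (DCC) with GARCH(1,1) margins.

Two-step quasi-maximum-likelihood estimation:

1. Each (mean-centered) series gets a GARCH(1,1) volatility model

       sigma2_t = omega + alpha * y_{t-1}^2 + beta * sigma2_{t-1},

   fitted by maximizing the Gaussian likelihood.  Dividing the series by
   the fitted conditional standard deviations ("DE-GARCHING") gives the
   standardized residuals r_t.

2. The residuals drive a mean-reverting quasi-correlation recursion with
   first-order correlation targeting,

       Q_t = (1 - a - b) * S_hat + a * r_{t-1} r_{t-1}' + b * Q_{t-1},

   where S_hat is the sample correlation matrix of the residuals.  The
   parameters (a, b) maximize the correlation part of the likelihood.  An
   integrated variant Q_t = lam * r_{t-1} r_{t-1}' + (1 - lam) * Q_{t-1}
   drops mean reversion (useful when correlation jumps and stays).

Finally each Q_t is rescaled to a proper correlation matrix
R_t = diag(Q_t)^{-1/2} Q_t diag(Q_t)^{-1/2}; the reported path is the
off-diagonal of R_t for t = 1..T (Q_1 = S_hat).

The likelihood surfaces can be badly behaved — especially with heavy-tailed
data, where near-singular R_t make the optimization unstable.  Numerical
guard activations (determinant floors, correlation clamps) are therefore
counted and reported in a diagnostics record rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter

from .base import PairEstimator
from .core import BivariateSeries, CorrelationPath

_LOG2PI = float(np.log(2.0 * np.pi))
_DET_FLOOR = 1e-12
_RHO_CLAMP = 1.0 - 1e-10


class ConvergenceError(RuntimeError):
    """Raised when an optimization step fails to converge after restarts."""


@dataclass(frozen=True)
class GarchFit:
    """Fitted GARCH(1,1) parameters and conditional variance path."""

    omega: float
    alpha: float
    beta: float
    sigma2: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        if not (self.omega > 0 and self.alpha >= 0 and self.beta >= 0):
            raise ValueError("need omega > 0, alpha >= 0, beta >= 0")
        if self.alpha + self.beta >= 1:
            raise ValueError("covariance stationarity requires alpha + beta < 1")
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("conditional variances must be strictly positive")


@dataclass(frozen=True)
class DCCParams:
    """Correlation-dynamics parameters and the targeting matrix."""

    a: float
    b: float
    S_hat: np.ndarray
    lam: float | None = None
    variant: str = "mean-reverting"

    def __post_init__(self) -> None:
        if self.variant not in ("mean-reverting", "integrated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "mean-reverting":
            if not (self.a >= 0 and self.b >= 0 and self.a + self.b < 1):
                raise ValueError("need a >= 0, b >= 0, a + b < 1")
        else:
            if self.lam is None or not 0 < self.lam <= 1:
                raise ValueError("integrated variant needs 0 < lam <= 1")
        S = np.asarray(self.S_hat, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("S_hat must be a symmetric 2x2 matrix")
        object.__setattr__(self, "S_hat", S)


@dataclass
class DCCResult:
    """Full two-step fit: GARCH margins, correlation parameters, path."""

    garch: tuple[GarchFit, GarchFit]
    params: DCCParams
    path: CorrelationPath
    loglik: float
    diagnostics: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.garch, self.params, self.path))


# ---------------------------------------------------------------------------
# step 1: GARCH(1,1)
# ---------------------------------------------------------------------------

def garch11_filter(y, omega: float, alpha: float, beta: float, sigma2_init: float) -> np.ndarray:
    """Conditional variance recursion for t = 2..T with sigma2_1 given."""
    if sigma2_init <= 0:
        raise ValueError("sigma2_init must be positive")
    y = np.asarray(y, dtype=float)
    u = omega + alpha * y[:-1] ** 2
    # sigma2_t = u_t + beta * sigma2_{t-1} is an AR(1) filter in sigma2
    tail, _ = lfilter([1.0], [1.0, -beta], u, zi=[beta * sigma2_init])
    return np.concatenate([[sigma2_init], tail])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _garch_unpack(theta: np.ndarray) -> tuple[float, float, float]:
    omega = float(np.exp(np.clip(theta[0], -35, 35)))
    persistence = float(_sigmoid(theta[1])) * (1 - 1e-6)
    share = float(_sigmoid(theta[2]))
    return omega, persistence * share, persistence * (1 - share)


def _garch_nll(theta: np.ndarray, y: np.ndarray, s2_init: float) -> float:
    omega, alpha, beta = _garch_unpack(theta)
    s2 = garch11_filter(y, omega, alpha, beta, s2_init)
    if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
        return np.inf
    return 0.5 * float(np.sum(_LOG2PI + np.log(s2) + y**2 / s2))


_GARCH_STARTS = [(0.05, 0.90), (0.10, 0.80), (0.02, 0.50), (0.20, 0.70), (0.01, 0.05)]


def garch11_fit(y, sigma2_init: float | None = None) -> GarchFit:
    """Quasi-ML GARCH(1,1) fit of a (centered) series.

    Parameters are optimized on an unconstrained scale (log omega; logistic
    persistence/share for the alpha + beta < 1 simplex) with multiple
    starting points; sigma2_1 is pinned to the sample variance.

    Raises
    ------
    ConvergenceError
        If no start converges.
    ValueError
        For degenerate (constant) input.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 20:
        raise ValueError("GARCH(1,1) fitting needs a 1-d series with T >= 20")
    v = float(np.var(y))
    if v == 0:
        raise ValueError("cannot fit GARCH to a constant series")
    s2_init = v if sigma2_init is None else float(sigma2_init)

    def logit(p):
        return np.log(p / (1 - p))

    best = None
    for a0, b0 in _GARCH_STARTS:  # later starts only reached on failure
        p0 = a0 + b0
        theta0 = np.array([np.log(v * (1 - p0)), logit(p0), logit(a0 / p0)])
        res = minimize(_garch_nll, theta0, args=(y, s2_init), method="L-BFGS-B")
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("GARCH(1,1) optimization failed from all starts")
    if not best.success:
        # polish with a derivative-free pass before giving up
        res = minimize(_garch_nll, best.x, args=(y, s2_init), method="Nelder-Mead")
        if np.isfinite(res.fun) and res.fun <= best.fun:
            best = res
        if not (best.success and np.isfinite(best.fun)):
            raise ConvergenceError("GARCH(1,1) optimization did not converge")
    omega, alpha, beta = _garch_unpack(best.x)
    sigma2 = garch11_filter(y, omega, alpha, beta, s2_init)
    return GarchFit(omega, alpha, beta, sigma2, loglik=-float(best.fun))


def degarch(series: BivariateSeries, fits: tuple[GarchFit, GarchFit]) -> np.ndarray:
    """Standardized residuals r_{i,t} = (y_{i,t} - mean_i) / sigma_{i,t}.

    Returns an array of shape (2, T).
    """
    c = series.centered()
    out = np.empty((2, series.T))
    for i, (y, fit) in enumerate(zip((c.y1, c.y2), fits)):
        sigma = np.sqrt(fit.sigma2)
        if np.any(sigma == 0):
            raise ValueError("zero conditional standard deviation in DE-GARCHING")
        out[i] = y / sigma
    return out


# ---------------------------------------------------------------------------
# step 2: quasi-correlation recursion
# ---------------------------------------------------------------------------

def _q_paths(r: np.ndarray, a: float, b: float, intercept: np.ndarray, Q1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the scalar recursions for q11, q12, q22 (t = 1..T)."""
    r1, r2 = r
    comps = []
    for x, c, q1 in (
        (r1 * r1, intercept[0, 0], Q1[0, 0]),
        (r1 * r2, intercept[0, 1], Q1[0, 1]),
        (r2 * r2, intercept[1, 1], Q1[1, 1]),
    ):
        u = c + a * x[:-1]
        tail, _ = lfilter([1.0], [1.0, -b], u, zi=[b * q1])
        comps.append(np.concatenate([[q1], tail]))
    return tuple(comps)


def dcc_recursion(r: np.ndarray, params: DCCParams, Q_init: np.ndarray | None = None) -> CorrelationPath:
    """Correlation path from the quasi-correlation recursion.

    ``r`` holds the standardized residual pair, shape (2, T).  The
    recursion uses r_{t-1} (information up to t-1); rho_1 comes from Q_1
    (= S_hat unless ``Q_init`` is given).  Each Q_t is rescaled to unit
    diagonal, so every reported value lies in [-1, 1].
    """
    r = np.asarray(r, dtype=float)
    Q1 = params.S_hat if Q_init is None else np.asarray(Q_init, dtype=float)
    if params.variant == "integrated":
        a, b = params.lam, 1.0 - params.lam
        intercept = np.zeros((2, 2))
    else:
        a, b = params.a, params.b
        intercept = (1.0 - a - b) * params.S_hat
    q11, q12, q22 = _q_paths(r, a, b, intercept, Q1)
    denom = q11 * q22
    bad = ~(denom > 1e-300)
    if bad.any():
        t_bad = int(np.argmax(bad)) + 1
        raise np.linalg.LinAlgError(
            f"quasi-correlation matrix numerically singular at t={t_bad}"
        )
    rho = np.clip(q12 / np.sqrt(denom), -1.0, 1.0)
    return CorrelationPath(1, rho)


def _dcc_nll(ab: tuple[float, float], r: np.ndarray, S: np.ndarray, diagnostics: dict | None = None) -> float:
    """Negative correlation log-likelihood L2 at (a, b)."""
    a, b = ab
    intercept = (1.0 - a - b) * S
    q11, q12, q22 = _q_paths(r, a, b, intercept, S)
    denom = q11 * q22
    if np.any(~(denom > 0)) or not np.all(np.isfinite(denom)):
        return np.inf
    rho = q12 / np.sqrt(denom)
    n_clamp = int(np.sum(np.abs(rho) > _RHO_CLAMP))
    rho = np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)
    det = 1.0 - rho**2
    n_floor = int(np.sum(det < _DET_FLOOR))
    det = np.maximum(det, _DET_FLOOR)
    if diagnostics is not None:
        diagnostics["rho_clamped"] += n_clamp
        diagnostics["det_floored"] += n_floor
    r1, r2 = r
    quad = (r1**2 - 2.0 * rho * r1 * r2 + r2**2) / det
    return 0.5 * float(np.sum(np.log(det) + quad - (r1**2 + r2**2)))


def _ab_unpack(theta: np.ndarray) -> tuple[float, float]:
    persistence = float(_sigmoid(theta[0])) * (1 - 1e-6)
    share = float(_sigmoid(theta[1]))
    return persistence * share, persistence * (1 - share)


_DCC_STARTS = [(0.05, 0.90), (0.02, 0.95), (0.10, 0.80), (0.01, 0.50), (0.30, 0.40)]


def _fit_ab(r: np.ndarray, S: np.ndarray, diagnostics: dict) -> tuple[float, float, float]:
    def nll(theta):
        return _dcc_nll(_ab_unpack(theta), r, S)

    def logit(p):
        return np.log(p / (1 - p))

    best = None
    for a0, b0 in _DCC_STARTS:  # later starts only reached on failure
        p0 = a0 + b0
        theta0 = np.array([logit(p0), logit(a0 / p0)])
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("DCC (a, b) optimization failed from all starts")
    a, b = _ab_unpack(best.x)
    # recompute at the optimum once, with guard accounting switched on
    final = _dcc_nll((a, b), r, S, diagnostics)
    return a, b, -final


def _fit_lambda(r: np.ndarray, S: np.ndarray, diagnostics: dict) -> tuple[float, float]:
    def nll(theta):
        lam = float(_sigmoid(theta)) * (1 - 1e-6) + 1e-9
        intercept = np.zeros((2, 2))
        q11, q12, q22 = _q_paths(r, lam, 1 - lam, intercept, S)
        denom = q11 * q22
        if np.any(~(denom > 0)):
            return np.inf
        rho = np.clip(q12 / np.sqrt(denom), -_RHO_CLAMP, _RHO_CLAMP)
        det = np.maximum(1.0 - rho**2, _DET_FLOOR)
        r1, r2 = r
        quad = (r1**2 - 2.0 * rho * r1 * r2 + r2**2) / det
        return 0.5 * float(np.sum(np.log(det) + quad - (r1**2 + r2**2)))

    best = None
    for lam0 in (0.02, 0.05, 0.2, 0.5):
        theta0 = np.array([np.log(lam0 / (1 - lam0))])
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("integrated-DCC lambda optimization failed")
    lam = float(_sigmoid(best.x[0])) * (1 - 1e-6) + 1e-9
    return lam, -float(best.fun)


def dcc_fit(
    series: BivariateSeries,
    variant: str = "mean-reverting",
    lam: float | None = None,
) -> DCCResult:
    """Two-step quasi-ML DCC fit of a bivariate series.

    Step 1 fits a GARCH(1,1) per centered series and de-garches; step 2
    targets S_hat at the residual sample correlation and maximizes the
    correlation likelihood over (a, b) (or lam for the integrated variant,
    unless a fixed ``lam`` is supplied).  ``result.diagnostics`` counts the
    numerical guard activations encountered at the optimum — persistent
    clamping (a flat |rho| near 1) signals the instability seen on
    heavy-tailed data.
    """
    diagnostics = {"rho_clamped": 0, "det_floored": 0}
    g1 = garch11_fit(series.y1 - series.y1.mean())
    g2 = garch11_fit(series.y2 - series.y2.mean())
    r = degarch(series, (g1, g2))
    T = series.T
    S = (r @ r.T) / T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)

    if variant == "integrated":
        if lam is None:
            lam_hat, l2 = _fit_lambda(r, S, diagnostics)
        else:
            lam_hat, l2 = float(lam), np.nan
        params = DCCParams(a=0.0, b=0.0, S_hat=S, lam=lam_hat, variant="integrated")
    elif variant == "mean-reverting":
        a, b, l2 = _fit_ab(r, S, diagnostics)
        params = DCCParams(a=a, b=b, S_hat=S)
    else:
        raise ValueError(f"unknown DCC variant {variant!r}")

    path = dcc_recursion(r, params)
    total = g1.loglik + g2.loglik + (l2 if np.isfinite(l2) else 0.0)
    return DCCResult((g1, g2), params, path, loglik=total, diagnostics=diagnostics)


class DCCCorrelation(PairEstimator):
    """DCC-GARCH dynamic correlation estimator (two-step QMLE).

    Parameters
    ----------
    variant : {"mean-reverting", "integrated"}, default="mean-reverting"
    lam : float or None
        Fixed smoothing weight for the integrated variant; estimated from
        the data when None.

    Attributes
    ----------
    path_, rho_, start_ : fitted correlation path (start = 1).
    garch_fits_ : (GarchFit, GarchFit)
    params_ : DCCParams
    diagnostics_ : dict of numerical-guard activation counts.
    """

    def __init__(self, variant: str = "mean-reverting", lam: float | None = None):
        self.variant = variant
        self.lam = lam

    def fit(self, X, y=None):
        series = self._validate_pair(X)
        result = dcc_fit(series, variant=self.variant, lam=self.lam)
        self.garch_fits_ = result.garch
        self.params_ = result.params
        self.diagnostics_ = result.diagnostics
        self.loglik_ = result.loglik
        self._set_path(result.path)
        return self
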