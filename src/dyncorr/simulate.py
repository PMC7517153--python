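"""Synthetic bivariate series with a prescribed time-varying correlation.

At every time ``t`` the pair is drawn (independently across ``t``) with
location (0, 0) and scale matrix

    Sigma(t) = [[2,            sqrt(6) p(t)],
                [sqrt(6) p(t), 3           ]],

so that the implied correlation is exactly ``p(t)`` (sqrt(2 * 3) = sqrt(6)).
Three designs for ``p(t)`` cover the cases of interest:

- ``D1``   : p(t) = 0 — a static null, used to measure spurious dynamics.
- ``D2a/b``: p(t) = sin(t / Delta), Delta = 1024 / 2^k with k = 3 (a) or
  4 (b) — slowly varying correlation; T = 600.
- ``D3a/b``: p(t) = exp(-(t - 250)^2 / (2 (15 k)^2)), k = 3 (a) or 4 (b) —
  a unit-amplitude Gaussian bump, i.e. a rapid change near t = 250; T = 600.

Two innovation distributions: ``normal`` (bivariate Gaussian with covariance
Sigma(t)) and ``cauchy`` (elliptical bivariate Cauchy: a Gaussian pair
divided by an independent half-normal scalar, i.e. a bivariate t with 1
degree of freedom).  Cauchy draws follow the convention of the standard
bivariate-Cauchy generators: a *unit* scale matrix ``[[1, p(t)], [p(t), 1]]``
(the implied correlation parameter is still exactly ``p(t)``; a Cauchy has
no covariance, so the Gaussian marginal scales do not carry over).  Cauchy
values are clipped element-wise to ``[-clip, clip]`` (default 50), mimicking
bounded recording equipment while keeping plenty of extreme values.  The
clip bound interacts with the scale, so this convention is load-bearing for
the heavy-tail benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BivariateSeries, CorrelationPath

DESIGNS = ("D1", "D2a", "D2b", "D3a", "D3b")
_DEFAULT_T = {"D1": 300, "D2a": 600, "D2b": 600, "D3a": 600, "D3b": 600}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: design, distribution, length, seed, clip."""

    design: str = "D1"
    dist: str = "normal"
    T: int | None = None
    seed: int = 0
    clip: float = 50.0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        if self.dist not in ("normal", "cauchy"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        T = _DEFAULT_T[self.design] if self.T is None else int(self.T)
        if T < 2:
            raise ValueError("T must be at least 2")
        if self.clip <= 0:
            raise ValueError("clip bound must be positive")
        object.__setattr__(self, "T", T)


def _p_of_t(design: str, T: int) -> np.ndarray:
    t = np.arange(1, T + 1, dtype=float)
    if design == "D1":
        return np.zeros(T)
    if design in ("D2a", "D2b"):
        k = 3 if design == "D2a" else 4
        delta = 1024.0 / 2**k
        return np.sin(t / delta)
    k = 3 if design == "D3a" else 4
    sd = 15.0 * k
    return np.exp(-((t - 250.0) ** 2) / (2.0 * sd**2))


def true_correlation(spec: ScenarioSpec) -> CorrelationPath:
    """The designed correlation path rho(t) = p(t) for t = 1..T."""
    return CorrelationPath(1, _p_of_t(spec.design, spec.T))


def draw_pair(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[BivariateSeries, CorrelationPath]:
    """Draw one bivariate series under the scenario, with its true path.

    With ``rng`` omitted, a fresh generator seeded from ``spec.seed`` is
    used, so identical specs give bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = _p_of_t(spec.design, spec.T)
    if np.any(np.abs(p) > 1):
        raise ValueError("|p(t)| > 1: scale matrix not positive semi-definite")
    z = rng.standard_normal((2, spec.T))
    if spec.dist == "normal":
        # Cholesky of Sigma(t): y1 = sqrt(2) z1, y2 = sqrt(3)(p z1 + sqrt(1-p^2) z2)
        y1 = np.sqrt(2.0) * z[0]
        y2 = np.sqrt(3.0) * (p * z[0] + np.sqrt(1.0 - p**2) * z[1])
    else:
        # elliptical Cauchy, unit scale matrix [[1, p], [p, 1]], then clip
        g1 = z[0]
        g2 = p * z[0] + np.sqrt(1.0 - p**2) * z[1]
        denom = np.abs(rng.standard_normal(spec.T))
        y1 = np.clip(g1 / denom, -spec.clip, spec.clip)
        y2 = np.clip(g2 / denom, -spec.clip, spec.clip)
    return BivariateSeries(y1, y2), CorrelationPath(1, p)


def replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-replicate generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
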