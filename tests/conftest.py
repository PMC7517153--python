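"""Shared fixtures: replicated simulation metric sets, reused across tests.

The heavy Monte-Carlo fixtures are session-scoped so the benchmark-style
tests and the qualitative-ordering tests share one set of replicates.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyncorr import dcc_fit, max_abs, mean_abs, mse, sw_correlation, wga_correlation
from dyncorr.dcc import ConvergenceError
from dyncorr.simulate import ScenarioSpec, draw_pair, replicate_rngs, true_correlation


def _replicate_metrics(spec_kwargs, methods, R, seed, metrics=("mean_abs", "max_abs")):
    """Per-replicate scalar metrics for each method under one scenario."""
    fns = {"mean_abs": mean_abs, "max_abs": max_abs}
    out = {m: {met: [] for met in metrics} for m in methods}
    out["n_nonconverged"] = 0
    spec = ScenarioSpec(**spec_kwargs)
    truth = true_correlation(spec)
    for rng in replicate_rngs(seed, R):
        series, _ = draw_pair(spec, rng)
        for m in methods:
            try:
                if m == "sw":
                    path = sw_correlation(series)
                elif m == "wga":
                    path = wga_correlation(series)
                else:
                    path = dcc_fit(series).path
            except ConvergenceError:
                out["n_nonconverged"] += 1
                continue
            for met in metrics:
                out[m][met].append(fns[met](path) if met in fns else None)
            if "mse" in metrics:
                out[m]["mse"].append(mse(path, truth))
    return out


@pytest.fixture(scope="session")
def d1_normal_t300():
    """R=200 static-null bivariate-normal replicates at T=300, all methods."""
    return _replicate_metrics(
        dict(design="D1", dist="normal", T=300), ("sw", "wga", "dcc"), R=200, seed=11
    )


@pytest.fixture(scope="session")
def d1_normal_t150():
    return _replicate_metrics(
        dict(design="D1", dist="normal", T=150), ("sw", "wga", "dcc"), R=200, seed=12
    )


@pytest.fixture(scope="session")
def d1_cauchy_t600():
    return _replicate_metrics(
        dict(design="D1", dist="cauchy", T=600), ("sw", "wga"), R=200, seed=13
    )


@pytest.fixture(scope="session")
def d1_cauchy_t300():
    return _replicate_metrics(
        dict(design="D1", dist="cauchy", T=300), ("sw", "dcc"), R=200, seed=14
    )


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of order
    return np.random.default_rng(20240617)
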