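"""Independent reference implementations used as test oracles.

Deliberately naive: explicit loops and off-the-shelf numpy calls, no reuse
of the package's optimized code paths.
"""

import numpy as np


def brute_force_wga(y1, y2, ws):
    """All-pairs, all-windows weighted-graph correlation reference.

    Returns (profiles1, profiles2, rho) with profiles row i the median
    weight vector at right-end time ws + i.
    """

    def wmat(x):
        T = len(x)
        W = np.zeros((T, T))
        for a in range(T):
            for b in range(T):
                if a != b:
                    W[a, b] = np.arctan((x[b] - x[a]) / (b - a))
        return W

    W1, W2 = wmat(y1), wmat(y2)
    T = len(y1)
    profiles1, profiles2, rhos = [], [], []
    for i in range(ws, T + 1):  # 1-based right end
        p1 = np.median(W1[i - ws : i], axis=0)
        p2 = np.median(W2[i - ws : i], axis=0)
        profiles1.append(p1)
        profiles2.append(p2)
        rhos.append(np.corrcoef(p1, p2)[0, 1])
    return np.array(profiles1), np.array(profiles2), np.array(rhos)


def naive_sw(y1, y2, ws):
    """Independent per-window Pearson recomputation."""
    T = len(y1)
    out = []
    for t in range(ws, T + 1):
        a, b = np.asarray(y1[t - ws : t]), np.asarray(y2[t - ws : t])
        if np.all(a == a[0]) or np.all(b == b[0]):
            out.append(np.nan)
        else:
            out.append(np.corrcoef(a, b)[0, 1])
    return np.array(out)


def simulate_garch_series(omega, alpha, beta, T, rng):
    """Direct GARCH(1,1) simulation from the stationary start."""
    y = np.empty(T)
    s2 = omega / (1 - alpha - beta)
    for t in range(T):
        y[t] = np.sqrt(s2) * rng.standard_normal()
        s2 = omega + alpha * y[t] ** 2 + beta * s2
    return y
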