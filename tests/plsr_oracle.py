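"""Independent textbook NIPALS PLS1 oracle for cross-checking.

Deliberately naive: explicit loops, data-matrix deflation, no shared
code with the package implementation.  Used only by the tests.
"""

import numpy as np


def nipals_pls1_oracle(X, y, n_components):
    """Return (W, P, q, coefficients) of PLS1 on mean-centered data.

    W columns are unit-norm weight vectors; coefficients solve
    yhat = y_mean + (x - x_mean) @ B with B = W (P'W)^-1 q.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        w = w / np.sqrt(np.sum(w * w))
        t = E @ w
        tt = np.sum(t * t)
        p_a = (E.T @ t) / tt
        q_a = np.sum(f * t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a] = w
        P[:, a] = p_a
        q[a] = q_a
    B = W @ np.linalg.inv(P.T @ W) @ q
    return W, P, q, B


def loo_press_oracle(X, y, n_components):
    """Leave-one-out RMSE per component count, each fold refitted from
    scratch with the oracle above."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    sq = np.zeros(n_components)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        for a in range(1, n_components + 1):
            _, _, _, B = nipals_pls1_oracle(Xtr, ytr, a)
            pred = ytr.mean() + (X[i] - Xtr.mean(axis=0)) @ B
            sq[a - 1] += (pred - y[i]) ** 2
    return np.sqrt(sq / n)
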