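"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (double loops, SVD-based weight
extraction) and shares no code with the implementation under test.
"""
from __future__ import annotations

import numpy as np


def gra_oracle(ref, comps, rho: float, normalization: str = "none"):
    """Naive double-loop evaluation of the gray relational formulas."""

    def norm(series):
        s = [float(v) for v in series]
        if normalization == "none":
            return s
        if normalization == "mean":
            mu = sum(s) / len(s)
            return [v / mu for v in s]
        if normalization == "minmax":
            lo, hi = min(s), max(s)
            return [(v - lo) / (hi - lo) for v in s]
        raise ValueError(normalization)

    x0 = norm(ref)
    xs = [norm(c) for c in comps]
    deltas = [[abs(x0[k] - xi[k]) for k in range(len(x0))] for xi in xs]
    flat = [d for row in deltas for d in row]
    dmin, dmax = min(flat), max(flat)
    if dmax == 0:
        return [1.0] * len(xs), dmin, dmax
    grades = []
    for row in deltas:
        coeffs = [(dmin + rho * dmax) / (d + rho * dmax) for d in row]
        grades.append(sum(coeffs) / len(coeffs))
    return grades, dmin, dmax


def pls1_svd_oracle(X, y, n_components: int, scaling: str = "autoscale"):
    """PLS1 via SVD weight extraction (leading right singular vector of y'X).

    Returns (coef_original_scale, intercept, T, W).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    x_scale = np.ones(p)
    y_scale = 1.0
    if scaling == "none":
        x_mean = np.zeros(p)
        y_mean = 0.0
    if scaling == "autoscale":
        x_scale = X.std(axis=0, ddof=1)
        y_scale = y.std(ddof=1)
    Xd = (X - x_mean) / x_scale
    yd = (y - y_mean) / y_scale

    A = n_components
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        M = yd[None, :] @ Xd  # 1 x p cross-covariance
        _u, _s, vt = np.linalg.svd(M, full_matrices=False)
        w = vt[0]
        if float(w @ (Xd.T @ yd)) < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        pl = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, qa
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = y_scale * B / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return coef, intercept, T, W


def vip_oracle(W, ss):
    """Plain-loop VIP formula: sqrt(P * sum_a ss_a (w_ja/|w_a|)^2 / sum ss)."""
    W = np.asarray(W, dtype=float)
    ss = np.asarray(ss, dtype=float)
    p, A = W.shape
    total = float(ss.sum())
    out = []
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wa = W[:, a]
            acc += ss[a] * (W[j, a] / np.linalg.norm(wa)) ** 2
        out.append(float(np.sqrt(p * acc / total)))
    return np.array(out)


def finite_difference_grads(loss_fn, params, eps: float = 1e-6):
    """Central finite differences of a scalar loss over a dict of arrays."""
    grads = {}
    for key, value in params.items():
        value = np.asarray(value, dtype=float)
        g = np.zeros_like(value)
        it = np.nditer(value, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            plus = {k: np.array(v, dtype=float) for k, v in params.items()}
            minus = {k: np.array(v, dtype=float) for k, v in params.items()}
            plus[key][idx] += eps
            minus[key][idx] -= eps
            g[idx] = (loss_fn(plus) - loss_fn(minus)) / (2 * eps)
        grads[key] = g
    return grads
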