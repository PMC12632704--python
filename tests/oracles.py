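"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain scalar loops directly from the model
definitions (GMM posterior, CPD M-step linear system, point-to-triangle
geometry, weighted quantiles) and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


# ----------------------------------------------------------------------
# GMM / CPD
# ----------------------------------------------------------------------

def brute_posterior(X, TY, sigma2, w=0.0, gamma=0.0):
    """E-step posterior by scalar loops: (P, outlier_mass)."""
    X = np.asarray(X, float)
    TY = np.asarray(TY, float)
    N, M = len(X), len(TY)
    P = np.zeros((M, N))
    out = np.zeros(N)
    uniform = (2.0 * math.pi * sigma2) ** 1.5 * (w / (1.0 - w)) * (M / N)
    for n in range(N):
        nums = []
        for m in range(M):
            d = math.dist(X[n], TY[m])
            nums.append(math.exp(-d * d / (2.0 * sigma2)) * math.exp(-gamma * d))
        denom = sum(nums) + uniform
        for m in range(M):
            P[m, n] = nums[m] / denom
        out[n] = uniform / denom
    return P, out


def brute_sigma2(X, TY, P):
    X = np.asarray(X, float)
    TY = np.asarray(TY, float)
    num = 0.0
    den = 0.0
    for n in range(len(X)):
        for m in range(len(TY)):
            d = math.dist(X[n], TY[m])
            num += P[m, n] * d * d
            den += P[m, n]
    return max(num / (3.0 * den), 1e-10)


def brute_gram(Y0, beta):
    Y0 = np.asarray(Y0, float)
    M = len(Y0)
    G = np.zeros((M, M))
    for i in range(M):
        for j in range(M):
            d = math.dist(Y0[i], Y0[j])
            G[i, j] = math.exp(-d * d / (2.0 * beta * beta))
    return G


def standard_cpd(X, Y0, alpha=1.0, beta=5.0, w=0.0, n_iter=20):
    """Classic nonrigid CPD EM trajectory (no distance decay).

    Mirrors the canonical update order — E-step at the current transform,
    solve for W, move the points, update sigma^2 at the new positions —
    and records sigma^2 and T(Y) per iteration.
    """
    X = np.asarray(X, float)
    Y0 = np.asarray(Y0, float)
    M, N = len(Y0), len(X)
    G = brute_gram(Y0, beta)
    s2 = 0.0
    for n in range(N):
        for m in range(M):
            s2 += math.dist(X[n], Y0[m]) ** 2
    sigma2 = max(s2 / (3.0 * M * N), 1e-10)
    TY = Y0.copy()
    hist_sigma2 = []
    hist_TY = []
    hist_W = []
    for _ in range(n_iter):
        P, _ = brute_posterior(X, TY, sigma2, w=w, gamma=0.0)
        p = P.sum(axis=1)
        p = np.maximum(p, 1e-12)
        A = G + alpha * sigma2 * np.diag(1.0 / p)
        rhs = (P @ X) / p[:, None] - Y0
        W = np.linalg.solve(A, rhs)
        TY = Y0 + G @ W
        sigma2 = brute_sigma2(X, TY, P)
        hist_sigma2.append(sigma2)
        hist_TY.append(TY.copy())
        hist_W.append(W.copy())
    return hist_sigma2, hist_TY, hist_W


# ----------------------------------------------------------------------
# Geometry
# ----------------------------------------------------------------------

def closest_point_on_triangle(p, a, b, c):
    """Ericson's region-based closest point on a single triangle."""
    p, a, b, c = (np.asarray(x, float) for x in (p, a, b, c))
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    u = vc * denom
    return a + ab * v + ac * u


def brute_point_surface_distances(points, mesh):
    """Exact vertex-to-surface distances via a double loop over triangles."""
    out = []
    tris = mesh.vertices[mesh.faces]
    for p in np.asarray(points, float):
        best = math.inf
        for t in tris:
            q = closest_point_on_triangle(p, t[0], t[1], t[2])
            best = min(best, math.dist(p, q))
        out.append(best)
    return np.asarray(out)


# ----------------------------------------------------------------------
# Statistics
# ----------------------------------------------------------------------

def brute_weighted_quantile(values, q, weights):
    """Hazen-type weighted quantile by explicit cumulative positions."""
    pairs = sorted(zip(values, weights))
    v = [x for x, _ in pairs]
    w = [y for _, y in pairs]
    W = sum(w)
    pos = []
    cum = 0.0
    for wi in w:
        pos.append((cum + 0.5 * wi) / W)
        cum += wi
    if q <= pos[0]:
        return v[0]
    if q >= pos[-1]:
        return v[-1]
    for i in range(len(pos) - 1):
        if pos[i] <= q <= pos[i + 1]:
            t = (q - pos[i]) / (pos[i + 1] - pos[i])
            return v[i] + t * (v[i + 1] - v[i])
    raise AssertionError("unreachable")
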