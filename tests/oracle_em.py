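"""Brute-force reference implementation of the copula-mixture IDR.

Independent of the production module: per-point root finding for the
pseudo-value inversion (scipy brentq) and explicit per-pair loops for
the E and M steps.
"""

import math

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rankdata


def _phi(zv):
    return 0.5 * (1.0 + math.erf(zv / math.sqrt(2.0)))


def _g_cdf(zv, mu, sigma, rho, p):
    return p * _phi((zv - mu) / sigma) + (1 - p) * _phi(zv)


def _invert(u, mu, sigma, rho, p):
    lo = min(-10.0, mu - 10.0 * sigma)
    hi = max(10.0, mu + 10.0 * sigma)
    return [brentq(lambda zv: _g_cdf(zv, mu, sigma, rho, p) - ui,
                   lo, hi, xtol=1e-10) for ui in u]


def oracle_idr(scores1, scores2, mu=3.0, sigma=1.0, rho=0.9, p=0.5,
               tol=1e-6, max_iter=200):
    """Return (local_idr, global_idr) arrays."""
    x = np.asarray(scores1, float)
    y = np.asarray(scores2, float)
    n = len(x)
    u1 = rankdata(x, method="average") / (n + 1.0)
    u2 = rankdata(y, method="average") / (n + 1.0)
    last_ll = -math.inf
    w = [p] * n
    for _ in range(max_iter):
        z1 = _invert(u1, mu, sigma, rho, p)
        z2 = _invert(u2, mu, sigma, rho, p)
        ll = 0.0
        w = []
        det = 1.0 - rho * rho
        for a, b in zip(z1, z2):
            d1 = (a - mu) / sigma
            d2 = (b - mu) / sigma
            f1 = math.exp(-0.5 * (d1 * d1 - 2 * rho * d1 * d2 + d2 * d2)
                          / det) / (2 * math.pi * sigma * sigma
                                    * math.sqrt(det))
            f0 = math.exp(-0.5 * (a * a + b * b)) / (2 * math.pi)
            tot = p * f1 + (1 - p) * f0
            w.append(p * f1 / tot)
            ll += math.log(tot)
        sw = sum(w)
        p = min(max(sw / n, 1e-4), 1 - 1e-4)
        if sw > 0:
            mu = sum(wi * (a + b) for wi, a, b in zip(w, z1, z2)) \
                / (2 * sw)
            var = sum(wi * ((a - mu) ** 2 + (b - mu) ** 2)
                      for wi, a, b in zip(w, z1, z2)) / (2 * sw)
            var = max(var, 1e-6)
            sigma = math.sqrt(var)
            rho = min(max(sum(wi * (a - mu) * (b - mu)
                              for wi, a, b in zip(w, z1, z2))
                          / (var * sw), -0.999), 0.999)
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    local = np.array([1.0 - wi for wi in w])
    # running mean over ranked pairs; tie blocks share their final value
    order = sorted(range(n), key=lambda i: local[i])
    global_idr = np.empty(n)
    running = 0.0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and local[order[j + 1]] == local[order[i]]:
            j += 1
        running_sum = sum(local[order[k]] for k in range(0, j + 1))
        value = running_sum / (j + 1)
        for k in range(i, j + 1):
            global_idr[order[k]] = value
        i = j + 1
    return local, global_idr
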