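"""Independent brute-force oracles used by the test suite.

These are deliberately written in a different style from the package code
(explicit per-sample loops, textbook formulas) so that agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def wc_theta_brute(genos_a, genos_b) -> float:
    """Weir & Cockerham (1984) theta for one biallelic locus, two populations.

    ``genos_a``/``genos_b`` are lists of diploid alternate-allele counts
    (0/1/2), missing already removed.  Returns the unclamped a/(a+b+c) ratio.
    """
    pops = [list(genos_a), list(genos_b)]
    r = len(pops)
    n_i = [len(g) for g in pops]
    p_i = [sum(g) / (2 * n) for g, n in zip(pops, n_i)]
    h_i = [sum(1 for x in g if x == 1) / n for g, n in zip(pops, n_i)]

    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)

    a = (nbar / nc) * (s2 - (1 / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    denom = a + b + c
    return a / denom if denom != 0 else 0.0


def bernoulli_loglik_naive(xs, ys, predict) -> float:
    """Plain-python Bernoulli log-likelihood: sum of log p / log (1 - p)."""
    total = 0.0
    for x, y in zip(xs, ys):
        p = min(max(predict(x), 1e-9), 1 - 1e-9)
        total += math.log(p) if y == 1 else math.log(1 - p)
    return total


def gaussian_loglik_naive(xs, ys, predict, sd) -> float:
    """Plain-python Gaussian log-likelihood via the density formula."""
    total = 0.0
    for x, y in zip(xs, ys):
        mu = predict(x)
        total += -0.5 * math.log(2 * math.pi * sd * sd) - (y - mu) ** 2 / (2 * sd * sd)
    return total


def polyline_min_distance_dense(point, vertices, step_km: float = 0.001) -> float:
    """Unsigned point-to-polyline distance by dense discretisation (1 m steps)."""
    point = np.asarray(point, dtype=float)
    best = math.inf
    V = np.asarray(vertices, dtype=float)
    for a, b in zip(V[:-1], V[1:]):
        seg_len = float(np.hypot(*(b - a)))
        n = max(2, int(math.ceil(seg_len / step_km)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        pts = a[None, :] + ts[:, None] * (b - a)[None, :]
        d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1]).min()
        best = min(best, float(d))
    return best
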