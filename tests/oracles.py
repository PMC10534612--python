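"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive every quantity with literal loops over the
defining formulas, sharing no code path with the package implementation.
"""

import math

import numpy as np

from thermaffect.features import quantize


def glcm_brute_force(matrix, angle, distance, levels):
    """Direct four-index enumeration of the co-occurrence pair predicates."""
    q = quantize(matrix, levels)
    rows, cols = q.shape
    P = np.zeros((levels, levels))
    for a in range(rows):
        for b in range(cols):
            for e in range(rows):
                for f in range(cols):
                    if angle == 0:
                        hit = a == e and abs(b - f) == distance
                    elif angle == 90:
                        hit = abs(a - e) == distance and b == f
                    elif angle == 45:
                        hit = (a - e == distance and b - f == -distance) or (
                            a - e == -distance and b - f == distance
                        )
                    else:  # 135
                        hit = (a - e == distance and b - f == distance) or (
                            a - e == -distance and b - f == -distance
                        )
                    if hit:
                        P[q[a, b], q[e, f]] += 1
    return P


def texture_stats_brute_force(P):
    """Plain double-sum evaluation of the five texture statistics."""
    n = P.shape[0]
    mu_x = sum((i + 1) * P[i, j] for i in range(n) for j in range(n))
    mu_y = sum((j + 1) * P[i, j] for i in range(n) for j in range(n))
    sigma_x = np.sqrt(
        sum((i + 1 - mu_x) ** 2 * P[i, j] for i in range(n) for j in range(n))
    )
    sigma_y = np.sqrt(
        sum((j + 1 - mu_y) ** 2 * P[i, j] for i in range(n) for j in range(n))
    )
    asm = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    contrast = sum(
        k**2 * sum(P[i, j] for i in range(n) for j in range(n) if abs(i - j) == k)
        for k in range(n)
    )
    corr = (
        sum((i + 1) * (j + 1) * P[i, j] for i in range(n) for j in range(n))
        - mu_x * mu_y
    ) / (sigma_x * sigma_y)
    homog = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    dissim = sum(abs(i - j) * P[i, j] for i in range(n) for j in range(n))
    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": corr,
        "homogeneity": homog,
        "dissimilarity": dissim,
    }


def nca_probabilities_oracle(w, X, y, sigma):
    """Literal per-pair evaluation of the reference-point probabilities."""
    n, d = X.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D = sum(w[l] ** 2 * abs(X[i, l] - X[j, l]) for l in range(d))
            K[i, j] = math.exp(-D / sigma)
    p = np.zeros((n, n))
    for i in range(n):
        denom = sum(K[i, j] for j in range(n) if j != i)
        for j in range(n):
            p[i, j] = 0.0 if i == j else K[i, j] / denom
    p_i = np.array(
        [sum(p[i, j] for j in range(n) if y[j] == y[i]) for i in range(n)]
    )
    return p, p_i
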