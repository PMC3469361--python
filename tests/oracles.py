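"""Independent brute-force oracles used to validate the vectorized
statistics and the choice probabilities.

Everything here enumerates dyads/triads with explicit Python loops straight
from the definitions, deliberately sharing no code with the package
internals.
"""

import math

import numpy as np


def brute_network_statistic(name, i, x, v=None, vbar=0.0, vrange=1.0, mean_sim=0.0):
    """Effect statistic for focal actor i by direct enumeration."""
    n = x.shape[0]
    if name == "density":
        return sum(x[i, j] for j in range(n) if j != i)
    if name == "reciprocity":
        return sum(x[i, j] * x[j, i] for j in range(n) if j != i)
    if name == "transitive_triplets":
        total = 0
        for j in range(n):
            for h in range(n):
                total += x[i, j] * x[j, h] * x[i, h]
        return total
    if name == "three_cycles":
        total = 0
        for j in range(n):
            for h in range(n):
                total += x[i, j] * x[j, h] * x[h, i]
        return total
    if name == "in_degree_popularity":
        return sum(x[i, j] * sum(x[h, j] for h in range(n)) for j in range(n))
    if name == "out_degree_popularity":
        return sum(x[i, j] * sum(x[j, h] for h in range(n)) for j in range(n))
    if name == "out_degree_activity":
        return sum(x[i, j] for j in range(n)) ** 2
    if name == "ego":
        return (v[i] - vbar) * sum(x[i, j] for j in range(n))
    if name == "alter":
        return sum(x[i, j] * (v[j] - vbar) for j in range(n))
    if name == "similarity":
        return sum(
            x[i, j] * (1.0 - abs(v[i] - v[j]) / vrange - mean_sim) for j in range(n)
        )
    if name == "same":
        return sum(x[i, j] * (1 if v[i] == v[j] else 0) for j in range(n))
    raise ValueError(name)


def brute_behavior_statistic(name, i, x, z, zbar, v=None, vbar=0.0):
    zc = z[i] - zbar
    n = x.shape[0]
    if name == "linear_shape":
        return zc
    if name == "quadratic_shape":
        return zc**2
    if name == "average_alter":
        od = sum(x[i, j] for j in range(n))
        if od == 0:
            return 0.0
        return zc * sum(x[i, j] * (z[j] - zbar) for j in range(n)) / od
    if name == "covariate_effect":
        return zc * (v[i] - vbar)
    raise ValueError(name)


def softmax(values):
    m = max(values)
    w = [math.exp(u - m) for u in values]
    s = sum(w)
    return [wi / s for wi in w]


def random_digraph(rng, n, p=0.3):
    x = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(x, 0)
    return x
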