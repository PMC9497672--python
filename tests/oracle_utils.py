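"""Independent brute-force information-theory oracles for the tests.

Everything here works from the explicit joint probability table built by
counting tuples — no shared code with the package's estimators.
"""

from collections import Counter
from math import log2

import numpy as np


def joint_table(*columns):
    """Empirical joint distribution p(tuple) from aligned columns."""
    rows = list(zip(*columns))
    n = len(rows)
    return {key: count / n for key, count in Counter(rows).items()}


def bf_entropy(*columns):
    """H of the tuple variable by direct summation."""
    return -sum(p * log2(p) for p in joint_table(*columns).values() if p > 0)


def bf_mutual_information(x, y):
    """I(X;Y) = sum p(x,y) log p(x,y)/(p(x)p(y))."""
    pxy = joint_table(x, y)
    px = joint_table(x)
    py = joint_table(y)
    return sum(p * log2(p / (px[(a,)] * py[(b,)])) for (a, b), p in pxy.items())


def bf_conditional_entropy(x, y):
    return bf_entropy(x, y) - bf_entropy(y)


def bf_conditional_mutual_information(x, y, z):
    """I(X;Y|Z) = sum p(x,y,z) log p(x,y|z) / (p(x|z) p(y|z))."""
    pxyz = joint_table(x, y, z)
    pxz = joint_table(x, z)
    pyz = joint_table(y, z)
    pz = joint_table(z)
    total = 0.0
    for (a, b, c), p in pxyz.items():
        num = (p / pz[(c,)])
        den = (pxz[(a, c)] / pz[(c,)]) * (pyz[(b, c)] / pz[(c,)])
        total += p * log2(num / den)
    return total


def bf_interaction_information(x, y, z):
    return bf_mutual_information(x, y) - bf_conditional_mutual_information(x, y, z)


def random_table(rng, n_rows=50, n_cols=3, n_levels=3):
    """Seeded random categorical columns for property sweeps."""
    return [rng.integers(0, n_levels, size=n_rows) for _ in range(n_cols)]


def random_network(rng, n):
    """A random MI-transfer network (symmetric U, zero diagonal, b >= 0)."""
    from mitn import MITransferNetwork

    U = rng.uniform(0.0, 0.6, size=(n, n))
    U = (U + U.T) / 2.0
    np.fill_diagonal(U, 0.0)
    b = rng.uniform(0.0, 1.0, size=n)
    return MITransferNetwork(U=U, b=b, names=tuple(f"f{i}" for i in range(n)),
                             big_M=float(b.sum()))
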