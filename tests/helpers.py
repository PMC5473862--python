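"""Independent oracles and network factories shared across tests.

The relevance-score oracle here deliberately avoids the package's
matrix-product implementation: walk probabilities are accumulated by
explicit enumeration of every typed walk (itertools.product over all
intermediate node choices), with transition probabilities recomputed from
adjacency rows on the fly.  It is exact and exponential in path length —
fine for the tiny networks it is used on.
"""

from __future__ import annotations

import itertools

import numpy as np

from heteropath.netio import HeteroNetwork


def walk_distribution(net: HeteroNetwork, types, start_pos: int) -> np.ndarray:
    """Probability over end-type nodes of a walk from ``start_pos`` along ``types``."""
    if len(types) == 1:
        out = np.zeros(net.n_nodes(types[0]))
        out[start_pos] = 1.0
        return out
    out = np.zeros(net.n_nodes(types[-1]))
    sizes = [net.n_nodes(t) for t in types[1:]]
    for combo in itertools.product(*(range(s) for s in sizes)):
        nodes = (start_pos, *combo)
        prob = 1.0
        for a, b, i, j in zip(types, types[1:], nodes, nodes[1:]):
            adj = net.relation(a, b)
            row_sum = adj[i].sum()
            if row_sum == 0:
                prob = 0.0
                break
            prob *= adj[i, j] / row_sum
        out[nodes[-1]] += prob
    return out


def hetesim_oracle(net: HeteroNetwork, types, i: int, j: int) -> float:
    """Brute-force relevance score along the type sequence ``types``.

    Splits the path at its middle node (both ways, averaged, when the edge
    count is odd) and takes the cosine of the two enumerated walk
    distributions; zero-norm distributions score 0.
    """
    n = len(types) - 1
    mids = [n // 2 + 1] if n % 2 == 0 else [(n + 1) // 2, (n + 3) // 2]
    scores = []
    for mid in mids:
        left = walk_distribution(net, types[:mid], i)
        right = walk_distribution(net, tuple(reversed(types[mid - 1 :])), j)
        denom = np.linalg.norm(left) * np.linalg.norm(right)
        scores.append(float(left @ right) / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def random_lp_network(
    rng: np.random.Generator,
    n_l: int = 6,
    n_p: int = 5,
    density: float = 0.4,
) -> HeteroNetwork:
    """Random binary two-type network with L-L, L-P and P-P relations."""

    def symmetric(n: int) -> np.ndarray:
        upper = np.triu((rng.random((n, n)) < density).astype(float), k=1)
        return upper + upper.T

    return HeteroNetwork(
        {"L": [f"l{i}" for i in range(n_l)], "P": [f"p{j}" for j in range(n_p)]},
        {
            ("L", "L"): symmetric(n_l),
            ("L", "P"): (rng.random((n_l, n_p)) < density).astype(float),
            ("P", "P"): symmetric(n_p),
        },
    )


def mann_whitney_auc(labels, scores) -> float:
    """AUC by exhaustive positive-negative pair counting (ties count 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))
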