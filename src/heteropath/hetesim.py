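"""HeteSim: path-constrained relevance between typed nodes.

HeteSim measures how related two nodes are *along a given metapath*: walks
are launched from both endpoints toward the path's middle node, and the
score is the cosine between the two resulting probability distributions
over middle-type nodes.  Because both walk distributions are nonnegative
the score lies in [0, 1]; it is symmetric (score of (a, b) along P equals
score of (b, a) along reversed P) and self-maximal.

Building blocks:

* transition matrix — a relation's adjacency row-normalized to walk
  probabilities (all-zero rows, i.e. zero-degree nodes, stay all-zero);
* reachable matrix — the ordered product of a metapath's transition
  matrices, giving start-to-end walk probabilities;
* the HeteSim score — split the path at its middle node (twice, and
  average, when the edge count is odd), take the cosine of the two
  endpoint rows.  A zero-degree endpoint has a zero walk distribution and
  scores 0 against everything: no evidence, no relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metapath import MetaPath, reverse_metapath, split_metapath
from .netio import HeteroNetwork

__all__ = [
    "TransitionMatrix",
    "ReachableMatrix",
    "HeteSimMatrix",
    "transition_matrix",
    "reachable_matrix",
    "hetesim_pairwise",
    "hetesim_pair",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic walk probabilities for one relation (zero rows allowed)."""

    source_type: str
    target_type: str
    values: np.ndarray


@dataclass(frozen=True)
class ReachableMatrix:
    """Walk probabilities from path-start nodes to path-end nodes.

    Rows sum to at most 1; mass is lost only through zero-degree dead ends.
    A single-node path yields the identity.
    """

    path: MetaPath
    values: np.ndarray


@dataclass(frozen=True)
class HeteSimMatrix:
    """HeteSim scores in [0, 1] for all (start-type, end-type) node pairs."""

    path: MetaPath
    scores: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]


def transition_matrix(
    network: HeteroNetwork, source_type: str, target_type: str
) -> TransitionMatrix:
    """Row-normalize the (source, target) adjacency; zero rows stay zero."""
    return TransitionMatrix(
        source_type, target_type, network.transition(source_type, target_type)
    )


def _reachable_values(network: HeteroNetwork, path: MetaPath) -> np.ndarray:
    values = np.eye(network.n_nodes(path.types[0]))
    for a, b in zip(path.types, path.types[1:]):
        values = values @ network.transition(a, b)
    return values


def reachable_matrix(network: HeteroNetwork, path: MetaPath) -> ReachableMatrix:
    """Ordered product of the path's transition matrices (identity if trivial)."""
    return ReachableMatrix(path, _reachable_values(network, path))


def _split_walk_distributions(network, split):
    """Rows of walk probabilities from both endpoints toward the mid node."""
    left = _reachable_values(network, split.left)
    right = _reachable_values(network, reverse_metapath(split.right))
    return left, right


def _cosine_rows(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Cosine of every row of ``left`` against every row of ``right``.

    Rows with zero norm (zero-degree endpoints) score 0 by convention.
    """
    num = left @ right.T
    left_norm = np.linalg.norm(left, axis=1)
    right_norm = np.linalg.norm(right, axis=1)
    denom = np.outer(left_norm, right_norm)
    scores = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return np.clip(scores, 0.0, 1.0)


def hetesim_pairwise(network: HeteroNetwork, path: MetaPath) -> HeteSimMatrix:
    """HeteSim scores along ``path`` for all start-type x end-type node pairs.

    Even edge count: one split at the middle node, cosine of the two
    endpoint walk distributions.  Odd edge count: two splits (either side
    of the missing middle), arithmetic mean of the two cosines.
    """
    splits = split_metapath(path)
    per_split = []
    for split in splits:
        left, right = _split_walk_distributions(network, split)
        per_split.append(_cosine_rows(left, right))
    scores = per_split[0] if len(per_split) == 1 else (per_split[0] + per_split[1]) / 2.0
    return HeteSimMatrix(
        path=path,
        scores=scores,
        row_ids=network.node_ids(path.types[0]),
        col_ids=network.node_ids(path.types[-1]),
    )


def hetesim_pair(
    network: HeteroNetwork, path: MetaPath, source_id: str, target_id: str
) -> float:
    """HeteSim score for one (source, target) pair along ``path``.

    Equals the corresponding entry of :func:`hetesim_pairwise` but walks
    only the two endpoint rows (vector-matrix propagation), which is much
    cheaper when scoring few pairs on a large network.
    """
    i = network.position(path.types[0], source_id)
    j = network.position(path.types[-1], target_id)
    scores = []
    for split in split_metapath(path):
        left = _propagate_row(network, split.left, i)
        right = _propagate_row(network, reverse_metapath(split.right), j)
        denom = np.linalg.norm(left) * np.linalg.norm(right)
        scores.append(float(left @ right) / denom if denom > 0 else 0.0)
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def _propagate_row(network: HeteroNetwork, path: MetaPath, start_pos: int) -> np.ndarray:
    row = np.zeros(network.n_nodes(path.types[0]))
    row[start_pos] = 1.0
    for a, b in zip(path.types, path.types[1:]):
        row = row @ network.transition(a, b)
    return row
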