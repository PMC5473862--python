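"""Edge-list I/O and heterogeneous-network assembly.

A heterogeneous lncRNA-protein network is built from three weighted edge
lists: lncRNA-lncRNA co-expression similarity, lncRNA-protein association
scores, and protein-protein interaction confidences.  Sparse "cutoff
networks" are obtained by thresholding edge weights (e.g. at 0.3 / 0.5 /
0.9 — the higher the cutoff, the sparser the network) and, by default,
binarizing the surviving edges to a 0/1 adjacency.

The central container is :class:`HeteroNetwork`: typed node layers with a
stable id ↔ index bijection per type, and one nonnegative relation matrix
per node-type pair.  Relations are undirected: asking for the (B, A)
relation of a stored (A, B) matrix returns its transpose, exactly.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigError,
    DuplicateEdgeError,
    EdgeListParseError,
    MissingRelationError,
    NodeLookupError,
)

__all__ = [
    "WeightedEdgeSet",
    "NetworkConfig",
    "HeteroNetwork",
    "read_edge_list",
    "write_edge_list",
    "combine_coexpression",
    "build_hetero_network",
    "hetero_network_from_edge_sets",
    "threshold_network",
    "network_to_edge_sets",
    "network_summary",
]


@dataclass
class WeightedEdgeSet:
    """A typed weighted edge list, e.g. the lncRNA-protein association scores.

    ``edges`` holds ``(source_id, target_id, weight)`` triples.  Node ids are
    opaque case-sensitive strings (whitespace-trimmed on parsing); weights
    must be finite.
    """

    source_type: str
    target_type: str
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def check_no_duplicates(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s, t, _ in self.edges:
            if (s, t) in seen:
                raise DuplicateEdgeError(
                    f"duplicate edge ({s!r}, {t!r}) in {self.source_type}-"
                    f"{self.target_type} edge set"
                )
            seen.add((s, t))


@dataclass
class NetworkConfig:
    """How edge lists are turned into a cutoff network.

    Parameters
    ----------
    cutoff : float in [0, 1]
        Edges with ``weight >= cutoff`` are retained, others dropped.
    binarize : bool
        Set retained weights to 1 (the default: relevance scoring runs on a
        0/1 adjacency) or keep the original weights.
    keep_isolated_nodes : bool
        Index every node seen in any edge set even if thresholding leaves it
        without edges, so feature matrices keep fixed dimensions across
        cutoffs.
    relation_cutoffs : mapping (source_type, target_type) -> float, optional
        Per-relation overrides of ``cutoff``.
    """

    cutoff: float = 0.0
    binarize: bool = True
    keep_isolated_nodes: bool = True
    relation_cutoffs: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        for value in [self.cutoff, *(self.relation_cutoffs or {}).values()]:
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"cutoff must lie in [0, 1], got {value}")

    def cutoff_for(self, pair: tuple[str, str]) -> float:
        overrides = self.relation_cutoffs or {}
        if pair in overrides:
            return overrides[pair]
        if pair[::-1] in overrides:
            return overrides[pair[::-1]]
        return self.cutoff


class HeteroNetwork:
    """Typed node layers plus nonnegative relation matrices between them.

    Parameters
    ----------
    index : mapping type-label -> sequence of node ids
        Node ids per type, in index order (row/column order of the matrices).
    relations : mapping (source_type, target_type) -> array
        One matrix per unordered type pair; the reverse orientation is served
        as the exact transpose.  Within-type matrices must be symmetric.

    Matrices are stored read-only; derived quantities (row-normalized
    transition matrices) are cached per network instance, which is safe
    because instances are immutable — :meth:`replace_relation` returns a new
    network sharing the untouched matrices.
    """

    def __init__(
        self,
        index: Mapping[str, Sequence[str]],
        relations: Mapping[tuple[str, str], np.ndarray],
        validate: bool = True,
    ) -> None:
        self._ids: dict[str, tuple[str, ...]] = {
            t: tuple(ids) for t, ids in index.items()
        }
        self._pos: dict[str, dict[str, int]] = {
            t: {node: i for i, node in enumerate(ids)} for t, ids in self._ids.items()
        }
        for t, ids in self._ids.items():
            if len(self._pos[t]) != len(ids):
                raise ConfigError(f"duplicate node ids in type {t!r}")
        self._relations: dict[tuple[str, str], np.ndarray] = {}
        self._tcache: dict[tuple[str, str], np.ndarray] = {}
        for (a, b), mat in relations.items():
            if (b, a) in self._relations and a != b:
                raise ConfigError(
                    f"type-pair collision: both ({a},{b}) and ({b},{a}) supplied"
                )
            arr = np.ascontiguousarray(np.asarray(mat, dtype=float))
            if validate:
                self._check_matrix(a, b, arr)
            arr.flags.writeable = False
            self._relations[(a, b)] = arr

    def _check_matrix(self, a: str, b: str, arr: np.ndarray) -> None:
        if a not in self._ids or b not in self._ids:
            raise ConfigError(f"relation ({a},{b}) references an unindexed type")
        expected = (len(self._ids[a]), len(self._ids[b]))
        if arr.shape != expected:
            raise ConfigError(
                f"relation ({a},{b}) has shape {arr.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(arr)):
            raise ConfigError(f"relation ({a},{b}) contains non-finite weights")
        if np.any(arr < 0):
            raise ConfigError(f"relation ({a},{b}) contains negative weights")
        if a == b and not np.array_equal(arr, arr.T):
            raise ConfigError(f"within-type relation ({a},{a}) must be symmetric")

    # -- node layer -------------------------------------------------------
    @property
    def node_types(self) -> set[str]:
        return set(self._ids)

    def node_ids(self, node_type: str) -> tuple[str, ...]:
        try:
            return self._ids[node_type]
        except KeyError:
            raise NodeLookupError(f"unknown node type {node_type!r}") from None

    def n_nodes(self, node_type: str) -> int:
        return len(self.node_ids(node_type))

    def position(self, node_type: str, node_id: str) -> int:
        try:
            return self._pos[node_type][node_id]
        except KeyError:
            raise NodeLookupError(
                f"node {node_id!r} is not indexed under type {node_type!r}"
            ) from None

    # -- relations --------------------------------------------------------
    def relation_pairs(self) -> list[tuple[str, str]]:
        """Stored (canonical-orientation) type pairs."""
        return list(self._relations)

    def has_relation(self, a: str, b: str) -> bool:
        return (a, b) in self._relations or (b, a) in self._relations

    def relation(self, a: str, b: str) -> np.ndarray:
        """Adjacency of (a, b); the reverse orientation is the exact transpose."""
        if (a, b) in self._relations:
            return self._relations[(a, b)]
        if (b, a) in self._relations:
            return self._relations[(b, a)].T
        raise MissingRelationError(f"network has no relation between ({a}, {b})")

    def replace_relation(self, a: str, b: str, matrix: np.ndarray) -> "HeteroNetwork":
        """New network with the (a, b) relation replaced; others are shared."""
        matrix = np.asarray(matrix, dtype=float)
        new = dict(self._relations)
        if (a, b) in new or not self.has_relation(a, b):
            new[(a, b)] = matrix
        else:
            new[(b, a)] = matrix.T
        return HeteroNetwork(self._ids, new)

    def transition(self, a: str, b: str) -> np.ndarray:
        """Row-normalized (a, b) adjacency; all-zero rows stay all-zero."""
        key = (a, b)
        cached = self._tcache.get(key)
        if cached is None:
            adj = self.relation(a, b)
            row_sums = adj.sum(axis=1, keepdims=True)
            cached = np.divide(
                adj, row_sums, out=np.zeros_like(adj), where=row_sums > 0
            )
            cached.flags.writeable = False
            self._tcache[key] = cached
        return cached


def read_edge_list(path, source_type: str, target_type: str) -> WeightedEdgeSet:
    """Parse a 3-column TSV edge list (source_id, target_id, weight).

    Lines starting with ``#`` are comments; blank lines are skipped.  A line
    with the wrong column count or a non-finite/non-numeric weight raises
    :class:`EdgeListParseError` naming the 1-based line number; a repeated
    ordered (source, target) pair raises :class:`DuplicateEdgeError`.
    """
    edges: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            src, tgt = fields[0].strip(), fields[1].strip()
            try:
                weight = float(fields[2])
            except ValueError:
                raise EdgeListParseError(
                    f"{path}:{lineno}: weight {fields[2]!r} is not numeric"
                ) from None
            if not math.isfinite(weight):
                raise EdgeListParseError(
                    f"{path}:{lineno}: weight {fields[2]!r} is not finite"
                )
            if (src, tgt) in seen:
                raise DuplicateEdgeError(
                    f"{path}:{lineno}: duplicate edge ({src!r}, {tgt!r})"
                )
            seen.add((src, tgt))
            edges.append((src, tgt, weight))
    return WeightedEdgeSet(source_type, target_type, edges)


def write_edge_list(edge_set: WeightedEdgeSet, path) -> None:
    """Write a :class:`WeightedEdgeSet` as 3-column TSV with a comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {edge_set.source_type}\t{edge_set.target_type}\tweight\n")
        for src, tgt, weight in edge_set.edges:
            fh.write(f"{src}\t{tgt}\t{weight:.10g}\n")


def combine_coexpression(per_dataset_scores: Iterable[float]) -> float:
    """Combine per-dataset Pearson correlations into one association score.

    Datasets with non-positive correlation are dropped; the retained scores
    ``c_d`` are combined as ``1 - prod(1 - c_d)`` (a noisy-OR: the pair is
    "co-expressed" if any dataset supports it).  With no positive score left
    the pair has no co-expression edge and the score is 0.  Scores must lie
    in (-1, 1].
    """
    retained = []
    for score in per_dataset_scores:
        if not (-1.0 < score <= 1.0):
            raise ConfigError(
                f"correlation score {score} outside the valid range (-1, 1]"
            )
        if score > 0:
            retained.append(score)
    if not retained:
        return 0.0
    return 1.0 - float(np.prod([1.0 - c for c in retained]))


def hetero_network_from_edge_sets(
    edge_sets: Sequence[WeightedEdgeSet],
    config: NetworkConfig | None = None,
    extra_nodes: Mapping[str, Sequence[str]] | None = None,
) -> HeteroNetwork:
    """Assemble a cutoff network from typed edge sets.

    The node universe per type is the union of ids seen in any edge set
    (plus ``extra_nodes``), sorted for a deterministic index.  Edges below
    the (per-relation) cutoff are dropped; retained weights are set to 1
    when ``config.binarize``.  Within-type edge sets are symmetrized and
    self-loops are discarded (zero diagonal).
    """
    config = config or NetworkConfig()
    by_pair: dict[tuple[str, str], WeightedEdgeSet] = {}
    for es in edge_sets:
        pair = (es.source_type, es.target_type)
        if pair in by_pair or pair[::-1] in by_pair:
            raise ConfigError(f"two edge sets claim the type pair {pair}")
        es.check_no_duplicates()
        by_pair[pair] = es

    universe: dict[str, set[str]] = {}
    for (a, b), es in by_pair.items():
        universe.setdefault(a, set())
        universe.setdefault(b, set())
        for src, tgt, _ in es.edges:
            universe[a].add(src)
            universe[b].add(tgt)
    for t, ids in (extra_nodes or {}).items():
        universe.setdefault(t, set()).update(ids)
    index = {t: sorted(ids) for t, ids in universe.items()}
    pos = {t: {node: i for i, node in enumerate(ids)} for t, ids in index.items()}

    relations: dict[tuple[str, str], np.ndarray] = {}
    for (a, b), es in by_pair.items():
        mat = np.zeros((len(index[a]), len(index[b])))
        cutoff = config.cutoff_for((a, b))
        for src, tgt, weight in es.edges:
            if not weight >= 0:
                raise ConfigError(
                    f"negative weight {weight} on ({src!r}, {tgt!r}); association "
                    "scores must be nonnegative (combine evidence first)"
                )
            if weight < cutoff:
                continue
            i, j = pos[a][src], pos[b][tgt]
            if a == b and i == j:
                continue  # self-similarity adds trivial hops; keep zero diagonal
            value = 1.0 if config.binarize else weight
            if a == b:
                existing = mat[j, i]
                if existing != 0.0 and existing != value:
                    raise DuplicateEdgeError(
                        f"conflicting weights for undirected edge ({src!r}, {tgt!r})"
                    )
                mat[i, j] = mat[j, i] = value
            else:
                mat[i, j] = value
        relations[(a, b)] = mat

    if not config.keep_isolated_nodes:
        keep: dict[str, np.ndarray] = {
            t: np.zeros(len(ids), dtype=bool) for t, ids in index.items()
        }
        for (a, b), mat in relations.items():
            keep[a] |= mat.any(axis=1)
            keep[b] |= mat.any(axis=0)
        index = {
            t: [node for node, k in zip(index[t], keep[t]) if k] for t in index
        }
        relations = {
            (a, b): mat[np.ix_(keep[a], keep[b])] for (a, b), mat in relations.items()
        }

    return HeteroNetwork(index, relations)


def build_hetero_network(
    ll: WeightedEdgeSet,
    lp: WeightedEdgeSet,
    pp: WeightedEdgeSet,
    config: NetworkConfig | None = None,
) -> HeteroNetwork:
    """Build the lncRNA-protein heterogeneous network from its three edge sets.

    ``ll``: lncRNA-lncRNA similarity, ``lp``: lncRNA-protein association,
    ``pp``: protein-protein interaction.  See
    :func:`hetero_network_from_edge_sets` for thresholding semantics.
    """
    return hetero_network_from_edge_sets([ll, lp, pp], config)


def threshold_network(
    network: HeteroNetwork, config: NetworkConfig | None = None
) -> HeteroNetwork:
    """Apply cutoff/binarization directly to an assembled network's matrices."""
    config = config or NetworkConfig()
    relations = {}
    for pair in network.relation_pairs():
        mat = network.relation(*pair)
        keep = mat >= config.cutoff_for(pair)
        keep &= mat > 0
        out = np.where(keep, 1.0 if config.binarize else mat, 0.0)
        relations[pair] = out
    return HeteroNetwork({t: network.node_ids(t) for t in network.node_types}, relations)


def network_to_edge_sets(network: HeteroNetwork) -> list[WeightedEdgeSet]:
    """Decompose a network back into one edge set per stored relation.

    Within-type relations emit each undirected edge once (i < j).
    """
    out = []
    for a, b in network.relation_pairs():
        mat = network.relation(a, b)
        rows = network.node_ids(a)
        cols = network.node_ids(b)
        edges = []
        for i, j in zip(*np.nonzero(mat)):
            if a == b and j <= i:
                continue
            edges.append((rows[i], cols[j], float(mat[i, j])))
        out.append(WeightedEdgeSet(a, b, edges))
    return out


def network_summary(network: HeteroNetwork) -> dict:
    """JSON-able node/edge counts per type and relation."""
    edge_counts = {}
    for a, b in network.relation_pairs():
        mat = network.relation(a, b)
        n = int(np.count_nonzero(mat))
        if a == b:
            n //= 2
        edge_counts[f"{a}-{b}"] = n
    return {
        "nodes": {t: network.n_nodes(t) for t in sorted(network.node_types)},
        "edges": edge_counts,
    }
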