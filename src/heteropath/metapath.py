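"""Metapaths: typed walk templates through the heterogeneous network.

A metapath is an ordered sequence of node-type labels, e.g. ``LLP`` =
lncRNA → lncRNA → protein.  Different sequences carry different semantics
(``LLP``: a lncRNA similar to an interacting lncRNA is itself a candidate
interactor; ``LPP``: a protein interacting with a bound protein is a
candidate partner).  With the two endpoint types L and P there are exactly
14 lncRNA-to-protein metapaths of 3-5 nodes, which form the feature set of
the interaction classifier; ``CANONICAL_PATH_IDS`` is the bundled manifest
mapping their conventional ids 1-14 to names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property

from .exceptions import ConfigError

__all__ = [
    "MetaPath",
    "SplitPair",
    "parse_metapath",
    "enumerate_metapaths",
    "reverse_metapath",
    "split_metapath",
    "canonical_feature_paths",
    "CANONICAL_PATH_IDS",
]

#: Conventional id -> name manifest for the 14 lncRNA-to-protein metapaths
#: with 3-5 nodes over the {L, P} alphabet (ids fix the reporting order).
CANONICAL_PATH_IDS: dict[int, str] = {
    1: "LLP",
    2: "LPP",
    3: "LLPP",
    4: "LPLP",
    5: "LLLP",
    6: "LPPP",
    7: "LPPPP",
    8: "LPPLP",
    9: "LPLPP",
    10: "LPLLP",
    11: "LLPPP",
    12: "LLPLP",
    13: "LLLPP",
    14: "LLLLP",
}


@dataclass(frozen=True)
class MetaPath:
    """An ordered sequence of node-type labels (P1 ... P_{n+1})."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 1:
            raise ConfigError("a metapath needs at least one node type")

    @cached_property
    def name(self) -> str:
        """Compact one-letter-per-type name when all labels are single chars."""
        if all(len(t) == 1 for t in self.types):
            return "".join(self.types)
        return "-".join(self.types)

    @property
    def node_count(self) -> int:
        return len(self.types)

    @property
    def edge_count(self) -> int:
        """Path length n (edges) = node count - 1."""
        return len(self.types) - 1

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class SplitPair:
    """A metapath split at 1-based node index ``mid`` into left/right halves.

    The mid node is shared: ``left`` ends and ``right`` starts with it, and
    the halves' edge counts sum to the parent's.
    """

    left: MetaPath
    right: MetaPath
    mid: int

    def __post_init__(self) -> None:
        assert self.left.types[-1] == self.right.types[0]


def parse_metapath(name: str, alphabet: set[str] | frozenset[str]) -> MetaPath:
    """Decode a compact name like ``"LLPP"`` over single-letter type labels."""
    types = []
    for ch in name:
        if ch not in alphabet:
            raise ConfigError(
                f"unknown type code {ch!r} in metapath {name!r}; "
                f"alphabet is {sorted(alphabet)}"
            )
        types.append(ch)
    return MetaPath(tuple(types))


def enumerate_metapaths(
    start: str,
    end: str,
    alphabet: set[str] | frozenset[str],
    max_nodes: int,
    min_nodes: int = 2,
) -> list[MetaPath]:
    """All metapaths from ``start`` to ``end`` with node counts in range.

    Intermediate positions range freely over the alphabet, so there are
    ``|alphabet|**(k-2)`` paths with k nodes.  Order is deterministic:
    by node count, then lexicographic by name.
    """
    if min_nodes < 2:
        raise ConfigError("a start-to-end metapath needs at least 2 nodes")
    if max_nodes < min_nodes:
        raise ConfigError("max_nodes must be >= min_nodes")
    letters = sorted(alphabet)
    paths = []
    for k in range(min_nodes, max_nodes + 1):
        for middle in itertools.product(letters, repeat=k - 2):
            paths.append(MetaPath((start, *middle, end)))
        # itertools.product over sorted letters is already lexicographic
    return paths


def canonical_feature_paths() -> list[MetaPath]:
    """The 14 manifest metapaths (L to P, 3-5 nodes), in manifest id order."""
    alphabet = frozenset("LP")
    return [parse_metapath(CANONICAL_PATH_IDS[i], alphabet) for i in sorted(CANONICAL_PATH_IDS)]


def reverse_metapath(path: MetaPath) -> MetaPath:
    return MetaPath(tuple(reversed(path.types)))


def split_metapath(path: MetaPath) -> list[SplitPair]:
    """Split a metapath at its middle node for relevance scoring.

    For even edge count n there is a single middle node, at 1-based index
    ``n/2 + 1``.  For odd n no equal split exists, so the path is split
    twice, at ``(n+1)/2`` and ``(n+3)/2`` (scores from the two splits are
    later averaged).  Single-node halves are legal; their reachable matrix
    is the identity.
    """
    n = path.edge_count
    if n < 1:
        raise ConfigError("cannot split a single-node metapath")
    if n % 2 == 0:
        mids = [n // 2 + 1]
    else:
        mids = [(n + 1) // 2, (n + 3) // 2]
    return [
        SplitPair(
            left=MetaPath(path.types[:mid]),
            right=MetaPath(path.types[mid - 1 :]),
            mid=mid,
        )
        for mid in mids
    ]
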