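"""Feature assembly and the interaction classifier.

Each candidate (lncRNA, protein) pair is described by one feature per
metapath: the pair's HeteSim score along that path, damped by
``beta ** (node_count - 2)`` so that longer, semantically weaker paths
contribute less (3-node paths are scaled by beta, 4-node by beta^2,
5-node by beta^3).  An SVM with a continuous decision score is trained on
labeled pairs and ranks candidates by signed margin.

The core is exposed two ways:

* :class:`PairClassifier` — a scikit-learn estimator (standardization +
  SVC) that accepts :class:`FeatureTable` or plain arrays and enforces the
  training-time column manifest;
* :class:`MetaPathFeaturizer` — a scikit-learn transformer mapping
  sequences of (lncRNA_id, protein_id) pairs to damped feature matrices
  for a fixed network, so the whole method composes into a Pipeline.

The module-level functions (`build_feature_table`, `sample_training_pairs`,
`train_classifier`, `score_pairs`, `rank_candidate_proteins`) are thin
wrappers over these estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigError, SamplingError, SchemaError, TrainingError
from .hetesim import hetesim_pair, hetesim_pairwise
from .metapath import MetaPath, canonical_feature_paths
from .netio import HeteroNetwork

__all__ = [
    "FeatureTable",
    "LabeledPairSet",
    "ClassifierConfig",
    "MetaPathFeaturizer",
    "PairClassifier",
    "build_feature_table",
    "sample_training_pairs",
    "train_classifier",
    "score_pairs",
    "rank_candidate_proteins",
]

# Below this many pairs, per-pair row propagation beats full pairwise matrices.
_PAIRWISE_THRESHOLD = 8


@dataclass
class FeatureTable:
    """Rows = (lncRNA, protein) pairs, columns = damped per-metapath scores."""

    pairs: list[tuple[str, str]]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pairs), len(self.columns)):
            raise SchemaError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.columns)} columns"
            )

    def drop_row(self, i: int) -> "FeatureTable":
        pairs = self.pairs[:i] + self.pairs[i + 1 :]
        return FeatureTable(pairs, self.columns, np.delete(self.values, i, axis=0))


@dataclass
class LabeledPairSet:
    """(lncRNA, protein, label) triples with sampling provenance."""

    pairs: list[tuple[str, str, int]]
    source_networks: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        by_pair: dict[tuple[str, str], int] = {}
        for l, p, y in self.pairs:
            if y not in (0, 1):
                raise ConfigError(f"label for ({l}, {p}) must be 0 or 1, got {y}")
            if by_pair.setdefault((l, p), y) != y:
                raise ConfigError(f"pair ({l}, {p}) appears with both labels")

    @property
    def ids(self) -> list[tuple[str, str]]:
        return [(l, p) for l, p, _ in self.pairs]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=int)

    def drop(self, i: int) -> "LabeledPairSet":
        return LabeledPairSet(
            self.pairs[:i] + self.pairs[i + 1 :], self.source_networks, self.seed
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ClassifierConfig:
    """SVM and feature-assembly settings.

    beta in (0, 1) damps long-path features; kernel/regularization are the
    SVC settings (RBF, C=1 by default: 14 bounded correlated features);
    feature_scaling "standard" standardizes using training statistics only.
    """

    beta: float = 0.2
    kernel: str = "rbf"
    regularization: float = 1.0
    feature_scaling: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ConfigError(f"beta must lie in (0, 1), got {self.beta}")
        if self.regularization <= 0:
            raise ConfigError("regularization must be positive")
        if self.feature_scaling not in ("standard", "none"):
            raise ConfigError("feature_scaling must be 'standard' or 'none'")


def _damping_factors(paths: Sequence[MetaPath], beta: float) -> np.ndarray:
    return np.array([float(beta) ** (p.node_count - 2) for p in paths])


class MetaPathFeaturizer(BaseEstimator, TransformerMixin):
    """Transform (lncRNA_id, protein_id) pairs into damped HeteSim features.

    Parameters
    ----------
    network : HeteroNetwork
        The network walks are scored on.
    paths : sequence of MetaPath, or "auto"
        Feature metapaths; "auto" uses the canonical 14-path manifest.
    beta : float in [0, 1]
        Damping base; a path with k nodes is scaled by ``beta**(k-2)``.
    """

    def __init__(self, network: HeteroNetwork = None, paths="auto", beta: float = 0.2):
        self.network = network
        self.paths = paths
        self.beta = beta

    def fit(self, X=None, y=None):
        if self.network is None:
            raise ConfigError("MetaPathFeaturizer needs a network")
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigError(f"beta must lie in [0, 1], got {self.beta}")
        self.paths_ = (
            canonical_feature_paths() if isinstance(self.paths, str) else list(self.paths)
        )
        starts = {p.types[0] for p in self.paths_}
        ends = {p.types[-1] for p in self.paths_}
        if len(starts) != 1 or len(ends) != 1:
            raise ConfigError("all feature metapaths must share endpoint types")
        self.source_type_, self.target_type_ = starts.pop(), ends.pop()
        self.feature_names_ = [p.name for p in self.paths_]
        return self

    def transform(self, X: Sequence[tuple[str, str]]) -> np.ndarray:
        pairs = [(str(l), str(p)) for l, p in X]
        damping = _damping_factors(self.paths_, self.beta)
        values = np.empty((len(pairs), len(self.paths_)))
        if len(pairs) <= _PAIRWISE_THRESHOLD:
            for j, path in enumerate(self.paths_):
                for i, (l, p) in enumerate(pairs):
                    values[i, j] = hetesim_pair(self.network, path, l, p)
        else:
            rows = [self.network.position(self.source_type_, l) for l, _ in pairs]
            cols = [self.network.position(self.target_type_, p) for _, p in pairs]
            for j, path in enumerate(self.paths_):
                scores = hetesim_pairwise(self.network, path).scores
                values[:, j] = scores[rows, cols]
        return values * damping

    def feature_table(self, X: Sequence[tuple[str, str]]) -> FeatureTable:
        return FeatureTable(
            [(str(l), str(p)) for l, p in X], list(self.feature_names_), self.transform(X)
        )


class PairClassifier(BaseEstimator, ClassifierMixin):
    """Max-margin classifier over per-metapath features.

    A Pipeline of optional standardization (fitted on training data only)
    and an SVC; the continuous decision score (signed margin) ranks pairs.
    When fitted on a :class:`FeatureTable` the column manifest is recorded
    and later inputs must match it exactly, by name and order.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 1.0,
        gamma="scale",
        feature_scaling: str = "standard",
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.feature_scaling = feature_scaling
        self.random_state = random_state

    def _extract(self, X, fitting: bool = False) -> np.ndarray:
        if isinstance(X, FeatureTable):
            if fitting:
                self.feature_names_ = list(X.columns)
            elif getattr(self, "feature_names_", None) is not None:
                if list(X.columns) != self.feature_names_:
                    raise SchemaError(
                        f"feature columns {X.columns} do not match training "
                        f"columns {self.feature_names_}"
                    )
            return X.values
        if fitting:
            self.feature_names_ = None
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        values = self._extract(X, fitting=True)
        y = np.asarray(y, dtype=int)
        if values.shape[0] != y.shape[0]:
            raise TrainingError("feature rows do not align with labels")
        classes = np.unique(y)
        if classes.size < 2:
            raise TrainingError("training labels contain a single class")
        steps = []
        if self.feature_scaling == "standard":
            steps.append(("scale", StandardScaler()))
        steps.append(
            (
                "svc",
                SVC(
                    kernel=self.kernel,
                    C=self.C,
                    gamma=self.gamma,
                    random_state=self.random_state,
                ),
            )
        )
        self.pipeline_ = Pipeline(steps)
        self.pipeline_.fit(values, y)
        self.classes_ = classes
        self.n_features_in_ = values.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        values = self._extract(X)
        if values.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {values.shape[1]}"
            )
        return self.pipeline_.decision_function(values)

    def predict(self, X) -> np.ndarray:
        return self.pipeline_.predict(self._extract(X))


def build_feature_table(
    network: HeteroNetwork,
    pairs: Sequence[tuple[str, str]],
    paths: Sequence[MetaPath],
    beta: float,
) -> FeatureTable:
    """Damped HeteSim feature table for the given pairs and metapaths."""
    featurizer = MetaPathFeaturizer(network=network, paths=paths, beta=beta).fit()
    return featurizer.feature_table(pairs)


def sample_training_pairs(
    positive_net: HeteroNetwork,
    negative_net: HeteroNetwork,
    n_pos: int,
    n_neg: int,
    seed: int,
    mandatory_positives: Sequence[tuple[str, str]] = (),
    lnc_type: str = "L",
    prot_type: str = "P",
) -> LabeledPairSet:
    """Sample a balanced labeled pair set from two cutoff networks.

    Positives are drawn uniformly without replacement from the edges of the
    (sparse, high-confidence) ``positive_net`` lncRNA-protein relation and
    forced to include ``mandatory_positives`` (a curated gold set).
    Negatives are drawn uniformly from (L x P) pairs with no edge in the
    (dense, permissive) ``negative_net`` — absence from a dense network is
    the most conservative evidence of non-interaction.
    """
    rng = np.random.default_rng(seed)

    adj = positive_net.relation(lnc_type, prot_type)
    lnc_ids = positive_net.node_ids(lnc_type)
    prot_ids = positive_net.node_ids(prot_type)
    edges = [(lnc_ids[i], prot_ids[j]) for i, j in zip(*np.nonzero(adj))]
    edge_set = set(edges)
    mandatory = [(str(l), str(p)) for l, p in mandatory_positives]
    for pair in mandatory:
        if pair not in edge_set:
            raise SamplingError(
                f"mandatory positive {pair} is not an edge of the positive network"
            )
    if n_pos < len(mandatory):
        raise SamplingError(
            f"n_pos={n_pos} is smaller than the {len(mandatory)} mandatory positives"
        )
    if n_pos > len(edges):
        raise SamplingError(
            f"requested {n_pos} positives but the positive network has only "
            f"{len(edges)} lncRNA-protein edges"
        )
    pool = sorted(edge_set - set(mandatory))
    drawn = [pool[k] for k in rng.choice(len(pool), n_pos - len(mandatory), replace=False)] if n_pos > len(mandatory) else []
    positives = mandatory + drawn

    neg_adj = negative_net.relation(lnc_type, prot_type)
    neg_lnc = negative_net.node_ids(lnc_type)
    neg_prot = negative_net.node_ids(prot_type)
    positive_ids = set(positives)
    candidates = [
        (neg_lnc[i], neg_prot[j])
        for i, j in zip(*np.nonzero(neg_adj == 0))
        if (neg_lnc[i], neg_prot[j]) not in positive_ids
    ]
    if n_neg > len(candidates):
        raise SamplingError(
            f"requested {n_neg} negatives but only {len(candidates)} non-edges "
            "exist in the negative network"
        )
    negatives = [candidates[k] for k in rng.choice(len(candidates), n_neg, replace=False)]

    pairs = [(l, p, 1) for l, p in positives] + [(l, p, 0) for l, p in negatives]
    return LabeledPairSet(pairs, source_networks=("positive", "negative"), seed=seed)


def train_classifier(
    features: FeatureTable, labels: LabeledPairSet, config: ClassifierConfig
) -> PairClassifier:
    """Fit the SVM on a feature table aligned row-for-row with labeled pairs."""
    if features.pairs != labels.ids:
        raise SchemaError("feature rows do not align with the labeled pair set")
    clf = PairClassifier(
        kernel=config.kernel,
        C=config.regularization,
        feature_scaling=config.feature_scaling,
        random_state=config.seed,
    )
    return clf.fit(features, labels.labels)


def score_pairs(
    classifier: PairClassifier, features: FeatureTable
) -> list[tuple[tuple[str, str], float]]:
    """Continuous decision score per pair; ranking by score orders predictions."""
    scores = classifier.decision_function(features)
    return [(pair, float(s)) for pair, s in zip(features.pairs, scores)]


def rank_candidate_proteins(
    network: HeteroNetwork,
    classifier: PairClassifier,
    lncRNA_id: str,
    paths: Sequence[MetaPath],
    beta: float,
) -> list[tuple[str, float]]:
    """Score every protein against one lncRNA, descending; ties by protein id."""
    prot_type = paths[0].types[-1]
    network.position(paths[0].types[0], lncRNA_id)  # fail fast on unknown lncRNA
    proteins = network.node_ids(prot_type)
    table = build_feature_table(
        network, [(lncRNA_id, p) for p in proteins], paths, beta
    )
    scored = score_pairs(classifier, table)
    return sorted(
        [(p, s) for (_, p), s in scored], key=lambda item: (-item[1], item[0])
    )
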