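# heteropath

Metapath-constrained relevance scoring and SVM-based interaction
prediction for lncRNA–protein heterogeneous networks.

Long non-coding RNAs (lncRNAs) act largely through the proteins they
bind, but experimentally confirmed lncRNA–protein interactions are
scarce. `heteropath` is for computational biologists who want to
prioritize candidate interactions from network context alone: it takes a
lncRNA–lncRNA co-expression similarity network, a lncRNA–protein
association network and a protein–protein interaction network, and ranks
candidate (lncRNA, protein) pairs by combining path-constrained relevance
scores with a max-margin classifier.

## The method

A **metapath** is a sequence of node types, e.g. `LLP` =
lncRNA → lncRNA → protein. Different metapaths carry different meanings
(`LLP`: lncRNAs similar to a binder are candidate binders; `LPP`:
partners of a bound protein are candidate binders). Over the two-type
alphabet {L, P} there are exactly 14 lncRNA-to-protein metapaths with 3–5
nodes; each contributes one feature per pair.

Relevance along a metapath 𝒫 = (P₁ … P₊₁) is the **HeteSim** score.
Each relation's adjacency is row-normalized into a transition matrix

> T(i, j) = I(i, j) / Σₖ I(i, k),

the reachable matrix of a path is the ordered product
R_𝒫 = T₁₂ T₂₃ ⋯, and the path is split at its middle node into 𝒫_L and
𝒫_R (twice, and averaged, when the edge count is odd). The score of a
pair (l, p) is the cosine of the two walk distributions meeting in the
middle:

> HeteSim(l, p | 𝒫) = R_{𝒫_L}(l, :) · R_{𝒫_R⁻¹}(p, :)ᵀ
> / ( ‖R_{𝒫_L}(l, :)‖₂ · ‖R_{𝒫_R⁻¹}(p, :)‖₂ ),

which is symmetric, self-maximal, and lies in [0, 1] (a zero-degree
endpoint scores 0). The feature for a k-node path is damped by
β^(k−2) with β ∈ (0, 1) (default 0.2) so longer, semantically weaker
paths count less. An SVM (RBF kernel, standardized features) is trained
on labeled pairs — positives sampled from a sparse high-confidence
cutoff network, negatives from non-edges of a dense permissive one — and
its continuous decision score ranks candidates. Evaluation supports
leave-one-out cross-validation (the held-out pair's edge is removed from
the network before its features are computed), an independent test, and
the usual confusion metrics plus ROC/AUC.

The `synthetic` module generates seeded planted-block benchmark networks
so the whole pipeline is testable without any external downloads.

## Worked example

```python
import numpy as np
from heteropath import (
    toy_network, parse_metapath, hetesim_pairwise, hetesim_pair,
    planted_benchmark, canonical_feature_paths, ClassifierConfig, loocv,
)

# 1. Path-constrained relevance on the bundled toy network
net = toy_network()                      # 3 lncRNAs, 4 T nodes, 2 proteins
path = parse_metapath("LTP", frozenset("LTP"))
print(np.round(hetesim_pairwise(net, path).scores, 4))
print("score(l3, p1) =", round(hetesim_pair(net, path, "l3", "p1"), 4))

# 2. Full pipeline on a planted-signal synthetic benchmark
network, labeled = planted_benchmark()   # 60 lncRNAs, 40 proteins, 200 pairs
paths = canonical_feature_paths()        # the 14 L-to-P metapaths, 3-5 nodes
held_out, report = loocv(network, labeled, paths, ClassifierConfig(beta=0.2))
print(f"LOOCV on {len(labeled)} pairs: AUC={report.auc:.3f} "
      f"ACC={report.ACC:.3f} MCC={report.MCC:.3f}")
```

Output:

```
[[0.     0.4082]
 [1.     0.5774]
 [0.5774 0.6667]]
score(l3, p1) = 0.5774
LOOCV on 200 pairs: AUC=1.000 ACC=1.000 MCC=1.000
```

The first matrix is the HeteSim score of every (lncRNA, protein) pair
along L–T–P: `l2`–`p1` score 1 because every walk from either endpoint
meets at the same middle node, while `l1`–`p1` score 0 because their walk
distributions never overlap. The LOOCV line shows that β-damped path
features let the classifier recover the planted block structure of the
synthetic benchmark essentially perfectly.

A command-line interface mirrors the library (`heteropath simulate`,
`hetesim`, `train`, `predict`, `loocv`, `eval`); see
`heteropath --help`.

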