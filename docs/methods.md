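# Methods

## Model

`heteropath` treats lncRNA–protein interaction prediction as link
prediction on a heterogeneous information network with node types L
(lncRNA) and P (protein) and three relations: L–L co-expression
similarity, L–P association, and P–P interaction confidence. All
relations are undirected and stored so that the (B, A) matrix is the
exact transpose of the (A, B) matrix; within-type matrices are symmetric
with zero diagonal (self-similarity would only add trivial hops).

Relevance between a pair of nodes is path-constrained. For a metapath
𝒫 = (P₁ … Pₙ₊₁) of edge count n:

1. each relation's adjacency I is row-normalized into a transition
   matrix T (rows of zero-degree nodes remain all-zero);
2. the reachable matrix R_𝒫 is the ordered product of the path's
   transition matrices (a single-node path gives the identity);
3. 𝒫 is split at its middle node, at index n/2 + 1 for even n, and at
   both (n+1)/2 and (n+3)/2 for odd n;
4. the HeteSim score of (l, p) is the cosine of l's walk distribution
   along the left half and p's walk distribution along the reversed
   right half; for odd n the two splits' scores are averaged with equal
   weight.

Because both distributions are nonnegative the score lies in [0, 1]; it
is symmetric under reversing the path and swapping endpoints, and a node
with at least one edge scores 1 against itself along a palindromic path.

### Degenerate inputs and numerical choices

- **Zero-degree nodes.** Row normalization is 0/0 for an all-zero row;
  the row is kept at zero and any cosine with a zero-norm vector is
  defined as 0 — no walk evidence means no relatedness. This is the only
  extension that keeps scores in [0, 1].
- **Representation.** Matrices are dense `float64`; at the scales this
  package targets (10²–10⁴ nodes) dense products are simpler and fast
  enough. Scores are clipped to [0, 1] to absorb ≤1-ulp cosine
  overshoot; no other tolerance enters the scoring path.
- **Caching.** Transition matrices are cached per network instance.
  Networks are immutable (matrices are stored read-only and editing
  operations return a new instance sharing untouched matrices), so a
  cache can never serve stale values; tests assert cold- and warm-cache
  results are bit-identical.
- **Batching.** Scoring few pairs propagates single rows
  (vector–matrix); scoring many pairs computes the full pairwise matrix
  per path once. Both routes are asserted equal to 1e-12.

## Networks and features

Cutoff networks retain edges with weight ≥ cutoff (applied to all three
relations by default, overridable per relation) and binarize retained
weights by default — relevance then runs on 0/1 adjacency, matching the
closed-form toy example; weighted scoring is available via
`NetworkConfig(binarize=False)`. Every node seen in any edge list keeps
its index even when isolated after thresholding, so feature matrices
have fixed dimensions across cutoffs. Multi-dataset co-expression
evidence is combined with the noisy-OR 1 − ∏(1 − c_d) over datasets with
positive correlation; non-positive correlations are dropped first.

The feature vector of a pair has one column per metapath — the 14
L-to-P paths with 3–5 nodes, in a fixed manifest order — each damped by
β^(node count − 2): 3-node paths scale by β, 4-node by β², 5-node by β³.
Default β = 0.2; the damping mainly encodes the prior that longer paths
are semantically weaker, and downstream rankings are fairly insensitive
to β within (0, 1).

## Classifier

An SVM with RBF kernel, C = 1 and feature standardization (fitted on
training rows only) is the default: the features are 14 bounded,
strongly correlated scores, for which a regularized kernel machine is a
reasonable default and the margin provides the continuous ranking
score. Kernel, C, scaling and seed are exposed in `ClassifierConfig`;
training is deterministic given data and seed. Ranking and ROC use the
signed margin directly rather than calibrated probabilities; the
operating threshold for confusion metrics defaults to 0.

Positive training pairs are drawn uniformly without replacement from
the edges of a sparse high-confidence cutoff network (optionally forcing
a curated gold set in); negatives are drawn uniformly from pairs with no
edge in a dense permissive network — absence from a permissive network
is the most conservative available evidence of non-interaction.

## Evaluation

- **Metrics.** SEN, SPE, ACC, PRE, MCC and F1 from the confusion table;
  any metric with a zero denominator is reported as 0 with a warning.
  ROC is traced over all score thresholds; AUC equals the Mann–Whitney
  statistic with ties counted ½ (asserted against exhaustive pair
  counting).
- **LOOCV.** Each labeled pair is held out in turn; its L–P edge (if
  present) is removed from the network before its features are
  computed, and the classifier is retrained on the remaining pairs,
  whose features are computed once on the full network. A `strict` mode
  additionally removes all L–P edges incident to either endpoint.
  Deleting the endpoint *nodes* instead would make the held-out pair
  unscorable, so edge removal is the leakage control used. If a
  training round degenerates to a single class (only possible for tiny
  sets), the held-out score is the remaining class at unit margin.
- **Independent test.** The classifier is fitted once on training
  pairs; test positives' edges are removed from the network before test
  features are computed; train/test overlap is rejected.

## Synthetic benchmark

The generator plants a block structure: lncRNAs and proteins are
assigned round-robin to `n_blocks` modules; L–P edges are Bernoulli
with probability `within_block_edge_prob` (default 0.6) inside a module
and `cross_block_edge_prob` (default 0.05) across; within-type
similarities are 1 − |ε| inside a module and |ε| across, with
ε ~ N(0, `similarity_noise`) (default 0.1), clipped to [0, 1], symmetric,
zero diagonal. Defaults are 60 lncRNAs, 40 proteins, 4 blocks, seed 7 —
small enough that a full 14-path LOOCV finishes in seconds on one CPU,
while keeping the planted signal recoverable. Similarities are generated
directly in [0, 1] rather than via simulated expression profiles and
Pearson correlation; this exercises the same thresholding behavior with
far less machinery.

The standard benchmark (`planted_benchmark`) thresholds similarities at
0.5 (which cleanly separates the two similarity modes at the default
noise) and samples 100 within-block and 100 cross-block pairs from the
ground truth. Ground truth is block co-membership, not edge presence:
the benchmark asks whether path features expose the module structure,
which is the property the method claims, rather than whether a pair's
own (removed) edge was previously seen.

What the generator does *not* emulate: heavy-tailed degree
distributions, overlapping modules, correlated noise across the three
evidence layers, incomplete node coverage between layers, and the
scale of real lncRNA/protein catalogs. Passing the recovery benchmark
therefore shows the pipeline is correct and sensitive to planted
topology; it does not by itself predict performance on real networks.

### Permutation null

The no-signal reference is LOOCV AUC under label permutation. Two
protocol points matter. First, the shuffle RNG must be independent of
the pair-sampling RNG; seeding both streams identically correlates the
shuffle with the sampling order and biases the null. Second, the null
AUC is reported as the mean over five independent shuffles: with
strongly clustered feature vectors, a single-shuffle LOOCV AUC is a
high-variance draw and is pessimistically biased (removing a sample
tilts its near-duplicates' majority against it), so individual shuffles
can stray well below 0.5 while the expectation stays near chance.

## Problem sizes used in checks

Brute-force oracle comparisons (explicit walk enumeration vs matrix
products) run on random networks with at most 8 nodes per type, all 14
paths, at 1e-10; symmetry and range are asserted across 100 seeded
random networks; AUC equivalence across 1000 random score vectors; the
recovery and null runs use the default 60×40 benchmark with 200 labeled
pairs. These sizes make every property cheap to check exhaustively
while remaining large enough to exercise zero-degree nodes, ties and
both odd and even path splits.

## Known limitations

- Metapaths with repeated relation types reuse the same global
  transition matrix at every hop; walks may revisit nodes (this is
  inherent to the reachable-matrix formulation, not a bug).
- Relations are unweighted by default after thresholding; HeteSim on
  weighted matrices is supported but the package's reference behavior
  and tests target the binarized form.
- Negatives are unverified non-edges, as is standard in this setting;
  some are surely undiscovered positives on real data.
- LOOCV retrains the classifier per round, which is exact but
  quadratic-ish in the labeled-set size; for much larger labeled sets a
  k-fold scheme (out of scope here) would be the practical choice.
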