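# Methods

## Model

`winmda` treats miRNA–disease association prediction as a proximity query on
a weighted heterogeneous graph whose `D + M` nodes are the diseases and
miRNAs of a curated association list. The working assumptions are the two
standard ones for this problem class: functionally similar miRNAs tend to be
implicated in similar diseases, and similar diseases tend to involve
functionally similar miRNAs. Everything below is deterministic given the
inputs; the only randomness in the package lives in the synthetic-data
generator and the k-fold partitioner, both seeded.

### Similarity layers

**Disease semantic similarity (SDD).** Disease terms carry one or more
dot-delimited tree codes; stripping the last segment of a code yields its
parent. The DAG of a disease consists of the term plus all prefix-ancestors,
edges pointing from general to specific. Contributions attenuate by
`α ∈ (0, 1)` per hierarchy level and are weighted by the code multiplicity
`β` of the contributing term:

    D_H(H) = 1,   D_H(d) = β(d) · Σ over directed paths d→H of α^len.

This is evaluated as the memoized recursion `P(d) = α · Σ_children P(c)`,
`D_H(d) = β(d)·P(d)`, which is algebraically identical to the path sum (a
property test checks it against exhaustive path enumeration on random DAGs).
The pairwise similarity normalizes the shared contribution mass by the two
total semantic values. `α` defaults to 0.5, the value conventionally used
for this family of ontology measures; larger `α` flattens the hierarchy
(remote ancestors matter more), smaller `α` localizes it.

Two conventions worth making explicit:

* a term's multiplicity `β` counts *all* tree codes the ontology lists for
  it, and the focus term's own multiplicity is irrelevant (its contribution
  is pinned to 1);
* two annotated diseases whose DAGs share no term get similarity 0 — a
  defined value, distinct from the sentinel −1 that marks diseases absent
  from the ontology altogether. Zero cannot occur in a real MeSH-style
  hierarchy (everything shares top-level roots) but does occur in synthetic
  fixtures with disjoint block subtrees.

**miRNA functional similarity (SMM).** Each miRNA's disease group is its
column support in the association matrix. One disease versus a group scores
the best match; a pair of miRNAs scores the average of all cross-group best
matches, both directions, divided by the combined group size. Sentinel
entries are skipped inside the max (missing data is not a similarity of −1);
if some but not all cross matches are undefined, the undefined ones drop out
of both the numerator and the denominator; a pair with no defined cross
match, or an empty group, is sentinel.

**Interaction-profile kernels.** Gaussian kernels on the binary
rows/columns, `exp(−γ‖u−v‖²)` with `γ = n / Σ‖profile‖²`, so the bandwidth
adapts to the matrix density. The disease-side kernel passes through the
logistic map `1/(1 + exp(−15·x + ln 9999))`, which sends 0 to 10⁻⁴ and
≈0.55+ toward 1 — it suppresses the spuriously moderate kernel similarity
two empty-ish profiles would otherwise get. The miRNA-side kernel is used
uncorrected; the asymmetry is kept deliberately as the method defines it,
and the diagonal of the corrected matrix is logistic(1) ≈ 0.997, not forced
to 1. Integration is entrywise: semantic/functional similarity where defined
(`≥ 0`, so an exact 0 counts as defined), kernel similarity otherwise. An
all-zero association matrix leaves the bandwidth undefined and is rejected.

### Network and scoring

Edge weights are `1/exp(s)` of the relevant similarity, so weights lie in
`[1/e, 1]` and higher similarity means a shorter edge. Disease–disease and
miRNA–miRNA edges always exist (similarity 0 gives weight 1, still an edge);
disease–miRNA edges exist for every known pair (weight exactly `1/e`) and
for unknown pairs whose miRNA has a most-similar peer already known to the
disease — weighted by `1/exp` of the best such peer similarity. The
self-loop weights the formula produces are harmless: with strictly positive
weights no shortest path uses them, so the path matrix has a zero diagonal.

All-pairs shortest paths are computed by per-source Dijkstra
(`scipy.sparse.csgraph`); absent edges are infinite distances, and
unreachable pairs stay infinite through scoring and sort last in rankings.
Correctness is checked against brute-force simple-path enumeration on random
graphs of up to 8 nodes.

The final score blends the direct path with the mean path length to the `T`
most integrated-similar neighbors of each endpoint (neighbor lists exclude
the node itself, clamp to the population, and break ties toward the lower
index):

    FPR(i, j) = w · (SDM + SMD) / (2T) + (1 − w) · SPM(i, j).

Defaults `T = 16`, `w = 0.6` follow the parameter study of the source
method. `w = 0` degenerates to pure shortest-path ranking; `w = 1` discards
the direct edge entirely, which on the planted fixture measurably hurts
(the sensitivity table in the acceptance tests shows the drop). Smaller
scores are stronger predictions; rankings are ascending, with a descending
option retained only for auditability.

## Evaluation

Global LOOCV removes each known pair in turn, re-runs every quantity that
depends on the association matrix (functional similarity, kernels, inferred
edges, neighbor sets — the ontology-based SDD is cached, as it cannot leak),
and ranks the held-out pair's score against all unknown pairs. Local LOOCV
restricts the candidate set to the same disease's unknown miRNAs, skipping
diseases with fewer than two known miRNAs or no candidates, and aggregates
per-disease AUCs weighted by test count. Repeated k-fold partitions the
known pairs at random (seeded), holds out whole folds, and reports
mean ± sd of the per-repeat AUC; with `k` equal to the number of known
pairs it coincides exactly with global LOOCV.

AUC is rank-based with midrank tie handling (the probability a random
positive outranks a random candidate); infinite test scores rank behind all
finite ones. The in-package implementation is cross-checked against
scikit-learn's `roc_auc_score` in the test suite but never delegated to it.
A `refit=False` mode scores all folds from the full-data network — faster
and useful for sweeps, but optimistic because the held-out edge influences
the network; the leakage-free mode is the default everywhere.

`sensitivity_table` shares the expensive per-fold network/shortest-path
computation across all `(T, w)` settings, since only the neighbor
aggregation depends on `T` and only the final convex combination on `w`.

## Synthetic data

The generator emulates the two inputs: a rooted ontology forest (one subtree
per block, random-depth chains, ~30% of diseases carrying a second code so
multiplicity β > 1 occurs) and a planted-block association matrix. The
within-block signal is *column-shared* — each in-block miRNA switches on for
all the block's diseases at rate `(density − noise)/(1 − noise)` — and iid
Bernoulli(noise) associations are added everywhere. Hence the within-block
marginal is exactly `density`, the cross-block marginal exactly `noise`,
`noise = 0` gives identical row supports inside a block, and
`noise = density` collapses to an exchangeable no-signal null (measured
LOOCV AUC ≈ 0.42–0.5 on it). `noise > density` is rejected as infeasible.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real curated databases, name noise/synonymy, annotation
depth heterogeneity of real MeSH, or cross-block ontology sharing (real
diseases all share top-level roots). A green planted-fixture test therefore
establishes that the pipeline recovers block-structured signal and is
correctly wired end to end — not that it attains any particular AUC on a
real HMDD snapshot, whose headline numbers depend on the exact 2018 data
freeze and are out of scope here.

## Numerical choices and edge cases

- Sentinel for "undefined similarity" is exactly −1.0 and is compared by
  equality; all defined similarities are ≥ 0 by construction.
- Neighbor and ranking ties break toward the lower index, making every
  output deterministic for a fixed input ordering (which is itself fixed to
  first occurrence in the association file).
- Diseases/miRNAs mentioned only in the ontology but never in an
  association do not enter the model; a miRNA losing its last association
  during cross-validation falls back to kernel similarity via the sentinel
  path.
- Shortest-path input weights are validated nonnegative; distances use
  IEEE infinity rather than a magic number, and `inf` serializes literally
  in TSV output.

## Known limitations

- Per-fold refitting is O(folds × pipeline); fine at fixture scale
  (~seconds for 123 folds on 20×20), but a full 383×495 database at LOOCV
  scale would want the `refit=False` screen or fold-level parallelism.
- The functional-similarity pairwise loop is vectorized per pair of groups,
  not fully matrixized; it is the pipeline bottleneck on large inputs.
- Only the stated logistic constants (−15, ln 9999) are supported; they are
  not exposed as parameters because the measure is defined with them.
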