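# Methods

## Graphlets, orbits, and interaction isomers

A graphlet is a connected, non-isomorphic induced subgraph; we restrict to
2–4 nodes, giving nine graphlets G0–G8 ordered by (node count, edge count,
degree sequence): the edge, the 3-path, the triangle, the 4-path, the
3-star, the 4-cycle, the paw, the diamond, and K4. Vertices of a graphlet
fall into automorphism orbits — 15 in total, labeled 0–14 in graphlet
order and, within a graphlet, by ascending vertex degree (on ≤ 4 nodes no
two distinct orbits of a graphlet share a degree, so this is well
defined). Orbit 0 is the end of the edge, orbits 1/2 the end/middle of the
3-path, orbit 3 the triangle, and so on.

A **graphlet-interaction isomer** is a graphlet with an ordered pair of
marked vertices, up to automorphisms of the graphlet. Enumerating ordered
marked pairs modulo automorphism yields 1, 3, 1, 6, 3, 2, 7, 4, 1 isomers
for G0..G8 — 28 in all. The catalog orders them by graphlet and, within a
graphlet, by (target orbit, source orbit, marked-pair adjacency). That
convention anchors:

- I1 — the edge;
- I2 — 3-path, both marks at the ends (non-adjacent);
- I3 — 3-path, source at the middle: counts third nodes attached to the
  source only;
- I4 — 3-path, target at the middle: counts third nodes attached to the
  target only;
- I5 — the triangle.

Reversing the marked pair is an involution `sym` on {1..28} (`sym` fixes
I1, I2, I5 and swaps I3↔I4, etc.), and counts obey
`N_ij(I_k) = N_ji(I_sym(k))` exactly. The catalogs are enumerated at run
time from first principles — only the ordering convention is an input.

Everything is classified through canonical certificates: the minimum edge
bitmask over relabelings that fix the marked vertices (marked-pair
certificate) or the single marked vertex (orbit certificate). With at most
two unmarked vertices the minimization is over at most two permutations,
so certificates are cheap enough to use inside counting loops.

## Counting conventions

Occurrences are **induced**: a vertex subset realizes a graphlet only if
its induced subgraph equals it, so absent edges are forbidden. This
convention is what makes the toy worked examples come out exactly (e.g. an
adjacent pair with a common neighbor is the triangle isomer, not also a
path isomer), and it makes per-subset classification unambiguous.

Three counting routes share the same contract:

- `oracle_count` — exhaustive enumeration of every 2/3/4-subset containing
  the pair; O(n²) subsets per pair with no shortcuts. Test oracle only; it
  refuses networks above 15 nodes.
- `count_interaction` — the definitional traversal over third nodes l and
  unordered fourth pairs {l, m}, classifying each configuration by
  certificate.
- `count_interaction_fast` — the production path. The four 3-node counts
  are closed-form neighbor-set expressions (common-neighbor intersection
  for I2/I5 depending on adjacency; one-sided set differences for I3/I4).
  For 4-node isomers, candidates are restricted to the joint neighborhood
  (a connected 4-subset containing i and j must draw l from N(i) ∪ N(j)
  and m from N(i) ∪ N(j) ∪ N(l)) and each configuration is classified by a
  precomputed 64-entry adjacency-bitmask table. Cost is roughly
  sum-of-squared-degrees per source, which is what makes the benchmark
  evaluation tractable.

Pairwise vectors are memoized per network, and the reverse direction is
derived through `sym` instead of being recounted.

Graphlet signatures (15 orbit counts per gene) enumerate connected
subsets containing the gene by frontier expansion and classify the gene's
position by the single-marked certificate; orbit 0 equals the degree by
construction.

## Scoring and normalization

Disease gene i's outflow totals `N_i(I_k)` are summed over a
**normalization set**. Two conventions are supported because the method's
worked protocol normalizes over all other genes, while in production one
normalizes over the genes actually competing:

- `candidates` (default): (C ∪ D) \ {i};
- `all`: every other node of the network.

Division by a zero total is defined as 0 — an isomer the disease gene
never exhibits carries no evidence. With nonzero totals the normalized
values sum to exactly 1 over the normalization set, a conservation law the
tests assert.

Scores are additive over disease genes and non-negative under
non-negative weights. Ranking ties are broken by lexicographic gene
identifier, keeping rankings deterministic without any random state. Genes
listed in a family but absent from the network are scored 0 with a logged
warning rather than dropped silently. Known disease genes are excluded
from ordinary rankings; they are scored only while held out in
cross-validation.

## Weight regression

The design matrix has one row per (family, gene in C ∪ D) with features
`x_jk = Σ_{i∈D} norm(N_ij(I_k))` and binary labels (1 for known disease
genes). A disease gene's own row is computed against D minus itself, so no
row uses self-interaction to predict its own label. Weights solve ordinary
least squares **without intercept** via the minimum-norm solution
(pseudoinverse), which coincides with (XᵀX)⁻¹Xᵀs at full column rank and
stays defined under rank deficiency. Weights are unconstrained in sign; on
noiseless synthetic labels at full rank the recovery is exact to < 1e-8,
which the acceptance suite asserts.

## Leave-one-out cross-validation

For each family with at least two in-network known genes, each known gene
is held out in turn; the reduced known set scores the pool
(C \ D) ∪ {held-out}; the held-out gene is the sole positive of that
leave-out. Confusion counts are pooled over leave-outs and families
(micro-averaging — one printed curve, matching how single summary curves
are usually produced), and thresholds sweep the distinct observed scores
from highest to lowest, tied scores sharing one threshold point.
Precision, recall, FPR, TPR and F follow the standard formulas; AUROC is
the trapezoidal area of the swept ROC, equivalent to a Mann–Whitney
statistic with ties credited one half.

Baselines:

- **Neighborhood-k**: a candidate is positive with ≥ k direct links to the
  known genes; as a scorer, the link count itself is the ranking score.
- **Random walk with restart**: p ← (1−r)·W·p + r·p0 on the
  column-normalized adjacency, uniform restart over the seed set, default
  r = 0.7, iterated until the L1 change is below 1e-10 (hard cap 10⁴
  iterations, then an error reporting the residual).

Curve domination (`pr_dominates`) compares precision–recall **upper
envelopes**: at every recall the other method attains, the envelope of the
dominating curve must be at least as high, and strictly higher somewhere.
Pointwise strictness everywhere would be unsatisfiable whenever both
curves touch precision 1.0.

## Synthetic benchmark

The generator emulates the statistical structure the method exploits in
real interactomes: disease genes of one family occupy densely
interconnected modules and therefore share many graphlets, while decoy
candidates are ordinary network genes.

Defaults (`SimulationConfig`): a 500-gene preferential-attachment
background with attachment 7 — mean degree ≈ 14, matching the density of
curated integrated interactomes (on the order of 10⁴ proteins and 8×10⁴
interactions, mean degree ≈ 13), where decoys plausibly touch disease
genes and direct-link counting is informative but not trivially perfect;
ten disjoint 8-gene modules, each absent within-module pair wired with
probability 0.8 (near-cliques, the strong-module regime); 50 uniform decoy
candidates per family; all randomness from one seed. With p_within = 0
planting adds nothing and the families are a null model.

The full evaluation pipeline fits isomer weights on an **independent
training realization** with three times as many families (seeded by a
fixed offset from the benchmark seed), then runs LOOCV on the test
realization — mirroring held-out splits in which the training portion is
several times the test portion. Weight learning matters here: with 28
isomers at unit weight, abundant but weakly informative 4-node isomers
(hub-driven paths and stars) dilute the module signal, and the regression
learns to emphasize the clique-like isomers instead.

Problem sizes were chosen so the whole benchmark (training counts, test
counts, baselines, and a three-seed null) completes in a few minutes of
one CPU: 80 pooled leave-outs give stable curves, and the pooled-AUROC
null estimator has a standard deviation of ≈ 0.035 per draw, which is why
the null check averages three fixed seeds (0, 1, 2) rather than trusting
one.

What the generator does **not** emulate: overlapping disease families,
locus structure (decoys are uniform, not co-located genes), degree bias of
disease-gene discovery, false-positive/false-negative interaction edges,
and any annotation-driven candidate filtering. Passing the benchmark shows
the pipeline recovers planted dense-module structure; it does not certify
performance on curated disease data.

Toy fixtures: the 5-node protocol network and the two schema networks are
transcriptions; the protocol topology was recovered by exhaustive search
over all 5-node graphs for those reproducing the printed normalized vector
exactly (unique up to relabeling, see the fixture docstring), and the
schema topologies are the minimal graphs consistent with their printed
vectors and scores.

## Numerical and degenerate-input choices

- Self-loops and duplicate edges are dropped at load with a logged count;
  isolated genes get all-zero vectors and signatures.
- Signature similarity is |Pearson r| of the 15-orbit vectors; a constant
  signature (e.g. a degree-1 pendant) makes r undefined, returned as NaN
  and excluded from histograms with a logged count.
- The two-sample comparison defaults to Welch's t-test; Student's pooled
  variant is a flag. Identical degenerate samples return (t=0, p=1);
  degenerate samples with different means raise.
- Largest-component ties are broken by the component containing the
  lexicographically smallest gene identifier.
- The RWR column normalization leaves zero-degree columns zero; since the
  pipeline extracts the largest connected component first, no probability
  mass is lost in practice.

## Known limitations

- Counting is exact but Python-level; networks of ≥ 10⁵ edges with
  high-degree hubs will be slow. The per-network pair cache helps LOOCV
  (the same ordered pairs recur across leave-outs) but is never persisted.
- Graphlets with ≥ 5 nodes, weighted or directed networks, and
  full 73-orbit graphlet degree vectors are out of scope.
- One global weight vector is fitted per training split; per-family
  weights are not supported.
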