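# Methods

## The classification problem

A genetic interaction between two genes is invisible to either gene alone:
synthetic lethality (SL) kills the cell only when both genes are inhibited,
synthetic viability (SV) rescues it. `ginet` treats the prediction of the
interaction class {SL, SV, NOT} of a gene pair as a supervised three-class
problem whose only inputs are topological properties of the pair's position
in a physical protein–protein interaction network. The working hypothesis is
geometric: SL partners tend to back up each other's function from *different*
network neighborhoods (they are distant, separated by small edge cuts, yet
individually central), while SV partners act in the *same* process (adjacent
or nearly adjacent, same community, hard to disconnect from one another).

## Features

Node-wise properties (Table: degree, betweenness, closeness, k-core index,
Burt's constraint, reciprocal eccentricity, eigenvector centrality, hub
score, 1/2/3-neighborhood sizes, triangle count) are computed per gene and
averaged over the pair — `x(ab) = (x(a)+x(b))/2`; sum, absolute difference,
max and min are available as alternative aggregations but averaging is the
default. Pairwise properties are computed directly: shortest-path length,
local vertex connectivity (cohesion), local edge connectivity (adhesion),
common-neighbor count, Leiden community co-membership (0/1) and mean
community size. The default registry has 18 features; the `CORE5` subset
{shortest_path, avg_neighbor2, avg_betweenness, avg_triangle, adhesion} is
what bootstrap selection retains.

Numerical conventions, chosen where the standard definitions leave room:

* **Betweenness** is unnormalized, undirected (each unordered pair counted
  once), with geodesic ties split fractionally (Brandes). No normalization
  is applied before averaging.
* **Closeness** on a disconnected graph is computed within the node's
  component and scaled by (reachable−1)/(n−1), so values remain comparable
  across components.
* **Eccentricity** is stored as the *reciprocal* of the maximum finite
  geodesic from the node (`eccentricity_mode="raw"` restores the plain
  maximum); 0 is reserved for isolated nodes.
* **Coreness** is the standard k-core index (largest k surviving k-core
  peeling).
* **Infinite shortest paths** between disconnected pairs are replaced by the
  network's finite diameter — on a disconnected graph, the longest finite
  geodesic over all components. Cohesion and adhesion of disconnected pairs
  are both 0.
* **Adjacent-pair vertex connectivity** is undefined under Menger's theorem,
  so the deterministic convention κ(a,b) := κ_{G−(a,b)}(a,b) + 1 is used.
* **Eigenvector centrality and hub score** are max-normalized to [0, 1]. On
  connected non-bipartite graphs the two coincide; on bipartite or
  disconnected graphs the A² eigenproblem underlying the hub score is
  degenerate and the returned vector is one of several valid solutions (the
  property test restricts itself accordingly).
* **Communities** come from Leiden with the constant Potts model objective,
  resolution 0.005, 10 refinement iterations and an explicit seed (a
  modularity objective with the same resolution knob is available). Low CPM
  resolution keeps cliques and dense blocks intact, which is what the
  co-membership feature needs.

## Dataset construction

The NOT class is sampled uniformly from the unordered pair space of the
network's genes, excluding any supplied known-interaction or
ortholog-derived pair lists, by rejection sampling with a retry cap of
200·n + 1000 draws (the admissible space is never materialized; the cap only
triggers when the space is nearly exhausted, which is reported as a
guardrail error).

Balancing supports random under-sampling, random over-sampling
(duplication), a hybrid of the two, and `hybrid-smote`, which synthesizes
minority rows by interpolating toward one of the k = 5 nearest same-class
neighbors in feature space. The published class sizes
(SL 26,445 / SV 3,867 / NOT 9,986 balanced to 11,238 / 11,601 / 4,230)
shrink one class while growing another, which only a hybrid scheme can
produce; those balanced sizes ship as the `PUBLISHED_BALANCE_TARGETS` preset and
the split arithmetic (70% of 27,069 = 18,948) is verified exactly. Splitting
is stratified per class: floor(frac·count) rows per class, with the
remaining whole-row budget assigned by largest fractional remainder so
|train| = floor(frac·total) exactly.

## Classifier and feature selection

The forest uses 500 trees, √p feature subsampling, unlimited depth, and an
explicit seed; out-of-bag (OOB) error is always computed. Class-probability
ties are broken by the fixed order SL < SV < NOT. Evaluation reports the
3×3 confusion matrix, per-class recall, accuracy with a Wilson 90% binomial
CI, one-vs-rest ROC/AUC per class with an unweighted macro average, and a
one-vs-rest accuracy sweep over probability thresholds 0.1–0.9.

Two permutation-importance estimators are provided:

* `permutation_importance` — whole-model holdout drop: baseline accuracy
  minus mean accuracy over r permutations of one column (default r = 5).
* `oob_permutation_importance` — per-tree OOB drop, averaged over trees,
  i.e. the classic random-forest variable importance. This is the default
  inside bootstrap selection because averaging over hundreds of trees makes
  the ranking stable at small sample sizes, and evaluating on OOB rows stops
  noise features the forest merely overfits from scoring as informative.

Bootstrap selection fits B models (default 1000; a guardrail refuses
B > 2000 without `force`), each on a freshly drawn NOT set with all classes
under-sampled to the smallest class count. A feature is "selected by a
model" when its importance ranks in the top k (default 5); features selected
in more than 90% of models with mean rank ≤ k are retained. A Spearman
correlation screen is advisory only — correlated features are flagged, not
dropped, since each of the correlated core features still costs accuracy
when removed.

## Statistical tests

The two-sample Kolmogorov–Smirnov test uses the asymptotic Kolmogorov
distribution with the effective-sample-size correction n₁n₂/(n₁+n₂); exact
small-sample p-values are deliberately out of scope. DeLong's test for two
correlated AUCs is implemented from the structural components of the
Mann–Whitney statistic (midrank form); it requires paired scores on the same
cases and returns a two-sided normal p-value (identical score vectors give
z = 0, p = 1 rather than 0/0). ROC curves sweep thresholds over the unique
scores; the trapezoidal AUC equals the tie-corrected pairwise U estimate to
1e-10, which the tests verify against an independent pairwise-comparison
oracle. The two-proportion z-test uses the pooled variance. Under their null
simulations (N(0,1) vs N(0,1) at n = 200; two noisy copies of one score at
n = 500) both KS and DeLong reject at 4.8–5.7% for nominal α = 5%.

## GO pair statistics

Average term count `(|T(a)|+|T(b)|)/2` and Jaccard index `|T(a)∩T(b)| /
|T(a)∪T(b)|` are computed from *direct* annotations (no ancestor
propagation), by default restricted to the biological_process namespace,
counting distinct term IDs rather than annotation lines, with no
evidence-code filtering. Pairs with an unannotated gene, or an empty union,
yield a missing value that is logged, never an error.

## Synthetic benchmark

The generator plants the class structure the classifier assumes into a
stochastic block model: 600 nodes in 12 blocks, intra-block edge probability
0.12, inter-block probability 1.5e-4, 300 pairs per class, seeded end to end
(network, pairs and annotation checksums are recorded in a manifest).

* **SV pairs** are same-block and preferentially adjacent (80%) or at
  distance ≤ 2, so they inherit short paths, co-membership, and adhesion
  near their min degree.
* **SL pairs** connect different blocks, with endpoints drawn with
  probability ∝ degree³ (hubs). The inter-block probability is set so that a
  block's total capacity to the rest of the network (≈ 50·550·1.5e-4 ≈ 4–5
  edges) sits *below* a hub's degree: the sparse inter-block cut, not the
  endpoint degree, then limits the max-flow between SL endpoints, giving SL
  pairs low adhesion while their endpoints keep high betweenness, triangle
  counts and 2-neighborhoods. With a denser inter-block regime adhesion
  reduces to min(degree) and degree-biased SL endpoints could never show
  lower adhesion than SV pairs — the effect the feature set depends on.
  These two knobs (p_out, hub bias) were calibrated once so that all five
  core feature directions hold with KS p ≤ 3e-7 and then frozen as the
  defaults.
* **NOT pairs** are uniform background, excluding planted pairs.
* **GO annotations** draw 10–40 terms per gene from a 4,000-term universe;
  SV pairs share 50% of their terms, SL pairs 3%, and SL genes carry 1.6×
  richer term sets.

What the benchmark does *not* emulate: BioGRID's heavy-tailed degree
distribution and scale (~20k proteins), annotation incompleteness and
study bias, or label noise in curated interaction databases. Passing the
recovery tests therefore demonstrates that the pipeline's machinery —
feature computation, balancing, training, selection, statistics — recovers a
planted signal of the assumed geometry at desk scale; it does not certify
accuracy on real interaction databases.

At these conditions (seed 1): three-class test accuracy 0.80 with per-class
one-vs-rest AUC 0.89 (SL) / 1.00 (SV) / 0.87 (NOT); all five core feature
directions significant; B = 50 bootstrap selection retains all five core
features in 100% of models against five pure-noise features; OOB error
changes by < 0.01 between 100 and 500 trees. The test suite and
`scripts/acceptance.py` recompute each of these numbers; none are stored.

## Problem sizes

Simulations were sized for quick desk-scale runs: a 600-node benchmark, 900
labeled pairs, 200 twelve-node graphs for the brute-force oracle
comparisons, B = 50 bootstrap models at 100 trees, and 2000/1000-replicate
calibration nulls. The full test suite runs in under a minute; the
acceptance script in about 40 seconds.

## Known limitations

* Node identity is the raw gene-symbol string; no alias mapping is applied,
  so networks and pair lists must share a symbol namespace.
* Unweighted, undirected networks only; STRING-style confidence scores must
  be thresholded upstream.
* The DeLong implementation is strictly paired (same cases, same labels);
  comparing models evaluated on different case sets is not supported.
* The whole-model holdout permutation importance is noisy below ~10³ rows;
  prefer the OOB variant there (the default in bootstrap selection).
* Model archives are joblib files tied to the scikit-learn major version
  that wrote them; the loader refuses mismatched feature sets but cannot
  migrate estimators across incompatible sklearn versions.
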