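# Methods

## The mapping criterion

A deletion panel is a mutant-by-marker matrix of presence (1) / absence
(0) calls. The model assumes each absence is caused by physical deletion
of a contiguous chromosome segment, so in a candidate marker order every
present→deleted or deleted→present transition within one mutant witnesses
at least one chromosome break. The score of an order is the total count of
such obligate breaks over all mutants and all adjacencies, including two
virtual end markers: the start of the mapped region is present in every
mutant (the region is entered from intact chromosome), while the opposite
end is either deleted in all mutants (`del`) or copies its neighbour's
status and contributes nothing (`any`). `del` suits regions known to
terminate in deletable sequence; `any` is robust when the mutant panel was
ascertained by phenotype so that some markers are deleted in most mutants.
Minimising total breaks over orders is a travelling-salesman-path problem
with non-negative integer edge costs.

Because the start end is fixed present and the far end is not, the two
reading directions of a map can differ by at most one break under `any`
(the two end markers' deletion counts), and reversed orders are frequently
co-optimal. A physical map has no intrinsic orientation, so everything
downstream (accuracy scoring in particular) treats an order and its
reversal as the same map.

## Exact search and co-optimal enumeration

`solve_exact` enumerates **all** minimum-break orders by depth-first
branch and bound. Per-mutant states are packed into integer bitmasks, so
one adjacency evaluation is a handful of bit operations. Two admissible
bounds prune the tree: the partial-path cost itself (edge costs are
non-negative), and a pairwise bound — for every unordered item, the
cheapest possible entering break count given any classification its
predecessor could hand over — summed over the unplaced suffix. Children
are expanded cheapest-increment-first with lexicographic tie-break, so
results are deterministic.

Degenerate, weakly constrained matrices (for example panels where most
mutants carry only a two-marker deletion) can hold astronomically many
co-optimal orders. Three caps keep a search bounded, all deterministic:
an order cap (50 000 by default — any search of ≤ 8 items remains
exhaustive even under complete ties), a node budget that progressively
narrows the accepted cost band and finally freezes tie collection, and a
hard node ceiling that abandons a pathological search with the best
results found. None of these activates on well-determined panels of the
study's scale.

## The clustered pipeline

Ordering 70+ markers directly is infeasible, so `map_pipeline` follows a
divide-and-conquer recursion:

1. **Cluster.** Markers are grouped into *n* clusters (default 12, the
   setting used for ~70 markers) by the asymmetric-binary distance between
   their presence profiles — among mutants where at least one of two
   markers is present, the fraction where exactly one is — under Ward
   (squared-distance) agglomeration. Two never-present profiles are at
   distance 0 and a never-present profile is at distance 1 from any other,
   keeping the distance total. This matches the R idiom
   `hclust(dist(x, method="binary"), method="ward.D2")`, and a test
   cross-checks the partition against Rscript when available.
2. **Smooth.** A cluster is a multi-state virtual marker whose state is
   its count of present members. A state of *num* − 1 in a cluster of more
   than three members is treated as a PCR artefact and reset to *num*.
   The same correction is applied to the underlying matrix (the lone
   deleted member is reset to present) and **all** downstream costs use
   the corrected matrix: ranking assembled maps by uncorrected breaks
   would reward maps that rearrange markers to absorb isolated errors —
   precisely what the correction exists to prevent.
3. **Order clusters exactly.** The multi-state walk carries a per-mutant
   present/deleted classification: from a present predecessor, a fully
   present cluster costs 0 (stay present) and any other state costs 1
   (classify deleted); from a deleted predecessor, any present member
   costs 1 (classify present) and state 0 costs 0. With singleton clusters
   this reduces exactly to the plain binary walk (a tested invariant).
4. **Refine within clusters.** For every near-optimal cluster order, each
   cluster's actual markers are ordered exactly between virtual markers
   representing the adjoining clusters: the left flank enters as the
   classification the cluster-order walk assigns there, the right flank
   prices one terminal adjacency by the same rules. Markers with identical
   (corrected) profiles are collapsed to single units first — no data can
   order them. A cluster whose distinct units exceed the search ceiling
   (14) is handled recursively the way the whole map is: cluster the
   units, order the sub-clusters between the flanks, recurse.
5. **Assemble and re-rank.** The break count of an assembled map
   decomposes into block-internal costs, pairwise block-boundary costs and
   the end terms, so a dynamic programme over each cluster order's
   candidate member orders finds the exact minimum over all assemblies and
   backtracks every optimal one. The reported maps are those minimal in
   actual (corrected-matrix) break count across all refined cluster
   orders; one representative is kept per family of maps differing only
   inside identical-profile groups, and `n_best_maps` counts families.

The clustered walk only approximates the assembled map's break count
(smoothing rewrites states; a cluster's internal arrangement can absorb or
expose boundary breaks), so refinement is not restricted to exactly
cost-minimal cluster orders: orders within a small slack (default 2
breaks — covering the one-break orientation asymmetry plus one smoothing
distortion) are refined too, and the final exact re-ranking keeps true
minima only. Without the slack, the pipeline's reported best cost exceeded
the true optimum on a substantial fraction of simulated panels.

## The synthetic-panel generator

The generator emulates a mutagenised deletion panel with a known true
marker order. Every mutant starts with one deleted adjacent marker pair —
uniform over the *Ma* − 1 pairs, or, for panels ascertained by phenotype
("biased"), at a position drawn from Normal(*Ma*/2, *Ma*/2), rounded and
resampled until inside the map. Runs then grow to an exact genome-wide
budget of deleted cells: each operation deletes a uniformly drawn number
of the cells currently neighbouring deleted runs (a uniform subset of run
ends, so every run grows by at most one cell per side per operation), and
an operation that would overshoot the budget is discarded and redrawn.
This yields moderately dispersed run lengths around budget/mutants.
Optional PCR errors are injected afterwards: single cells drawn uniformly
among present cells whose neighbours in the true order are all present, so
no real run changes length and every error is an isolated singleton.

What the generator does **not** emulate: multiple independent real
deletions per mutant (real panels have them; here extra runs arise only as
injected errors), mutagen physics (dose, LET), marker spacing
heterogeneity, and missing or ambiguous genotype calls (the model has no
missing-data state). Passing tests therefore demonstrate correctness of
the method under the stated deletion model, not robustness to every
artefact of a wet-lab panel.

## The accuracy study

A scenario fixes generator and mapping settings and runs replicates:
generate, shuffle the marker columns (the solver must not inherit the
truth from input order), map, score. A replicate succeeds if the true
order — after collapsing identical-profile groups and disregarding
reading direction — is among the co-optimal maps. Replicate seeds derive
deterministically from the scenario's base seed, and all sweep points
share one replicate seed stream, so comparisons between sweep points and
between end options are paired. The standard suite sweeps deleted
elements (200–500, crossed with bias and end option), mutant count,
marker count (both at the fixed deleted-cell proportion 0.1374, the value
that gives 400 deleted cells at 71 × 41, rounded half away from zero) and
injected PCR errors.

At the study scale (71 markers, 41 mutants, `any`, 12 clusters) the
pipeline recovers the true order in roughly 75–85 % of panels with 400
deleted elements and ~90 % with 442, with a mean of ~1.5–2.5 co-optimal
maps; accuracy rises and ambiguity falls monotonically along the
deleted-element sweep, and `any` outperforms `del` on non-biased panels.
The graded tests run the two headline points at 30 replicates and the
trend sweep at 12 replicates for the two weakly determined points and 30
for the rest — problem sizes chosen so the whole suite solves in minutes
while leaving the subtle comparisons their precision.

## Robustness to PCR errors — a known limitation

Isolated genotyping errors are handled by the smoothing rule, which
corrects ~80 % of injected singletons. The remainder are structurally
uncorrectable from the stated rule: errors inside clusters of ≤ 3
markers, two errors of one mutant inside one cluster, and errors sharing
a cluster with the same mutant's real run. Each uncorrected error admits
a within-cluster swap that strictly beats the true order (placing the
error marker adjacent to deleted neighbours saves two breaks and affects
no other mutant), and two same-mutant errors on markers with identical
real profiles create an identical-profile group whose members are
physically separated — the collapsed true order then contains a repeated
group and cannot equal any single map. Measured on 400-deletion panels,
accuracy is nearly unchanged at 10 injected errors but drops steeply at
30–50, and an upper bound (the fraction of replicates whose profile
groups are all contiguous in the truth) shows *no* ordering method could
avoid the drop under this error model and success definition. Users
mapping error-prone genotype data should duplicate PCR calls rather than
rely on the smoothing rule alone.

## Numerical and design choices

- Costs are integers; mutants are unweighted; the matrix must be complete
  (no missing-data state exists in the model).
- Cell values parse strictly as the characters `0`/`1`; matrices merge
  only over identical marker sets (a missing genotype is not "present");
  name matching is case-sensitive exact.
- Phenotype encoding appends GSF/SPF columns: hermaphrodite → (0, 1),
  asexual → (1, 0), female-like → (0, 0), non-maturing anthers and male →
  (1, 1).
- Agglomeration ties and search ties are broken deterministically
  (scipy's agglomeration order; lexicographic item names), so every run
  of every entry point is bit-reproducible under a fixed seed.
- The search ceiling (14 orderable units per exact search), the refinement
  slack (2), the enumeration caps and the node budgets are configurable
  constants in `delmap.solver`; their defaults are chosen so that exact
  guarantees hold wherever the guarantees are claimed and degenerate
  inputs stay bounded.
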