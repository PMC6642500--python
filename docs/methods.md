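# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its simulation-based tests do and do not show.

## The constrained merge

**Inputs.** A dissimilarity matrix `D` on taxa `S` (symmetric, zero
diagonal, nonnegative; the triangle inequality is *not* assumed, since
estimated distances routinely violate it) and unrooted binary constraint
trees on pairwise disjoint subsets of `S`.

**Loop.** The merge shares NJ's formulas verbatim: the Studier–Keppler
form of the selection criterion, `Q[i,j] = (r-2)·D[i,j] − Σ_k D[i,k] −
Σ_k D[j,k]` over the `r` active nodes, and the update `D[z,k] = (D[x,k] +
D[y,k] − D[x,y])/2` after the join `z = (x,y)`.  Each iteration sorts the
strict upper triangle of `Q` ascending (ties broken lexicographically on
the sorted label pair, which makes every routine deterministic and
label-permutation equivariant) and accepts the first pair passing two
screens:

1. *Cherry screen.*  In every constraint tree containing both `x` and
   `y`, the pair must form a cherry.  Trees shrunk to ≤ 3 leaves carry no
   unrooted topology and impose nothing; trees shrunk to ≤ 2 leaves are
   dropped.
2. *Compatibility screen.*  The relabeling `x, y → z` is simulated on
   copies; every affected constraint tree containing `z` (with ≥ 4
   leaves) is rooted at `z`, and each unordered pair is tested for rooted
   compatibility with BUILD.  Only trees containing `x` or `y` are
   examined — all other pairs are untouched by the join and compatible by
   induction.  A `groupwise` mode tests the whole set of trees containing
   `z` jointly; group compatibility implies pairwise, so `groupwise`
   never accepts what `pairwise` rejects.  `pairwise` is the default
   because it is the heuristic whose failure behavior we document and
   test.

On acceptance the constraint forest is relabeled in place: a tree with
exactly one of `x, y` has that leaf renamed `z`; a tree with both has the
cherry contracted to the single leaf `z` (implemented as prune-one-and-
rename, which is the same operation).  Merged labels are fresh
identifiers (`@z1`, `@z2`, ...) that cannot collide with taxon names; a
registry maps them back to the original taxon sets.

**Failure.**  Pairwise compatibility of the evolving forest does not
imply joint compatibility, so the greedy scan can strand itself: when a
full scan of the remaining pairs finds no acceptable proposal the merge
raises `NJMergeFailure` carrying the join log.  When a tree *is*
returned it is verified internally (disable with `verify=False`) to be a
compatibility supertree of the original forest.

**Guarantee tested.**  A matrix is *nearly additive* for an
edge-weighted tree `T*` when every entry is within half the shortest
branch length of the corresponding path length.  NJ on such a matrix
returns `T*`; with constraints that agree with `T*` the screens never
block NJ's own trajectory, so the merge returns `T*` as well.  The
acceptance suite exercises this at n ∈ {10, 20, 30} with constraints cut
from centroid decompositions (200/200 recoveries expected), and the
soundness property — supertree or loud failure, never a wrong tree —
over 1000 deliberately abusive runs.

## BUILD

Rooted compatibility is decided by the classic recursion on rooted
triplets: at each level, leaves are joined into components whenever some
input triplet `ab|c` (with all three leaves at that level) links `a` and
`b`; a level with ≥ 3 leaves and a single component is incompatible,
otherwise recurse into components.  Components are computed with
union-find over deterministically sorted leaves.  Trees with ≤ 2 leaves
contribute nothing.  The implementation is validated against exhaustive
enumeration of all rooted binary trees on ≤ 6 leaves (945 shapes).

## Distances

* **AGID** (`agid_matrix`): entry (i, j) is the mean, over gene trees
  containing both taxa, of the number of *internal nodes* on the i–j
  path, computed on the unrooted gene-tree topology.  The node-count
  convention matters only by an affine shift relative to the edge-count
  convention (+1 off-diagonal), and a constant off-diagonal shift moves
  every Q entry by the same amount, so downstream NJ/merge topologies are
  unchanged — this is asserted in tests.  Taxa missing from a gene tree
  are averaged over the co-occurring trees; a pair that never co-occurs
  is an error naming the pair.
* **Log-det / paralinear** (`logdet_matrix`): for each pair, `F` is the
  4×4 relative joint-frequency matrix over sites where both sequences
  show a plain `A/C/G/T` (anything else is excluded pairwise), and
  `d = −(1/4)[ln det F − (1/2) ln(Π_a f_a · Π_a g_a)]` with `f, g` the
  row/column marginals.  This form is additive under general Markov
  substitution and equals expected substitutions/site under Jukes-Cantor,
  which the tests exploit as a closed-form anchor.  Saturation (`det F ≤
  0` or a zero marginal) raises an error naming the pair — no silent
  capping.
* **Additive** (`additive_matrix`): pairwise path lengths of a tree with
  strictly positive branch lengths; the four-point condition is the test
  oracle.

Matrix I/O uses the PHYLIP square dialect (count line, then label + n
reals per row); asymmetry beyond 1e-6 is rejected.

## Decomposition

Centroid-edge decomposition: recursively delete the edge minimizing the
larger side of its leaf bipartition until every part fits `max_size`,
recursing on the *restricted* trees so centroid choices stay
well-defined.  Ties take the smallest lexicographic leaf on the smaller
side, making the decomposition deterministic.  No minimum subset size is
enforced; subsets of < 4 taxa simply yield constraint-free trees.
Defaults follow usage at the scales this package targets: `max_size` 30
for ~100 taxa (and 120 would suit ~1000).

## Pipeline

Steps: (1) estimate `D` (AGID or log-det); (2) NJ starting tree from
`D`, centroid-decomposed; (3) a subset tree per part — `internal:nj`
(NJ on the restricted matrix), `internal:true` (restriction of a
reference tree; the idealized regime), or an external shell template
with `{taxa}`/`{output}` placeholders; (4) NJMerge on the subset trees
and `D`.  External subset-tree methods are *invoked*, never
reimplemented.  The ledger records `t_D`, each `t_T(i)` and `t_M`;
`aggregate_runtime` returns the serialized total `t_D + Σ t_T(i) + t_M`,
and per-subset times allow deriving a parallel wall clock.  An optional
`iterations` count feeds the merged tree back as the next decomposition's
starting tree; it defaults to 1 and carries no accuracy claims.

## Simulation fixtures

The generators define the study conditions; all are seed-deterministic.

* **Random topologies**: uniform over unrooted binary shapes (leaf
  insertion on a uniformly chosen edge), branch lengths log-uniform on
  [0.05, 1.0] — wide enough to give both short and long edges without
  degenerate zero-length branches.
* **Yule species trees**: pure-birth via dendropy, extended by one extra
  exponential waiting time so the newest tips have positive pendant
  edges, snapped to exact ultrametry, and rescaled to a target root
  height in generations.
* **MSC gene trees**: msprime with one haploid lineage per species and
  `ploidy=1`, so a branch of `g` generations spans `g/N` coalescent
  units with `N` the haploid-equivalent effective population size
  (default 200,000); lineages coalesce freely above the root.  The
  module's statistical anchor is the 3-taxon law: the probability that a
  gene tree matches the species-tree triplet is `1 − (2/3)e^{−T}` for an
  internal branch of `T` coalescent units, checked at T ∈ {0.1, 0.5, 1,
  2} with 10^4 genes within 3 binomial standard errors.
* **Jukes-Cantor sequences**: i.i.d. sites, per-branch change probability
  `(3/4)(1 − e^{−4t/3})`, no indels.  Real data differ in every way that
  matters beyond topology signal — rate heterogeneity, composition bias,
  indels and alignment error are all absent — so passing tests certify
  the estimators' internal consistency, not robustness to model
  violation.
* **Nearly additive perturbation**: i.i.d. uniform noise of amplitude
  0.49× the shortest branch length on the off-diagonal entries, symmetric
  by construction, staying strictly inside the recovery envelope.
* **Adversarial instances**: randomized search over 10–12-taxon
  instances (symmetric noise matrix; each constraint tree restricted
  from its own independent random tree) certified by running the merge;
  roughly 1 instance in 25 fails, so the default budget of 500 attempts
  finds one essentially always.  The contrast — same matrix, constraints
  restricted from a single tree — always succeeds, because NJ joins are
  cherries of NJ's own output and restrictions of one tree can never
  clash.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to make the
guarantees sharp rather than to replicate any cluster-scale benchmark:
recovery at n ∈ {10, 20, 30} (200 trials), soundness over 1000 runs at
n ≤ 13, BUILD versus enumeration on 6-leaf universes (500 forests),
pipeline consistency on 10-taxon species trees with 1000 gene trees and
20 replicates (root height 20 N — a deep-speciation, low-ILS regime),
log-det on 10^5-site pairs.  The full suite runs in well under a minute
on one CPU.

## Known limitations

* Exact (non-heuristic) unrooted-forest compatibility testing is
  NP-complete and out of scope; the pairwise heuristic's failure mode is
  documented and surfaced, not avoided.
* Branch lengths on merged trees are not estimated; all contracts are
  topological (plain NJ assigns standard pendant lengths, advisory only).
* The Newick dialect is deliberately small: optional branch lengths,
  internal labels ignored, quoted labels rejected.
* Constraint trees arriving with branch lengths have them accepted and
  ignored.
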