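# Methods

## The network model

A skull is a simple undirected unweighted graph: bones are nodes, suture
joints / bone contacts are links.  Telescoped sutures are ordinary links —
the model deliberately records *whether* two bones touch, not how.  Every
bone carries a laterality (`left` / `right` / `midline`); bilaterally paired
bones share a `pair_id`.  A pair with only one member present (e.g. a skull
that has lost one nasal) is legal: the singleton counts as paired for the
unpaired-bone ratio but is excluded from mirror-symmetry comparison, since it
has no antimere to compare against.  A fused bone (e.g. an interparietal
fused to the supraoccipital) is simply absent; no merging logic is applied.

Node identity is the exact bone-name string after whitespace trimming,
case-sensitive, so `Frontal_L` and `frontal_l` never merge silently.  The
`_L` / `_R` suffix convention is recognized when no attribute table is given;
all other names default to midline.

Validation reports connectivity, isolated bones, and the mirror-asymmetric
link list: a link `(x, y)` is asymmetric when its image under the mirror map
(paired bone ↦ antimere, midline bone ↦ itself) is absent.  Self-mirrored
links (midline–midline, within-pair `x_L–x_R`) are trivially symmetric.

## Descriptors

With `N` bones, `K` links and degree sequence `k_i`:

| symbol | definition | default conventions |
|---|---|---|
| D | `2K / N(N-1)` | requires `N ≥ 2` |
| L | mean geodesic distance over unordered pairs (BFS) | errors when disconnected; giant-component fallback by flag |
| C | mean local clustering over all nodes | degree<2 nodes contribute 0; exclusion by flag |
| H | `sd(k_i) / mean(k_i)` | sample sd (`n-1`); population sd by flag |
| P | `1 - Σ (n_i/N)²` over partition blocks | computed from the best-Q partition |
| UBR | midline bones / N | needs laterality attributes |

The sd flavor for H is a switch because reference descriptor tables in this
literature do not state which was used; sample sd is the default as the
field's reference implementations are R-based, where `sd()` is the sample
form.  Rounding (3 dp; 2 dp for betweenness) is applied only at reporting,
never internally.

## Bone-level centralities

Betweenness uses Brandes' algorithm on the undirected graph with each
unordered pair counted once, endpoints excluded, equal credit split across
co-shortest paths, and **no normalization** — values are pair counts, so on a
35-bone skull the theoretical maximum is 561 and fractional values such as
172.87 are representable.  This convention matches the magnitudes that
Gephi-era AnNA studies print; a normalized variant is a reporting option.

Harmonic closeness `(1/(N-1)) Σ 1/d` is the primary closeness (it stays
defined on disconnected graphs, where unreachable pairs contribute 0); the
classic form `(N-1)/Σd` is emitted alongside and is undefined (None) when the
network is disconnected.

## Modules and parcellation

The analysis era's standard community detector (Louvain) is run with
`n_restarts` seeded restarts (restart *r* seeds the partitioner with
`seed + r`); the partition with maximal Newman modularity Q is kept, ties
broken by fewer blocks, then by lexicographically smallest block fingerprint,
making the result bit-reproducible.  Because module detection on anatomical
networks is acknowledged to be unstable, a consensus variant re-clusters the
co-assignment matrix over many runs; a bone's stability is the mean Jaccard
overlap between its run-block and its consensus block.  Both the best-Q P
and consensus-based P are available, as is a pair-merged P that unites
blocks that are left/right images of each other.

## Morphospace and PERMANOVA

PCA is performed on the correlation matrix: each descriptor column is
z-scored (mean 0, sample sd 1) and the `p × p` correlation matrix is
eigendecomposed, so variance percentages are `100 λ_j / p`.  Component signs
are fixed by making the largest-magnitude loading of each component
positive.  Two presets mirror the two standard ordinations: `tetrapod`
(D, L, C, H) and `cetacean` (D, L, C, H, P).

PERMANOVA uses Anderson's one-way pseudo-F computed from the matrix of
Euclidean distances between z-scored descriptor vectors:
`SS_total = Σ d²/n`, `SS_within = Σ_groups Σ d²/n_g`,
`F = (SS_among/(a-1)) / (SS_within/(n-a))`.  Euclidean-on-z-scores is the
natural distance for small all-quantitative descriptor tables and is stated
in every output.  The permutation p-value is `(b+1)/(m+1)` with `b` the
number of permuted F values ≥ the observed one, so `p = 0` is impossible and
the attainable minimum is `1/(m+1)`.  Pairwise tests report raw and
Bonferroni-adjusted p side by side.  The implementation is cross-checked in
the tests against scikit-bio's PERMANOVA on identical distance matrices.

## Parsimony mapping

Descriptors are optimized on a fixed rooted topology under linear
(Wagner/Farris) parsimony: minimize the summed absolute change over
branches.  Branch lengths are ignored.  The down-pass assigns each internal
node the *median interval* of its children's intervals — for `k` child
intervals, the interval between the `k`-th and `(k+1)`-th smallest of the
`2k` endpoints — which is exact for polytomies as well as binary nodes,
because each child edge contributes a distance-to-interval cost with unit
slopes.  The gap closed at each node accrues to the total change.  The
up-pass combines each node's children with its ancestral context (the median
interval of its siblings and the parent's context), yielding the full set of
most-parsimonious states per node; these intervals are verified in the tests
against exhaustive enumeration (for linear parsimony an optimal labelling
exists using only tip values, so exhaustive search over tip values is an
exact oracle).  Ancestral intervals never leave the tip-value range, and the
total change is bounded below by the tip span; both are asserted.

Note that most-parsimonious intervals are often degenerate points, so they
should be read as the states *some* optimal reconstruction uses — not as
confidence intervals.  On Brownian-simulated traits they track the true
internal values far better than an uninformed tip-mean estimate, but exact
containment of a continuous value is rare by construction; the test suite
freezes both behaviours.

## The synthetic generator

The generator emulates the structural features the analysis consumes, not
the suture anatomy of any real taxon.  Defaults are the scale of published
cetacean skull networks: 7 midline + 14 paired bones (N = 35, UBR = 0.2) and
link counts in the 78–105 range (default target 90).  Links are sampled as
mirror-symmetry *orbits* (a midline–midline contact; a within-pair contact; a
mirrored pair of contacts), so the left/right link sets are exact mirrors by
construction; a spanning backbone (midline chain plus one mirrored attachment
per pair) guarantees connectivity before random filling.  Midline bones are
preferentially attached, most strongly the vomer and supraoccipital
analogues, which additionally receive a minimum of 6 contacts — in real
skulls these bones are contact hubs (roughly 5–15 contacts), and telescoping
edits act on that base.  An `asymmetry` fraction breaks that share of
mirrored orbits by deleting one side (connectivity preserved; K drops by the
number of broken links).

Telescoping edits: *prograde* adds `extra_links` contacts incident to the
midline supraoccipital analogue, choosing the best-connected free targets
(mirrored over pairs; an odd remainder goes to a midline bone), which raises
its degree and with it H — prograde telescoping in real skulls contacts the
richly connected rostral elements, and the degree-greedy choice makes the
designed H increase robust across seeds.  *Retrograde* adds `extra_links/2`
mirrored contact pairs to the maxilla analogues, raising D by exactly
`extra_links / (N(N-1)/2)`.

What the generator does **not** emulate: planar embeddability of real suture
graphs, anatomically meaningful module boundaries, the empirical clustering
levels of real skulls (generated C runs lower than published values at equal
N and K), or shape variation of any kind.  Passing tests on generated data
therefore demonstrate correctness of the computations and of the structural
invariants, not biological realism of any particular network.

## Packaged fixtures

- The 21-taxon cetacean descriptor table (N, K, D, L, C, H, P, UBR with
  group and extinct/extant category) is embedded verbatim from its published
  source.  Two internal inconsistencies of that source are preserved and
  flagged by the tests rather than silently corrected: the *Balaenoptera
  borealis* row prints K = 87 next to D = 0.150 (87 links on 35 bones give
  0.146), and the printed PC2 variance (21.19%) disagrees with the PCA of
  the printed table itself (21.91%) while PC1 matches to 2 dp — consistent
  with a digit transposition.  The genus spelling of two rows is normalized.
- A composite 21-taxon cetacean topology, assembled from published cetacean
  phylogenies, ships as an editable Newick string.  It is a working fixture
  for the parsimony machinery, not an extraction of any published figure.

## Problem sizes and defaults

Synthetic cohorts in the tests use 35-bone skulls with 78–105 links (the
published scale); property suites run exhaustively on all connected graphs
with ≤ 5 nodes plus random 6–10-node graphs, parsimony oracles on trees with
≤ 6 leaves, and the PERMANOVA null calibration on 500 simulated 20 × 5
datasets at 199 permutations (with `m` permutations the attainable p-values
are multiples of `1/(m+1)`, so the α = 0.05 rejection set is exact).
Module detection defaults to 100 restarts; consensus runs default to the
same count.  All stochastic stages take explicit integer seeds and are
bit-reproducible given them.

## Known limitations

- Descriptors are unweighted and undirected by design; no weighted variants.
- Parcellation is partition-dependent: P from the best-Q partition can
  differ across resolutions, which is why the resolution and seed are
  recorded in every output.
- The PERMANOVA is one-way only (no strata/nested designs).
- The parsimony mapper does no tree inference and no squared-change or
  likelihood ancestral reconstruction.
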