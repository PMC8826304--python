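# Methods

This note documents the models, conventions and numerical choices behind
`treeislands`, in the order the pipeline applies them.

## Trees, splits and canonical form

All trees are stored unrooted with anonymous internal nodes of degree
≥ 3; a rooted binary encoding (degree-2 root) is normalized on input by
suppressing the root, so rooted and unrooted serializations of one
topology are indistinguishable downstream. Branch lengths and internal
labels are parsed and discarded: every statistic in the package is a
function of topology alone. Polytomies are preserved, never arbitrarily
resolved.

A bipartition (split) is the two-way partition of the taxon universe
induced by one branch; it is *nontrivial* when both sides hold ≥ 2
taxa. Splits are represented as integer bit-vectors over the ordered
taxon universe, canonicalized so the bit of taxon 0 is clear — split
identity is then a single integer comparison and split sets hash
directly, which is what makes the O(T²) pairwise RF stage cheap (split
sets are extracted once per tree; the pairwise stage is pure set
arithmetic).

Parsing is delegated to dendropy (Newick lists and NEXUS trees blocks,
including MrBayes translate tables and `[&U]`/`[&R]` comments); writing
is the package's own deterministic serializer (children ordered by
lowest taxon rank), so repeated runs are byte-identical. Quoted labels
are preserved verbatim and unquoted underscores are *not* converted to
spaces — silently diverging label conventions between files are the
main practical hazard when pooling, and the pipeline insists on exact
label agreement rather than guessing (rename inputs upstream if two
programs emitted different spellings).

Burnin is applied per input file, before pooling, as a fraction of the
trees on file (`floor(burnin · T)` leading trees dropped): sample files,
not generation counts, are what this package sees, so sampling frequency
is a property of the upstream run. The conventional default in the
bundled examples is 0.25.

## Robinson–Foulds distance

`rf_distance` returns either the raw symmetric-difference count
|S₁ Δ S₂| or the normalized proportion |S₁ Δ S₂| / (|S₁| + |S₂|),
defined as 0 when both trees are stars. The proportion is the default —
it matches the definition of unweighted RF as the proportion of
bipartitions in one tree lacking from the other — while the count form
is kept because the common upstream tooling reports counts and classical
MDS is invariant only up to a global scale when all trees are equally
resolved. With unequally resolved trees the two forms genuinely differ
(the proportion's denominator uses the trees' actual split counts), so
the pipeline config names one explicitly.

Both forms are metrics on topologies; the count is bounded by 2(n − 3)
for binary trees and the proportion by 1. These properties, and
equality with a naive edge-removal enumeration oracle, are exercised in
the test suite and the acceptance script rather than assumed.

## Classical MDS and the additive constant

Classical MDS (principal coordinates) eigendecomposes
B = −½ J (D∘D) J with J = I − 11ᵀ/n. Coordinates are eigenvectors
scaled by √λ for the top-k positive eigenvalues, so embedded Euclidean
distances approximate the input distances; k defaults to 2 (the two
axes one plots) and is silently reduced — and recorded on the returned
`Embedding` — when fewer positive eigenvalues exist. The full spectrum
is always reported so the share of variation carried by the plotted
axes can be judged.

RF matrices are typically non-Euclidean, so the Cailliez additive
constant is applied first: the smallest c ≥ 0 such that adding c to
every off-diagonal distance makes B positive semi-definite, computed as
the largest eigenvalue of the standard 2n × 2n companion matrix built
from the centered D and D∘D, then verified by re-centering the
corrected matrix. The constant is applied to *distances*, not squared
distances (the alternative convention is not implemented). Numerical
choices: eigenvalues with |λ| below 1e-8 × max|λ| are clamped to zero;
c is nudged upward by amounts ~1e-12 (far below the 10% minimality
probe used in tests) when eigensolver rounding leaves the smallest
eigenvalue marginally negative; axis signs are fixed by making each
axis's first nonzero coordinate positive. Embeddings are meaningful
only up to rotation/reflection, so all tests compare inter-point
distances, never raw coordinates. Duplicate topologies are retained as
distinct (coincident) points, matching how posterior samples are
plotted.

## Clade hypotheses and classification

Clade talk requires a root; the package roots each tree on a single
declared outgroup leaf (multi-taxon outgroups are out of scope — they
reintroduce exactly the non-monophyly ambiguity the classification is
meant to resolve). The clades of a tree are then the split sides not
containing the outgroup, plus the root clade of all non-outgroup taxa.

"Focal taxon forms a clade with X" is formalized as clade existence:
some clade contains the focal taxon, all of `require_all`, at least one
of `require_any` (vacuous when empty), and none of `forbid`. This
generic triple was chosen because every placement category of interest
is a configuration of it, including overlapping ones; a tree's category
is its full satisfied set, so "satisfies both" and "satisfies none" are
ordinary categories and totals are conserved by construction. The
bundled preset draws one defensible set of boundaries (e.g.
`with_opabinia` forbids both radiodonts and deuteropods inside the
clade; a laxer reading would forbid only radiodonts) — these are
documented configuration, not fixed semantics, and the README says so.

The sister-position report uses the strict operational reading "there
is a clade equal to {focal} ∪ G": attaching *inside* a monophyletic G
also produces such a clade (the spanned group plus the focal), which is
the intended meaning of testing a group as the focal taxon's sister.
Zero-count groups are dropped from the table body and listed in a
footer, so the set of tested positions stays on record.

## Synthetic samples

The generator emulates the one feature of real posterior/MPT samples
this package analyses: island structure keyed to focal-taxon placement.
Per island it takes a target category, a size, an attachment pool and a
per-tree NNI jitter budget; per tree it jitters a fixed backbone
(protecting the stem branch of the attachment region, since one NNI
changes exactly one bipartition), attaches the focal taxon on an edge
inside the pool, and keeps the tree only if its classified category
equals the target (retry budget 100 per tree; exhaustion names the
island, which is how inconsistent specs fail). Realized counts
therefore equal the spec exactly — recovery tests are exact, not
statistical. NNI-only jitter (no SPR) keeps islands tight: each move
shifts the RF count by at most 2.

What the generator does *not* emulate: MCMC autocorrelation, burnin
transients, character-matrix signal, heterogeneous resolution (all
generated trees are binary), and wildcard taxa that hop between distant
positions. Passing recovery tests show the classification, distance and
embedding machinery is correct on island-structured samples; they say
nothing about whether a given empirical posterior has such structure.

The bundled demo uses 54 taxa and 500 trees in four islands scaled from
the island proportions of the study it emulates (3102 : 251 : 28 : 12 →
457 : 37 : 4 : 2), a size chosen so the full pipeline (including the
O(T²) RF matrix and the 2n × 2n companion eigenproblem) runs in seconds
on one CPU while preserving the supermajority/minority/sparse-zone
shape; the backbone places *Opabinia* sister to (radiodonts,
deuteropods) with both groups monophyletic so that every demo category
is realizable by a single attachment. At T ≈ 5000 trees the RF matrix
and MDS are minutes-scale in this implementation; the pipeline is
single-process by design.

## Consensus

Majority-rule consensus retains exactly the splits with frequency
strictly greater than 0.5 (ties at exactly 0.5 are excluded, the
standard convention); such splits are pairwise compatible by a counting
argument, and the tree is assembled by nesting the corresponding
clusters relative to taxon 0. Supports are the retained splits'
frequencies, written as internal node labels with two decimals.

## Degenerate inputs and tie-breaks

Empty samples, burnin ≥ 1, fewer than 4 taxa for split work, fewer than
3 points for embedding, k < 1, and unknown labels all raise typed
errors naming the offending item. A star tree has no nontrivial splits,
distance 0 to itself in both RF forms, and is a warned no-op for NNI.
Pooling requires identical taxon universes and reports the symmetric
difference on mismatch; a failed pipeline stage removes its partial
outputs and reports the stage name.

## Known limitations

- Single-leaf outgroup rooting only; no rogue-taxon detection or
  pruning.
- Unweighted RF only — no branch-score, quartet or SPR distances; no
  non-metric MDS.
- The classification is clade-existence per tree; it does not attempt
  to segment treespace geometrically (islands are defined by
  categories, and visually by the embedding, not by clustering).
- TNT's native tree format is not parsed; convert MP trees to
  Newick/NEXUS first.
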