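# Methods

This note documents the model implemented in `duproot`, the choices made
where the design was genuinely open, and what the bundled simulator does
and does not establish about real data.

## Problem setting

Input is one unrooted binary species tree over t species (branch lengths
and support values are accepted and discarded — the method is purely
topological) and a set of unrooted gene trees whose leaves map to those
species. Every branch of the species tree corresponds to a bipartition
K = B1 | B2 of the species set; the b = 2t − 3 bipartitions, with blocks in
canonical order (lexicographically smaller block first, branches sorted by
block content), are the coordinate system for everything downstream, so
branch ids are reproducible across runs, input rotations and platforms.
Rooted input Newick is silently unrooted by collapsing the degree-2 root
(one log line records this); gene trees with fewer than four leaves are
parsed and simply yield no events.

## Detection of well-supported duplications

A duplication node in an unrooted gene tree betrays itself by species
overlap: of the three subtrees incident on it, the two post-duplication
copies share species. For each degree-3 node, each of the three pairs of
incident subtrees (t1, t2) is tested:

1. **overlap** — S(t1) ∩ S(t2) ≠ ∅;
2. **block mapping** — the union S(t1) ∪ S(t2) must map to a *unique*
   smallest containing block β of the species tree. Mapping to the
   smallest containing block (rather than requiring equality) makes the
   assignment robust to partial gene loss; a tie between equally small
   blocks means the placement is ambiguous and the candidate is dropped;
3. **grandchild presence** — each copy separately must contain at least one
   gene from every grandchild clade of β (children and grandchildren of the
   subtree obtained by rooting β at the branch separating it from its
   complement). When a child of β is a single species, its grandchild slots
   degenerate to that species' singleton, so 2- and 3-species blocks remain
   detectable under a correspondingly weaker criterion;
4. **local topology** — each copy's root must split into two clades that
   are subsets of opposite child clades of β. A copy whose root is a leaf
   or a polytomy cannot show this structure and passes only for degenerate
   2-species blocks, where no structure is expected.

Nodes of degree > 3 (unresolved polytomies) are skipped entirely: they are
amalgamations of weakly supported splits and unreliable witnesses. A node
yields at most one event — if several pairs pass, the smallest mapped block
wins, and a tie discards the node (one biological event per node,
deterministically).

**Edge events.** The deepest duplication of a gene family has no
pre-duplication edge left once the tree is unrooted: the event sits *on an
edge*, its copies being the two sides. Whenever the gene tree's species
span a proper block of the species tree (the only case in which the
union of both sides can map to a block at all), every edge is therefore
also tested, with the same criteria applied to the two sides. Edge and
node events cannot double-count the same divergence: if a side's root is
itself a duplication node its two child clades share species and can never
be subsets of the disjoint child clades of β, so the topology test fails.

Detection uses a per-tree cache of the species set on the far side of
every directed edge, filled by one postorder and one preorder pass (the
two sides of an edge can overlap — that is the signal — so the upward sets
are unions, never complements). Each gene tree costs O(M·n) for M genes
over n species. Every rejected candidate is tallied by reason (polytomy,
no overlap, ambiguous block, missing grandchild, topology, pair tie),
which is what makes the deliberately low recall of the detector
explainable in any given run.

Events observed in a single species are real duplications but carry no
rooting information; they are tallied separately and excluded from all
branch counts.

## Maximum-parsimony root

An event with duplicates in block B excludes the root from strictly inside
B: a candidate branch violates the event iff one of its own blocks is a
proper subset of B (the event's own branch never violates — if the root
spans it, both of its blocks are clades, which is what the event says).
The plateau is the argmin of violation counts over all branches; with no
events every branch ties. An event *conflicts* with the solution iff every
plateau member violates it — a definition that stays meaningful under
ties.

## Probability model

Observed counts d = (m, n) on a branch are a superposition of true
positives (rate λ) and false positives (rate αλ). λ is set per branch so
the expected total matches the observed total: λ = (m+n)/(1+α).

* α is one tenth of the conflicting : non-conflicting ratio at the
  parsimony root. The deliberate deflation avoids rewarding contradictory
  events with an expectation of their own. Floor: `alpha_floor = 1e−6`
  (configurable); a zero rate would assign probability zero to any
  conflicting observation and destroy normalisation. The model is nearly
  insensitive to α in practice: on clear-signal simulated data the argmax
  never moves over α ∈ [1e−6, 0.1] and the peak probability moves by
  < 0.02% over [1e−6, 0.01] (≈5% dilution appears by α = 0.1).

* Orientation likelihoods: P(d|←) = Po(m;λ)Po(n;αλ) and symmetrically for
  →. For the root orientation the branch is split at an unknown fraction x
  into two half-branches with opposite time direction; integrating x out
  and summing over the allocation (s, t) of false positives to the two
  halves gives a closed form with a beta-function factor per term (the
  integrand, a product of four Poisson masses, collapses to two superposed
  Poisson pmfs whose rates are linear in x, so the integral is of a
  polynomial times a constant — the closed form is verified against
  quadrature to ~1e−14 relative in the test suite, exhaustively for
  m, n ≤ 30). All likelihood arithmetic is in log space via log-gamma with
  logsumexp reductions: counts in real datasets reach thousands and naive
  factorials overflow.

* Priors: P(root) = 1/b, P(←) = P(→) = (b−1)/2b.

* Terminal branches: outward (single-species) duplications are ignored;
  only the count of inward duplications (block = complement of the leaf)
  is modelled, as Po(m; λ_term,TP) if the branch spans the root and
  Po(m; λ_term,FP) otherwise. The rates are empirical means of inward
  counts over terminal branches inside / outside the parsimony plateau.
  Two under-determined corners required decisions:
  * *no terminal branch in the plateau* (the usual case — most roots are
    internal): λ_term,TP falls back to the tree-wide density of
    non-conflicting events per branch, the best available per-branch
    true-positive proxy. The choice is isolated in
    `estimate_terminal_rates` so it can be swapped.
  * *terminal priors*: a terminal branch has only two feasible
    orientations (time cannot flow from a leaf into the tree). The
    orientation prior masses are kept at 1/b and (b−1)/2b and renormalised
    over the two feasible states — i.e. the infeasible outward orientation
    is excluded by conditioning rather than re-inflating the toward-leaf
    prior to (b−1)/b. This is the unique choice under which the tree-level
    distribution is *exactly uniform* (1/b per branch) when no
    duplications are observed, which we regard as non-negotiable for an
    uninformative dataset.

* Tree level: conditional on the root being branch k, the orientation of
  every other branch is implied (time flows away from k). The log score of
  k is Σ_j log P(o_j^(k) | d_j) using the per-branch orientation
  posteriors, and the distribution is the softmax over all b branches.
  Direct O(b²) evaluation; at desk scale (b ≤ a few hundred) the O(b)
  re-rooting propagation is not worth its complexity.

## Simulator

The generator exists to provide controlled ground truth, not biological
realism. Species trees are Yule topologies. Each gene family starts as one
copy at the root; on each branch a copy is lost with probability
`loss_prob`, then spawns Poisson(`dup_rate`) duplications; with probability
`nni_noise` one random NNI is applied to the finished gene tree (after
truth logging), emulating gene-tree inference error / ILS at the level the
rooting method experiences it. Defaults — 12 species, 500 families,
dup_rate 0.2, loss_prob 0.2, no noise — give a moderately duplicating,
moderately lossy clade with a few hundred informative events per dataset.
Each family uses an independent stream seeded by (seed, family index), so
identical configurations are byte-identical and single families can be
regenerated in isolation.

Truth events are logged at their *observable* scope: the smallest
species-tree block containing the species in which both copies survive
(falling back to the clade of occurrence if that mapping is ambiguous),
for events surviving in ≥ 2 species. Loss downstream of a duplication
shrinks what any unrooted-gene-tree method could possibly see; logging the
occurrence clade instead would misclassify correct detections of such
events. For the same reason, precision/recall scoring matches a found
event to a truth event of the same gene tree when the found block equals
or nests inside the truth block (exact matches claimed first, each truth
event consumable once); `strict=True` restricts to exact matching, and for
loss-free simulations the two coincide.

What passing simulator-based tests does **not** show: robustness to
alignment/inference error beyond single NNIs, to coalescent-process ILS
with realistic population sizes, to horizontal transfer, or to the
orthogroup-inference errors of real pipelines. The noise knob is a proxy,
not a population-genetic model, and sequence evolution is not simulated at
all.

## Numerical conventions and degenerate inputs

* `log Po(k; 0)` is 0 for k = 0 and −∞ otherwise; rate floors keep
  estimated rates strictly positive.
* m = n = 0 gives all three orientation log-likelihoods equal to 0, so the
  posterior equals the prior.
* Empty event sets: full plateau, α at floor, uniform root distribution.
* Smallest-block ties, whole-species-set unions, polytomies: candidate
  rejected, never guessed.
* Ties in the plateau and all outputs are reported in canonical branch-id
  order; `--threads` parallelism aggregates in input order, so results are
  byte-identical to serial execution.

## Known limitations

Loss events carry rooting information that is deliberately not used (gene
trees cannot distinguish parallel losses from shared ones, and genome
annotation quality makes absence evidence weak). Recall of the detector is
intentionally low (strict grandchild and topology requirements); datasets
with few informative duplications per species yield diffuse root
distributions rather than wrong-but-confident ones, which is the intended
behaviour. Branch lengths are never used, so the method cannot exploit
clock-like signal even where it exists.
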