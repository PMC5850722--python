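"""Detection of well-supported gene duplication events in unrooted gene trees.

A duplication node in an unrooted gene tree is recognisable without rooting:
of its three incident subtrees, the two post-duplication copies contain
overlapping species sets, while a speciation node's subtrees do not.  A
candidate pair of copies is accepted as *well-supported* only when

1. the species sets of the two copies overlap;
2. their union maps to a unique smallest containing block of the species
   tree (robustness to partial gene loss; ambiguous ties are rejected);
3. each copy separately contains at least one gene from every grandchild
   clade of that block; and
4. the local topology of each copy is consistent with the species tree:
   the copy root's two child clades are subsets of opposite child clades
   of the block.

This trades recall for precision deliberately: only events carrying strong,
internally consistent evidence are emitted, because each accepted event is
treated as a synapomorphy excluding the species-tree root from the block in
which the duplicates are found.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .trees import GeneTree, SpeciesTree

__all__ = [
    "DuplicationEvent",
    "BranchDupCounts",
    "AggregatedCounts",
    "DetectionStats",
    "cache_species_sets",
    "is_duplication",
    "find_duplications",
    "aggregate_counts",
]

# directed-edge species cache: (u, v) -> species of the subtree containing v
EdgeSpeciesCache = Dict[Tuple[int, int], FrozenSet[str]]


@dataclass(frozen=True)
class DuplicationEvent:
    """One well-supported duplication assigned to a species-tree branch.

    ``dup_block`` is the species-tree block the duplicate copies fall in;
    the event is evidence that this block is a monophyletic clade and hence
    that the root lies outside it.  ``species_observed`` is the union of
    species seen in the two copies (a subset of ``dup_block`` when genes
    were lost).
    """

    gene_tree_id: str
    node_id: int
    branch_id: int
    dup_block: FrozenSet[str]
    species_observed: FrozenSet[str]

    @property
    def is_informative(self) -> bool:
        """Events observed in a single species carry no rooting signal."""
        return len(self.species_observed) >= 2


@dataclass
class DetectionStats:
    """Per-reason tallies of rejected candidates (makes recall explainable)."""

    polytomy_nodes: int = 0
    no_overlap: int = 0
    block_ambiguous: int = 0
    no_block: int = 0
    grandchild_fail: int = 0
    topology_fail: int = 0
    node_pair_tie: int = 0
    events: int = 0

    def merge(self, other: "DetectionStats") -> None:
        for k in vars(other):
            setattr(self, k, getattr(self, k) + getattr(other, k))


def cache_species_sets(gt: GeneTree) -> EdgeSpeciesCache:
    """Species set on the far side of every directed edge of a gene tree.

    ``cache[(u, v)]`` is the species set of the subtree containing ``v``
    after deleting edge ``{u, v}``.  Built with one postorder pass (sets
    below each edge, relative to an arbitrary root) and one preorder pass
    (sets above), so both directions of every edge are filled in O(M * n)
    for M genes over n species.  Species sets on the two sides of an edge
    may overlap -- that is exactly the duplication signal -- so the upward
    sets are computed by unions, never by complement.
    """
    tree = gt.tree
    if tree.n_leaves == 1:
        return {}
    root, parent, postorder = tree.rooted_orders()
    cache: EdgeSpeciesCache = {}
    for u in postorder:  # children before parents: sets below each edge
        if parent[u] is None:
            continue
        if u in tree.leaf_labels:
            cache[(parent[u], u)] = frozenset([gt.species_of_node(u)])
        else:
            cache[(parent[u], u)] = frozenset().union(
                *(cache[(u, w)] for w in tree.neighbors(u) if w != parent[u])
            )
    for u in reversed(postorder):  # parents before children: sets above
        for v in tree.neighbors(u):
            if parent.get(v) != u:
                continue
            parts: List[FrozenSet[str]] = []
            if u in tree.leaf_labels:
                parts.append(frozenset([gt.species_of_node(u)]))
            if parent[u] is not None:
                parts.append(cache[(u, parent[u])])
            parts.extend(cache[(u, w)] for w in tree.neighbors(u) if w != v and parent.get(w) == u)
            cache[(v, u)] = frozenset().union(*parts)
    return cache


def _copy_root_topology_ok(
    gt: GeneTree,
    node: int,
    copy_root: int,
    cache: EdgeSpeciesCache,
    X: FrozenSet[str],
    Y: FrozenSet[str],
    degenerate: bool,
) -> bool:
    """Local-topology test for one post-duplication copy.

    The copy hangs from ``node`` and is rooted at ``copy_root``; its root's
    two child clades must be subsets of opposite child clades of the block.
    A copy whose root is a leaf or a polytomy cannot exhibit the expected
    branching structure, so it passes only for degenerate 2-species blocks
    where no structure is expected.
    """
    tree = gt.tree
    if copy_root in tree.leaf_labels or tree.degree(copy_root) != 3:
        return degenerate
    c1, c2 = (w for w in tree.neighbors(copy_root) if w != node)
    A, B = cache[(copy_root, c1)], cache[(copy_root, c2)]
    return (A <= X and B <= Y) or (A <= Y and B <= X)


def is_duplication(
    gt: GeneTree,
    node: int,
    pair: Tuple[int, int],
    cache: EdgeSpeciesCache,
    st: SpeciesTree,
    stats: Optional[DetectionStats] = None,
) -> Optional[DuplicationEvent]:
    """Test whether two subtrees incident on ``node`` are duplicate copies.

    ``pair`` holds the neighbour nodes of ``node`` that root the two
    putative post-duplication subtrees.  Returns the event, or ``None``
    with the rejection reason tallied in ``stats``.
    """
    n1, n2 = pair
    S1 = cache[(node, n1)]
    S2 = cache[(node, n2)]
    if not (S1 & S2):
        if stats:
            stats.no_overlap += 1
        return None
    union = S1 | S2
    if union == st.species:
        if stats:
            stats.no_block += 1
        return None
    block = st.smallest_containing_block(union)
    if block is None:
        if stats:
            stats.block_ambiguous += 1
        return None
    gc = st.grandchild_clades(block)
    for g in gc.distinct_grandchildren():
        if not (S1 & g) or not (S2 & g):
            if stats:
                stats.grandchild_fail += 1
            return None
    degenerate = len(block) == 2
    for copy_root in (n1, n2):
        if not _copy_root_topology_ok(gt, node, copy_root, cache, gc.X, gc.Y, degenerate):
            if stats:
                stats.topology_fail += 1
            return None
    return DuplicationEvent(
        gene_tree_id=gt.tree_id,
        node_id=node,
        branch_id=st.branch_of_block(block),
        dup_block=block,
        species_observed=union,
    )


def _edge_duplication(
    gt: GeneTree,
    edge: Tuple[int, int],
    cache: EdgeSpeciesCache,
    st: SpeciesTree,
    block: FrozenSet[str],
    stats: Optional[DetectionStats] = None,
) -> Optional[DuplicationEvent]:
    """Test whether the two sides of an edge are duplicate copies.

    A duplication that is the deepest divergence in a gene family has no
    third (pre-duplication) edge left in the unrooted gene tree: the event
    sits on an edge, with the two sides as the copies.  ``block`` is the
    smallest species-tree block containing the whole gene tree's species
    (identical for every edge of the tree, so it is computed once by the
    caller).  Such an event cannot double-count a node event: a side whose
    root is itself a duplication node has overlapping child species sets
    and always fails the local-topology test.
    """
    n1, n2 = edge
    S1 = cache[(n2, n1)]
    S2 = cache[(n1, n2)]
    if not (S1 & S2):
        if stats:
            stats.no_overlap += 1
        return None
    gc = st.grandchild_clades(block)
    for g in gc.distinct_grandchildren():
        if not (S1 & g) or not (S2 & g):
            if stats:
                stats.grandchild_fail += 1
            return None
    degenerate = len(block) == 2
    if not _copy_root_topology_ok(gt, n2, n1, cache, gc.X, gc.Y, degenerate):
        if stats:
            stats.topology_fail += 1
        return None
    if not _copy_root_topology_ok(gt, n1, n2, cache, gc.X, gc.Y, degenerate):
        if stats:
            stats.topology_fail += 1
        return None
    return DuplicationEvent(
        gene_tree_id=gt.tree_id,
        node_id=min(n1, n2),
        branch_id=st.branch_of_block(block),
        dup_block=block,
        species_observed=S1 | S2,
    )


def find_duplications(
    gt: GeneTree,
    st: SpeciesTree,
    stats: Optional[DetectionStats] = None,
) -> List[DuplicationEvent]:
    """All well-supported duplication events in one unrooted gene tree.

    Two candidate classes are tested.  Every internal node of degree
    exactly 3 is visited and each of its 3 unordered pairs of incident
    subtrees is tested; higher-degree nodes (unresolved polytomies) are
    skipped.  A node yields at most one event: if several pairs pass, the
    pair mapping to the smallest block wins and a tie discards the node
    entirely, keeping detection deterministic and one-event-per-node.
    Additionally, when the gene tree's species span a proper block of the
    species tree, every edge is tested with its two sides as the copies --
    the configuration left behind when the deepest node of the family is a
    duplication and the unrooted tree has no third edge for it.  The result
    is independent of any rooting of the gene tree, since only the
    undirected structure is consulted.
    """
    cache = cache_species_sets(gt)
    events: List[DuplicationEvent] = []
    tree = gt.tree
    for node in tree.internal_nodes():
        deg = tree.degree(node)
        if deg != 3:
            if stats:
                stats.polytomy_nodes += 1
            continue
        a, b, c = tree.neighbors(node)
        candidates = [
            ev
            for pair in ((a, b), (a, c), (b, c))
            if (ev := is_duplication(gt, node, pair, cache, st, stats)) is not None
        ]
        if not candidates:
            continue
        best = min(len(ev.dup_block) for ev in candidates)
        winners = [ev for ev in candidates if len(ev.dup_block) == best]
        if len(winners) > 1:
            if stats:
                stats.node_pair_tie += 1
            continue
        events.append(winners[0])
        if stats:
            stats.events += 1
    all_species = gt.species_set()
    if all_species and all_species != st.species and tree.n_leaves >= 2:
        block = st.smallest_containing_block(all_species)
        if block is None:
            if stats:
                stats.block_ambiguous += 1
        else:
            for edge in tree.edges():
                ev = _edge_duplication(gt, edge, cache, st, block, stats)
                if ev is not None:
                    events.append(ev)
                    if stats:
                        stats.events += 1
    return events


@dataclass(frozen=True)
class BranchDupCounts:
    """Ordered duplication counts on one species-tree branch.

    ``m`` counts events whose duplicates lie in ``block_a`` of the canonical
    bipartition, ``n`` those in ``block_b``; the pair is the branch datum
    d_i = (m_i, n_i) consumed by the probability model.
    """

    branch_id: int
    m: int
    n: int

    @property
    def total(self) -> int:
        return self.m + self.n


@dataclass
class AggregatedCounts:
    """Branch-indexed duplication counts plus the uninformative remainder."""

    counts: List[BranchDupCounts]
    informative_events: List[DuplicationEvent]
    outward_terminal: Counter = field(default_factory=Counter)  # species -> count

    @property
    def n_informative(self) -> int:
        return len(self.informative_events)


def aggregate_counts(events: Iterable[DuplicationEvent], st: SpeciesTree) -> AggregatedCounts:
    """Tally events per branch and orientation.

    Single-species events (duplicates observed in one species only) are
    uninformative about the root; they are excluded from every (m, n) pair
    and tallied separately as terminal "outward" events.
    """
    m = [0] * st.n_branches
    n = [0] * st.n_branches
    informative: List[DuplicationEvent] = []
    outward: Counter = Counter()
    for ev in events:
        if not 0 <= ev.branch_id < st.n_branches:
            raise ValueError(f"event references unknown branch {ev.branch_id}")
        if not ev.is_informative:
            outward[next(iter(ev.species_observed))] += 1
            continue
        informative.append(ev)
        bip = st.bipartitions[ev.branch_id]
        if ev.dup_block == bip.block_a:
            m[ev.branch_id] += 1
        elif ev.dup_block == bip.block_b:
            n[ev.branch_id] += 1
        else:
            raise ValueError("event block does not match either block of its branch")
    counts = [BranchDupCounts(i, m[i], n[i]) for i in range(st.n_branches)]
    return AggregatedCounts(counts, informative, outward)
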