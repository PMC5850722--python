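"""Unrooted trees, Newick I/O and species-tree bipartitions.

Both species trees and gene trees are handled as unrooted, undirected
trees over labelled leaves.  Newick parsing is delegated to :mod:`dendropy`;
the parsed tree is converted to a lightweight adjacency-list representation
on which the duplication-detection traversals operate.  Branch lengths and
internal-node labels (e.g. support values) are accepted on input and
discarded: the method uses topology only.

A branch of an unrooted species tree is identified with the bipartition of
the species set obtained by deleting it.  Bipartitions are put in a
canonical order (lexicographically smaller block first, branches sorted by
block content) so that branch ids are stable across runs and platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Tuple

import dendropy

__all__ = [
    "NewickError",
    "MappingError",
    "UnrootedTree",
    "Bipartition",
    "SpeciesTree",
    "GeneTree",
    "MappingRule",
    "parse_newick",
    "write_newick",
]


class NewickError(ValueError):
    """Raised for malformed Newick input (message includes the position)."""


class MappingError(KeyError):
    """Raised when a gene label cannot be mapped to a species."""


class UnrootedTree:
    """Undirected, connected, acyclic graph with labelled degree-1 nodes.

    Internal (degree >= 3) nodes are anonymous.  Degree-2 nodes -- e.g. the
    root of a rooted input Newick -- are collapsed on construction, so a
    rooted and an unrooted serialisation of the same topology compare equal.
    """

    __slots__ = ("_adj", "leaf_labels")

    def __init__(self, adj: Dict[int, List[int]], leaf_labels: Dict[int, str]):
        self._adj = adj
        self.leaf_labels = leaf_labels
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "UnrootedTree":
        adj: Dict[int, List[int]] = {}
        labels: Dict[int, str] = {}
        ids: Dict[int, int] = {}

        def nid(node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = len(ids)
                adj[ids[key]] = []
            return ids[key]

        for node in tree.preorder_node_iter():
            u = nid(node)
            if node.taxon is not None:
                labels[u] = node.taxon.label
            for child in node.child_nodes():
                v = nid(child)
                adj[u].append(v)
                adj[v].append(u)

        _collapse_degree_two(adj, labels)
        return cls(adj, labels)

    # -- basic queries ------------------------------------------------

    @property
    def nodes(self) -> List[int]:
        return list(self._adj)

    def neighbors(self, u: int) -> List[int]:
        return self._adj[u]

    def degree(self, u: int) -> int:
        return len(self._adj[u])

    def edges(self) -> List[Tuple[int, int]]:
        return [(u, v) for u in self._adj for v in self._adj[u] if u < v]

    def leaves(self) -> List[int]:
        return sorted(self.leaf_labels)

    def internal_nodes(self) -> List[int]:
        return sorted(u for u in self._adj if u not in self.leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def label_set(self) -> FrozenSet[str]:
        return frozenset(self.leaf_labels.values())

    # -- traversal helpers --------------------------------------------

    def rooted_orders(self, root: Optional[int] = None):
        """Parent map and postorder node list for an arbitrary rooting.

        Iterative (no recursion-depth limit).  Returns ``(root, parent,
        postorder)`` where ``parent[root] is None``.
        """
        if root is None:
            root = next(iter(self._adj))
        parent: Dict[int, Optional[int]] = {root: None}
        order: List[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self._adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        order.reverse()  # children precede parents
        return root, parent, order

    def isomorphic_to(self, other: "UnrootedTree") -> bool:
        """Topological equality under leaf-label matching (split sets)."""
        if self.label_set() != other.label_set():
            return False
        return self._splits() == other._splits()

    def _splits(self) -> FrozenSet[FrozenSet[str]]:
        all_labels = self.label_set()
        out = set()
        for block in _clades_away_from_root(self).values():
            out.add(min(block, all_labels - block, key=lambda b: tuple(sorted(b))))
        return frozenset(out)

    # -- invariants ---------------------------------------------------

    def _validate(self) -> None:
        if not self._adj:
            raise NewickError("empty tree")
        n_edges = sum(len(v) for v in self._adj.values()) // 2
        if n_edges != len(self._adj) - 1:
            raise NewickError("graph is not a tree")
        seen: Dict[str, int] = {}
        for u in self._adj:
            deg = len(self._adj[u])
            if deg <= 1:
                if u not in self.leaf_labels:
                    raise NewickError(f"unlabelled leaf node {u}")
            elif u in self.leaf_labels and deg > 1:
                raise NewickError(f"labelled internal node {self.leaf_labels[u]}")
        for u, lab in self.leaf_labels.items():
            if lab in seen:
                raise NewickError(f"duplicate leaf label: {lab!r}")
            seen[lab] = u


def _collapse_degree_two(adj: Dict[int, List[int]], labels: Dict[int, str]) -> None:
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if len(adj[u]) == 2 and u not in labels:
                a, b = adj[u]
                adj[a] = [b if x == u else x for x in adj[a]]
                adj[b] = [a if x == u else x for x in adj[b]]
                del adj[u]
                changed = True


def _clades_away_from_root(tree: UnrootedTree) -> Dict[Tuple[int, int], FrozenSet[str]]:
    """For a fixed arbitrary root: leaf labels below each directed edge.

    Keys are ``(parent, child)``; the value is the label set of the subtree
    containing ``child``.
    """
    root, parent, postorder = tree.rooted_orders()
    below: Dict[Tuple[int, int], FrozenSet[str]] = {}
    acc: Dict[int, FrozenSet[str]] = {}
    for u in postorder:
        if u in tree.leaf_labels:
            acc[u] = frozenset([tree.leaf_labels[u]])
        else:
            parts = [acc[v] for v in tree.neighbors(u) if parent.get(v) == u]
            acc[u] = frozenset().union(*parts)
        if parent[u] is not None:
            below[(parent[u], u)] = acc[u]
    return below


def parse_newick(text: str) -> UnrootedTree:
    """Parse one Newick statement into an :class:`UnrootedTree`.

    Branch lengths, support values, internal labels and square-bracket
    comments (NHX etc.) are tolerated and stripped.  Quoted labels and
    labels containing underscores are preserved verbatim.  A rooted input
    is unrooted by collapsing its degree-2 root node.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy error messages carry line/column
        raise NewickError(f"malformed Newick: {exc}") from exc
    return UnrootedTree.from_dendropy(dt)


def write_newick(tree: UnrootedTree, branch_labels: Optional[Dict[Tuple[int, int], str]] = None) -> str:
    """Serialise an unrooted tree deterministically.

    The tree is written rooted at an internal node of maximal degree (or at
    a leaf for 1- and 2-leaf trees); sibling order follows the smallest leaf
    label in each subtree.  ``branch_labels`` optionally maps undirected
    edges (as sorted node-id tuples) to annotation strings emitted as
    ``[&...]`` comments on the corresponding branch.
    """
    if tree.n_leaves == 1:
        (u, lab), = tree.leaf_labels.items()
        return f"{lab};"
    root = max(tree.nodes, key=lambda u: (tree.degree(u), -u))
    _, parent, postorder = tree.rooted_orders(root)
    minlab: Dict[int, str] = {}
    part: Dict[int, str] = {}
    for u in postorder:
        children = sorted(
            (v for v in tree.neighbors(u) if parent.get(v) == u),
            key=lambda v: minlab[v],
        )
        if u in tree.leaf_labels:
            minlab[u] = tree.leaf_labels[u]
            part[u] = _quote_label(tree.leaf_labels[u])
        else:
            minlab[u] = min(minlab[v] for v in children)
            part[u] = "(" + ",".join(part[v] for v in children) + ")"
        if parent[u] is not None and branch_labels:
            key = (min(u, parent[u]), max(u, parent[u]))
            if key in branch_labels:
                part[u] += f"[&{branch_labels[key]}]"
    return part[root] + ";"


_SAFE_LABEL = re.compile(r"^[\w.\-|]+$")


def _quote_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


@dataclass(frozen=True)
class Bipartition:
    """One branch of the species tree as a two-block split of the species.

    ``block_a`` is the lexicographically smaller block (sorted-tuple order),
    so the (block_a, block_b) assignment is canonical.
    """

    branch_id: int
    block_a: FrozenSet[str]
    block_b: FrozenSet[str]

    @property
    def is_terminal(self) -> bool:
        return len(self.block_a) == 1 or len(self.block_b) == 1

    @property
    def terminal_species(self) -> Optional[str]:
        if len(self.block_a) == 1:
            return next(iter(self.block_a))
        if len(self.block_b) == 1:
            return next(iter(self.block_b))
        return None

    @property
    def inward_block(self) -> Optional[FrozenSet[str]]:
        """For a terminal branch, the block complementary to its species."""
        if len(self.block_a) == 1:
            return self.block_b
        if len(self.block_b) == 1:
            return self.block_a
        return None

    def __str__(self) -> str:
        return ",".join(sorted(self.block_a)) + " | " + ",".join(sorted(self.block_b))


@dataclass(frozen=True)
class GrandchildClades:
    """Child (X, Y) and grandchild (x1, x2, y1, y2) species sets of a block.

    When a child clade is a single species its two grandchild slots
    degenerate to that species' singleton, so 2- and 3-species blocks keep a
    well-defined (if weaker) grandchild criterion.
    """

    X: FrozenSet[str]
    Y: FrozenSet[str]
    x1: FrozenSet[str]
    x2: FrozenSet[str]
    y1: FrozenSet[str]
    y2: FrozenSet[str]

    def distinct_grandchildren(self) -> Tuple[FrozenSet[str], ...]:
        seen: List[FrozenSet[str]] = []
        for g in (self.x1, self.x2, self.y1, self.y2):
            if g not in seen:
                seen.append(g)
        return tuple(seen)


class SpeciesTree:
    """A binary unrooted species tree with indexed bipartitions.

    For ``t`` species the tree has ``b = 2t - 3`` branches; branch ids are
    assigned by canonical bipartition order and are the coordinate system
    for duplication counts, parsimony scores and root probabilities.
    """

    def __init__(self, tree: UnrootedTree):
        self.tree = tree
        if tree.n_leaves < 3:
            raise ValueError("species tree needs at least 3 species")
        for u in tree.internal_nodes():
            if tree.degree(u) != 3:
                raise ValueError(
                    f"species tree must be binary: internal node of degree {tree.degree(u)}"
                )
        self.species: FrozenSet[str] = tree.label_set()
        below = _clades_away_from_root(tree)
        # clade(u -> v): labels of the component containing v after deleting {u,v}
        self._clade: Dict[Tuple[int, int], FrozenSet[str]] = {}
        for (p, c), blk in below.items():
            self._clade[(p, c)] = blk
            self._clade[(c, p)] = self.species - blk
        bips: List[Tuple[FrozenSet[str], FrozenSet[str], Tuple[int, int]]] = []
        for (u, v) in tree.edges():
            b1 = self._clade[(u, v)]
            b2 = self._clade[(v, u)]
            if tuple(sorted(b1)) <= tuple(sorted(b2)):
                bips.append((b1, b2, (u, v)))
            else:
                bips.append((b2, b1, (v, u)))
        bips.sort(key=lambda x: (tuple(sorted(x[0])), tuple(sorted(x[1]))))
        self.bipartitions: List[Bipartition] = [
            Bipartition(i, a, b) for i, (a, b, _) in enumerate(bips)
        ]
        # directed edge (u, v) such that clade(u -> v) == block, per block
        self._edge_of_block: Dict[FrozenSet[str], Tuple[int, int]] = {}
        self._branch_of_block: Dict[FrozenSet[str], int] = {}
        for i, (a, b, (u, v)) in enumerate(bips):
            self._edge_of_block[self._clade[(u, v)]] = (u, v)
            self._edge_of_block[self._clade[(v, u)]] = (v, u)
            self._branch_of_block[a] = i
            self._branch_of_block[b] = i
        self._blocks_by_size: List[FrozenSet[str]] = sorted(
            self._branch_of_block, key=lambda blk: (len(blk), tuple(sorted(blk)))
        )

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text))

    # -- counts -------------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.tree.n_leaves

    @property
    def n_branches(self) -> int:
        return len(self.bipartitions)

    def branch_of_block(self, block: FrozenSet[str]) -> int:
        return self._branch_of_block[block]

    def edge_of_branch(self, branch_id: int) -> Tuple[int, int]:
        """Undirected node-id pair of the edge carrying this branch."""
        u, v = self._edge_of_block[self.bipartitions[branch_id].block_a]
        return (min(u, v), max(u, v))

    # -- block machinery for duplication mapping ----------------------

    def smallest_containing_block(self, S: Iterable[str]) -> Optional[FrozenSet[str]]:
        """The unique minimum-size block containing ``S``, or ``None``.

        ``None`` is returned both when no block contains S (S spans the
        whole species set) and when the minimum is attained by more than
        one block, in which case the placement is ambiguous and the
        candidate event is rejected.
        """
        S = frozenset(S)
        if not S:
            raise ValueError("empty species set")
        unknown = S - self.species
        if unknown:
            raise KeyError(f"species not in species tree: {sorted(unknown)}")
        best: Optional[FrozenSet[str]] = None
        for blk in self._blocks_by_size:
            if best is not None and len(blk) > len(best):
                return best
            if S <= blk:
                if best is not None:  # tie at the same size
                    return None
                best = blk
        return best

    def grandchild_clades(self, block: FrozenSet[str]) -> GrandchildClades:
        """Child and grandchild species sets of the subtree for ``block``.

        The subtree is rooted on the node separating the block from its
        complement.  Degenerate single-species children contribute their
        singleton for both grandchild slots.
        """
        if block not in self._branch_of_block:
            raise KeyError("not a block of this species tree")

        def children_of(edge: Tuple[int, int]) -> List[Tuple[int, int]]:
            u, v = edge
            return [(v, w) for w in self.tree.neighbors(v) if w != u]

        edge = self._edge_of_block[block]
        if len(block) == 1:
            s = block
            return GrandchildClades(s, s, s, s, s, s)
        (eX, eY) = children_of(edge)
        X, Y = self._clade[eX], self._clade[eY]

        def split(e: Tuple[int, int], blk: FrozenSet[str]):
            if len(blk) == 1:
                return blk, blk
            e1, e2 = children_of(e)
            return self._clade[e1], self._clade[e2]

        x1, x2 = split(eX, X)
        y1, y2 = split(eY, Y)
        return GrandchildClades(X, Y, x1, x2, y1, y2)


# ---------------------------------------------------------------------------
# gene -> species mapping


class MappingRule:
    """Deterministic rule translating a gene label into a species label.

    Three flavours, mirroring common gene-naming conventions:

    * ``delimiter`` -- the species is the prefix before the first
      occurrence of a delimiter (default ``"_"``), e.g. ``Hsap_ENSG01``;
    * ``regex`` -- first capture group of a regular expression;
    * ``table`` -- explicit gene -> species lookup (two-column TSV).
    """

    def __init__(self, fn: Callable[[str], Optional[str]], description: str):
        self._fn = fn
        self.description = description

    def __call__(self, gene_label: str) -> str:
        species = self._fn(gene_label)
        if not species:
            raise MappingError(
                f"cannot map gene label {gene_label!r} to a species using {self.description}"
            )
        return species

    @classmethod
    def delimiter(cls, delim: str = "_") -> "MappingRule":
        def fn(label: str) -> Optional[str]:
            head, sep, _ = label.partition(delim)
            return head if sep or head else None

        return cls(fn, f"delimiter rule (split on {delim!r})")

    @classmethod
    def regex(cls, pattern: str) -> "MappingRule":
        rx = re.compile(pattern)

        def fn(label: str) -> Optional[str]:
            m = rx.search(label)
            return m.group(1) if m and m.groups() else None

        return cls(fn, f"regex rule ({pattern!r})")

    @classmethod
    def table(cls, mapping: Dict[str, str]) -> "MappingRule":
        return cls(mapping.get, f"map table ({len(mapping)} entries)")

    @classmethod
    def from_table_file(cls, path) -> "MappingRule":
        mapping: Dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping.get, f"map file {path}")


@dataclass
class GeneTree:
    """An unrooted gene tree plus its gene -> species assignment."""

    tree: UnrootedTree
    species_of: Dict[str, str]
    tree_id: str = ""
    _species_by_node: Dict[int, str] = field(default_factory=dict, repr=False)

    @classmethod
    def from_newick(
        cls,
        text: str,
        rule: MappingRule,
        tree_id: str = "",
        known_species: Optional[FrozenSet[str]] = None,
    ) -> "GeneTree":
        tree = parse_newick(text)
        species_of = {lab: rule(lab) for lab in tree.leaf_labels.values()}
        if known_species is not None:
            missing = set(species_of.values()) - set(known_species)
            if missing:
                raise MappingError(
                    f"gene tree {tree_id or '<anon>'} contains species absent from "
                    f"the species tree: {sorted(missing)}"
                )
        return cls(tree, species_of, tree_id)

    def species_of_node(self, node: int) -> str:
        return self.species_of[self.tree.leaf_labels[node]]

    def species_set(self) -> FrozenSet[str]:
        return frozenset(self.species_of.values())
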