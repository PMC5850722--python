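"""Seeded duplication-loss simulator with ground-truth event logs.

Generates a Yule species tree and, per gene family, walks it from the root
downward: on each branch a surviving gene copy is lost with a fixed
probability and spawns a Poisson-distributed number of duplication events,
each creating an independent copy.  Every duplication whose two copies both
survive, in two or more species combined, is logged as an informative
ground-truth event on the species-tree branch where it occurred.  Optional
topological noise (one random NNI per gene tree, applied after logging)
emulates gene-tree inference error and incomplete lineage sorting at the
level the rooting method experiences them: events whose local topology has
been scrambled.

The generator is a controlled testbed, not a calibrated biological
simulator: losses are per-branch geometric thinning rather than a
continuous-time birth-death process, and there is no sequence evolution.
Same seed, same output, byte for byte.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .detect import DuplicationEvent
from .trees import GeneTree, MappingRule, SpeciesTree, UnrootedTree, parse_newick, write_newick

__all__ = [
    "SimConfig",
    "TrueEvent",
    "SimDataset",
    "DetectionScore",
    "simulate_species_tree",
    "simulate_gene_tree",
    "simulate_dataset",
    "write_dataset",
    "score_detection",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a moderately duplicating, moderately lossy clade: with
    0.2 expected duplications per gene copy per branch and a 0.2 per-branch
    loss probability most gene families stay near single copy while a
    sizeable minority carry one or more informative duplications.
    """

    n_species: int = 12
    n_gene_trees: int = 500
    dup_rate: float = 0.2
    loss_prob: float = 0.2
    nni_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")
        if not (0 <= self.loss_prob <= 1 and 0 <= self.nni_noise <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth informative duplication, in detector coordinates."""

    gene_tree_id: str
    branch_id: int
    block: FrozenSet[str]


class _SpNode:
    __slots__ = ("children", "label", "clade")

    def __init__(self):
        self.children: List["_SpNode"] = []
        self.label: Optional[str] = None
        self.clade: FrozenSet[str] = frozenset()


def simulate_species_tree(n_species: int, seed: int) -> Tuple[_SpNode, str]:
    """Rooted Yule-process topology with leaves s1..sk.

    Returns the rooted node structure and its Newick string.  Pure
    topology: no branch lengths are drawn because nothing downstream uses
    them.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(seed)
    root = _SpNode()
    root.children = [_SpNode(), _SpNode()]
    leaves = list(root.children)
    while len(leaves) < n_species:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        node.children = [_SpNode(), _SpNode()]
        leaves.extend(node.children)
    counter = [0]

    def label(node: _SpNode) -> FrozenSet[str]:
        if not node.children:
            counter[0] += 1
            node.label = f"s{counter[0]}"
            node.clade = frozenset([node.label])
        else:
            node.clade = frozenset().union(*(label(c) for c in node.children))
        return node.clade

    label(root)
    return root, _rooted_newick(root)


def _rooted_newick(node: _SpNode) -> str:
    def rec(nd: _SpNode) -> str:
        if not nd.children:
            return nd.label
        return "(" + ",".join(rec(c) for c in nd.children) + ")"

    return rec(node) + ";"


class _GNode:
    __slots__ = ("children", "label")

    def __init__(self, children=None, label=None):
        self.children = children or []
        self.label = label


def _gene_newick(node: _GNode) -> str:
    def rec(nd: _GNode) -> str:
        if not nd.children:
            return nd.label
        return "(" + ",".join(rec(c) for c in nd.children) + ")"

    return rec(node) + ";"


def _leaf_species(node: _GNode) -> FrozenSet[str]:
    out = set()
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.children:
            stack.extend(nd.children)
        else:
            out.add(nd.label.split("_", 1)[0])
    return frozenset(out)


def simulate_gene_tree(
    sp_root: _SpNode,
    st: SpeciesTree,
    cfg: SimConfig,
    rng: np.random.Generator,
    tree_id: str,
) -> Tuple[Optional[str], List[TrueEvent]]:
    """Evolve one gene family down the rooted species tree.

    Returns the unrooted Newick of the surviving gene tree (``None`` if
    every copy was lost) and the ground-truth log of informative
    duplications.  Events are logged before NNI noise is applied, so noise
    degrades detection relative to an unchanged truth.
    """
    gene_counter = Counter()
    events: List[TrueEvent] = []

    def new_leaf(species: str) -> _GNode:
        gene_counter[species] += 1
        return _GNode(label=f"{species}_{gene_counter[species]}")

    def descend(sp: _SpNode) -> Optional[_GNode]:
        # one surviving copy at the bottom of the branch above sp
        if not sp.children:
            return new_leaf(sp.label)
        kids = [evolve(c) for c in sp.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _GNode(children=kids)

    def evolve(sp: _SpNode) -> Optional[_GNode]:
        # one copy enters the branch above sp
        if rng.random() < cfg.loss_prob:
            return None
        n_dups = int(rng.poisson(cfg.dup_rate))
        if n_dups == 0:
            return descend(sp)
        acc = descend(sp)
        for _ in range(n_dups):
            copy = descend(sp)
            if acc is None:
                acc = copy
                continue
            if copy is None:
                continue
            sa, sc = _leaf_species(acc), _leaf_species(copy)
            union = sa | sc
            if len(union) >= 2:
                # The observable scope of the event: subsequent losses can
                # shrink the species sharing the duplication below the clade
                # where it occurred, so the truth is logged at the smallest
                # block containing the surviving species of both copies
                # (falling back to the clade of occurrence if ambiguous).
                block = st.smallest_containing_block(union) or sp.clade
                events.append(TrueEvent(tree_id, st.branch_of_block(block), block))
            acc = _GNode(children=[acc, copy])
        return acc

    copies = [evolve(c) for c in sp_root.children]
    copies = [c for c in copies if c is not None]
    if not copies:
        return None, []
    gene_root = copies[0] if len(copies) == 1 else _GNode(children=copies)
    newick = _gene_newick(gene_root)
    if cfg.nni_noise > 0 and rng.random() < cfg.nni_noise:
        tree = parse_newick(newick)
        _apply_random_nni(tree, rng)
        newick = write_newick(tree)
    return newick, events


def _apply_random_nni(tree: UnrootedTree, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange on a random internal edge, in place."""
    adj = tree._adj
    internal_edges = [
        (u, v)
        for (u, v) in tree.edges()
        if u not in tree.leaf_labels and v not in tree.leaf_labels
    ]
    if not internal_edges:
        return
    u, v = internal_edges[int(rng.integers(len(internal_edges)))]
    a = [w for w in adj[u] if w != v][int(rng.integers(tree.degree(u) - 1))]
    b = [w for w in adj[v] if w != u][int(rng.integers(tree.degree(v) - 1))]
    adj[u][adj[u].index(a)] = b
    adj[v][adj[v].index(b)] = a
    adj[a][adj[a].index(u)] = v
    adj[b][adj[b].index(v)] = u


@dataclass
class SimDataset:
    """A complete synthetic dataset plus its ground truth."""

    config: SimConfig
    rooted_newick: str
    unrooted_newick: str
    species_tree: SpeciesTree
    true_root_branch: int
    gene_trees: List[Tuple[str, str]]  # (tree_id, newick)
    truth_events: List[TrueEvent]
    n_all_lost: int = 0

    def parsed_gene_trees(self) -> List[GeneTree]:
        rule = MappingRule.delimiter("_")
        return [
            GeneTree.from_newick(nwk, rule, tree_id=tid, known_species=self.species_tree.species)
            for tid, nwk in self.gene_trees
        ]


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Species tree, gene trees and truth log for one configuration.

    Each gene tree uses an independent random stream derived from
    ``(seed, tree index)``, so per-tree generation order cannot leak state
    between families and parallel regeneration of any single tree is
    possible.
    """
    sp_root, rooted_newick = simulate_species_tree(cfg.n_species, cfg.seed)
    st = SpeciesTree.from_newick(rooted_newick)
    true_root_branch = st.branch_of_block(sp_root.children[0].clade)
    gene_trees: List[Tuple[str, str]] = []
    truth: List[TrueEvent] = []
    n_lost = 0
    width = len(str(max(cfg.n_gene_trees - 1, 0)))
    for i in range(cfg.n_gene_trees):
        rng = np.random.default_rng([cfg.seed, i])
        tid = f"gt{i:0{width}d}"
        newick, events = simulate_gene_tree(sp_root, st, cfg, rng, tid)
        if newick is None:
            n_lost += 1
            continue
        gene_trees.append((tid, newick))
        truth.extend(events)
    return SimDataset(
        config=cfg,
        rooted_newick=rooted_newick,
        unrooted_newick=write_newick(st.tree),
        species_tree=st,
        true_root_branch=true_root_branch,
        gene_trees=gene_trees,
        truth_events=truth,
        n_all_lost=n_lost,
    )


def write_dataset(ds: SimDataset, outdir) -> Path:
    """Materialise a dataset as Newick/TSV/JSON files under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "gene_trees").mkdir(parents=True, exist_ok=True)
    (outdir / "species_tree.nwk").write_text(ds.unrooted_newick + "\n")
    (outdir / "species_tree_rooted.nwk").write_text(ds.rooted_newick + "\n")
    for tid, nwk in ds.gene_trees:
        (outdir / "gene_trees" / f"{tid}.nwk").write_text(nwk + "\n")
    lines = ["gene_tree_id\tbranch_id\tblock"]
    lines += [
        f"{ev.gene_tree_id}\t{ev.branch_id}\t{';'.join(sorted(ev.block))}"
        for ev in ds.truth_events
    ]
    (outdir / "truth_events.tsv").write_text("\n".join(lines) + "\n")
    meta = {
        **{k: getattr(ds.config, k) for k in (
            "n_species", "n_gene_trees", "dup_rate", "loss_prob", "nni_noise", "seed")},
        "true_root_branch": ds.true_root_branch,
        "n_all_lost": ds.n_all_lost,
        "n_truth_events": len(ds.truth_events),
    }
    (outdir / "config.json").write_text(json.dumps(meta, indent=2) + "\n")
    return outdir


@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    n_matched: int
    n_found: int
    n_truth: int
    empty_found: bool = False  # precision reported as 1.0 by convention


def score_detection(
    found: Sequence[DuplicationEvent],
    truth: Sequence[TrueEvent],
    strict: bool = False,
) -> DetectionScore:
    """Precision/recall of detected events against the ground-truth log.

    Events are matched within each gene tree, each truth event consumable
    once, so parallel duplications on the same branch count individually.
    A detection is correct when it reflects a real duplication: its block
    must equal a truth event's block or, failing that, nest inside one --
    gene loss (and the collapse of a root duplication node when the gene
    tree is unrooted) can shrink the observable scope of a real event to a
    sub-block, and such a detection is evidence of the real event, not a
    spurious one.  ``strict=True`` restricts matching to identical
    (branch, block) keys.

    Only informative (multi-species) detections are scored; the truth log
    contains only informative events by construction.  With nothing found,
    precision is reported as 1.0 by convention (flagged via
    ``empty_found``) and recall carries the signal.
    """
    found_inf = [ev for ev in found if ev.is_informative]
    by_tree: Dict[str, List[TrueEvent]] = {}
    for ev in truth:
        by_tree.setdefault(ev.gene_tree_id, []).append(ev)
    consumed: Dict[str, List[bool]] = {tid: [False] * len(evs) for tid, evs in by_tree.items()}
    matched_found = set()
    # two passes: exact (branch, block) matches claim truth events first,
    # then nested matches take the smallest remaining containing block
    passes = ("exact",) if strict else ("exact", "nested")
    for mode in passes:
        for fi, ev in enumerate(found_inf):
            if fi in matched_found:
                continue
            candidates = by_tree.get(ev.gene_tree_id, [])
            best: Optional[int] = None
            for i, te in enumerate(candidates):
                if consumed[ev.gene_tree_id][i]:
                    continue
                if mode == "exact":
                    hit = te.branch_id == ev.branch_id and te.block == ev.dup_block
                else:
                    hit = ev.dup_block <= te.block
                if hit and (best is None or len(candidates[i].block) < len(candidates[best].block)):
                    best = i
            if best is not None:
                consumed[ev.gene_tree_id][best] = True
                matched_found.add(fi)
    matched = len(matched_found)
    n_found = len(found_inf)
    n_truth = len(truth)
    precision = matched / n_found if n_found else 1.0
    recall = matched / n_truth if n_truth else 1.0
    return DetectionScore(precision, recall, matched, n_found, n_truth, n_found == 0)
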