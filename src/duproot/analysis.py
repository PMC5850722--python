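"""End-to-end root inference: detection -> parsimony -> probability model."""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .detect import (
    AggregatedCounts,
    DetectionStats,
    DuplicationEvent,
    aggregate_counts,
    find_duplications,
)
from .model import (
    ModelParams,
    RootDistribution,
    estimate_alpha,
    estimate_terminal_rates,
    root_distribution,
)
from .parsimony import ParsimonyResult, mp_roots
from .trees import GeneTree, SpeciesTree, write_newick


@dataclass
class RootInference:
    """Everything one run produces, ready for reporting or inspection."""

    species_tree: SpeciesTree
    events: List[DuplicationEvent]
    aggregated: AggregatedCounts
    parsimony: ParsimonyResult
    params: ModelParams
    distribution: RootDistribution
    stats: DetectionStats
    n_gene_trees: int

    def summary(self) -> Dict:
        st = self.species_tree
        best = self.distribution.argmax
        return {
            "n_species": st.n_species,
            "n_branches": st.n_branches,
            "n_gene_trees": self.n_gene_trees,
            "n_events": len(self.events),
            "n_informative_dups": self.aggregated.n_informative,
            "n_single_species_dups": int(sum(self.aggregated.outward_terminal.values())),
            "n_conflicting_dups": self.parsimony.n_conflicting,
            "mp_roots": [self._branch_label(i) for i in self.parsimony.plateau],
            "mp_root_ids": list(self.parsimony.plateau),
            "alpha": self.params.alpha,
            "lambda_term_tp": self.params.lambda_term_tp,
            "lambda_term_fp": self.params.lambda_term_fp,
            "best_root_branch_id": best,
            "best_root_branch": self._branch_label(best),
            "best_root_probability": float(self.distribution.probs[best]),
            "discarded_candidates": {
                "polytomy_nodes": self.stats.polytomy_nodes,
                "no_species_overlap": self.stats.no_overlap,
                "block_ambiguous": self.stats.block_ambiguous,
                "no_containing_block": self.stats.no_block,
                "grandchild_fail": self.stats.grandchild_fail,
                "topology_fail": self.stats.topology_fail,
                "node_pair_tie": self.stats.node_pair_tie,
            },
        }

    def _branch_label(self, branch_id: int) -> str:
        return str(self.species_tree.bipartitions[branch_id])

    # -- tabular reports ----------------------------------------------

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_tree_id": ev.gene_tree_id,
                    "node_id": ev.node_id,
                    "branch_id": ev.branch_id,
                    "dup_block": ";".join(sorted(ev.dup_block)),
                    "n_species_observed": len(ev.species_observed),
                }
                for ev in self.events
            ],
            columns=["gene_tree_id", "node_id", "branch_id", "dup_block", "n_species_observed"],
        )

    def branch_table(self) -> pd.DataFrame:
        st = self.species_tree
        plateau = set(self.parsimony.plateau)
        rows = []
        for bip in st.bipartitions:
            c = self.aggregated.counts[bip.branch_id]
            rows.append(
                {
                    "branch_id": bip.branch_id,
                    "block_a": ";".join(sorted(bip.block_a)),
                    "block_b": ";".join(sorted(bip.block_b)),
                    "m": c.m,
                    "n": c.n,
                    "n_violations": int(self.parsimony.scores[bip.branch_id]),
                    "is_mp_root": bip.branch_id in plateau,
                    "p_root": float(self.distribution.probs[bip.branch_id]),
                }
            )
        return pd.DataFrame(rows)

    def annotated_newick(self) -> str:
        st = self.species_tree
        plateau = set(self.parsimony.plateau)
        labels = {}
        for bip in st.bipartitions:
            tag = f"p_root={self.distribution.probs[bip.branch_id]:.6g}"
            if bip.branch_id in plateau:
                tag += ",mp_root"
            labels[st.edge_of_branch(bip.branch_id)] = tag
        return write_newick(st.tree, branch_labels=labels)


def _detect_one(args: Tuple[GeneTree, SpeciesTree]):
    gt, st = args
    stats = DetectionStats()
    return find_duplications(gt, st, stats), stats


def infer_root(
    st: SpeciesTree,
    gene_trees: Sequence[GeneTree],
    alpha_override: Optional[float] = None,
    alpha_floor: float = 1e-6,
    rate_floor: float = 1e-6,
    threads: int = 1,
) -> RootInference:
    """Run the full pipeline on parsed trees.

    Detection is embarrassingly parallel over gene trees; results are
    aggregated in input order, so any thread count produces byte-identical
    output.  ``alpha_override`` bypasses the conflict-ratio estimate of the
    relative false-positive rate.
    """
    stats = DetectionStats()
    events: List[DuplicationEvent] = []
    if threads > 1 and len(gene_trees) > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            for evs, s in pool.map(
                _detect_one, ((gt, st) for gt in gene_trees), chunksize=32
            ):
                events.extend(evs)
                stats.merge(s)
    else:
        for gt in gene_trees:
            events.extend(find_duplications(gt, st, stats))
    agg = aggregate_counts(events, st)
    pars = mp_roots(agg.informative_events, st)
    alpha = (
        max(alpha_floor, alpha_override)
        if alpha_override is not None
        else estimate_alpha(pars.n_conflicting, pars.n_nonconflicting, alpha_floor)
    )
    lam_tp, lam_fp = estimate_terminal_rates(agg, pars, st, rate_floor)
    params = ModelParams(alpha, lam_tp, lam_fp, alpha_floor, rate_floor)
    dist = root_distribution(agg, st, params)
    return RootInference(st, events, agg, pars, params, dist, stats, len(gene_trees))


def write_reports(result: RootInference, outdir) -> Path:
    """Write the TSV/Newick/JSON report set for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.events_table().to_csv(outdir / "events.tsv", sep="\t", index=False)
    branch = result.branch_table()
    branch.drop(columns=["m", "n", "p_root"]).to_csv(
        outdir / "branch_scores.tsv", sep="\t", index=False
    )
    branch[["branch_id", "block_a", "block_b", "m", "n", "p_root"]].to_csv(
        outdir / "root_distribution.tsv", sep="\t", index=False
    )
    (outdir / "species_tree_annotated.nwk").write_text(result.annotated_newick() + "\n")
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=2) + "\n")
    return outdir
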