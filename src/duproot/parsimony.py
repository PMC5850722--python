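"""Maximum-parsimony root: the branch violating the fewest duplications.

Each informative duplication event excludes the root from the interior of
the block containing the duplicates.  A candidate root branch *violates*
an event iff it lies strictly inside that block's subtree, i.e. one of the
candidate's own blocks is a proper subset of the event's block.  The
branch (or set of tied branches, the "plateau") minimising the number of
violated events is the maximum-parsimony root.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import FrozenSet, List, Sequence, Tuple

import numpy as np

from .detect import DuplicationEvent
from .trees import SpeciesTree

__all__ = ["ParsimonyResult", "violates", "mp_roots"]


def violates(candidate_branch: int, event: DuplicationEvent, st: SpeciesTree) -> bool:
    """True iff rooting on ``candidate_branch`` contradicts ``event``.

    The event's own branch never violates: if the root spans that branch,
    both of its blocks are monophyletic clades, which is exactly what the
    event supports.
    """
    return _block_violates(st.bipartitions[candidate_branch], event.dup_block)


def _block_violates(bip, dup_block: FrozenSet[str]) -> bool:
    return (bip.block_a < dup_block) or (bip.block_b < dup_block)


@dataclass
class ParsimonyResult:
    """Violation scores, the plateau, and per-event conflict flags."""

    scores: np.ndarray  # violations per branch id
    plateau: Tuple[int, ...]  # argmin branches, canonical order
    event_conflicts: List[bool]  # per input event: violated by every MP root?

    @property
    def n_conflicting(self) -> int:
        return sum(self.event_conflicts)

    @property
    def n_nonconflicting(self) -> int:
        return len(self.event_conflicts) - self.n_conflicting

    @property
    def is_unique(self) -> bool:
        return len(self.plateau) == 1


def mp_roots(events: Sequence[DuplicationEvent], st: SpeciesTree) -> ParsimonyResult:
    """Argmin-violation branches with full score table and conflict flags.

    With no events every branch ties at zero (an uninformative plateau).
    An event *conflicts* with the parsimony solution iff it is violated by
    every member of the plateau -- a definition that stays meaningful under
    ties.  Scoring is grouped by distinct duplication block, so the cost is
    O(#distinct blocks * b) rather than O(#events * b).
    """
    scores = np.zeros(st.n_branches, dtype=np.int64)
    block_multiplicity = Counter(ev.dup_block for ev in events)
    violated_by_block = {
        block: np.array(
            [_block_violates(bip, block) for bip in st.bipartitions], dtype=bool
        )
        for block in block_multiplicity
    }
    for block, mult in block_multiplicity.items():
        scores += mult * violated_by_block[block]
    best = scores.min() if len(scores) else 0
    plateau = tuple(int(i) for i in np.flatnonzero(scores == best))
    conflicts = [
        bool(all(violated_by_block[ev.dup_block][i] for i in plateau)) for ev in events
    ]
    return ParsimonyResult(scores, plateau, conflicts)
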