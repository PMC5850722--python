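"""Poisson-mixture probability model for the location of the species-tree root.

Duplications observed on a branch are modelled as a superposition of two
Poisson processes: true positives at rate lambda and false positives at
rate alpha * lambda, with alpha the tree-wide relative false-positive
frequency.  Writing d = (m, n) for the counts supporting the two
orientations of a branch and fixing lambda = N / (1 + alpha) with
N = m + n (total expected count matches the observed count), the three
orientation likelihoods are

    P(d | into_a) = Po(m; lambda) Po(n; alpha lambda)
    P(d | into_b) = Po(n; lambda) Po(m; alpha lambda)
    P(d | root)   = sum_{s<=m} sum_{t<=n} Int_0^1 Po(m-s; x lambda)
                    Po(t; x alpha lambda) Po(n-t; (1-x) lambda)
                    Po(s; (1-x) alpha lambda) dx

The root case splits the branch at an unknown fraction x into two rooted
branches with opposite time direction and marginalises both the split
point and the allocation of the observed counts to true/false positives
on either side; the integral has the closed form
B(m-s+t+1, n-t+s+1) multiplying the Poisson mass factors, with B the beta
function.  Orientation posteriors use priors P(root) = 1/b and
P(into_a) = P(into_b) = (b-1)/(2b) on a tree with b = 2t - 3 branches.

Terminal branches are special: outward (single-species) duplications are
uninformative and excluded upstream, so only the count of inward
duplications is modelled, against empirical true/false-positive rates
estimated from the maximum-parsimony root.

The tree-level model combines all branches: conditional on the root being
branch k, every other branch's orientation is determined (time flows away
from the root), so the posterior probability that k spans the root is the
normalised product over branches of per-branch orientation posteriors.

All arithmetic is in log space via log-gamma; observed counts can reach
thousands, far beyond naive factorials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .detect import AggregatedCounts, BranchDupCounts
from .parsimony import ParsimonyResult
from .trees import SpeciesTree

__all__ = [
    "ModelParams",
    "BranchOrientationPosterior",
    "RootDistribution",
    "log_poisson_pmf",
    "branch_log_likelihoods",
    "branch_posterior",
    "terminal_log_likelihoods",
    "terminal_posterior",
    "estimate_alpha",
    "estimate_terminal_rates",
    "inward_count",
    "root_distribution",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters; rates are events per branch (topology-only units).

    Floors keep every Poisson rate strictly positive: a rate of exactly
    zero assigns probability zero to any conflicting observation and
    destroys the normalisation of the root distribution.
    """

    alpha: float
    lambda_term_tp: float
    lambda_term_fp: float
    alpha_floor: float = 1e-6
    rate_floor: float = 1e-6

    def __post_init__(self):
        if self.alpha < self.alpha_floor or self.alpha_floor <= 0:
            raise ValueError("alpha must satisfy alpha >= alpha_floor > 0")
        if min(self.lambda_term_tp, self.lambda_term_fp) < self.rate_floor:
            raise ValueError("terminal rates must be >= rate_floor")


def log_poisson_pmf(k: int, rate: float) -> float:
    """log Po(k; rate), with the rate-0 convention log 1 = 0 for k = 0."""
    if k < 0:
        return -np.inf
    if rate == 0.0:
        return 0.0 if k == 0 else -np.inf
    return k * np.log(rate) - rate - float(gammaln(k + 1))


def _log_root_likelihood(m: int, n: int, alpha: float) -> float:
    """Closed form of the root-orientation likelihood, in log space.

    Double sum over the allocation (s, t) of false positives to the two
    sides of the root, each term carrying the beta-function factor from
    integrating the root position along the branch.  Evaluated with a
    single logsumexp over the (m+1) x (n+1) grid.
    """
    N = m + n
    lam = N / (1.0 + alpha)
    if N == 0:
        return 0.0
    s = np.arange(m + 1)[:, None]
    t = np.arange(n + 1)[None, :]
    log_lam = np.log(lam)
    log_alam = np.log(alpha * lam) if alpha > 0 else -np.inf
    coef = s + t
    with np.errstate(invalid="ignore"):
        fp_part = np.where(coef == 0, 0.0, coef * log_alam)
    terms = (
        betaln(m - s + t + 1, n - t + s + 1)
        - lam * (1.0 + alpha)
        + (N - coef) * log_lam
        + fp_part
        - gammaln(m - s + 1)
        - gammaln(t + 1)
        - gammaln(n - t + 1)
        - gammaln(s + 1)
    )
    return float(logsumexp(terms))


def branch_log_likelihoods(m: int, n: int, alpha: float) -> Tuple[float, float, float]:
    """(log P(d|into_a), log P(d|into_b), log P(d|root)) for d = (m, n).

    "into_a" is the orientation with time flowing into block_a of the
    canonical bipartition, i.e. the m duplications are the true positives.
    """
    if m < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    lam = (m + n) / (1.0 + alpha)
    alam = alpha * lam
    ll_a = log_poisson_pmf(m, lam) + log_poisson_pmf(n, alam)
    ll_b = log_poisson_pmf(n, lam) + log_poisson_pmf(m, alam)
    ll_root = _log_root_likelihood(m, n, alpha)
    return ll_a, ll_b, ll_root


@dataclass(frozen=True)
class BranchOrientationPosterior:
    """Posterior over the three orientations of one internal branch."""

    branch_id: int
    p_into_a: float
    p_into_b: float
    p_root: float


def _normalise_log(logs: Sequence[float]) -> np.ndarray:
    arr = np.asarray(logs, dtype=float)
    return np.exp(arr - logsumexp(arr))


def branch_posterior(m: int, n: int, alpha: float, b: int, branch_id: int = -1) -> BranchOrientationPosterior:
    """Bayes posterior over orientations given only this branch's counts.

    Priors: P(root) = 1/b and P(into_a) = P(into_b) = (b-1)/(2b).  With
    m = n = 0 the posterior equals the prior.
    """
    if b < 1:
        raise ValueError("branch count must be >= 1")
    ll_a, ll_b, ll_root = branch_log_likelihoods(m, n, alpha)
    lp_dir = np.log((b - 1) / (2.0 * b)) if b > 1 else -np.inf
    lp_root = np.log(1.0 / b)
    p = _normalise_log([ll_a + lp_dir, ll_b + lp_dir, ll_root + lp_root])
    return BranchOrientationPosterior(branch_id, float(p[0]), float(p[1]), float(p[2]))


def terminal_log_likelihoods(m_inward: int, params: ModelParams) -> Tuple[float, float]:
    """(log P(d|toward leaf), log P(d|root)) for a terminal branch.

    Only inward duplications (supporting the complement of the terminal
    species as a clade) are modelled; if the branch does not span the root
    they are false positives at the empirical rate lambda_term_fp, if it
    does they are true positives at lambda_term_tp.
    """
    return (
        log_poisson_pmf(m_inward, params.lambda_term_fp),
        log_poisson_pmf(m_inward, params.lambda_term_tp),
    )


def terminal_posterior(m_inward: int, params: ModelParams, b: int) -> Tuple[float, float]:
    """(P(toward leaf | d), P(root | d)) for a terminal branch.

    Time cannot flow from a leaf into the tree, so the outward orientation
    is excluded a priori and the remaining two keep the same relative prior
    masses as on internal branches, 1/b for root versus (b-1)/(2b) for
    toward-leaf.  This conditioning (rather than re-inflating the
    toward-leaf prior to (b-1)/b) is what makes the tree-level root
    distribution exactly uniform when no duplications are observed.
    """
    ll_leaf, ll_root = terminal_log_likelihoods(m_inward, params)
    lp_leaf = np.log((b - 1) / (2.0 * b)) if b > 1 else -np.inf
    lp_root = np.log(1.0 / b)
    p = _normalise_log([ll_leaf + lp_leaf, ll_root + lp_root])
    return float(p[0]), float(p[1])


def estimate_alpha(
    n_conflicting: int, n_nonconflicting: int, alpha_floor: float = 1e-6
) -> float:
    """Tree-wide relative false-positive rate.

    One tenth of the ratio of conflicting to non-conflicting duplications
    of the maximum-parsimony root -- deliberately deflated so that
    conflicting events are down-weighted rather than rewarded with an
    expectation of their own.  Floored for numerical safety; with no
    non-conflicting events the ratio is undefined and the floor is used.
    """
    if n_nonconflicting <= 0:
        return alpha_floor
    return max(alpha_floor, (n_conflicting / n_nonconflicting) / 10.0)


def inward_count(counts: BranchDupCounts, st: SpeciesTree) -> int:
    """Inward duplications on a terminal branch (dup block = big block)."""
    bip = st.bipartitions[counts.branch_id]
    if not bip.is_terminal:
        raise ValueError(f"branch {counts.branch_id} is not terminal")
    return counts.n if len(bip.block_a) == 1 else counts.m


def estimate_terminal_rates(
    agg: AggregatedCounts,
    parsimony: ParsimonyResult,
    st: SpeciesTree,
    rate_floor: float = 1e-6,
) -> Tuple[float, float]:
    """(lambda_term_tp, lambda_term_fp) from the maximum-parsimony root.

    The false-positive rate is the mean inward count over terminal
    branches outside the MP plateau; the true-positive rate is the mean
    over terminal branches inside it.  The usual case is an internal MP
    root, leaving the true-positive rate with no terminal observations to
    estimate from; it then falls back to the tree-wide density of
    non-conflicting events per branch, the best available proxy for a
    per-branch true-positive rate.  Both rates are floored, and the TP
    rate is never below the FP rate.
    """
    plateau = set(parsimony.plateau)
    inside: List[int] = []
    outside: List[int] = []
    for c in agg.counts:
        if st.bipartitions[c.branch_id].is_terminal:
            (inside if c.branch_id in plateau else outside).append(inward_count(c, st))
    lam_fp = max(rate_floor, float(np.mean(outside)) if outside else 0.0)
    if inside:
        lam_tp = max(lam_fp, float(np.mean(inside)))
    else:
        lam_tp = max(lam_fp, parsimony.n_nonconflicting / st.n_branches)
    return lam_tp, lam_fp


@dataclass
class RootDistribution:
    """Posterior probability, per species-tree branch, of spanning the root."""

    probs: np.ndarray  # indexed by branch id; sums to 1

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.probs))

    def top(self, k: int = 3) -> List[Tuple[int, float]]:
        order = np.argsort(self.probs)[::-1][:k]
        return [(int(i), float(self.probs[i])) for i in order]

    def as_dict(self) -> Dict[int, float]:
        return {int(i): float(p) for i, p in enumerate(self.probs)}


def _branch_side_matrix(st: SpeciesTree) -> np.ndarray:
    """side[j, k] True iff branch k lies on the block_a side of branch j.

    For k != j exactly one block of k is a proper subset of one block of
    j; the diagonal is unused.
    """
    b = st.n_branches
    side = np.zeros((b, b), dtype=bool)
    for j, bj in enumerate(st.bipartitions):
        for k, bk in enumerate(st.bipartitions):
            if j == k:
                continue
            side[j, k] = (bk.block_a < bj.block_a) or (bk.block_b < bj.block_a)
    return side


def root_distribution(
    agg: AggregatedCounts,
    st: SpeciesTree,
    params: ModelParams,
) -> RootDistribution:
    """Tree-level posterior over all branches for the root location.

    For each candidate root branch k the orientation of every other branch
    j is implied (time flows away from k), so the candidate's log score is
    the sum over branches of log per-branch orientation posteriors, with
    branch k itself contributing its root-orientation posterior.  The
    distribution is the softmax of the scores over all 2t-3 branches.
    Direct O(b^2) evaluation; b is the branch count of a desk-scale tree.
    """
    b = st.n_branches
    by_branch = {c.branch_id: c for c in agg.counts}
    if set(by_branch) != set(range(b)):
        raise ValueError("need exactly one count pair per species-tree branch")
    # Per-branch log posteriors for each possible orientation.
    lp_root = np.empty(b)
    lp_if_k_in_a = np.empty(b)  # root on block_a side => time flows into block_b
    lp_if_k_in_b = np.empty(b)
    for j, bip in enumerate(st.bipartitions):
        c = by_branch[j]
        if bip.is_terminal:
            p_leaf, p_root = terminal_posterior(inward_count(c, st), params, b)
            with np.errstate(divide="ignore"):
                lp_root[j] = np.log(p_root)
                # whichever side the candidate is on, time flows toward the leaf
                lp_if_k_in_a[j] = lp_if_k_in_b[j] = np.log(p_leaf)
        else:
            post = branch_posterior(c.m, c.n, params.alpha, b, j)
            with np.errstate(divide="ignore"):
                lp_root[j] = np.log(post.p_root)
                lp_if_k_in_a[j] = np.log(post.p_into_b)
                lp_if_k_in_b[j] = np.log(post.p_into_a)
    side = _branch_side_matrix(st)
    scores = np.empty(b)
    for k in range(b):
        others = np.arange(b) != k
        contrib = np.where(side[:, k], lp_if_k_in_a, lp_if_k_in_b)
        scores[k] = lp_root[k] + contrib[others].sum()
    probs = np.exp(scores - logsumexp(scores))
    probs /= probs.sum()
    return RootDistribution(probs)
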