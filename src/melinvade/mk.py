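"""Equal-rates Mk model of geographic-region evolution on a rooted tree.

The model: a continuous-time Markov chain over k region states with a single
exchange rate q for every ordered state pair (off-diagonal entries of the
generator are q, diagonals -(k-1)q).  The chain is reversible with uniform
stationary distribution, and the transition matrix has the closed form

    P_same(t) = 1/k + (1 - 1/k) exp(-k q t)
    P_diff(t) = 1/k - (1/k)     exp(-k q t).

Tree likelihoods use Felsenstein's pruning algorithm with per-node scaling;
polytomies and zero-length branches are handled natively.  Marginal
ancestral states combine the downward (subtree) conditional likelihoods with
the complementary rest-of-tree flow, which is equivalent to re-rooting at
each node.  Invasion calls flag focal-region tips whose surrounding
reconstruction places them on a lineage of foreign ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import PhyloTree, RegionCoding

log = logging.getLogger(__name__)

Q_LOWER = 1e-8  # lower bound scale for the rate search, x 1/tree-height
Q_UPPER = 1e3


def transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    e = np.exp(-k * q * t)
    p = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(p, 1.0 / k + (1.0 - 1.0 / k) * e)
    return p


@dataclass
class MkFit:
    q: float
    log_likelihood: float
    n_states: int
    states: list[str]
    root_prior: np.ndarray
    at_lower_bound: bool = False


@dataclass
class AncestralStates:
    states: list[str]
    probs: dict[str, np.ndarray]  # node id -> probability vector

    def argmax(self) -> dict[str, str]:
        return {nid: self.states[int(np.argmax(v))] for nid, v in self.probs.items()}


def _tip_partials(tree: PhyloTree, coding: RegionCoding) -> np.ndarray:
    coding.validate_against(tree)
    k = len(coding.states)
    state_idx = {s: i for i, s in enumerate(coding.states)}
    down = np.zeros((tree.n_nodes, k))
    for i in range(tree.n_nodes):
        if tree.is_leaf[i]:
            down[i, state_idx[coding.assignment[tree.node_ids[i]]]] = 1.0
    return down


def _downward(tree: PhyloTree, coding: RegionCoding, q: float,
              ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pruning pass. Returns (down partials, log-scalers, per-node child msgs).

    down[v, s] is the scaled conditional likelihood of the tip data below v
    given state s at v; msgs[v][ci] is the message that child ci of v sends
    up through its edge.
    """
    k = len(coding.states)
    down = _tip_partials(tree, coding)
    logscale = np.zeros(tree.n_nodes)
    msgs: list[np.ndarray] = [np.empty(0)] * tree.n_nodes
    for v in range(tree.n_nodes):  # postorder by construction
        if tree.is_leaf[v]:
            continue
        acc = np.ones(k)
        child_msgs = np.empty((len(tree.children[v]), k))
        for ci, c in enumerate(tree.children[v]):
            p = transition_matrix(k, q, tree.edge_len[c])
            child_msgs[ci] = p @ down[c]
            acc = acc * child_msgs[ci]
            logscale[v] += logscale[c]
        msgs[v] = child_msgs
        m = acc.max()
        if m <= 0:
            raise FloatingPointError("zero likelihood during pruning")
        down[v] = acc / m
        logscale[v] += np.log(m)
    return down, logscale, msgs


def mk_loglik(tree: PhyloTree, coding: RegionCoding, q: float,
              root_prior: np.ndarray | None = None) -> float:
    """Log-likelihood of the tip regions under the equal-rates Mk model."""
    if q < 0:
        raise ValueError("rate q must be non-negative")
    k = len(coding.states)
    prior = _check_prior(root_prior, k)
    down, logscale, _ = _downward(tree, coding, q)
    r = tree.root_index
    return float(np.log(prior @ down[r]) + logscale[r])


def _check_prior(root_prior, k: int) -> np.ndarray:
    if root_prior is None:
        return np.full(k, 1.0 / k)
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (k,) or not np.isclose(prior.sum(), 1.0):
        raise ValueError("root_prior must be a length-k probability vector")
    return prior


def fit_mk(tree: PhyloTree, coding: RegionCoding,
           root_prior: np.ndarray | None = None) -> MkFit:
    """Maximum-likelihood single rate by bounded search on log q.

    The search interval is [1e-8, 1e3] scaled by the inverse tree height.
    Monomorphic tip data drive the rate to the lower bound (no evidence of
    change); the fit is still returned, with a warning.
    """
    k = len(coding.states)
    prior = _check_prior(root_prior, k)
    h = tree.height()
    lo, hi = np.log(Q_LOWER / h), np.log(Q_UPPER / h)
    observed = {coding.assignment[l] for l in tree.tip_labels}
    monomorphic = len(observed) == 1

    def neg(logq: float) -> float:
        return -mk_loglik(tree, coding, float(np.exp(logq)), prior)

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    q = float(np.exp(res.x))
    ll = -float(res.fun)
    at_lower = res.x < lo + 1e-6 or monomorphic
    if monomorphic:
        q = float(np.exp(lo))
        ll = mk_loglik(tree, coding, q, prior)
        log.warning("monomorphic tip data: rate fixed at the lower bound")
    return MkFit(q=q, log_likelihood=ll, n_states=k, states=list(coding.states),
                 root_prior=prior, at_lower_bound=bool(at_lower))


def marginal_ancestral_states(tree: PhyloTree, coding: RegionCoding,
                              fit: MkFit) -> AncestralStates:
    """Marginal posterior over states at every internal node.

    For node v, P(state_v = s | all tips) combines the downward conditional
    likelihood of v's subtree with the "outside" flow from the rest of the
    tree, obtained by a preorder pass.
    """
    k = fit.n_states
    q = fit.q
    prior = fit.root_prior
    down, _, msgs = _downward(tree, coding, q)
    # outside[v, s]: flow arriving at v from everything outside v's subtree,
    # already transported across v's own edge (states measured at v).
    outside = np.zeros((tree.n_nodes, k))
    r = tree.root_index
    outside[r] = prior
    for v in reversed(range(tree.n_nodes)):  # preorder
        if tree.is_leaf[v]:
            continue
        child_msgs = msgs[v]
        for ci, c in enumerate(tree.children[v]):
            sib = np.ones(k)
            for cj in range(child_msgs.shape[0]):
                if cj != ci:
                    sib = sib * child_msgs[cj]
            at_parent = outside[v] * sib
            p = transition_matrix(k, q, tree.edge_len[c])
            vec = p.T @ at_parent  # ER: symmetric, direction immaterial
            m = vec.max()
            outside[c] = vec / m if m > 0 else vec
    probs: dict[str, np.ndarray] = {}
    for v in range(tree.n_nodes):
        if tree.is_leaf[v]:
            continue
        joint = down[v] * outside[v]
        total = joint.sum()
        if total <= 0:
            raise FloatingPointError("zero marginal normalizer")
        probs[tree.node_ids[v]] = joint / total
    return AncestralStates(states=list(fit.states), probs=probs)


@dataclass
class InvasionCall:
    tip_label: str
    observed_region: str
    anchor_node_id: str        # highest ancestor whose tips are all focal
    parent_node_id: str        # the anchor's parent (basis of the call)
    parent_probs: dict[str, float]
    inferred_source: str
    confidence: float          # parent-node mass on states != observed region
    flagged: bool


@dataclass
class CladeCall:
    anchor_node_id: str
    parent_node_id: str
    tips: list[str]
    inferred_source: str
    confidence: float


def call_invasions(tree: PhyloTree, coding: RegionCoding,
                   ancestral: AncestralStates, focal_region: str,
                   threshold: float = 0.9,
                   ) -> tuple[list[InvasionCall], list[CladeCall]]:
    """Flag focal-region tips on lineages of reconstructed foreign ancestry.

    Each focal tip is anchored at the highest ancestor all of whose
    descendant tips are in the focal region (the tip itself when its parent
    already subtends a foreign tip); the tip is flagged when the anchor's
    parent carries probability mass >= threshold on non-focal states.  Tips
    sharing an anchor form one clade-level call.  A tip observed outside the
    focal region is never flagged.
    """
    if focal_region not in coding.states:
        raise ValueError(f"focal region {focal_region!r} not in state set")
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    coding.validate_against(tree)
    below = tree.tips_below()
    all_focal = np.array([
        all(coding.assignment[tree.node_ids[t]] == focal_region for t in below[v])
        for v in range(tree.n_nodes)])
    calls: list[InvasionCall] = []
    clades: dict[str, CladeCall] = {}
    state_idx = {s: i for i, s in enumerate(ancestral.states)}
    focal_i = state_idx[focal_region]
    for v in range(tree.n_nodes):
        if not tree.is_leaf[v]:
            continue
        tip = tree.node_ids[v]
        if coding.assignment[tip] != focal_region:
            continue
        anchor = v
        while tree.parent[anchor] >= 0 and all_focal[tree.parent[anchor]]:
            anchor = tree.parent[anchor]
        par = tree.parent[anchor]
        if par < 0:
            continue  # the whole tree is focal; nothing to call against
        par_id = tree.node_ids[par]
        pvec = ancestral.probs[par_id]
        conf = float(1.0 - pvec[focal_i])
        nonfocal = [(p, s) for s, p in zip(ancestral.states, pvec)
                    if s != focal_region]
        source = max(nonfocal)[1]
        flagged = conf >= threshold
        calls.append(InvasionCall(
            tip_label=tip, observed_region=focal_region,
            anchor_node_id=tree.node_ids[anchor], parent_node_id=par_id,
            parent_probs={s: float(p) for s, p in zip(ancestral.states, pvec)},
            inferred_source=source, confidence=conf, flagged=flagged))
        if flagged:
            cc = clades.get(tree.node_ids[anchor])
            if cc is None:
                clades[tree.node_ids[anchor]] = CladeCall(
                    anchor_node_id=tree.node_ids[anchor], parent_node_id=par_id,
                    tips=[tip], inferred_source=source, confidence=conf)
            else:
                cc.tips.append(tip)
    return calls, list(clades.values())
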