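"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: naive per-pair loops
for the mixed distance, and exhaustive enumeration over internal-state
assignments for the Mk likelihood and marginals.
"""

import itertools

import numpy as np

from melinvade.mk import transition_matrix


def brute_force_gower(values: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Naive per-pair Gower distance; NaN = missing, ranges given per column."""
    n, p = values.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for c in range(p):
                x, y = values[i, c], values[j, c]
                if np.isnan(x) or np.isnan(y) or ranges[c] <= 0:
                    continue
                num += abs(x - y) / ranges[c]
                den += 1.0
            out[i, j] = num / den if den else np.nan
    return out


def enum_mk(tree, coding, q, root_prior=None):
    """Exhaustive sum over internal-state assignments.

    Returns (loglik, {internal node id -> marginal probability vector}).
    """
    k = len(coding.states)
    prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior)
    sidx = {s: i for i, s in enumerate(coding.states)}
    internals = [v for v in range(tree.n_nodes) if not tree.is_leaf[v]]
    total = 0.0
    marg = {v: np.zeros(k) for v in internals}
    pmats = {v: transition_matrix(k, q, float(tree.edge_len[v]))
             for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    tip_state = {v: sidx[coding.assignment[tree.node_ids[v]]]
                 for v in range(tree.n_nodes) if tree.is_leaf[v]}
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        st.update(tip_state)
        pr = prior[st[tree.root_index]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                pr *= pmats[v][st[p], st[v]]
        total += pr
        for v in internals:
            marg[v][st[v]] += pr
    return float(np.log(total)), {
        tree.node_ids[v]: m / total for v, m in marg.items()}


def brute_force_triple_tail(values, threshold) -> float:
    """P(sum of 3 distinct cells > threshold) by explicit iteration."""
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    count = 0
    total = 0
    for i, j, l in itertools.combinations(range(n), 3):
        total += 1
        if v[i] + v[j] + v[l] > threshold:
            count += 1
    return count / total
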