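"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as straight-line enumeration, not
shared with the package implementation: likelihoods and posteriors by
exhaustive summation over internal-node states, binomial tails by direct
pmf summation, and the divergence score by a literal transcription of its
definition.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from kinevo.alphabet import AA_INDEX, N_AA
from kinevo.trees import branch_length, node_id


def enumerate_site_likelihood(tree, column_states, model):
    """Site likelihood by summing over all internal-node assignments."""
    internals = list(tree.postorder_internal_node_iter())
    leaves = list(tree.leaf_node_iter())
    P = {nd: model.transition_matrix(branch_length(nd))
         for nd in tree.preorder_node_iter() if nd.parent_node is not None}
    total = 0.0
    for assign in itertools.product(range(N_AA), repeat=len(internals)):
        state = {nd: s for nd, s in zip(internals, assign)}
        prob = model.frequencies[state[tree.seed_node]]
        for nd in internals:
            for ch in nd.child_nodes():
                if ch.is_leaf():
                    obs = column_states[node_id(ch)]
                    if obs in AA_INDEX:
                        prob_factor = P[ch][state[nd], AA_INDEX[obs]]
                    else:
                        prob_factor = 1.0  # gap: sums over leaf state
                else:
                    prob_factor = P[ch][state[nd], state[ch]]
                prob *= prob_factor
        total += prob
    return math.log(total)


def enumerate_posteriors(tree, column_states, model):
    """Marginal internal-node posteriors by exhaustive joint enumeration."""
    internals = list(tree.postorder_internal_node_iter())
    P = {nd: model.transition_matrix(branch_length(nd))
         for nd in tree.preorder_node_iter() if nd.parent_node is not None}
    marg = {node_id(nd): np.zeros(N_AA) for nd in internals}
    total = 0.0
    for assign in itertools.product(range(N_AA), repeat=len(internals)):
        state = {nd: s for nd, s in zip(internals, assign)}
        prob = model.frequencies[state[tree.seed_node]]
        for nd in internals:
            for ch in nd.child_nodes():
                if ch.is_leaf():
                    obs = column_states[node_id(ch)]
                    prob *= (P[ch][state[nd], AA_INDEX[obs]]
                             if obs in AA_INDEX else 1.0)
                else:
                    prob *= P[ch][state[nd], state[ch]]
        for nd in internals:
            marg[node_id(nd)][state[nd]] += prob
        total += prob
    return {k: v / total for k, v in marg.items()}


def enumerate_binary_marginals(tree, states, q):
    """Two-state marginal presence by exhaustive enumeration, flat root."""
    internals = list(tree.postorder_internal_node_iter())

    def trans(t):
        e = math.exp(-2 * q * t)
        return [[0.5 + 0.5 * e, 0.5 - 0.5 * e],
                [0.5 - 0.5 * e, 0.5 + 0.5 * e]]

    P = {nd: trans(branch_length(nd))
         for nd in tree.preorder_node_iter() if nd.parent_node is not None}
    marg = {node_id(nd): [0.0, 0.0] for nd in internals}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internals)):
        st = {nd: s for nd, s in zip(internals, assign)}
        prob = 0.5
        for nd in internals:
            for ch in nd.child_nodes():
                if ch.is_leaf():
                    prob *= P[ch][st[nd]][states[node_id(ch)]]
                else:
                    prob *= P[ch][st[nd]][st[ch]]
        for nd in internals:
            marg[node_id(nd)][st[nd]] += prob
        total += prob
    return ({k: v[1] / sum(v) for k, v in marg.items()},
            math.log(total))


def binomial_upper_tail(k, n, p0):
    """P(X >= k) for X ~ Binomial(n, p0) by direct pmf summation."""
    if k <= 0:
        return 1.0
    return sum(math.comb(n, j) * p0**j * (1 - p0) ** (n - j)
               for j in range(k, n + 1))


def straight_line_divergence_score(clade_residues, res_a, res_b,
                                   posterior_b, matrix):
    """Literal transcription of S = RC - AC * p(AC)."""
    pairs = list(itertools.combinations(range(len(clade_residues)), 2))
    rc_sum = 0.0
    for i, j in pairs:
        a, b = clade_residues[i], clade_residues[j]
        if a == "-" or b == "-":
            continue
        rc_sum += matrix[(a, b)]
    rc = rc_sum / len(pairs)
    if res_a == res_b:
        ac = 1
        p_ac = posterior_b[AA_INDEX[res_b]]
    else:
        ac = -1
        p_ac = 1.0 - (posterior_b[AA_INDEX[res_a]]
                      if res_a in AA_INDEX else 0.0)
    return rc - ac * p_ac
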