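"""Marginal ancestral sequence reconstruction by the pruning algorithm.

Site likelihoods use Felsenstein's pruning recursion with the root weighted
by the model's equilibrium frequencies; gaps are treated as fully ambiguous
observations (conditional likelihood one for every residue).  Marginal
posteriors at internal nodes come from the standard inside-outside
computation: the "inside" (upward) conditional likelihoods are combined with
an "outside" message passed down from the root, so a single post-order and a
single pre-order sweep yield the posterior at every node.

This reconstructor is a single-rate stand-in: real reconstructions with
among-site rate heterogeneity can be supplied as an
:class:`~kinevo.io_formats.AncestralStateTable` file instead — the divergence
pipeline consumes the table, not the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from kinevo.alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from kinevo.io_formats import AlignedKinaseSet, AncestralStateTable
from kinevo.substitution import SubstitutionModel
from kinevo.trees import branch_length, node_id


@dataclass(frozen=True)
class SiteLikelihood:
    column: int
    log_likelihood: float


def _leaf_partial(state: str) -> np.ndarray:
    if state in AA_INDEX:
        v = np.zeros(N_AA)
        v[AA_INDEX[state]] = 1.0
        return v
    return np.ones(N_AA)  # gap / ambiguous


def _upward_pass(tree: dendropy.Tree, column_states: dict[str, str],
                 model: SubstitutionModel):
    """Post-order conditional likelihoods with per-node log scalers.

    Returns (partials, scalers, P) where partials[node] is the scaled inside
    vector, scalers[node] the accumulated log scaling for the subtree, and
    P[node] the transition matrix on the branch above node.
    """
    partials: dict[dendropy.Node, np.ndarray] = {}
    scalers: dict[dendropy.Node, float] = {}
    P: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.parent_node is not None:
            P[nd] = model.transition_matrix(branch_length(nd))
        if nd.is_leaf():
            name = node_id(nd)
            if name not in column_states:
                raise KeyError(f"leaf {name!r} missing from column states")
            partials[nd] = _leaf_partial(column_states[name])
            scalers[nd] = 0.0
        else:
            v = np.ones(N_AA)
            sc = 0.0
            for ch in nd.child_nodes():
                v = v * (P[ch] @ partials[ch])
                sc += scalers[ch]
            m = v.max()
            if m <= 0:
                raise ValueError("zero likelihood column")
            partials[nd] = v / m
            scalers[nd] = sc + np.log(m)
    return partials, scalers, P


def site_log_likelihood(tree: dendropy.Tree, column_states: dict[str, str],
                        model: SubstitutionModel,
                        column: int = 0) -> SiteLikelihood:
    """Log-likelihood of one alignment column under the model.

    ``column_states`` maps every leaf name to a residue or gap; at least one
    leaf must carry a residue.
    """
    observed = [s for s in column_states.values() if s in AA_INDEX]
    if not observed:
        raise ValueError("all leaves are gaps; site likelihood undefined")
    partials, scalers, _ = _upward_pass(tree, column_states, model)
    root = tree.seed_node
    ll = np.log(model.frequencies @ partials[root]) + scalers[root]
    return SiteLikelihood(column=column, log_likelihood=float(ll))


def _column_posteriors(tree: dendropy.Tree, column_states: dict[str, str],
                       model: SubstitutionModel) -> dict[str, np.ndarray]:
    """Marginal posterior over residues at every internal node."""
    partials, _, P = _upward_pass(tree, column_states, model)
    out: dict[dendropy.Node, np.ndarray] = {}
    posteriors: dict[str, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            msg = model.frequencies.copy()
        else:
            parent = nd.parent_node
            sib = out[parent].copy()
            for ch in parent.child_nodes():
                if ch is not nd:
                    sib = sib * (P[ch] @ partials[ch])
            msg = P[nd].T @ sib
            m = msg.max()
            if m > 0:
                msg = msg / m
        out[nd] = msg
        if not nd.is_leaf():
            post = msg * partials[nd]
            posteriors[node_id(nd)] = post / post.sum()
    return posteriors


def marginal_ancestral_states(tree: dendropy.Tree, aln: AlignedKinaseSet,
                              model: SubstitutionModel) -> AncestralStateTable:
    """Marginal reconstruction for every internal node and column.

    The predicted residue is the posterior argmax; exact ties are broken
    alphabetically and flagged in the returned table.  Columns that are
    all-gap are skipped.
    """
    leaves = {node_id(lf) for lf in tree.leaf_node_iter()}
    missing = sorted(leaves - set(aln.identifiers))
    if missing:
        raise KeyError(f"tree leaves missing from alignment: {missing}")
    seqs = dict(aln.sequences)
    entries: dict[tuple[str, int], tuple[str, np.ndarray]] = {}
    ties: set[tuple[str, int]] = set()
    for col in range(aln.n_columns):
        states = {name: seqs[name][col] for name in leaves}
        if not any(s in AA_INDEX for s in states.values()):
            continue
        for node, post in _column_posteriors(tree, states, model).items():
            best = int(np.argmax(post))  # first max = alphabetical tie-break
            if (post >= post[best] - 1e-12).sum() > 1:
                ties.add((node, col))
            entries[(node, col)] = (AMINO_ACIDS[best], post)
    return AncestralStateTable(entries, ties=ties)
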