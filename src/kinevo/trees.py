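"""Thin helpers over dendropy trees.

Trees throughout the package are rooted dendropy trees with unique leaf names
and nonnegative branch lengths.  Internal nodes carry deterministic string
identifiers: unnamed internal nodes are auto-labelled ``N1, N2, ...`` in
preorder when a tree is read or built, so node references in tables and
reports are reproducible.
"""

from __future__ import annotations

from typing import Iterable

import dendropy


def node_id(node: dendropy.Node) -> str:
    """Identifier of a node: taxon label for leaves, label for internals."""
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


def ensure_internal_names(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic preorder names N1.. to unnamed internal nodes."""
    used = {node_id(nd) for nd in tree if node_id(nd) is not None}
    counter = 1
    for nd in tree.preorder_node_iter():
        if node_id(nd) is None:
            while f"N{counter}" in used:
                counter += 1
            nd.label = f"N{counter}"
            used.add(nd.label)
    return tree


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [node_id(lf) for lf in tree.leaf_node_iter()]


def find_node(tree: dendropy.Tree, ident: str) -> dendropy.Node:
    for nd in tree.preorder_node_iter():
        if node_id(nd) == ident:
            return nd
    raise KeyError(f"node {ident!r} not found in tree")


def clade_leaf_names(node: dendropy.Node) -> frozenset[str]:
    return frozenset(node_id(lf) for lf in node.leaf_iter())


def branch_length(node: dendropy.Node) -> float:
    t = node.edge.length
    return 0.0 if t is None else float(t)


def validate_tree(tree: dendropy.Tree) -> None:
    """Check rootedness conventions: unique leaf names, branch lengths >= 0."""
    names = leaf_names(tree)
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and branch_length(nd) < 0:
            raise ValueError(f"negative branch length at node {node_id(nd)!r}")


def mrca(tree: dendropy.Tree, idents: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named nodes (leaves or internals)."""
    targets = set(idents)
    if not targets:
        raise ValueError("mrca of empty node set")
    # Deepest node whose subtree covers all targets, by postorder sweep.
    cover: dict[dendropy.Node, set[str]] = {}
    for nd in tree.postorder_node_iter():
        ids = {node_id(nd)} if node_id(nd) in targets else set()
        for ch in nd.child_nodes():
            ids |= cover[ch]
        cover[nd] = ids
        if ids >= targets:
            return nd
    raise KeyError(f"nodes {sorted(targets)} not all present in tree")


def postorder_internal_ids(tree: dendropy.Tree) -> list[str]:
    return [node_id(nd) for nd in tree.postorder_internal_node_iter()]


def vcv_matrix(tree: dendropy.Tree, taxa: list[str]) -> "np.ndarray":
    """Phylogenetic covariance matrix: shared root-to-MRCA path length."""
    import numpy as np

    depth: dict[dendropy.Node, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            depth[nd] = depth[nd.parent_node] + branch_length(nd)
    leaves = {node_id(lf): lf for lf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing}")
    # ancestor sets for pairwise MRCA depth
    anc: dict[str, list[dendropy.Node]] = {}
    for t in taxa:
        chain = []
        nd = leaves[t]
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        anc[t] = chain
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        set_a = set(id(x) for x in anc[a])
        V[i, i] = depth[leaves[a]]
        for j in range(i + 1, n):
            for nd in anc[taxa[j]]:
                if id(nd) in set_a:
                    V[i, j] = V[j, i] = depth[nd]
                    break
    return V
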