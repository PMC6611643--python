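"""Dating the origin of kinase units on a species tree.

The presence/absence of a kinase group, family or subfamily across taxa is
modelled as a two-state Markov chain (equal-rates Mk model, one rate q) on a
rooted species tree.  The rate is fitted by maximum likelihood with the
pruning algorithm, marginal presence probabilities are reconstructed at every
internal node with a flat root prior, the origin is called as the deepest
node(s) reconstructed present, multiple origins are resolved to their most
recent common ancestor, and the origin node is mapped to an age through a
divergence-time table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from kinevo.trees import branch_length, find_node, mrca, node_id

logger = logging.getLogger(__name__)

#: lower bound of the rate search (also the rate reported for degenerate
#: all-same-state data)
RATE_FLOOR = 1e-8
RATE_CEIL = 1e3

PRESENCE_THRESHOLD = 0.5


@dataclass
class BinaryTraitModel:
    model: str          # "equal-rates"
    q: float
    log_likelihood: float
    boundary: bool = False


@dataclass
class OriginAssignment:
    unit: str
    origin_node: str | None
    support: float
    multiple_origin: bool = False
    candidate_nodes: tuple[str, ...] = ()
    age_mya: float | None = None
    age_interval: tuple[float, float] | None = None
    reason: str = ""


def _transition(q: float, t: float) -> np.ndarray:
    """Equal-rates two-state transition matrix: stay = 1/2 + exp(-2qt)/2."""
    e = np.exp(-2.0 * q * t)
    stay = 0.5 + 0.5 * e
    move = 0.5 - 0.5 * e
    return np.array([[stay, move], [move, stay]])


def _upward(tree: dendropy.Tree, states: dict[str, int], q: float):
    partials: dict[dendropy.Node, np.ndarray] = {}
    scalers: dict[dendropy.Node, float] = {}
    P: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.parent_node is not None:
            P[nd] = _transition(q, branch_length(nd))
        if nd.is_leaf():
            s = states[node_id(nd)]
            v = np.zeros(2)
            v[s] = 1.0
            partials[nd] = v
            scalers[nd] = 0.0
        else:
            v = np.ones(2)
            sc = 0.0
            for ch in nd.child_nodes():
                v = v * (P[ch] @ partials[ch])
                sc += scalers[ch]
            m = v.max()
            partials[nd] = v / m
            scalers[nd] = sc + np.log(m)
    return partials, scalers, P


def _log_likelihood(tree: dendropy.Tree, states: dict[str, int],
                    q: float) -> float:
    partials, scalers, _ = _upward(tree, states, q)
    root = tree.seed_node
    return float(np.log(0.5 * partials[root].sum()) + scalers[root])


def fit_er_model(tree: dendropy.Tree, states: dict[str, int],
                 ll_tol: float = 1e-8) -> BinaryTraitModel:
    """Maximum-likelihood equal-rates fit by bounded search over log q.

    With all leaves in the same state the likelihood is maximised at q -> 0;
    the model is then returned with the boundary flag set and q at the
    search floor.
    """
    vals = set(states.values())
    if not vals <= {0, 1}:
        raise ValueError(f"states must be binary 0/1, got {sorted(vals)}")
    leaves = {node_id(lf) for lf in tree.leaf_node_iter()}
    missing = sorted(leaves - set(states))
    if missing:
        raise KeyError(f"leaves without a state: {missing}")
    if len(vals) == 1:
        ll = _log_likelihood(tree, states, RATE_FLOOR)
        return BinaryTraitModel("equal-rates", RATE_FLOOR, ll, boundary=True)

    res = minimize_scalar(
        lambda lq: -_log_likelihood(tree, states, np.exp(lq)),
        bounds=(np.log(RATE_FLOOR), np.log(RATE_CEIL)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    q = float(np.exp(res.x))
    ll = -float(res.fun)
    boundary = bool(q <= RATE_FLOOR * 1.01 or q >= RATE_CEIL * 0.99)
    # refine until successive ll change < tolerance (bounded search already
    # drives xatol far below this; the check guards pathological surfaces)
    if boundary:
        logger.info("rate fit hit search boundary (q=%.3g)", q)
    return BinaryTraitModel("equal-rates", q, ll, boundary=boundary)


def marginal_presence(tree: dendropy.Tree, states: dict[str, int],
                      model: BinaryTraitModel) -> dict[str, float]:
    """Marginal posterior P(state = 1) at every node, flat root prior."""
    partials, _, P = _upward(tree, states, model.q)
    out: dict[dendropy.Node, np.ndarray] = {}
    presence: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            msg = np.array([0.5, 0.5])
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
        post = msg * partials[nd]
        presence[node_id(nd)] = float(post[1] / post.sum())
    return presence


def call_origin(tree: dendropy.Tree, presence: dict[str, float],
                unit: str = "unit",
                threshold: float = PRESENCE_THRESHOLD) -> OriginAssignment:
    """Call the origin node of a kinase unit from presence probabilities.

    Candidate origins are the deepest nodes reconstructed present (presence
    strictly above the threshold) whose parent is not, or the root itself.
    A single candidate is the origin; multiple candidates resolve to their
    MRCA with the multiple-origin flag set; no node above the threshold
    yields an assignment with a "not reconstructed present" reason.
    """
    candidates = []
    for nd in tree.preorder_node_iter():
        ident = node_id(nd)
        if presence.get(ident, 0.0) > threshold:
            parent = nd.parent_node
            if parent is None or \
                    presence.get(node_id(parent), 0.0) <= threshold:
                candidates.append(ident)
    if not candidates:
        return OriginAssignment(unit, None, 0.0,
                                reason="not reconstructed present")
    if len(candidates) == 1:
        origin = candidates[0]
        multiple = False
    else:
        origin = node_id(mrca(tree, candidates))
        multiple = True
    return OriginAssignment(
        unit=unit, origin_node=origin,
        support=float(presence.get(origin, 0.0)),
        multiple_origin=multiple, candidate_nodes=tuple(candidates))


def assign_age(tree: dendropy.Tree, origin: OriginAssignment,
               times: dict[str, float]) -> OriginAssignment:
    """Map an origin node to its tabulated age (million years).

    The interval spans from the node's age to its parent's age; at the root
    of the time table the upper bound is unbounded (inf).
    """
    if origin.origin_node is None:
        return origin
    if origin.origin_node not in times:
        raise KeyError(f"node {origin.origin_node!r} missing from time table")
    node = find_node(tree, origin.origin_node)
    age = float(times[origin.origin_node])
    if node.parent_node is None:
        upper = float("inf")
    else:
        parent_id = node_id(node.parent_node)
        if parent_id not in times:
            raise KeyError(f"node {parent_id!r} missing from time table")
        upper = float(times[parent_id])
    origin.age_mya = age
    origin.age_interval = (age, upper)
    return origin


def date_units(tree: dendropy.Tree, pam, times: dict[str, float],
               threshold: float = PRESENCE_THRESHOLD
               ) -> list[OriginAssignment]:
    """Full dating pipeline over every unit of a presence/absence matrix."""
    out = []
    for unit in pam.units:
        states = pam.column(unit)
        model = fit_er_model(tree, states)
        presence = marginal_presence(tree, states, model)
        origin = call_origin(tree, presence, unit=unit, threshold=threshold)
        if origin.origin_node is not None:
            origin = assign_age(tree, origin, times)
        out.append(origin)
    return out
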