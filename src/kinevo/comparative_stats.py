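"""Phylogenetic comparative statistics for kinome-phosphoproteome coevolution.

Given per-species motif enrichment values and relative kinase frequencies on
a species tree, this module computes Felsenstein's phylogenetic independent
contrasts (PICs), regresses the contrasts through the origin (the appropriate
model for contrasts, whose expectation is zero), and measures phylogenetic
signal with Blomberg's K (permutation test) and Pagel's lambda
(likelihood-ratio test), both under a Brownian-motion trait model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from kinevo.io_formats import parse_tree
from kinevo.trees import branch_length, node_id, vcv_matrix

logger = logging.getLogger(__name__)


@dataclass
class ContrastSet:
    trait: str
    contrasts: list[tuple[str, float]]  # (node id, standardised contrast)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.contrasts])


@dataclass
class SignalStatistics:
    trait: str
    statistic: str        # "K" | "lambda"
    value: float
    p_value: float
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# independent contrasts


def _resolved_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Binary copy of the tree; polytomies resolved with zero-length edges.

    Children are processed in sorted-name order so the arbitrary resolution
    (and contrast signs) are deterministic.
    """
    newick = tree.as_string(schema="newick", unquoted_underscores=True,
                            suppress_rooting=True)
    copy = parse_tree(newick)
    for nd in list(copy.postorder_internal_node_iter()):
        children = sorted(nd.child_nodes(), key=node_id)
        while len(children) > 2:
            logger.info("resolving polytomy at %s with zero-length edge",
                        node_id(nd))
            a = children.pop(0)
            b = children.pop(0)
            for ch in (a, b):
                nd.remove_child(ch)
            newnode = dendropy.Node()
            newnode.label = f"{node_id(a)}+{node_id(b)}"
            newnode.edge.length = 0.0
            newnode.add_child(a)
            newnode.add_child(b)
            nd.add_child(newnode)
            children.insert(0, newnode)
    return copy


def pic(tree: dendropy.Tree, trait: dict[str, float],
        name: str = "trait") -> ContrastSet:
    """Felsenstein's phylogenetic independent contrasts.

    At each internal node of the (resolved) binary tree the contrast is
    ``(x_left - x_right) / sqrt(b_left + b_right)`` with the usual
    branch-length augmentation ``b' = b + b_l*b_r/(b_l+b_r)`` applied to
    internal nodes; children are ordered by node name, so contrast signs are
    deterministic.
    """
    tree = _resolved_copy(tree)
    missing = sorted({node_id(lf) for lf in tree.leaf_node_iter()}
                     - set(trait))
    if missing:
        raise KeyError(f"leaves without a trait value: {missing}")
    value: dict[dendropy.Node, float] = {}
    length: dict[dendropy.Node, float] = {}
    contrasts: list[tuple[str, float]] = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            value[nd] = float(trait[node_id(nd)])
            length[nd] = branch_length(nd)
            continue
        left, right = sorted(nd.child_nodes(), key=node_id)
        bl, br = length[left], length[right]
        if bl + br <= 0:
            raise ValueError(
                f"zero total child branch length at node {node_id(nd)}; "
                "contrast undefined")
        contrasts.append(
            (node_id(nd), (value[left] - value[right]) / np.sqrt(bl + br)))
        value[nd] = (value[left] / bl + value[right] / br) / \
            (1.0 / bl + 1.0 / br) if bl > 0 and br > 0 else \
            (value[left] if br > 0 else value[right])
        length[nd] = branch_length(nd) + bl * br / (bl + br)
    contrasts.sort(key=lambda t: t[0])
    return ContrastSet(trait=name, contrasts=contrasts)


def contrast_regression(x: ContrastSet, y: ContrastSet
                        ) -> tuple[float, float, float]:
    """Least-squares regression of y-contrasts on x-contrasts through the
    origin; returns (slope, r, two-sided p) with n-1 degrees of freedom."""
    nodes_x = [n for n, _ in x.contrasts]
    nodes_y = [n for n, _ in y.contrasts]
    if nodes_x != nodes_y:
        raise ValueError("contrast sets are over different node sets")
    xv, yv = x.values, y.values
    sxx = float(xv @ xv)
    if sxx == 0:
        raise ValueError("zero-variance x contrasts")
    sxy = float(xv @ yv)
    syy = float(yv @ yv)
    slope = sxy / sxx
    n = len(xv)
    df = n - 1
    rss = syy - slope * sxy
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    if rss <= 0 or df <= 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        se = np.sqrt(rss / df / sxx)
        t = slope / se
        p = float(2 * stats.t.sf(abs(t), df))
    return slope, float(r), p


# ---------------------------------------------------------------------------
# phylogenetic signal


def _gls_profile_loglik(V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ x) / (one @ Vi @ one)
    resid = x - mu
    sigma2 = (resid @ Vi @ resid) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def _k_statistic(V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ x) / (one @ Vi @ one)
    resid = x - mu
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ Vi @ resid) / (n - 1)
    if mse == 0:
        return np.nan
    observed = mse0 / mse
    expected = (np.trace(V) - n / (one @ Vi @ one)) / (n - 1)
    return float(observed / expected)


def blomberg_k(tree: dendropy.Tree, trait: dict[str, float],
               n_permutations: int = 999, seed: int = 0,
               name: str = "trait") -> SignalStatistics:
    """Blomberg's K with a tip-shuffling permutation test.

    K compares the observed ratio of the ordinary to the phylogenetically
    corrected mean squared error with its Brownian-motion expectation; K near
    1 indicates BM-like signal, near 0 no signal.  The permutation p-value is
    the add-one-corrected fraction of tip-shuffled datasets with K at least
    the observed value.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    taxa = sorted(trait)
    x = np.array([trait[t] for t in taxa], dtype=float)
    if np.ptp(x) == 0:
        return SignalStatistics(name, "K", float("nan"), 1.0,
                                {"undefined": "constant trait"})
    V = vcv_matrix(tree, taxa)
    k_obs = _k_statistic(V, x)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        k_perm = _k_statistic(V, rng.permutation(x))
        if k_perm >= k_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return SignalStatistics(name, "K", k_obs, p,
                            {"n_permutations": n_permutations})


def _lambda_vcv(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _lambda_max(V: np.ndarray, upper: float = 10.0) -> float:
    """Largest branch-length multiplier keeping the covariance PD."""
    def pd(lam: float) -> bool:
        try:
            np.linalg.cholesky(_lambda_vcv(V, lam))
            return True
        except np.linalg.LinAlgError:
            return False
    lo, hi = 1.0, upper
    if not pd(lo):
        return 1.0
    while pd(hi):
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if pd(mid):
            lo = mid
        else:
            hi = mid
    return lo


def pagel_lambda(tree: dendropy.Tree, trait: dict[str, float],
                 name: str = "trait") -> SignalStatistics:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test
    against lambda = 0 (no phylogenetic covariance)."""
    taxa = sorted(trait)
    if len(taxa) < 4:
        raise ValueError("need at least 4 leaves")
    x = np.array([trait[t] for t in taxa], dtype=float)
    V = vcv_matrix(tree, taxa)
    sign, _ = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValueError("singular phylogenetic covariance matrix")
    lam_max = _lambda_max(V)

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda lam: -_gls_profile_loglik(_lambda_vcv(V, lam), x),
        bounds=(0.0, lam_max), method="bounded", options={"xatol": 1e-8})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    ll0 = _gls_profile_loglik(_lambda_vcv(V, 0.0), x)
    lrt = max(0.0, 2 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return SignalStatistics(name, "lambda", lam_hat, p,
                            {"lrt": lrt, "lambda_max": lam_max,
                             "loglik": ll_hat})


def relative_kinase_frequency(counts: dict[str, tuple[int, int]]
                              ) -> dict[str, float]:
    """Per-taxon fraction of the kinome belonging to the unit of interest."""
    out = {}
    for taxon, (unit_count, total) in counts.items():
        if total <= 0:
            raise ValueError(f"taxon {taxon!r} has nonpositive kinome size")
        out[taxon] = unit_count / total
    return out
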