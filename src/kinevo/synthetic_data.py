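"""Synthetic inputs for every pipeline stage.

Real inputs to the pipeline come from curated kinome databases, literature
phosphosite collections and published species trees.  None of those are
needed for testing: this module generates each input under a known ground
truth —

* protein-family alignments evolved on a tree with specificity-determining
  substitutions implanted after a duplication (the signal the divergence
  score is built to detect), together with the true ancestral sequences;
* kinase target-site sets drawn from a stated PWM;
* species phosphoproteomes as mixtures of motif-bearing and background
  15-mers with stated mixture weights;
* binary presence/absence traits evolved under a two-state Markov model;
* correlated continuous traits evolved by Brownian motion.

All generators are pure functions of (spec, seed).  Random streams are split
deterministically per branch (keyed by node name) or per site, so removing
part of a tree does not reshuffle unrelated draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from kinevo.alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from kinevo.io_formats import (AlignedKinaseSet, AncestralStateTable,
                               PhosphoSiteCollection, SequenceLabels)
from kinevo.motif_analysis import CENTRE_INDEX, MotifPattern
from kinevo.specificity_models import FLANK_POSITIONS, SpecificityModel
from kinevo.substitution import get_model
from kinevo.trees import branch_length, find_node, node_id


def _node_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-node stream keyed by (seed, node name)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class FamilySimulationSpec:
    tree: dendropy.Tree
    root_length: int
    model: str = "POISSON"
    branch_rate: float = 0.05  # expected substitutions per site per branch
    implanted_switches: list[tuple[str, int, str]] = field(default_factory=list)
    seed: int = 0
    posterior_concentration: float | None = None  # None -> exact posteriors


@dataclass
class PhosphoproteomeSpec:
    species: str
    n_sites: int
    motif_mixture: list[tuple[MotifPattern, float]] = field(default_factory=list)
    background_freqs: np.ndarray | None = None  # default uniform over 20
    seed: int = 0

    def __post_init__(self) -> None:
        w = [wt for _, wt in self.motif_mixture]
        if any(x < 0 for x in w) or sum(w) > 1 + 1e-12:
            raise ValueError("mixture weights must be >= 0 and sum <= 1")
        if self.background_freqs is None:
            self.background_freqs = np.full(N_AA, 1.0 / N_AA)
        bf = np.asarray(self.background_freqs, dtype=float)
        if bf.shape != (N_AA,) or not np.isclose(bf.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1 over 20")
        self.background_freqs = bf


def random_binary_tree(n_leaves: int, seed: int = 0,
                       mean_branch: float = 0.3) -> dendropy.Tree:
    """Random rooted binary tree by joining random pairs; exponential
    branch lengths with the given mean."""
    from kinevo.io_formats import parse_tree

    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    nodes = [f"T{i}:{rng.exponential(mean_branch):.6f}"
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(f"({a},{b}):{rng.exponential(mean_branch):.6f}")
    return parse_tree(nodes[0][:nodes[0].rfind(':')] + ";")


def two_clade_tree(n_per_clade: int = 20, clade_branch: float = 0.3,
                   leaf_branch: float = 0.1) -> dendropy.Tree:
    """Balanced test tree: two sister clades (cladeA, cladeB) of equal size."""
    from kinevo.io_formats import parse_tree

    def clade(prefix: str) -> str:
        tips = ",".join(f"{prefix}{i}:{leaf_branch}"
                        for i in range(1, n_per_clade + 1))
        return f"({tips})clade{prefix}:{clade_branch}"

    return parse_tree(f"({clade('A')},{clade('B')})root;")


def simulate_family_alignment(spec: FamilySimulationSpec):
    """Evolve a family alignment and implant clade-specific switches.

    Sequences evolve down the tree under the named substitution model, each
    branch applying the model's transition matrix at time ``branch_rate``.
    For each implanted switch (clade, column, residue) the residue is then
    fixed at that column in the named clade's root and every descendant.

    Returns ``(alignment, ancestral_table, true_switches)``: the leaf
    alignment labelled by top-level clade, the TRUE simulated ancestral
    residues (posterior 1 on the truth, or Dirichlet-noised around it when
    ``posterior_concentration`` is set), and the set of implanted
    (clade, column) pairs.
    """
    tree = spec.tree
    L = spec.root_length
    for clade_id, col, res in spec.implanted_switches:
        find_node(tree, clade_id)  # raises KeyError if absent
        if not 0 <= col < L:
            raise ValueError(f"implanted column {col} outside 0..{L - 1}")
        if res not in AA_INDEX:
            raise ValueError(f"invalid implanted residue {res!r}")
    model = get_model(spec.model)
    root_rng = _node_rng(spec.seed, "__root__")
    seqs: dict[str, np.ndarray] = {}
    root = tree.seed_node
    seqs[node_id(root)] = root_rng.choice(N_AA, size=L, p=model.frequencies)
    P = model.transition_matrix(spec.branch_rate)
    cum = np.cumsum(P, axis=1)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        rng = _node_rng(spec.seed, node_id(nd))
        parent = seqs[node_id(nd.parent_node)]
        if spec.branch_rate == 0:
            seqs[node_id(nd)] = parent.copy()
        else:
            u = rng.random(L)
            child = (u[:, None] < cum[parent]).argmax(axis=1)
            seqs[node_id(nd)] = child

    true_switches = set()
    for clade_id, col, res in spec.implanted_switches:
        node = find_node(tree, clade_id)
        for nd in node.preorder_iter():
            seqs[node_id(nd)][col] = AA_INDEX[res]
        true_switches.add((clade_id, col))

    top = {}
    for child in tree.seed_node.child_nodes():
        for lf in child.leaf_iter():
            top[node_id(lf)] = node_id(child)
    sequences = []
    labels = {}
    for lf in tree.leaf_node_iter():
        name = node_id(lf)
        sequences.append(
            (name, "".join(AMINO_ACIDS[i] for i in seqs[name])))
        labels[name] = SequenceLabels(species="sim", group="SIM",
                                      family=top.get(name, "root"))
    aln = AlignedKinaseSet(sequences, labels,
                           column_map={c: c + 1 for c in range(L)})

    entries = {}
    post_rng = _node_rng(spec.seed, "__posteriors__")
    for nd in tree.preorder_internal_node_iter():
        name = node_id(nd)
        for col in range(L):
            true_idx = int(seqs[name][col])
            if spec.posterior_concentration is None:
                post = np.zeros(N_AA)
                post[true_idx] = 1.0
            else:
                alpha = np.full(N_AA, 0.5)
                alpha[true_idx] = spec.posterior_concentration
                post = post_rng.dirichlet(alpha)
            entries[(name, col)] = (AMINO_ACIDS[int(np.argmax(post))], post)
    return aln, AncestralStateTable(entries), true_switches


def sample_sites_from_pwm(model: SpecificityModel, n: int,
                          seed: int = 0) -> list[str]:
    """Draw n independent 15-mer target sites from a specificity model.

    Each flank position is drawn from its PWM column; the centre is S with
    probability equal to the model's S:T ratio.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    cols = []
    for j, _pos in enumerate(FLANK_POSITIONS):
        p = model.matrix[:, j]
        cols.append(rng.choice(N_AA, size=n, p=p / p.sum()))
    centre = np.where(rng.random(n) < model.st_ratio, "S", "T")
    sites = []
    for i in range(n):
        left = "".join(AMINO_ACIDS[cols[j][i]] for j in range(7))
        right = "".join(AMINO_ACIDS[cols[j][i]] for j in range(7, 14))
        sites.append(left + centre[i] + right)
    return sites


def simulate_phosphoproteome(spec: PhosphoproteomeSpec,
                             return_assignments: bool = False):
    """Generate one species' phosphoproteome as a motif/background mixture.

    Each of ``n_sites`` sites is independently assigned to a mixture
    component (leftover weight is pure background).  Background positions are
    drawn from the background residue frequencies; a motif-bearing site has
    each constrained position drawn uniformly from its residue class.  The
    centre is S or T with equal probability.  The returned collection is
    deduplicated; with ``return_assignments`` the pre-deduplication
    (site, component) list is also returned (component -1 = background).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, zlib.crc32(b"phospho")]))
    weights = np.array([w for _, w in spec.motif_mixture] +
                       [1.0 - sum(w for _, w in spec.motif_mixture)])
    comps = rng.choice(len(weights), size=spec.n_sites, p=weights)
    assignments = []
    seen, sites = set(), []
    for i in range(spec.n_sites):
        flank = rng.choice(N_AA, size=14, p=spec.background_freqs)
        chars = [AMINO_ACIDS[k] for k in flank]
        pep = chars[:7] + ["S" if rng.random() < 0.5 else "T"] + chars[7:]
        comp = int(comps[i])
        if comp < len(spec.motif_mixture):
            motif, _ = spec.motif_mixture[comp]
            for pos, cls in motif.constraints:
                members = sorted(cls)
                pep[CENTRE_INDEX + pos] = members[rng.integers(len(members))]
        else:
            comp = -1
        site = "".join(pep)
        assignments.append((site, comp))
        if site not in seen:
            seen.add(site)
            sites.append(site)
    coll = PhosphoSiteCollection(spec.species, sites, unique=True)
    if return_assignments:
        return coll, assignments
    return coll


def simulate_binary_trait(tree: dendropy.Tree, rate_gain: float,
                          rate_loss: float, root_state: int,
                          seed: int = 0,
                          return_internal: bool = False) -> dict[str, int]:
    """Two-state continuous-time Markov simulation down the tree.

    State 0 = absent, 1 = present; gains occur at ``rate_gain`` and losses
    at ``rate_loss`` per unit branch length.  By default only leaf states
    are returned; ``return_internal`` includes every node (useful when the
    true gain/loss history is needed as ground truth).
    """
    if rate_gain < 0 or rate_loss < 0:
        raise ValueError("rates must be nonnegative")
    if root_state not in (0, 1):
        raise ValueError("root state must be 0 or 1")

    def transition(t: float) -> np.ndarray:
        s = rate_gain + rate_loss
        if s == 0:
            return np.eye(2)
        e = np.exp(-s * t)
        return np.array([
            [(rate_loss + rate_gain * e) / s, rate_gain * (1 - e) / s],
            [rate_loss * (1 - e) / s, (rate_gain + rate_loss * e) / s],
        ])

    states: dict[str, int] = {node_id(tree.seed_node): root_state}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        rng = _node_rng(seed, node_id(nd))
        P = transition(branch_length(nd))
        parent_state = states[node_id(nd.parent_node)]
        states[node_id(nd)] = int(rng.random() < P[parent_state, 1])
    if return_internal:
        return states
    return {node_id(lf): states[node_id(lf)]
            for lf in tree.leaf_node_iter()}


def simulate_bm_traits(tree: dendropy.Tree, sigma2_x: float,
                       sigma2_y: float, slope: float,
                       seed: int = 0) -> dict[str, tuple[float, float]]:
    """Correlated Brownian traits: x ~ BM(sigma2_x); y = slope*x + BM noise.

    The y-noise is an independent Brownian motion of rate ``sigma2_y`` on the
    same tree, so (x, y) are jointly BM with the stated regression slope.
    With ``sigma2_y = 0``, y is exactly ``slope * x`` at every leaf.
    """
    if sigma2_x <= 0 or sigma2_y < 0:
        raise ValueError("sigma2_x must be > 0 and sigma2_y >= 0")
    x: dict[str, float] = {node_id(tree.seed_node): 0.0}
    z: dict[str, float] = {node_id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        rng = _node_rng(seed, node_id(nd))
        t = branch_length(nd)
        parent = node_id(nd.parent_node)
        x[node_id(nd)] = x[parent] + rng.normal(0, np.sqrt(sigma2_x * t))
        z[node_id(nd)] = z[parent] + (
            rng.normal(0, np.sqrt(sigma2_y * t)) if sigma2_y > 0 else 0.0)
    return {node_id(lf): (x[node_id(lf)],
                          slope * x[node_id(lf)] + z[node_id(lf)])
            for lf in tree.leaf_node_iter()}
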