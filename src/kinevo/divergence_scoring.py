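"""Per-position divergence scoring between sister kinase clades.

The core statistic assigns each alignment column a divergence score

    S = RC - AC * p(AC)

for a comparison of a focal clade (A, a kinase family or subfamily) against
its nearest sister clade (B).  RC ("recent conservation") measures how
conserved the column is within clade A, on a substitution-matrix similarity
scale rescaled to [0, 1].  AC is +1 when the reconstructed ancestral residues
of the two clades match and -1 when they differ, and p(AC) is the confidence
that the match/mismatch call is right, taken from the clade-B ancestral
posterior.  A column that is perfectly conserved within clade A but fixed for
a different residue in the sister clade, with confident ancestors, scores
S = 2; a conserved, ancestrally identical column scores 0.

Scores are pooled across comparisons at one level (family or subfamily);
columns scoring above the 95th percentile are called "switches", duplicate
comparisons (same unordered pair of ancestral nodes) are collapsed, and
per-domain-position switch counts feed the functional-category enrichment
tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy import stats

from kinevo.alphabet import AMINO_ACIDS, GAP
from kinevo.io_formats import (AlignedKinaseSet, AncestralStateTable,
                               FunctionalCategoryMap, SequenceLabels)
from kinevo.trees import clade_leaf_names, node_id

logger = logging.getLogger(__name__)

MIN_CLADE_SIZE = 5
MAX_SPURIOUS_FRACTION = 0.15
SWITCH_PERCENTILE = 95.0
FREQUENT_PERCENTILE = 90.0


def rescaled_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Substitution matrix rescaled linearly so min -> 0 and max -> 1.

    Only the 20 standard residues are considered for the rescaling range
    (for BLOSUM62 that range is [-4, 11], so W-W rescales to exactly 1).
    """
    m = substitution_matrices.load(name)
    vals = np.array([[m[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS])
    lo, hi = vals.min(), vals.max()
    scaled = (vals - lo) / (hi - lo)
    return {(a, b): float(scaled[i, j])
            for i, a in enumerate(AMINO_ACIDS)
            for j, b in enumerate(AMINO_ACIDS)}


@dataclass
class CladeComparison:
    """A focal clade and its sister, ready for scoring."""

    focal: str
    level: str  # "family" | "subfamily"
    clade_a_node: str | None = None
    clade_a_leaves: frozenset[str] = frozenset()
    clade_b_node: str | None = None
    clade_b_leaves: frozenset[str] = frozenset()
    ancestor_a: str | None = None
    ancestor_b: str | None = None
    purity: float = 0.0
    coverage: float = 0.0
    scorable: bool = True
    reason: str = ""


@dataclass
class DivergenceScoreTable:
    """Per-column RC, AC, p(AC) and S for one clade comparison."""

    comparison: CladeComparison
    scores: pd.DataFrame  # columns: column, domain_position, rc, ac, p_ac, s

    def __post_init__(self) -> None:
        s = self.scores
        if len(s):
            recomposed = s["rc"] - s["ac"] * s["p_ac"]
            if not np.allclose(recomposed, s["s"], atol=1e-12):
                raise ValueError("S does not recompose from RC, AC, p(AC)")
            if (s["s"] < -1 - 1e-12).any() or (s["s"] > 2 + 1e-12).any():
                raise ValueError("S outside [-1, 2]")


@dataclass
class SwitchProfile:
    """Aggregated switch counts per kinase-domain position at one level."""

    level: str
    counts: dict[int, int]
    threshold: float
    n_comparisons: int
    dedup_keys: set[frozenset[str]] = field(default_factory=set)


# ---------------------------------------------------------------------------
# clade selection


def _label_at_level(lb: SequenceLabels, level: str) -> str | None:
    return {"group": lb.group, "family": lb.family,
            "subfamily": lb.subfamily}[level]


def _parent_level(level: str) -> str:
    return {"family": "group", "subfamily": "family"}[level]


def select_focal_clade(tree: dendropy.Tree,
                       labels: dict[str, SequenceLabels],
                       focal: str, level: str,
                       min_clade_size: int = MIN_CLADE_SIZE,
                       max_spurious: float = MAX_SPURIOUS_FRACTION,
                       ) -> CladeComparison:
    """Locate the clade representing one family/subfamily in the phylogeny.

    Starting from the MRCA of all focal-labelled leaves, the MRCA clade is
    kept if non-focal ("spurious") leaves make up less than ``max_spurious``
    of it; otherwise the largest fully pure subclade is selected.  The result
    records purity (focal fraction of the clade) and coverage (fraction of
    all focal sequences captured).
    """
    focal_leaves = {ident for ident, lb in labels.items()
                    if _label_at_level(lb, level) == focal}
    if not focal_leaves:
        raise ValueError(f"no leaf carries {level} label {focal!r}")
    comp = CladeComparison(focal=focal, level=level)

    # subtree focal/total leaf counts by one postorder sweep
    n_focal: dict[dendropy.Node, int] = {}
    n_total: dict[dendropy.Node, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            n_total[nd] = 1
            n_focal[nd] = 1 if node_id(nd) in focal_leaves else 0
        else:
            n_total[nd] = sum(n_total[ch] for ch in nd.child_nodes())
            n_focal[nd] = sum(n_focal[ch] for ch in nd.child_nodes())
    root = tree.seed_node
    if n_focal[root] < len(focal_leaves):
        missing = focal_leaves - clade_leaf_names(root)
        raise KeyError(f"focal leaves missing from tree: {sorted(missing)}")

    # MRCA of focal leaves
    mrca_node = root
    descended = True
    while descended:
        descended = False
        for ch in mrca_node.child_nodes():
            if n_focal[ch] == len(focal_leaves):
                mrca_node = ch
                descended = True
                break

    spurious = 1.0 - n_focal[mrca_node] / n_total[mrca_node]
    if spurious < max_spurious:
        chosen = mrca_node
    else:
        # largest fully pure subclade, ties broken by preorder
        chosen = None
        for nd in mrca_node.preorder_iter():
            if n_focal[nd] == n_total[nd] and n_focal[nd] > 0:
                if chosen is None or n_total[nd] > n_total[chosen]:
                    chosen = nd
        if chosen is None:  # cannot happen: focal leaves are pure clades
            raise RuntimeError("no pure subclade found")

    comp.clade_a_node = node_id(chosen)
    comp.clade_a_leaves = clade_leaf_names(chosen)
    comp.ancestor_a = comp.clade_a_node
    comp.purity = n_focal[chosen] / n_total[chosen]
    comp.coverage = n_focal[chosen] / len(focal_leaves)
    if n_focal[chosen] < min_clade_size:
        comp.scorable = False
        comp.reason = (f"largest clade holds {n_focal[chosen]} focal "
                       f"sequences (< {min_clade_size})")
    return comp


def select_sister_clade(tree: dendropy.Tree, candidate: CladeComparison,
                        labels: dict[str, SequenceLabels],
                        min_clade_size: int = MIN_CLADE_SIZE,
                        ) -> CladeComparison:
    """Attach the nearest sister clade to a focal-clade candidate.

    The sister is the other child subtree of clade A's parent (for a
    polytomy, the largest other child, ties by preorder).  The comparison is
    scorable only if both clades hold at least ``min_clade_size`` sequences
    and the sister's dominant label shares the focal unit's parent level
    (sister subfamilies must belong to the same family; sister families to
    the same group).
    """
    if not candidate.scorable:
        return candidate
    comp = candidate
    node = None
    for nd in tree.preorder_node_iter():
        if node_id(nd) == comp.clade_a_node:
            node = nd
            break
    if node is None or node.parent_node is None:
        comp.scorable = False
        comp.reason = "focal clade is the whole tree; no sister exists"
        return comp
    siblings = [ch for ch in node.parent_node.child_nodes() if ch is not node]
    sister = max(siblings, key=lambda nd: (sum(1 for _ in nd.leaf_iter())))
    comp.clade_b_node = node_id(sister)
    comp.clade_b_leaves = clade_leaf_names(sister)
    comp.ancestor_b = comp.clade_b_node

    if len(comp.clade_a_leaves) < min_clade_size or \
            len(comp.clade_b_leaves) < min_clade_size:
        comp.scorable = False
        comp.reason = "clade below the 5-sequence minimum"
        return comp

    parent_level = _parent_level(comp.level)
    focal_parents = {
        _label_at_level(labels[x], parent_level)
        for x in comp.clade_a_leaves
        if x in labels and _label_at_level(labels[x], comp.level) == comp.focal
    }
    sister_parents = [
        _label_at_level(labels[x], parent_level)
        for x in comp.clade_b_leaves if x in labels
    ]
    if sister_parents:
        dominant = max(set(sister_parents),
                       key=lambda v: (sister_parents.count(v), str(v)))
        if dominant not in focal_parents:
            comp.scorable = False
            comp.reason = (f"sister clade dominated by {parent_level} "
                           f"{dominant!r}, outside the focal {parent_level}")
    return comp


# ---------------------------------------------------------------------------
# scoring


def recent_conservation(residues, matrix: dict[tuple[str, str], float]
                        ) -> float | None:
    """Mean rescaled similarity over all unordered sequence pairs.

    Pairs involving a gap contribute zero.  Columns with fewer than two
    residues are undefined (None) and are skipped by the caller.
    """
    residues = list(residues)
    non_gap = [r for r in residues if r != GAP and r != "-"]
    if len(non_gap) < 2:
        return None
    n = len(residues)
    total = 0.0
    for i in range(n):
        if residues[i] == GAP:
            continue
        for j in range(i + 1, n):
            if residues[j] == GAP:
                continue
            total += matrix[(residues[i], residues[j])]
    n_pairs = n * (n - 1) / 2
    return total / n_pairs


def ancestral_agreement(res_a: str, res_b: str,
                        posterior_b: np.ndarray) -> tuple[int, float]:
    """(AC, p(AC)) from the two ancestral residues and clade B's posterior.

    AC is +1 when the predicted residues match, -1 otherwise.  For a match,
    p(AC) is the clade-B posterior of the shared residue; for a mismatch it
    is the summed clade-B posterior of everything except clade A's residue.
    An ancestral gap never matches a residue (the residue-only posterior
    assigns it zero mass).
    """
    posterior_b = np.asarray(posterior_b, dtype=float)
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    if res_a == res_b and res_a in idx:
        return 1, float(posterior_b[idx[res_b]])
    p_a = float(posterior_b[idx[res_a]]) if res_a in idx else 0.0
    return -1, 1.0 - p_a


def divergence_scores(comparison: CladeComparison, aln: AlignedKinaseSet,
                      anc: AncestralStateTable,
                      matrix: dict[tuple[str, str], float] | None = None,
                      ) -> DivergenceScoreTable:
    """Score every mapped column of one clade comparison.

    Columns with undefined RC (fewer than two clade-A residues) or missing
    ancestral entries are skipped and logged.
    """
    if not comparison.scorable:
        raise ValueError(
            f"comparison for {comparison.focal!r} is unscorable: "
            f"{comparison.reason}")
    if matrix is None:
        matrix = rescaled_matrix()
    seqs = dict(aln.sequences)
    clade_a = sorted(comparison.clade_a_leaves & set(seqs))
    rows = []
    for col in range(aln.n_columns):
        rc = recent_conservation((seqs[x][col] for x in clade_a), matrix)
        if rc is None:
            logger.debug("column %d skipped: RC undefined", col)
            continue
        key_a = (comparison.ancestor_a, col)
        key_b = (comparison.ancestor_b, col)
        if key_a not in anc.entries or key_b not in anc.entries:
            logger.debug("column %d skipped: missing ancestral entry", col)
            continue
        res_a = anc.residue(*key_a)
        res_b = anc.residue(*key_b)
        ac, p_ac = ancestral_agreement(res_a, res_b, anc.posterior(*key_b))
        rows.append({
            "column": col,
            "domain_position": aln.column_map.get(col, -1),
            "rc": rc, "ac": ac, "p_ac": p_ac, "s": rc - ac * p_ac,
        })
    return DivergenceScoreTable(comparison, pd.DataFrame(
        rows, columns=["column", "domain_position", "rc", "ac", "p_ac", "s"]))


# ---------------------------------------------------------------------------
# aggregation


def call_switches(tables: list[DivergenceScoreTable], level: str,
                  percentile: float = SWITCH_PERCENTILE,
                  n_positions: int = 246) -> SwitchProfile:
    """Pool scores at one level, threshold at the 95th percentile, count
    switches per domain position.

    Comparisons sharing the same unordered pair of ancestral nodes are
    collapsed to one before pooling (the same duplication event must not be
    counted twice).  A (comparison, column) is a switch iff its score
    strictly exceeds the pooled percentile (linear-interpolation quantile).
    """
    if not tables:
        raise ValueError("no score tables supplied")
    seen: set[frozenset[str]] = set()
    unique_tables = []
    for tb in tables:
        key = frozenset((tb.comparison.ancestor_a, tb.comparison.ancestor_b))
        if key in seen:
            logger.info("duplicate comparison %s collapsed", set(key))
            continue
        seen.add(key)
        unique_tables.append(tb)
    pooled = np.concatenate([tb.scores["s"].to_numpy()
                             for tb in unique_tables if len(tb.scores)])
    threshold = float(np.percentile(pooled, percentile))
    counts = {p: 0 for p in range(1, n_positions + 1)}
    for tb in unique_tables:
        hits = tb.scores[tb.scores["s"] > threshold]
        for pos in hits["domain_position"]:
            if pos in counts:
                counts[int(pos)] += 1
    return SwitchProfile(level=level, counts=counts, threshold=threshold,
                         n_comparisons=len(unique_tables), dedup_keys=seen)


def frequently_switching(profile: SwitchProfile,
                         percentile: float = FREQUENT_PERCENTILE) -> set[int]:
    """Domain positions whose switch count strictly exceeds the 90th
    percentile of all per-position counts."""
    positions = sorted(profile.counts)
    counts = np.array([profile.counts[p] for p in positions], dtype=float)
    thr = np.percentile(counts, percentile)
    return {p for p, c in zip(positions, counts) if c > thr}


def category_tests(profile: SwitchProfile, frequent: set[int],
                   categories: FunctionalCategoryMap,
                   mw_category: str = "proximal") -> dict:
    """Functional-category enrichment of frequently switching positions.

    (a) One-sided Fisher's exact test on the 2x2 table of
    {frequently switching, not} x {any named category, 'other'}.
    (b) One-tailed Mann-Whitney (asymptotic, tie-corrected) comparing switch
    counts of ``mw_category`` positions against 'other' positions.
    """
    positions = sorted(profile.counts)
    named = {p for p in positions if categories.categories[p] != "other"}
    if not named or len(named) == len(positions):
        raise ValueError("need both named-category and 'other' positions")
    a = len(frequent & named)
    b = len(frequent - named)
    c = len(named - frequent)
    d = len(set(positions) - named - frequent)
    table = [[a, b], [c, d]]
    _, fisher_p = stats.fisher_exact(table, alternative="greater")

    cat_positions = [p for p in positions
                     if categories.categories[p] == mw_category]
    if not cat_positions:
        raise ValueError(f"category {mw_category!r} is empty")
    other_positions = [p for p in positions
                       if categories.categories[p] == "other"]
    x = [profile.counts[p] for p in cat_positions]
    y = [profile.counts[p] for p in other_positions]
    mw = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return {
        "fisher_table": table,
        "fisher_p": float(fisher_p),
        "mannwhitney_category": mw_category,
        "mannwhitney_U": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
    }
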