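"""Kinase specificity models (PWMs) and their comparison.

A specificity model is a 20-residue x 14-flank-position probability matrix
built from 15-mer target sites centred on S/T (flank positions -7..-1 and
+1..+7; the fixed centre column is excluded).  Models are compared with the
Frobenius distance — the square root of the summed squared elementwise
differences — within and between groups, families and subfamilies, and a
divergence threshold separating "same specificity" from "diverged" pairs is
derived by subsampling target sites of well-characterised kinases.  The
operating threshold derived from literature-curated kinase targets is 1.06
(:data:`SPECIFICITY_DIVERGENCE_THRESHOLD`); pipelines on synthetic data
should re-derive it with :func:`derive_threshold`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from kinevo.alphabet import AA_INDEX, N_AA, PAD
from kinevo.io_formats import AlignedKinaseSet

logger = logging.getLogger(__name__)

#: flank positions of the 15-mer window, centre excluded
FLANK_POSITIONS: tuple[int, ...] = tuple(range(-7, 0)) + tuple(range(1, 8))
N_FLANK = len(FLANK_POSITIONS)

#: operating Frobenius-distance threshold separating specificity-conserved
#: from specificity-diverged kinase pairs, derived from size-25 subsamples of
#: kinases with >= 50 literature-curated target sites
SPECIFICITY_DIVERGENCE_THRESHOLD = 1.06

DEFAULT_MIN_SITES = 10
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class SpecificityModel:
    """PWM over 14 flank positions plus provenance labels."""

    kinase: str
    matrix: np.ndarray  # (20, 14), columns are probability vectors
    n_sites: int
    st_ratio: float  # fraction of sites with centre S (vs T)
    group: str | None = None
    family: str | None = None
    subfamily: str | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (N_AA, N_FLANK):
            raise ValueError("matrix must be 20 x 14")
        if (M < 0).any():
            raise ValueError("matrix entries must be nonnegative")
        sums = M.sum(axis=0)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        self.matrix = M

    def label(self, level: str) -> str | None:
        return {"group": self.group, "family": self.family,
                "subfamily": self.subfamily}[level]


@dataclass
class PairwiseSpecificityReport:
    level: str
    within: list[float]
    between: list[float]
    ks_statistic: float
    ks_p: float
    example_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def build_pwm(sites: list[str], kinase: str = "kinase",
              min_sites: int = DEFAULT_MIN_SITES,
              pseudocount: float = DEFAULT_PSEUDOCOUNT,
              group: str | None = None, family: str | None = None,
              subfamily: str | None = None) -> SpecificityModel:
    """Estimate a PWM from 15-mer target sites.

    Each flank column is ``(count + pseudocount) / (n_eff + 20*pseudocount)``
    where ``n_eff`` is the number of non-padding characters observed at that
    position (terminal padding is excluded from counts).
    """
    if len(sites) < min_sites:
        raise ValueError(
            f"kinase {kinase!r}: {len(sites)} sites, need >= {min_sites}")
    M = np.zeros((N_AA, N_FLANK))
    n_centre_s = 0
    for s in sites:
        if len(s) != 15 or s[7] not in ("S", "T"):
            raise ValueError(f"invalid 15-mer site {s!r}")
        n_centre_s += s[7] == "S"
        for j, pos in enumerate(FLANK_POSITIONS):
            ch = s[7 + pos]
            if ch == PAD:
                continue
            if ch not in AA_INDEX:
                raise ValueError(f"invalid residue {ch!r} in site {s!r}")
            M[AA_INDEX[ch], j] += 1.0
    n_eff = M.sum(axis=0)
    denom = n_eff + N_AA * pseudocount
    with np.errstate(invalid="ignore"):
        P = (M + pseudocount) / denom
    P[:, denom == 0] = 0.0
    return SpecificityModel(
        kinase=kinase, matrix=P, n_sites=len(sites),
        st_ratio=n_centre_s / len(sites),
        group=group, family=family, subfamily=subfamily)


def frobenius_distance(a: SpecificityModel, b: SpecificityModel) -> float:
    """sqrt of summed squared elementwise matrix differences."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("matrix shape mismatch")
    return float(np.linalg.norm(a.matrix - b.matrix))


def derive_threshold(kinase_sites: list[tuple[str, list[str]]],
                     subsample_size: int = 25, n_draws: int = 100,
                     seed: int = 0, min_total_sites: int = 50,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Specificity-divergence threshold by same-kinase subsampling.

    For every kinase with at least ``min_total_sites`` sites, draw two
    independent subsamples of ``subsample_size`` sites (each without
    replacement), build the two PWMs, and record their Frobenius distance;
    the threshold is the maximum distance observed over all kinases and
    draws.  Kinases below the site minimum are excluded and logged.
    """
    rng = np.random.default_rng(seed)
    best = 0.0
    n_used = 0
    for kinase, sites in kinase_sites:
        if len(sites) < min_total_sites:
            logger.info("derive_threshold: %s excluded (%d < %d sites)",
                        kinase, len(sites), min_total_sites)
            continue
        n_used += 1
        sites = np.asarray(sites)
        for _ in range(n_draws):
            sub1 = rng.choice(sites, size=subsample_size, replace=False)
            sub2 = rng.choice(sites, size=subsample_size, replace=False)
            p1 = build_pwm(list(sub1), kinase=kinase,
                           min_sites=subsample_size, pseudocount=pseudocount)
            p2 = build_pwm(list(sub2), kinase=kinase,
                           min_sites=subsample_size, pseudocount=pseudocount)
            best = max(best, frobenius_distance(p1, p2))
    if n_used == 0:
        raise ValueError("no kinase reaches the site minimum")
    return best


def _parent_level(level: str) -> str | None:
    return {"group": None, "family": "group", "subfamily": "family"}[level]


def pairwise_level_analysis(models: list[SpecificityModel],
                            level: str) -> PairwiseSpecificityReport:
    """Within- vs between-grouping Frobenius distances at one level.

    Within distances pair models sharing the level label; between distances
    pair models with different labels that share the parent level (families
    are compared only within a group, subfamilies only within a family).  The
    two samples are compared with a two-sided two-sample KS test.
    """
    labelled = [m for m in models if m.label(level) is not None]
    groupings = {m.label(level) for m in labelled}
    if len(groupings) < 2:
        raise ValueError(f"need >= 2 groupings at level {level!r}")
    parent = _parent_level(level)
    within, between = [], []
    examples = []
    for a, b in itertools.combinations(labelled, 2):
        d = frobenius_distance(a, b)
        if a.label(level) == b.label(level):
            within.append(d)
        else:
            if parent is not None and a.label(parent) != b.label(parent):
                continue
            between.append(d)
        if len(examples) < 10:
            examples.append((a.kinase, b.kinase, d))
    if not within or not between:
        raise ValueError("empty within or between distance sample")
    ks = stats.ks_2samp(within, between)
    return PairwiseSpecificityReport(
        level=level, within=within, between=between,
        ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
        example_pairs=examples)


def identity_vs_distance(models: list[SpecificityModel],
                         aln: AlignedKinaseSet,
                         position_subset: set[int],
                         threshold: float = SPECIFICITY_DIVERGENCE_THRESHOLD,
                         n_bins: int = 10):
    """Relate kinase-domain sequence identity to specificity distance.

    For every pair of kinases present in both inputs, percent identity is
    computed over the given domain-position subset (a position counts as a
    match when both residues are equal and not gaps; the denominator is the
    subset size) and paired with the Frobenius distance of their PWMs.

    Returns ``(r, curve)`` where ``r`` is the Pearson correlation (NaN with a
    logged explanation when either variable has zero variance) and ``curve``
    is a list of (identity bin centre, fraction of pairs above threshold).
    """
    if not position_subset:
        raise ValueError("empty domain-position subset")
    pos_to_col = {p: c for c, p in aln.column_map.items()}
    missing = sorted(p for p in position_subset if p not in pos_to_col)
    if missing:
        raise KeyError(f"domain positions not mapped: {missing}")
    cols = [pos_to_col[p] for p in sorted(position_subset)]
    seqs = dict(aln.sequences)
    usable = [m for m in models if m.kinase in seqs]
    identities, distances = [], []
    for a, b in itertools.combinations(usable, 2):
        sa, sb = seqs[a.kinase], seqs[b.kinase]
        matches = sum(1 for c in cols if sa[c] == sb[c] and sa[c] != "-")
        identities.append(100.0 * matches / len(cols))
        distances.append(frobenius_distance(a, b))
    identities = np.asarray(identities)
    distances = np.asarray(distances)
    if len(identities) < 2 or np.std(identities) == 0 or \
            np.std(distances) == 0:
        logger.warning("identity_vs_distance: zero variance, r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(identities, distances).statistic)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    curve = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (identities >= lo) & (identities < hi if hi < 100
                                       else identities <= hi)
        if in_bin.any():
            frac = float((distances[in_bin] > threshold).mean())
            curve.append(((lo + hi) / 2, frac))
    return r, curve
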