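"""Phosphorylation-motif discovery, enrichment and filtering.

The phosphoproteome of a species is a set of unique 15-mer peptides centred
on phosphorylated S/T.  Motifs are degenerate positional patterns over the
flank positions (e.g. ``R-x-x-S/T`` or ``S/T-P-x-K``).  The machinery here:

* shuffled-flank backgrounds (each site's 14 flank characters permuted with
  the centre fixed, 10 shuffles per site), so foreground and background have
  identical amino-acid composition;
* a greedy motif-x-style extraction: constraints (position, residue) are
  added one at a time, each minimising a binomial p-value against the
  current background subset, until no constraint passes the significance
  threshold; matched sites are removed and extraction repeats;
* a superset-conditioned binomial enrichment p-value: the null probability
  of a motif is its background frequency *conditional on the most frequent
  superset motif* (the motif with one constraint removed that matches the
  most background sites), so deeper motifs are scored relative to their
  parents rather than to raw composition;
* cross-species filtering: synonym-class merging ({R,K}, {D,E}, {L,I,V,M}),
  superphylum prevalence rules, and discard rules for spurious patterns
  (S/T additions to classical motifs, D/E additions to the casein-kinase-2
  motif, motifs exclusive to singleton superphyla);
* phosphoproteome coverage: the percentage of sites matching at least one
  eligible motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from kinevo.alphabet import AMINO_ACIDS, PAD
from kinevo.io_formats import PhosphoSiteCollection

logger = logging.getLogger(__name__)

CENTRE_INDEX = 7
FLANK_OFFSETS = tuple(p for p in range(-7, 8) if p != 0)

#: residue classes treated as synonymous when merging motifs across species
SYNONYM_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("RK"), frozenset("DE"), frozenset("LIVM"),
)

#: preferred display order inside a residue class (R/K not K/R, etc.)
_DISPLAY_ORDER = "RKDELIVMSTAGCFHNPQWY"

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_MIN_OCCURRENCES = 20
DEFAULT_SHUFFLES_PER_SITE = 10


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate pattern over flank positions; centre fixed to S/T.

    ``constraints`` is a tuple of (flank position, residue class) pairs
    sorted by position; positions run -7..+7 excluding 0.
    """

    constraints: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        for pos, cls in self.constraints:
            if pos == 0 or not -7 <= pos <= 7:
                raise ValueError(f"invalid flank position {pos}")
            if not cls or not set(cls) <= set(AMINO_ACIDS):
                raise ValueError(f"invalid residue class {set(cls)}")
        positions = [p for p, _ in self.constraints]
        if positions != sorted(positions) or \
                len(positions) != len(set(positions)):
            raise ValueError("constraints must be sorted and unique by position")

    @classmethod
    def from_dict(cls, constraints: dict[int, set[str] | str]
                  ) -> "MotifPattern":
        items = tuple(sorted((p, frozenset(c))
                             for p, c in constraints.items()))
        return cls(items)

    @property
    def as_dict(self) -> dict[int, frozenset[str]]:
        return dict(self.constraints)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def without(self, pos: int) -> "MotifPattern":
        return MotifPattern(tuple((p, c) for p, c in self.constraints
                                  if p != pos))

    def to_string(self) -> str:
        """Dash-separated notation, e.g. ``R-x-x-S/T-P``."""
        positions = [p for p, _ in self.constraints]
        lo = min([0] + positions)
        hi = max([0] + positions)
        d = self.as_dict
        tokens = []
        for p in range(lo, hi + 1):
            if p == 0:
                tokens.append("S/T")
            elif p in d:
                members = sorted(d[p], key=_DISPLAY_ORDER.index)
                tokens.append("/".join(members))
            else:
                tokens.append("x")
        return "-".join(tokens)

    def __str__(self) -> str:
        return self.to_string()


def parse_motif(text: str) -> MotifPattern:
    """Parse dash-separated notation; the first ``S/T`` token is the centre."""
    tokens = text.strip().split("-")
    try:
        centre = tokens.index("S/T")
    except ValueError:
        raise ValueError(f"motif {text!r} has no S/T centre token") from None
    constraints: dict[int, set[str]] = {}
    for i, tok in enumerate(tokens):
        if i == centre or tok in ("x", "X"):
            continue
        constraints[i - centre] = set(tok.split("/"))
    return MotifPattern.from_dict(constraints)


# ---------------------------------------------------------------------------
# matching (byte-matrix helpers used throughout for speed)


def site_matrix(sites: list[str]) -> np.ndarray:
    """(n, 15) uint8 matrix of peptide characters."""
    if not sites:
        return np.empty((0, 15), dtype=np.uint8)
    return np.frombuffer("".join(sites).encode("ascii"),
                         dtype=np.uint8).reshape(len(sites), 15)


def match_mask(motif: MotifPattern, matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of rows matching the motif (padding matches nothing)."""
    mask = np.ones(matrix.shape[0], dtype=bool)
    for pos, cls in motif.constraints:
        col = matrix[:, CENTRE_INDEX + pos]
        allowed = np.frombuffer("".join(sorted(cls)).encode("ascii"),
                                dtype=np.uint8)
        mask &= np.isin(col, allowed)
    return mask


def match_motif(motif: MotifPattern, site: str) -> bool:
    """True iff every constrained position's character is in its class."""
    if len(site) != 15:
        raise ValueError(f"site {site!r} is not a 15-mer")
    for pos, cls in motif.constraints:
        if site[CENTRE_INDEX + pos] not in cls:
            return False
    return True


# ---------------------------------------------------------------------------
# backgrounds and enrichment


def generate_background(fore: PhosphoSiteCollection,
                        shuffles_per_site: int = DEFAULT_SHUFFLES_PER_SITE,
                        seed: int = 0) -> PhosphoSiteCollection:
    """Shuffled-flank background: per site, permute the 14 flank characters
    (padding included) with the centre fixed.

    The output holds ``shuffles_per_site`` rows per foreground site, in
    foreground order (site i's shuffles occupy rows i*k .. (i+1)*k - 1), so
    background rows can be traced back to their source site.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pep in fore.sites:
        flank = list(pep[:CENTRE_INDEX] + pep[CENTRE_INDEX + 1:])
        for _ in range(shuffles_per_site):
            perm = rng.permutation(len(flank))
            shuffled = [flank[i] for i in perm]
            out.append("".join(shuffled[:CENTRE_INDEX]) + pep[CENTRE_INDEX]
                       + "".join(shuffled[CENTRE_INDEX:]))
    return PhosphoSiteCollection(fore.species, out, unique=False)


@dataclass
class EnrichmentResult:
    motif: MotifPattern
    species: str
    k: int                    # foreground motif matches
    n: int                    # foreground superset matches
    bg_motif: int             # background motif matches
    bg_superset: int          # background superset matches
    p0: float                 # null probability
    p_value: float
    fold: float
    superset: MotifPattern
    testable: bool = True


def _best_superset(motif: MotifPattern, bg: np.ndarray
                   ) -> tuple[MotifPattern, int]:
    """Superset (one constraint removed) with the most background matches.

    For a single-constraint motif the superset is the bare S/T centre, i.e.
    all sites.  Ties break towards removing the position nearest the centre.
    """
    if motif.n_constraints == 1:
        bare = MotifPattern(())
        return bare, bg.shape[0]
    best = None
    for pos, _ in motif.constraints:
        sup = motif.without(pos)
        cnt = int(match_mask(sup, bg).sum())
        key = (-cnt, abs(pos), pos)
        if best is None or key < best[0]:
            best = (key, sup, cnt)
    return best[1], best[2]


def superset_binomial(motif: MotifPattern, fore: PhosphoSiteCollection,
                      back: PhosphoSiteCollection) -> EnrichmentResult:
    """Binomial enrichment of a motif conditional on its superset motif.

    ``p0`` = background motif matches / background superset matches;
    ``n`` = foreground superset matches, ``k`` = foreground motif matches;
    the p-value is the exact upper binomial tail P(Bin(n, p0) >= k).
    """
    if len(back) == 0:
        raise ValueError("background collection is empty")
    fg = site_matrix(fore.sites)
    bg = site_matrix(back.sites)
    superset, bg_sup = _best_superset(motif, bg)
    bg_motif = int(match_mask(motif, bg).sum())
    k = int(match_mask(motif, fg).sum())
    n = int(match_mask(superset, fg).sum())
    if bg_sup == 0:
        logger.warning("motif %s untestable: superset unmatched in background",
                       motif)
        return EnrichmentResult(motif, fore.species, k, n, bg_motif, 0,
                                float("nan"), float("nan"), float("nan"),
                                superset, testable=False)
    p0 = bg_motif / bg_sup
    if k == 0:
        p_value = 1.0
    else:
        p_value = float(stats.binom.sf(k - 1, n, p0))
    p_value = min(max(p_value, 0.0), 1.0)
    fold = (k / n) / p0 if n > 0 and p0 > 0 else float("inf") if k else 0.0
    return EnrichmentResult(motif, fore.species, k, n, bg_motif, bg_sup,
                            p0, p_value, fold, superset)


# ---------------------------------------------------------------------------
# discovery


def discover_motifs(fore: PhosphoSiteCollection, back: PhosphoSiteCollection,
                    p_threshold: float = DEFAULT_P_THRESHOLD,
                    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
                    back_parent: np.ndarray | None = None,
                    ) -> list[MotifPattern]:
    """Greedy recursive motif extraction over single-residue constraints.

    Starting from the bare S/T centre, repeatedly add the (position, residue)
    constraint minimising the binomial p-value of its foreground count
    against the current background subset frequency; a constraint is added
    only while its p-value is below ``p_threshold`` and its foreground count
    stays at or above ``min_occurrences`` (so every emitted motif meets the
    occurrence rule).  When no constraint passes, the motif (if any) is
    emitted, its matching foreground sites — and their background shuffles —
    are removed, and extraction restarts.  Ties break towards smaller
    p-value, then smaller absolute position, then alphabetical residue.

    ``back_parent`` maps each background row to the index of its source
    foreground site; when omitted and the background size is an exact
    multiple of the foreground size, consecutive blocks are assumed (the
    layout produced by :func:`generate_background`).  Otherwise background
    rows matching the emitted motif are removed instead.
    """
    fg_all = site_matrix(fore.sites)
    bg_all = site_matrix(back.sites)
    nf, nb = fg_all.shape[0], bg_all.shape[0]
    if back_parent is None and nf > 0 and nb % nf == 0:
        back_parent = np.repeat(np.arange(nf), nb // nf)
    fg_alive = np.ones(nf, dtype=bool)
    bg_alive = np.ones(nb, dtype=bool)
    residues = [ord(a) for a in AMINO_ACIDS]
    motifs: list[MotifPattern] = []

    while True:
        fg_idx = np.flatnonzero(fg_alive)
        bg_idx = np.flatnonzero(bg_alive)
        if len(fg_idx) < min_occurrences or len(bg_idx) == 0:
            break
        fg = fg_all[fg_idx]
        bg = bg_all[bg_idx]
        constraints: dict[int, str] = {}
        while True:
            n = fg.shape[0]
            m = bg.shape[0]
            if m == 0:
                break  # no background left to estimate a null from
            best = None
            for pos in FLANK_OFFSETS:
                if pos in constraints:
                    continue
                col_f = fg[:, CENTRE_INDEX + pos]
                col_b = bg[:, CENTRE_INDEX + pos]
                kf = np.bincount(col_f, minlength=128)
                kb = np.bincount(col_b, minlength=128)
                for code in residues:
                    k = int(kf[code])
                    if k < min_occurrences:
                        continue
                    p0 = kb[code] / m
                    p = float(stats.binom.sf(k - 1, n, p0)) if p0 > 0 else 0.0
                    key = (p, abs(pos), pos, chr(code))
                    if p < p_threshold and (best is None or key < best[0]):
                        best = (key, pos, chr(code))
            if best is None:
                break
            _, pos, res = best
            constraints[pos] = res
            keep_f = fg[:, CENTRE_INDEX + pos] == ord(res)
            keep_b = bg[:, CENTRE_INDEX + pos] == ord(res)
            fg, bg = fg[keep_f], bg[keep_b]
            fg_idx, bg_idx = fg_idx[keep_f], bg_idx[keep_b]
        if not constraints:
            break
        motif = MotifPattern.from_dict(
            {p: {r} for p, r in constraints.items()})
        motifs.append(motif)
        matched = match_mask(motif, fg_all) & fg_alive
        fg_alive &= ~matched
        if back_parent is not None:
            bg_alive &= ~matched[back_parent]
        else:
            bg_alive &= ~match_mask(motif, bg_all)
    return motifs


# ---------------------------------------------------------------------------
# cross-species filtering


def canonical_motif(motif: MotifPattern) -> MotifPattern:
    """Map every constraint class through the synonym classes.

    A class is widened to the union of the synonym classes its members touch
    ({R} and {K} both become {R,K}); residues outside any class stay as-is.
    """
    new = {}
    for pos, cls in motif.constraints:
        widened: set[str] = set()
        for r in cls:
            for syn in SYNONYM_CLASSES:
                if r in syn:
                    widened |= syn
                    break
            else:
                widened.add(r)
        new[pos] = widened
    return MotifPattern.from_dict(new)


#: classical kinase substrate signatures used by the S/T-addition rule
CLASSICAL_MOTIFS: tuple[str, ...] = (
    "S/T-P",            # proline-directed (CDK/MAPK)
    "R-x-x-S/T",        # basophilic
    "S/T-x-x-D/E",      # acidophilic
    "R-R-x-S/T",        # PKA/PKG
    "S/T-P-x-K",        # CDK
    "S/T-D/E-x-D/E",    # CK2
)

_CK2_MOTIF = "S/T-D/E-x-D/E"


@dataclass
class MotifCatalogEntry:
    motif: MotifPattern            # canonical (synonym-merged) form
    species: set[str]
    superphyla: dict[str, int]     # superphylum -> number of species
    passed_rules: list[str] = field(default_factory=list)
    discard_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.discard_reason is None and bool(self.passed_rules)


@dataclass
class MotifCatalog:
    entries: list[MotifCatalogEntry]

    @property
    def retained(self) -> list[MotifPattern]:
        return [e.motif for e in self.entries if e.retained]


def _is_extension_of(motif: MotifPattern, base: MotifPattern,
                     extra_allowed: frozenset[str]) -> bool:
    """True iff motif = base plus >= 1 extra constraints, every extra class
    a subset of ``extra_allowed``."""
    md, bd = motif.as_dict, base.as_dict
    if motif.n_constraints <= base.n_constraints:
        return False
    for pos, cls in bd.items():
        if md.get(pos) != cls:
            return False
    return all(cls <= extra_allowed
               for pos, cls in md.items() if pos not in bd)


def filter_motifs(per_species: dict[str, list[MotifPattern]],
                  superphylum_of: dict[str, str],
                  classical: tuple[str, ...] = CLASSICAL_MOTIFS,
                  excavate_clade: str = "excavates",
                  singleton_clades: tuple[str, ...] = ("amoebozoa",
                                                       "heterokonts"),
                  ) -> MotifCatalog:
    """Merge per-species discoveries and apply the retention protocol.

    Motifs are first mapped through the synonym classes and merged across
    species.  A merged motif is retained when it appears in at least a third
    of the species of some superphylum, or in at least two excavate species.
    It is discarded when it is exclusive to the singleton superphyla, when it
    is a classical motif plus only S/T additions, or when it is the
    casein-kinase-2 motif plus only D/E additions.  Every decision is
    recorded on the catalog entry.
    """
    unassigned = sorted({sp for sp in per_species if sp not in superphylum_of})
    if unassigned:
        raise KeyError(f"species without a superphylum: {unassigned}")
    clade_sizes: dict[str, int] = {}
    for sp, clade in superphylum_of.items():
        clade_sizes[clade] = clade_sizes.get(clade, 0) + 1

    merged: dict[MotifPattern, set[str]] = {}
    for sp, motifs in per_species.items():
        for m in motifs:
            merged.setdefault(canonical_motif(m), set()).add(sp)

    classical_canon = [canonical_motif(parse_motif(c)) for c in classical]
    ck2 = canonical_motif(parse_motif(_CK2_MOTIF))
    st = frozenset("ST")
    de = frozenset("DE")

    entries = []
    for motif, species in sorted(merged.items(),
                                 key=lambda kv: kv[0].to_string()):
        clade_counts: dict[str, int] = {}
        for sp in species:
            clade = superphylum_of[sp]
            clade_counts[clade] = clade_counts.get(clade, 0) + 1
        entry = MotifCatalogEntry(motif, species, clade_counts)

        if set(clade_counts) <= set(singleton_clades):
            entry.discard_reason = (
                "exclusive to singleton superphyla "
                f"({', '.join(sorted(clade_counts))})")
            entries.append(entry)
            continue
        if any(_is_extension_of(motif, base, st)
               for base in classical_canon):
            entry.discard_reason = "S/T addition to a classical motif"
            entries.append(entry)
            continue
        if _is_extension_of(motif, ck2, de):
            entry.discard_reason = "D/E addition to the CK2 motif"
            entries.append(entry)
            continue
        for clade, cnt in sorted(clade_counts.items()):
            if clade == excavate_clade:
                if cnt >= 2:
                    entry.passed_rules.append(
                        f"{cnt} {excavate_clade} species (>= 2)")
            elif clade in singleton_clades:
                continue
            elif cnt >= clade_sizes[clade] / 3:
                entry.passed_rules.append(
                    f"{cnt}/{clade_sizes[clade]} {clade} species (>= 1/3)")
        if not entry.passed_rules:
            entry.discard_reason = "below prevalence thresholds"
        entries.append(entry)
    return MotifCatalog(entries)


# ---------------------------------------------------------------------------
# coverage


_SINGLE_CONSTRAINT_EXCEPTIONS = ("S/T-P", "R-x-x-S/T")


def phosphoproteome_coverage(motifs, sites: PhosphoSiteCollection) -> float:
    """Percentage of phosphosites matching at least one eligible motif.

    Single-constraint motifs are ineligible (matches arise too easily by
    chance), except the classical S/T-P and R-x-x-S/T signatures, which are
    sufficient for kinase targeting on their own.
    """
    if isinstance(motifs, MotifCatalog):
        motifs = motifs.retained
    if len(sites) == 0:
        raise ValueError("empty phosphosite collection")
    exceptions = {canonical_motif(parse_motif(s))
                  for s in _SINGLE_CONSTRAINT_EXCEPTIONS}
    eligible = [m for m in motifs
                if m.n_constraints >= 2 or canonical_motif(m) in exceptions]
    mat = site_matrix(sites.sites)
    matched = np.zeros(len(sites), dtype=bool)
    for m in eligible:
        matched |= match_mask(m, mat)
    return 100.0 * float(matched.sum()) / len(sites)
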