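"""File formats and alignment quality filters.

Every external file the pipeline touches is read and written here: FASTA
alignments with TSV label tables, Newick trees, TSV ancestral-state tables
(node, column, residue, 20 posterior columns in ACDEFGHIKLMNPQRSTVWY order),
phosphosite 15-mer tables, binary presence/absence matrices, divergence-time
tables and functional-category maps.

Coordinate conventions: alignment columns are 0-based internally; kinase
domain positions are 1-based (1..246 for the canonical kinase domain model)
in every external file.

The alignment quality filters mirror a standard kinome-alignment protocol:
sequences lacking the expected catalytic residues at five diagnostic domain
positions are removed as pseudokinases, columns with >= 20% gaps are dropped,
and truncated sequences with fewer than 190 mapped non-gap positions are
removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from kinevo.alphabet import AA_INDEX, AMINO_ACIDS, GAP, N_AA, PAD
from kinevo.trees import ensure_internal_names, validate_tree

logger = logging.getLogger(__name__)

#: number of positions in the canonical kinase domain model
N_DOMAIN_POSITIONS = 246

#: diagnostic domain positions and their expected (canonical catalytic)
#: residues used by the pseudokinase filter: VAIK lysine, alphaC glutamate,
#: HRD aspartate, catalytic-loop asparagine, DFG aspartate.
DEFAULT_REQUIRED_RESIDUES: dict[int, frozenset[str]] = {
    30: frozenset("K"),
    48: frozenset("E"),
    123: frozenset("D"),
    128: frozenset("N"),
    141: frozenset("D"),
}

FUNCTIONAL_CATEGORIES = (
    "catalytic",
    "proximal",
    "distal_SDR",
    "regulatory",
    "interaction",
    "other",
)


@dataclass(frozen=True)
class SequenceLabels:
    species: str
    group: str
    family: str | None = None
    subfamily: str | None = None


@dataclass
class AlignedKinaseSet:
    """Labelled protein multiple sequence alignment with domain numbering.

    ``sequences`` is an ordered list of (identifier, aligned string) pairs;
    ``labels`` maps identifier to :class:`SequenceLabels`; ``column_map`` maps
    0-based alignment column to 1-based kinase-domain position for mapped
    columns (unmapped columns are simply absent from the map).
    """

    sequences: list[tuple[str, str]]
    labels: dict[str, SequenceLabels]
    column_map: dict[int, int]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment contains no sequences")
        ids = [i for i, _ in self.sequences]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence identifiers: {dup}")
        L = len(self.sequences[0][1])
        for ident, seq in self.sequences:
            if len(seq) != L:
                raise ValueError(
                    f"ragged alignment: sequence {ident!r} has length "
                    f"{len(seq)}, expected {L}"
                )
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"missing label for identifier(s): {missing}")
        cols = sorted(self.column_map)
        mapped = [self.column_map[c] for c in cols]
        if any(b <= a for a, b in zip(mapped, mapped[1:])):
            raise ValueError("column_map must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def identifiers(self) -> list[str]:
        return [i for i, _ in self.sequences]

    def sequence(self, ident: str) -> str:
        for i, s in self.sequences:
            if i == ident:
                return s
        raise KeyError(ident)

    def column(self, col: int) -> dict[str, str]:
        return {i: s[col] for i, s in self.sequences}

    def domain_position(self, col: int) -> int | None:
        return self.column_map.get(col)


@dataclass
class AncestralStateTable:
    """Per internal node, per alignment column: residue call and posterior.

    ``entries`` maps (node id, 0-based column) to (predicted residue,
    posterior vector over the 20 residues in alphabetical order). ``ties``
    collects keys where the argmax was tied and broken alphabetically.
    """

    entries: dict[tuple[str, int], tuple[str, np.ndarray]]
    ties: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, (res, post) in self.entries.items():
            post = np.asarray(post, dtype=float)
            if post.shape != (N_AA,):
                raise ValueError(f"posterior at {key} must have length 20")
            if not np.isclose(post.sum(), 1.0, atol=1e-6):
                raise ValueError(f"posterior at {key} does not sum to 1")
            if res in AA_INDEX and post[AA_INDEX[res]] < post.max() - 1e-12:
                raise ValueError(
                    f"predicted residue at {key} is not an argmax of the "
                    "posterior"
                )
            self.entries[key] = (res, post)

    def residue(self, node: str, col: int) -> str:
        return self.entries[(node, col)][0]

    def posterior(self, node: str, col: int) -> np.ndarray:
        return self.entries[(node, col)][1]


@dataclass
class PhosphoSiteCollection:
    """Species-level set of 15-mer peptides centred on S/T."""

    species: str
    sites: list[str]
    unique: bool = True

    def __post_init__(self) -> None:
        for s in self.sites:
            if len(s) != 15:
                raise ValueError(f"site {s!r} is not a 15-mer")
            if s[7] not in ("S", "T"):
                raise ValueError(f"site {s!r} centre is not S/T")
        if self.unique and len(self.sites) != len(set(self.sites)):
            raise ValueError("duplicate peptides in a unique collection")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PresenceAbsenceMatrix:
    """Binary kinase-unit presence across taxa."""

    taxa: list[str]
    units: list[str]
    levels: dict[str, str]  # unit -> group|family|subfamily
    values: np.ndarray  # taxa x units, 0/1

    def __post_init__(self) -> None:
        V = np.asarray(self.values)
        if V.shape != (len(self.taxa), len(self.units)):
            raise ValueError("matrix shape does not match taxa/units")
        if not np.isin(V, (0, 1)).all():
            raise ValueError("presence values must be 0/1")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        if len(set(self.units)) != len(self.units):
            raise ValueError("duplicate units")
        self.values = V.astype(np.int8)

    def column(self, unit: str) -> dict[str, int]:
        j = self.units.index(unit)
        return {t: int(self.values[i, j]) for i, t in enumerate(self.taxa)}


@dataclass
class FunctionalCategoryMap:
    """Kinase-domain position -> functional category."""

    categories: dict[int, str]
    n_positions: int = N_DOMAIN_POSITIONS

    def __post_init__(self) -> None:
        missing = [p for p in range(1, self.n_positions + 1)
                   if p not in self.categories]
        if missing:
            raise ValueError(
                f"positions without a category: {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        bad = sorted({c for c in self.categories.values()
                      if c not in FUNCTIONAL_CATEGORIES})
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    def positions(self, category: str) -> list[int]:
        return [p for p, c in self.categories.items() if c == category]


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment(path, labels_path, column_map_path=None) -> AlignedKinaseSet:
    """Read a FASTA alignment plus its TSV label table.

    The label table needs columns ``identifier``, ``species``, ``group`` and
    optionally ``family``/``subfamily`` (empty cells mean absent).  Gap
    characters '.' are normalised to '-'.  Without a column-map file the
    mapping is the identity (column i -> domain position i+1).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    sequences = [(r.id, str(r.seq).upper().replace(".", GAP)) for r in records]
    df = pd.read_csv(labels_path, sep="\t", dtype=str).fillna("")
    labels = {}
    for _, row in df.iterrows():
        labels[row["identifier"]] = SequenceLabels(
            species=row["species"],
            group=row["group"],
            family=row.get("family") or None,
            subfamily=row.get("subfamily") or None,
        )
    if column_map_path is not None:
        cm = pd.read_csv(column_map_path, sep="\t")
        column_map = dict(
            zip(cm["alignment_column"].astype(int),
                cm["domain_position"].astype(int))
        )
    else:
        ncol = len(sequences[0][1])
        column_map = {c: c + 1 for c in range(ncol)}
    return AlignedKinaseSet(sequences, labels, column_map)


def write_alignment(aln: AlignedKinaseSet, fasta_path, labels_path,
                    column_map_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for ident, seq in aln.sequences:
            fh.write(f">{ident}\n{seq}\n")
    rows = []
    for ident in aln.identifiers:
        lb = aln.labels[ident]
        rows.append({
            "identifier": ident, "species": lb.species, "group": lb.group,
            "family": lb.family or "", "subfamily": lb.subfamily or "",
        })
    pd.DataFrame(rows).to_csv(labels_path, sep="\t", index=False)
    if column_map_path is not None:
        pd.DataFrame(
            {"alignment_column": sorted(aln.column_map),
             "domain_position": [aln.column_map[c]
                                 for c in sorted(aln.column_map)]}
        ).to_csv(column_map_path, sep="\t", index=False)


def filter_alignment(
    aln: AlignedKinaseSet,
    required_residues: dict[int, frozenset[str]] | None = None,
    max_gap_fraction: float = 0.20,
    min_mapped_positions: int = 190,
) -> AlignedKinaseSet:
    """Apply the pseudokinase, gap-column and truncation filters, in order.

    1. Drop sequences lacking an allowed residue at each required domain
       position (required positions absent from the column map raise).
    2. Drop columns whose gap fraction is >= ``max_gap_fraction`` (closed
       bound: exactly 20% is dropped).
    3. Drop sequences with fewer than ``min_mapped_positions`` non-gap
       residues at mapped columns.

    Returns a new object; the input is not modified.
    """
    if required_residues is None:
        required_residues = DEFAULT_REQUIRED_RESIDUES
    pos_to_col = {p: c for c, p in aln.column_map.items()}
    for pos in required_residues:
        if pos not in pos_to_col:
            raise KeyError(f"required domain position {pos} is not mapped")

    # 1. pseudokinase filter
    kept = []
    for ident, seq in aln.sequences:
        ok = all(seq[pos_to_col[pos]] in allowed
                 for pos, allowed in required_residues.items())
        if ok:
            kept.append((ident, seq))
        else:
            logger.info("pseudokinase filter dropped %s", ident)
    logger.info("pseudokinase filter: %d -> %d sequences",
                len(aln.sequences), len(kept))
    if not kept:
        raise ValueError("all sequences filtered (pseudokinase filter)")

    # 2. gap-fraction column filter
    n = len(kept)
    ncol = len(kept[0][1])
    gap_counts = np.zeros(ncol, dtype=int)
    for _, seq in kept:
        gap_counts += np.frombuffer(seq.encode(), dtype=np.uint8) == ord(GAP)
    keep_cols = [c for c in range(ncol) if gap_counts[c] / n < max_gap_fraction]
    logger.info("gap-column filter: %d -> %d columns", ncol, len(keep_cols))
    new_map = {i: aln.column_map[c]
               for i, c in enumerate(keep_cols) if c in aln.column_map}
    kept = [(ident, "".join(seq[c] for c in keep_cols)) for ident, seq in kept]

    # 3. truncation filter
    mapped_cols = sorted(new_map)
    final = []
    for ident, seq in kept:
        n_mapped = sum(1 for c in mapped_cols if seq[c] != GAP)
        if n_mapped >= min_mapped_positions:
            final.append((ident, seq))
        else:
            logger.info("truncation filter dropped %s (%d mapped positions)",
                        ident, n_mapped)
    logger.info("truncation filter: %d -> %d sequences", len(kept), len(final))
    if not final:
        raise ValueError("all sequences filtered (truncation filter)")

    labels = {i: aln.labels[i] for i, _ in final}
    return AlignedKinaseSet(final, labels, new_map)


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree; unnamed internal nodes get preorder names."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"cannot parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True
    ensure_internal_names(tree)
    validate_tree(tree)
    return tree


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same conventions as :func:`read_tree`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse Newick string: {exc}") from exc
    tree.is_rooted = True
    ensure_internal_names(tree)
    validate_tree(tree)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def read_phosphosites(path, pad_char: str = PAD,
                      species: str | None = None):
    """Read a TSV of (species, peptide) rows into per-species collections.

    Peptides shorter than 15 are padded symmetrically with ``pad_char`` (odd
    leftovers pad the C-terminal side).  Rows whose centre is not S/T are
    rejected and counted.  Duplicate peptides within a species are removed.

    Returns (collections, rejection_report) where collections maps species to
    :class:`PhosphoSiteCollection` and rejection_report maps species to the
    number of rejected rows.  With ``species`` given, returns the single
    collection (and still logs rejections).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    collections: dict[str, PhosphoSiteCollection] = {}
    rejected: dict[str, int] = {}
    for sp, sub in df.groupby("species", sort=True):
        seen, sites = set(), []
        nrej = 0
        for pep in sub["peptide"]:
            pep = _pad_peptide(str(pep).strip().upper(), pad_char)
            if len(pep) != 15 or pep[7] not in ("S", "T"):
                nrej += 1
                continue
            if pep not in seen:
                seen.add(pep)
                sites.append(pep)
        collections[sp] = PhosphoSiteCollection(str(sp), sites, unique=True)
        rejected[sp] = nrej
        if nrej:
            logger.info("rejected %d non-S/T-centred sites for %s", nrej, sp)
    if species is not None:
        return collections[species]
    return collections, rejected


def _pad_peptide(pep: str, pad_char: str) -> str:
    if len(pep) >= 15:
        return pep[:15]
    total = 15 - len(pep)
    left = total // 2
    return pad_char * left + pep + pad_char * (total - left)


def write_phosphosites(collections, path) -> None:
    if isinstance(collections, PhosphoSiteCollection):
        collections = {collections.species: collections}
    rows = [{"species": sp, "peptide": pep}
            for sp, coll in collections.items() for pep in coll.sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_POSTERIOR_COLS = list(AMINO_ACIDS)


def read_ancestral_table(path) -> AncestralStateTable:
    """Read the TSV dialect: node, column, residue, 20 posterior columns."""
    df = pd.read_csv(path, sep="\t")
    entries = {}
    post = df[_POSTERIOR_COLS].to_numpy(dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        entries[(str(row.node), int(row.column))] = (str(row.residue), post[i])
    return AncestralStateTable(entries)


def write_ancestral_table(table: AncestralStateTable, path) -> None:
    rows = []
    for (node, col), (res, post) in sorted(table.entries.items()):
        row = {"node": node, "column": col, "residue": res}
        row.update({a: post[i] for i, a in enumerate(AMINO_ACIDS)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_presence_matrix(path, levels_path=None) -> PresenceAbsenceMatrix:
    """Read taxa x units binary TSV; unit levels from a sidecar TSV or
    encoded in the unit name as ``level:name``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    units = list(df.columns)
    if levels_path is not None:
        lv = pd.read_csv(levels_path, sep="\t", dtype=str)
        levels = dict(zip(lv["unit"], lv["level"]))
    else:
        levels = {}
        for u in list(units):
            if ":" in u:
                level, name = u.split(":", 1)
                levels[name] = level
            else:
                levels[u] = "family"
        units = [u.split(":", 1)[1] if ":" in u else u for u in units]
    return PresenceAbsenceMatrix(
        taxa=list(df.index.astype(str)), units=units,
        levels=levels, values=df.to_numpy(),
    )


def write_presence_matrix(pam: PresenceAbsenceMatrix, path) -> None:
    cols = [f"{pam.levels[u]}:{u}" for u in pam.units]
    pd.DataFrame(pam.values, index=pam.taxa, columns=cols).to_csv(path, sep="\t")


def read_divergence_times(path) -> dict[str, float]:
    """Read node -> age (million years) table with columns node, age_mya."""
    df = pd.read_csv(path, sep="\t")
    return {str(r.node): float(r.age_mya) for r in df.itertuples(index=False)}


def write_divergence_times(times: dict[str, float], path) -> None:
    pd.DataFrame(
        {"node": list(times), "age_mya": list(times.values())}
    ).to_csv(path, sep="\t", index=False)


def read_category_map(path, n_positions: int = N_DOMAIN_POSITIONS
                      ) -> FunctionalCategoryMap:
    df = pd.read_csv(path, sep="\t")
    cats = {int(r.domain_position): str(r.category)
            for r in df.itertuples(index=False)}
    return FunctionalCategoryMap(cats, n_positions=n_positions)


def write_category_map(cmap: FunctionalCategoryMap, path) -> None:
    pd.DataFrame(
        {"domain_position": sorted(cmap.categories),
         "category": [cmap.categories[p] for p in sorted(cmap.categories)]}
    ).to_csv(path, sep="\t", index=False)
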