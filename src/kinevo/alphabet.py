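"""Shared residue alphabet and index helpers.

All matrices and posterior vectors in the package are ordered over
``AMINO_ACIDS`` = ACDEFGHIKLMNPQRSTVWY (alphabetical one-letter codes).
``GAP`` ('-') marks alignment gaps; ``PAD`` ('_') marks terminal padding of
peptides shorter than 15 residues and is excluded from all residue counts.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA: int = 20
GAP: str = "-"
PAD: str = "_"


def residues_to_indices(residues: str) -> np.ndarray:
    """Map a residue string to alphabet indices; GAP/PAD map to -1."""
    return np.array([AA_INDEX.get(r, -1) for r in residues], dtype=np.int64)


def is_residue(ch: str) -> bool:
    return ch in AA_INDEX
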