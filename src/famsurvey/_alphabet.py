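"""Amino-acid alphabet constants shared across the package."""

from __future__ import annotations

import numpy as np

#: The 20 canonical amino acids, alphabetical. Column order of every
#: frequency/emission matrix in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

GAP = "-"

#: Sentinel used instead of -inf so scores stay arithmetic-safe.
NEG_SENTINEL = -1.0e4

#: Chemical classes used for logo annotation (WebLogo-style palette).
CHEMICAL_CLASS: dict[str, str] = {}
for _aa in "GSTYC":
    CHEMICAL_CLASS[_aa] = "polar"
for _aa in "QN":
    CHEMICAL_CLASS[_aa] = "neutral"
for _aa in "KRH":
    CHEMICAL_CLASS[_aa] = "basic"
for _aa in "DE":
    CHEMICAL_CLASS[_aa] = "acidic"
for _aa in "AVLIPWFM":
    CHEMICAL_CLASS[_aa] = "hydrophobic"


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to int indices; non-canonical letters -> -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def is_canonical(seq: str) -> bool:
    return all(c in AA_INDEX for c in seq)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)
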