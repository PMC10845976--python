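"""Per-clade consensus logos, conserved-site calling, motif segmentation.

Each clade's match strings yield per-column residue frequencies (gaps
excluded from the denominator, occupancy tracked separately), information
content ic = log2(20) - H in bits (the logo stack height), and a consensus
string of modal residues ('x' where occupancy is too low). Across clades, a
column is a conserved site when every clade is conserved there, and a
consensus-dominant site when all clades additionally agree on the modal
residue. The three characteristic motif blocks are segmented as maximal
runs of cross-clade-conserved columns separated by longer unconserved gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import AMINO_ACIDS, AA_INDEX, CHEMICAL_CLASS, GAP

__all__ = [
    "ConsensusLogo",
    "ConservedSiteReport",
    "column_frequencies",
    "information_content",
    "build_logo",
    "consensus_sequence",
    "call_conserved_sites",
    "cross_clade_logo",
    "motif_segments",
]

logger = logging.getLogger(__name__)

LOG2_20 = float(np.log2(20.0))


def column_frequencies(match_strings: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(freq (L, 20), occupancy (L,)) per column, gaps excluded from freq.

    A column where no sequence has a residue gets a zero frequency row and
    occupancy 0 (its information content is defined as 0 downstream).
    """
    if not match_strings:
        raise ValueError("at least one match string is required")
    L = len(match_strings[0])
    if any(len(s) != L for s in match_strings):
        raise ValueError("match strings must share one length")
    n = len(match_strings)
    counts = np.zeros((L, 20))
    for s in match_strings:
        for c_idx, ch in enumerate(s):
            a = AA_INDEX.get(ch)
            if a is not None:
                counts[c_idx, a] += 1
    n_res = counts.sum(axis=1)
    occupancy = n_res / n
    freq = np.zeros_like(counts)
    nz = n_res > 0
    freq[nz] = counts[nz] / n_res[nz, None]
    return freq, occupancy


def information_content(
    freq_row: np.ndarray,
    n_residues: int | None = None,
    small_sample_correction: bool = False,
) -> float:
    """ic = log2(20) - H(freq) in bits, optionally small-sample corrected.

    The correction subtracts e_n = 19 / (2 ln2 n); the result is floored at
    zero. A zero frequency row (empty column) returns 0.
    """
    f = np.asarray(freq_row, dtype=float)
    if f.sum() <= 0:
        return 0.0
    nzf = f[f > 0]
    h = float(-(nzf * np.log2(nzf)).sum())
    ic = LOG2_20 - h
    if small_sample_correction:
        if not n_residues:
            raise ValueError("n_residues is required for the small-sample correction")
        ic -= 19.0 / (2.0 * np.log(2.0) * n_residues)
    return max(ic, 0.0)


@dataclass(frozen=True)
class ConsensusLogo:
    """Frequencies, occupancy, information content and consensus for one clade."""

    clade_name: str
    freq: np.ndarray  # (L, 20)
    occupancy: np.ndarray  # (L,)
    ic: np.ndarray  # (L,) bits
    consensus: str
    n_members: int = 0

    @property
    def n_columns(self) -> int:
        return int(self.freq.shape[0])

    def to_table(self):
        """Logo as a pandas DataFrame, one row per match column (TSV export)."""
        import pandas as pd

        rows = []
        for i in range(self.n_columns):
            row: dict = {"column": i}
            row.update({a: self.freq[i, k] for k, a in enumerate(AMINO_ACIDS)})
            cons = self.consensus[i]
            row.update({
                "occupancy": self.occupancy[i],
                "ic": self.ic[i],
                "consensus": cons,
                "chemical_class": CHEMICAL_CLASS.get(cons, "none"),
            })
            rows.append(row)
        return pd.DataFrame(rows)


def _modal_residues(freq: np.ndarray, occupancy: np.ndarray, min_occupancy: float) -> str:
    """Modal residue per column, ties alphabetical, 'x' below min occupancy."""
    out = []
    for i in range(freq.shape[0]):
        if occupancy[i] < min_occupancy or freq[i].sum() <= 0:
            out.append("x")
        else:
            # np.argmax returns the first maximum; columns are alphabetical
            out.append(AMINO_ACIDS[int(np.argmax(freq[i]))])
    return "".join(out)


def build_logo(
    clade_name: str,
    match_strings: Sequence[str],
    min_occupancy: float = 0.5,
    small_sample_correction: bool = False,
) -> ConsensusLogo:
    """Assemble the full per-clade logo from its member match strings."""
    freq, occ = column_frequencies(match_strings)
    n = len(match_strings)
    ic = np.array([
        information_content(freq[i], max(int(round(occ[i] * n)), 1), small_sample_correction)
        for i in range(freq.shape[0])
    ])
    return ConsensusLogo(
        clade_name=clade_name, freq=freq, occupancy=occ, ic=ic,
        consensus=_modal_residues(freq, occ, min_occupancy), n_members=n,
    )


def consensus_sequence(logo: ConsensusLogo, min_occupancy: float = 0.5) -> str:
    """Modal residue per column; 'x' where occupancy < min_occupancy."""
    return _modal_residues(logo.freq, logo.occupancy, min_occupancy)


@dataclass(frozen=True)
class ConservedSiteReport:
    """Cross-clade conservation calls on a common match-column grid."""

    positions: tuple[int, ...]  # conserved in every clade
    dominant_positions: tuple[int, ...]  # same modal residue everywhere
    modal_table: Mapping[int, Mapping[str, str]]  # column -> clade -> modal residue

    def __post_init__(self) -> None:
        if not set(self.dominant_positions) <= set(self.positions):
            raise ValueError("dominant positions must be a subset of conserved positions")


def call_conserved_sites(
    logos: Sequence[ConsensusLogo],
    ic_min: float = 2.0,
    occupancy_min: float = 0.5,
) -> ConservedSiteReport:
    """Columns conserved in all clades; dominant where modal residues agree.

    A column is conserved when every clade reaches `ic_min` bits and
    `occupancy_min` occupancy there, and consensus-dominant when all clades
    additionally share one modal residue.
    """
    if len(logos) < 2:
        raise ValueError("conserved-site calling needs at least 2 clades")
    L = logos[0].n_columns
    if any(lg.n_columns != L for lg in logos):
        raise ValueError("all logos must share the match-column count")
    positions, dominant = [], []
    modal_table: dict[int, dict[str, str]] = {}
    for i in range(L):
        if all(lg.ic[i] >= ic_min and lg.occupancy[i] >= occupancy_min for lg in logos):
            positions.append(i)
            modals = {lg.clade_name: lg.consensus[i] for lg in logos}
            modal_table[i] = modals
            vals = set(modals.values())
            if len(vals) == 1 and "x" not in vals:
                dominant.append(i)
    return ConservedSiteReport(
        positions=tuple(positions), dominant_positions=tuple(dominant),
        modal_table=modal_table,
    )


def cross_clade_logo(
    logos: Sequence[ConsensusLogo],
    min_occupancy: float = 0.5,
) -> ConsensusLogo:
    """Logo over clade consensuses: one 'sequence' per clade.

    Each clade's consensus string becomes one row, so ic here measures
    between-clade agreement (the kingdom-wide logo comparison view) rather
    than within-clade conservation. 'x' columns count as gaps.
    """
    rows = [consensus_sequence(lg, min_occupancy).replace("x", GAP) for lg in logos]
    return build_logo("cross-clade", rows, min_occupancy=min_occupancy)


def cross_clade_conservation_mask(
    xlogo: ConsensusLogo,
    agreement_min: float = 0.6,
    occupancy_min: float = 0.5,
) -> np.ndarray:
    """Columns where clade consensuses agree on one residue.

    Agreement = modal frequency x occupancy = the fraction of all clades
    whose consensus shows the modal residue. Unlike a fixed ic cutoff,
    this discriminates conserved from free columns even for a handful of
    clades (where column entropy is bounded by log2 of the clade count).
    """
    agreement = xlogo.freq.max(axis=1) * xlogo.occupancy
    return (agreement >= agreement_min) & (xlogo.occupancy >= occupancy_min)


def motif_segments(
    conserved_mask: Sequence[bool] | np.ndarray,
    run_break: int = 3,
    min_block: int = 5,
    expected: int = 3,
) -> list[tuple[int, int]]:
    """Segment conserved columns into motif blocks.

    Maximal runs of conserved columns are merged across unconserved gaps of
    at most `run_break` columns; runs spanning fewer than `min_block`
    columns are discarded as isolated chance agreements (a motif is tens of
    columns long, a lone conserved column is a site). Blocks are returned
    as 0-based half-open (start, end) ranges in profile order. Fewer (or
    more) than `expected` blocks triggers a warning but still returns what
    exists.
    """
    mask = np.asarray(conserved_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.warning("no conserved columns: no motif blocks found")
        return []
    blocks: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 > run_break:
            blocks.append((start, prev + 1))
            start = i
        prev = i
    blocks.append((start, prev + 1))
    blocks = [b for b in blocks if b[1] - b[0] >= min_block]
    if len(blocks) != expected:
        logger.warning("expected %d motif blocks, found %d", expected, len(blocks))
    return blocks
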