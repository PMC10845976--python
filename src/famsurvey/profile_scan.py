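"""Position-specific scoring profile: construction and local domain scanning.

A seed multiple alignment of the target domain is reduced to match columns
(occupancy above a threshold), converted to per-column log-odds emission
scores in bits, and aligned locally against each protein with affine gap
penalties (Smith-Waterman over profile columns x residues). A hit records
1-based coordinates, bit score, match-column coverage, and the residue
assigned to every match column ('-' where a column is unoccupied), which is
the coordinate system for all downstream phylogenetic and motif analysis.
Completeness filtering (minimum coverage and score) decides which proteins
count as family members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._alphabet import AMINO_ACIDS, AA_INDEX, GAP, NEG_SENTINEL, uniform_background

__all__ = [
    "SeedAlignment",
    "ScoringProfile",
    "DomainHit",
    "DegenerateAlignmentError",
    "determine_match_columns",
    "build_profile",
    "profile_from_seed",
    "scan_protein",
    "filter_complete",
    "write_profile",
    "read_profile",
]

logger = logging.getLogger(__name__)


class DegenerateAlignmentError(ValueError):
    """No column of the seed alignment reaches the occupancy threshold."""


@dataclass(frozen=True)
class SeedAlignment:
    """An aligned set of domain sequences (rows may contain '-')."""

    sequence_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("a seed alignment needs at least 2 rows")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("sequence ids must be unique")
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("one id per row required")
        width = len(self.rows[0])
        if width < 1 or any(len(r) != width for r in self.rows):
            raise ValueError("all rows must share one positive length")
        ok = set(AMINO_ACIDS + GAP)
        for rid, row in zip(self.sequence_ids, self.rows):
            if not set(row) <= ok:
                raise ValueError(f"row {rid!r} contains letters outside the alphabet+gap")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SeedAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class ScoringProfile:
    """Log-odds emission profile over match columns, scores in bits."""

    emissions: np.ndarray  # (L, 20)
    background: np.ndarray  # (20,)
    gap_open: float = -4.0
    gap_extend: float = -0.5
    match_column_map: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        em = np.asarray(self.emissions, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "emissions", em)
        object.__setattr__(self, "background", bg)
        if em.ndim != 2 or em.shape[1] != 20 or em.shape[0] < 1:
            raise ValueError("emissions must be (L, 20) with L >= 1")
        if abs(float(bg.sum()) - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")

    @property
    def n_match_columns(self) -> int:
        return int(self.emissions.shape[0])

    def consensus(self) -> str:
        """Highest-scoring residue per match column."""
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.emissions, axis=1))


@dataclass(frozen=True)
class DomainHit:
    """One located domain occurrence (coordinates 1-based inclusive)."""

    protein_id: str
    start: int
    end: int
    score: float
    coverage: float
    match_string: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")
        n_occ = sum(1 for c in self.match_string if c != GAP)
        cov = n_occ / len(self.match_string)
        if abs(cov - self.coverage) > 1e-9:
            raise ValueError("coverage inconsistent with match_string")

    @property
    def domain_length(self) -> int:
        return self.end - self.start + 1


def determine_match_columns(alignment: SeedAlignment, occupancy_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask: column occupancy (non-gap fraction) >= threshold."""
    if not 0.0 < occupancy_threshold <= 1.0:
        raise ValueError("occupancy_threshold must be in (0, 1]")
    arr = np.array([list(r) for r in alignment.rows])
    occ = (arr != GAP).mean(axis=0)
    mask = occ >= occupancy_threshold
    if not mask.any():
        raise DegenerateAlignmentError(
            f"no column reaches occupancy {occupancy_threshold}; alignment is all gaps?"
        )
    return mask


def build_profile(
    alignment: SeedAlignment,
    mask: np.ndarray,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> ScoringProfile:
    """Per-column log-odds scores e(c,a) = log2((n_ca + a*bg_a)/(N_c + a)/bg_a).

    Counts run over non-gap rows of each match column. With pseudocount 0 an
    unobserved residue gets the finite sentinel score instead of -inf.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    arr = np.array([list(r) for r in alignment.rows])
    cols = np.flatnonzero(mask)
    L = len(cols)
    emissions = np.empty((L, 20))
    for out_c, c in enumerate(cols):
        col = arr[:, c]
        residues = col[col != GAP]
        n_c = len(residues)
        counts = np.zeros(20)
        for r in residues:
            counts[AA_INDEX[r]] += 1
        with np.errstate(divide="ignore"):
            p = (counts + pseudocount * bg) / (n_c + pseudocount)
            e = np.log2(p / bg)
        e[np.isneginf(e)] = NEG_SENTINEL
        emissions[out_c] = e
    return ScoringProfile(
        emissions=emissions, background=bg, gap_open=gap_open,
        gap_extend=gap_extend, match_column_map=tuple(int(c) for c in cols),
    )


def profile_from_seed(
    sequence_ids: Sequence[str],
    rows: Sequence[str],
    occupancy_threshold: float = 0.5,
    pseudocount: float = 1.0,
    **kwargs,
) -> ScoringProfile:
    """Convenience: SeedAlignment -> match columns -> profile in one call."""
    aln = SeedAlignment(tuple(sequence_ids), tuple(rows))
    mask = determine_match_columns(aln, occupancy_threshold)
    return build_profile(aln, mask, pseudocount=pseudocount, **kwargs)


def _emission_scores(profile: ScoringProfile, sequence: str) -> np.ndarray:
    """(L, n) score of each profile column against each sequence residue.

    Non-canonical letters (X, B, Z, U, ...) score as the background
    expectation of the column; they are logged, never fatal.
    """
    L = profile.n_match_columns
    n = len(sequence)
    idx = np.array([AA_INDEX.get(c, -1) for c in sequence])
    S = np.empty((L, n))
    known = idx >= 0
    if known.any():
        S[:, known] = profile.emissions[:, idx[known]]
    if (~known).any():
        bad = sorted({sequence[j] for j in np.flatnonzero(~known)})
        logger.info("non-canonical letters %s scored as background expectation", bad)
        S[:, ~known] = (profile.emissions * profile.background).sum(axis=1, keepdims=True)
    return S


def _dp_best_hit(
    S: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, int, int, list[tuple[int, int]]] | None:
    """One optimal local alignment of profile columns vs sequence.

    Returns (score, start, end, matched (column, position) pairs) with
    1-based inclusive sequence coordinates, or None when no
    positive-scoring cell exists.
    States: M consumes column+residue; D consumes a column (gap in the
    sequence, '-' in the match string); I consumes a residue (insertion).
    A gap of either kind costs gap_open for its first site and gap_extend
    per additional site; D and I runs may not be adjacent.
    """
    L, n = S.shape
    NEG = -np.inf
    M = np.full((L + 1, n + 1), NEG)
    D = np.full((L + 1, n + 1), NEG)
    I = np.full((L + 1, n + 1), NEG)
    M[0, :] = NEG
    for i in range(1, L + 1):
        base = np.maximum(0.0, np.maximum(M[i - 1, :-1], np.maximum(D[i - 1, :-1], I[i - 1, :-1])))
        M[i, 1:] = base + S[i - 1]
        D[i, :] = np.maximum(M[i - 1, :] + gap_open, D[i - 1, :] + gap_extend)
        # I chains along the sequence axis: closed form via running maximum
        c = M[i, :-1] - gap_extend * np.arange(n)
        run = np.maximum.accumulate(c)
        I[i, 1:] = gap_open - gap_extend + gap_extend * np.arange(1, n + 1) + run
    best = float(M[1:, 1:].max(initial=NEG))
    if not np.isfinite(best) or best <= 0.0:
        return None
    i, j = np.unravel_index(int(np.argmax(M[1:, 1:])), (L, n))
    i += 1
    j += 1
    end = j
    pairs: list[tuple[int, int]] = []  # (profile column, sequence position), 1-based
    state = "M"
    tol = 1e-9
    while True:
        if state == "M":
            pairs.append((i, j))
            cands = (M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            prev = max(0.0, *cands)
            i -= 1
            j -= 1
            if prev <= tol:
                break  # local alignment start
            if abs(prev - cands[0]) <= tol:
                state = "M"
            elif abs(prev - cands[1]) <= tol:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            from_open = abs(D[i, j] - (M[i - 1, j] + gap_open)) <= tol
            i -= 1
            state = "M" if from_open else "D"
        else:  # I: sequence residue inserted between match columns
            from_open = abs(I[i, j] - (M[i, j - 1] + gap_open)) <= tol
            j -= 1
            state = "M" if from_open else "I"
    start = min(jj for _, jj in pairs)
    return best, start, end, pairs


def scan_protein(
    profile: ScoringProfile,
    sequence: str,
    protein_id: str = "",
    genome_id: str = "",
    score_threshold: float = 15.0,
    max_hits: int = 10,
) -> list[DomainHit]:
    """Locate domain occurrences in one protein.

    Returns the best local alignment, then further best-scoring
    non-overlapping hits (greedy, previously hit spans masked out) while
    scores stay at or above `score_threshold`, up to `max_hits`.

    Reported start/end are envelope coordinates: the aligned span extended
    by any unaligned terminal profile columns (one residue per column),
    clamped to the sequence and to spans already claimed by earlier hits,
    so a few diverged terminal columns do not shrink the domain span.
    Score, coverage and match_string always describe the alignment itself.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    L = profile.n_match_columns
    if L > 10 * len(sequence):
        logger.warning(
            "profile (%d columns) is more than 10x longer than protein %r (%d aa); skipping",
            L, protein_id, len(sequence),
        )
        return []
    S = _emission_scores(profile, sequence)
    claimed = np.zeros(len(sequence), dtype=bool)
    hits: list[DomainHit] = []
    for _ in range(max_hits):
        res = _dp_best_hit(S, profile.gap_open, profile.gap_extend)
        if res is None:
            break
        score, start, end, pairs = res
        if hits and score < score_threshold:
            break
        chars = [GAP] * L
        for col, pos in pairs:
            chars[col - 1] = sequence[pos - 1]
        match_string = "".join(chars)
        n_occ = len(pairs)
        claimed[start - 1 : end] = True
        # envelope: push out over unaligned terminal columns
        lead = min(p[0] for p in pairs) - 1
        trail = L - max(p[0] for p in pairs)
        env_start, env_end = start, end
        while lead > 0 and env_start > 1 and not claimed[env_start - 2]:
            env_start -= 1
            lead -= 1
        while trail > 0 and env_end < len(sequence) and not claimed[env_end]:
            env_end += 1
            trail -= 1
        claimed[env_start - 1 : env_end] = True
        hits.append(DomainHit(
            protein_id=protein_id, genome_id=genome_id, start=env_start, end=env_end,
            score=round(float(score), 6), coverage=n_occ / L, match_string=match_string,
        ))
        S[:, env_start - 1 : env_end] = NEG_SENTINEL  # exclude overlap next pass
    return hits


def filter_complete(
    hits: Iterable[DomainHit],
    coverage_min: float = 0.8,
    score_min: float = 15.0,
) -> list[DomainHit]:
    """Keep complete domains only: coverage and bit score above thresholds."""
    if not 0.0 <= coverage_min <= 1.0:
        raise ValueError("coverage_min must be in [0, 1]")
    return [h for h in hits if h.coverage >= coverage_min and h.score >= score_min]


def write_profile(profile: ScoringProfile, tsv_path: str | Path, json_path: str | Path) -> None:
    """Serialize: TSV of per-column scores plus a JSON header."""
    with open(tsv_path, "w") as fh:
        fh.write("column\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(profile.emissions):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    header = {
        "background": [float(b) for b in profile.background],
        "gap_open": profile.gap_open,
        "gap_extend": profile.gap_extend,
        "match_column_map": list(profile.match_column_map),
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)


def read_profile(tsv_path: str | Path, json_path: str | Path) -> ScoringProfile:
    rows = []
    with open(tsv_path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    with open(json_path) as fh:
        header = json.load(fh)
    return ScoringProfile(
        emissions=np.array(rows), background=np.array(header["background"]),
        gap_open=header["gap_open"], gap_extend=header["gap_extend"],
        match_column_map=tuple(header["match_column_map"]),
    )
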