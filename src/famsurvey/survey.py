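"""Distribution metrics of a domain survey.

Per-genome positive-gene counts, per-group percentages and count modes,
protein/domain length means, and the domain-position classifier: the
midpoint of the domain span divided by protein length places a domain on
the N-terminal side (< 40%), the C-terminal side (> 60%) or the middle.
Genomes without any positive gene count toward the percentage metric but
are excluded from the count mode and histogram.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profile_scan import DomainHit

__all__ = [
    "PositionClass",
    "GenomeSummary",
    "ManifestError",
    "classify_position",
    "summarize_genomes",
    "group_statistics",
]


class ManifestError(ValueError):
    """A hit references a genome absent from the manifest."""


@dataclass(frozen=True)
class PositionClass:
    midpoint_fraction: float
    label: str  # "N", "middle" or "C"


@dataclass
class GenomeSummary:
    genome_id: str
    group: str
    velvet_count: int = 0
    protein_lengths: list[int] = field(default_factory=list)
    domain_lengths: list[int] = field(default_factory=list)
    position_labels: list[str] = field(default_factory=list)


def classify_position(hit: DomainHit, protein_length: int) -> PositionClass:
    """Midpoint rule: fraction < 0.40 is N-side, > 0.60 is C-side, else middle.

    The midpoint of an even-length span stays fractional; the thresholds are
    strict, so a fraction of exactly 0.40 or 0.60 is "middle".
    """
    if protein_length < hit.end:
        raise ValueError(
            f"protein length {protein_length} shorter than hit end {hit.end} for {hit.protein_id!r}"
        )
    frac = ((hit.start + hit.end) / 2.0) / protein_length
    if frac < 0.40:
        label = "N"
    elif frac > 0.60:
        label = "C"
    else:
        label = "middle"
    return PositionClass(midpoint_fraction=frac, label=label)


def summarize_genomes(
    hits: Iterable[DomainHit],
    manifest: pd.DataFrame,
    protein_lengths: Mapping[str, int],
) -> list[GenomeSummary]:
    """One summary per manifest genome; zero-hit genomes appear with count 0.

    `manifest` needs columns genome_id and group; `protein_lengths` maps
    protein id -> full protein length (needed for position classification).
    """
    by_genome: dict[str, GenomeSummary] = {
        row.genome_id: GenomeSummary(genome_id=row.genome_id, group=row.group)
        for row in manifest.itertuples()
    }
    for h in hits:
        if h.genome_id not in by_genome:
            raise ManifestError(f"hit on {h.protein_id!r} references unknown genome {h.genome_id!r}")
        s = by_genome[h.genome_id]
        plen = protein_lengths[h.protein_id]
        s.velvet_count += 1
        s.protein_lengths.append(plen)
        s.domain_lengths.append(h.domain_length)
        s.position_labels.append(classify_position(h, plen).label)
    return list(by_genome.values())


def _mode_smallest(counts: Sequence[int]) -> tuple[int, bool]:
    """Modal value; ties resolved toward the smaller count, flagged."""
    c = Counter(counts)
    top = max(c.values())
    modal = sorted(k for k, v in c.items() if v == top)
    return modal[0], len(modal) > 1


def group_statistics(summaries: Iterable[GenomeSummary]) -> pd.DataFrame:
    """Per-group survey report mirroring the headline distribution metrics.

    Columns: percent_with_genes, count_mode (over positive genomes only),
    count_mode_tied, count histogram (JSON-ish dict), mean_protein_len,
    mean_domain_len, pct_N / pct_middle / pct_C of domain positions.
    """
    groups: dict[str, list[GenomeSummary]] = {}
    for s in summaries:
        groups.setdefault(s.group, []).append(s)
    rows = []
    for group in sorted(groups):
        ss = groups[group]
        positive = [s for s in ss if s.velvet_count > 0]
        pct_with = 100.0 * len(positive) / len(ss)
        if positive:
            mode, tied = _mode_smallest([s.velvet_count for s in positive])
            hist = dict(sorted(Counter(s.velvet_count for s in positive).items()))
        else:
            mode, tied, hist = 0, False, {}
        plens = [x for s in ss for x in s.protein_lengths]
        dlens = [x for s in ss for x in s.domain_lengths]
        labels = [x for s in ss for x in s.position_labels]
        n_lab = len(labels)
        rows.append({
            "group": group,
            "n_genomes": len(ss),
            "percent_with_genes": pct_with,
            "count_mode": mode,
            "count_mode_tied": tied,
            "count_histogram": hist,
            "mean_protein_len": sum(plens) / len(plens) if plens else float("nan"),
            "mean_domain_len": sum(dlens) / len(dlens) if dlens else float("nan"),
            "pct_N": 100.0 * labels.count("N") / n_lab if n_lab else float("nan"),
            "pct_middle": 100.0 * labels.count("middle") / n_lab if n_lab else float("nan"),
            "pct_C": 100.0 * labels.count("C") / n_lab if n_lab else float("nan"),
        })
    return pd.DataFrame(rows)
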