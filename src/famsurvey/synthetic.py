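"""Synthetic protein-family generator with planted domains and ground truth.

Emulates a kingdom-wide domain survey at desk scale: a root domain built
from three conserved motif blocks (lengths 33/44/36 by default) separated by
an unconserved linker and a short spacer; clade ancestors and members derived
by seeded substitution (motif positions mutate at a quarter of the linker
rate, so conservation is planted, not assumed); variable N/C flanks that
realize an N-terminal / middle / C-terminal domain position; per-genome gene
counts drawn from a configurable distribution; and composition-shuffled
decoy proteins carrying no domain. Every protein is logged in a truth table
so detection, classification and clade recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS, AA_INDEX, is_canonical

__all__ = [
    "DomainTemplate",
    "SurveyConfig",
    "SurveyResult",
    "default_template",
    "make_root_domain",
    "evolve_sequence",
    "evolve_with_mask",
    "make_seed_rows",
    "generate_survey",
    "write_survey",
    "classify_midpoint",
]

#: Canonical reference anchors, assigned to planted clades in this order.
REFERENCE_ANCHORS = ("VeA", "VelB", "VelC", "VosA")

DEFAULT_GROUPS = (
    "Pezizomycotina",
    "Saccharomycotina",
    "Agaricomycotina",
    "Mucoromycotina",
    "Taphrinomycotina",
    "Blastocladiomycota",
    "Chytridiomycetes",
    "Cryptomycota",
)


class ConfigError(ValueError):
    """Raised when a survey configuration cannot be realized."""


def _check_motif(name: str, s: str) -> None:
    if not s or not is_canonical(s):
        raise ValueError(f"{name} must be a non-empty string over the 20 canonical amino acids")


@dataclass(frozen=True)
class DomainTemplate:
    """Blueprint of the planted domain: three motifs, linker, spacer."""

    motif1: str
    motif2: str
    motif3: str
    linker_length_range: tuple[int, int] = (60, 90)
    spacer_length_range: tuple[int, int] = (6, 12)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        _check_motif("motif1", self.motif1)
        _check_motif("motif2", self.motif2)
        _check_motif("motif3", self.motif3)
        for rng_name, (lo, hi) in (
            ("linker_length_range", self.linker_length_range),
            ("spacer_length_range", self.spacer_length_range),
        ):
            if lo < 0 or lo > hi:
                raise ValueError(f"{rng_name} must satisfy 0 <= min <= max, got ({lo}, {hi})")


def default_template(seed: int = 0) -> DomainTemplate:
    """Random motifs of the default lengths 33/44/36, deterministic in `seed`."""
    rng = np.random.default_rng(seed)

    def motif(n: int) -> str:
        return "".join(rng.choice(list(AMINO_ACIDS), size=n))

    return DomainTemplate(motif1=motif(33), motif2=motif(44), motif3=motif(36), rng_seed=seed)


def make_root_domain(template: DomainTemplate) -> str:
    """Assemble the root domain sequence; deterministic given template.rng_seed."""
    seq, _ = make_root_domain_with_mask(template)
    return seq


def make_root_domain_with_mask(template: DomainTemplate) -> tuple[str, np.ndarray]:
    """Root domain plus a boolean mask marking motif (conserved) positions."""
    rng = np.random.default_rng(template.rng_seed)
    n_linker = int(rng.integers(template.linker_length_range[0], template.linker_length_range[1] + 1))
    n_spacer = int(rng.integers(template.spacer_length_range[0], template.spacer_length_range[1] + 1))
    linker = "".join(rng.choice(list(AMINO_ACIDS), size=n_linker))
    spacer = "".join(rng.choice(list(AMINO_ACIDS), size=n_spacer))
    seq = template.motif1 + linker + template.motif2 + spacer + template.motif3
    mask = np.zeros(len(seq), dtype=bool)
    mask[: len(template.motif1)] = True
    m2_start = len(template.motif1) + n_linker
    mask[m2_start : m2_start + len(template.motif2)] = True
    m3_start = m2_start + len(template.motif2) + n_spacer
    mask[m3_start:] = True
    return seq, mask


def motif_column_ranges(template: DomainTemplate) -> list[tuple[int, int]]:
    """0-based half-open (start, end) of the three motif blocks in the root."""
    seq, mask = make_root_domain_with_mask(template)
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def evolve_with_mask(
    parent: str,
    rate: float,
    seed: int,
    motif_mask: np.ndarray | None = None,
    indel_rate: float = 0.01,
) -> tuple[str, np.ndarray]:
    """Mutate `parent`; returns (child, child motif mask).

    Each position substitutes independently with probability `rate`
    (`rate/4` at masked motif positions), drawing uniformly from the 19
    alternative residues. Unmasked (linker/flank) positions additionally
    suffer insertions or deletions at `indel_rate` per site, so match-state
    recovery against a profile stays well-posed: motif columns never shift
    relative to each other except through linker length changes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0, 1], got {rate}")
    if motif_mask is None:
        motif_mask = np.zeros(len(parent), dtype=bool)
    motif_mask = np.asarray(motif_mask, dtype=bool)
    if motif_mask.shape[0] != len(parent):
        raise ValueError("motif_mask length must equal parent length")

    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    out: list[str] = []
    out_mask: list[bool] = []
    for pos, c in enumerate(parent):
        masked = bool(motif_mask[pos])
        p_sub = rate / 4.0 if masked else rate
        if not masked and indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(aa[rng.integers(20)])  # insertion before this site
            out_mask.append(False)
        if rng.random() < p_sub:
            # uniform over the 19 alternatives: skip the parent residue's index
            idx = int(rng.integers(19))
            ci = AA_INDEX.get(c, -1)
            if ci != -1 and idx >= ci:
                idx += 1
            out.append(aa[idx % 20])
        else:
            out.append(c)
        out_mask.append(masked)
    return "".join(out), np.array(out_mask, dtype=bool)


def evolve_sequence(
    parent: str,
    rate: float,
    seed: int,
    motif_mask: np.ndarray | None = None,
    indel_rate: float = 0.01,
) -> str:
    """Substitution/indel mutation of `parent`; see `evolve_with_mask`."""
    child, _ = evolve_with_mask(parent, rate, seed, motif_mask, indel_rate)
    return child


def make_seed_rows(
    root: str,
    motif_mask: np.ndarray,
    n_rows: int = 20,
    divergence: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Gapless seed-alignment rows around the root (substitutions only).

    Indels are suppressed so the rows form an implicit alignment of equal
    length; this is the stand-in for a curated seed alignment of the domain.
    """
    ids = [f"seed{i:02d}" for i in range(n_rows)]
    rows = [
        evolve_sequence(root, divergence, seed=seed * 1000 + i, motif_mask=motif_mask, indel_rate=0.0)
        for i in range(n_rows)
    ]
    return ids, rows


def classify_midpoint(start: int, end: int, protein_length: int) -> str:
    """Fig-5-style rule on 1-based inclusive coordinates: <40% N, >60% C."""
    frac = ((start + end) / 2.0) / protein_length
    if frac < 0.40:
        return "N"
    if frac > 0.60:
        return "C"
    return "middle"


_DEFAULT_FLANKS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "N": ((0, 20), (200, 400)),
    "middle": ((80, 160), (80, 160)),
    "C": ((200, 400), (0, 20)),
}


@dataclass(frozen=True)
class SurveyConfig:
    """Study conditions for one synthetic survey."""

    n_groups: int = 5
    genomes_per_group: int = 10
    gene_count_distribution: Mapping[int, float] = field(
        default_factory=lambda: {3: 0.2, 4: 0.6, 5: 0.2}
    )
    n_clades: int = 4
    between_clade_divergence: float = 0.30
    within_clade_divergence: float = 0.05
    flank_length_ranges: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: dict(_DEFAULT_FLANKS)
    )
    decoys_per_genome: float = 0.4
    seed: int = 0
    # -- secondary knobs (defaults are the study conditions) --
    position_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"N": 1 / 3, "middle": 1 / 3, "C": 1 / 3}
    )
    group_names: tuple[str, ...] | None = None
    indel_rate: float = 0.01
    n_root_lineages: int = 1
    lineage_divergence: float = 0.40
    outgroup_divergence: float = 0.70
    template_seed: int = 0

    def __post_init__(self) -> None:
        tot = float(sum(self.gene_count_distribution.values()))
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"gene_count_distribution probabilities sum to {tot}, not 1")
        if any(k < 0 for k in self.gene_count_distribution):
            raise ConfigError("gene counts must be non-negative")
        for name, v in (
            ("between_clade_divergence", self.between_clade_divergence),
            ("within_clade_divergence", self.within_clade_divergence),
        ):
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        pt = float(sum(self.position_class_probs.values()))
        if abs(pt - 1.0) > 1e-9:
            raise ConfigError("position_class_probs must sum to 1")
        for cls, (lf, rf) in self.flank_length_ranges.items():
            for lo, hi in (lf, rf):
                if lo < 0 or lo > hi:
                    raise ConfigError(f"flank range for class {cls!r} must satisfy 0 <= min <= max")
        if self.decoys_per_genome < 0:
            raise ConfigError("decoys_per_genome must be >= 0")
        if self.n_clades < 1 or self.n_groups < 1 or self.genomes_per_group < 1:
            raise ConfigError("n_clades, n_groups and genomes_per_group must be >= 1")
        if self.n_root_lineages < 1 or self.n_root_lineages > self.n_clades:
            raise ConfigError("n_root_lineages must be in [1, n_clades]")


@dataclass
class SurveyResult:
    """Generated proteomes plus every piece of planted ground truth."""

    config: SurveyConfig
    template: DomainTemplate
    root_domain: str
    root_mask: np.ndarray
    clade_ancestors: list[str]
    clade_ancestor_masks: list[np.ndarray]
    clade_lineage: list[int]
    lineage_ancestors: list[str]
    proteomes: dict[str, list[tuple[str, str]]]
    manifest: pd.DataFrame
    truth: pd.DataFrame
    references: dict[str, tuple[str, str]]
    outgroup: tuple[str, str]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.manifest["genome_id"])


def _sample_flanks(
    rng: np.random.Generator,
    cls: str,
    ranges: Mapping[str, tuple[tuple[int, int], tuple[int, int]]],
    domain_len: int,
    max_attempts: int = 1000,
) -> tuple[int, int]:
    (llo, lhi), (rlo, rhi) = ranges[cls]
    for _ in range(max_attempts):
        left = int(rng.integers(llo, lhi + 1))
        right = int(rng.integers(rlo, rhi + 1))
        start, end = left + 1, left + domain_len
        if classify_midpoint(start, end, left + domain_len + right) == cls:
            return left, right
    raise ConfigError(
        f"cannot realize position class {cls!r} from flank ranges {ranges[cls]} "
        f"with domain length {domain_len} after {max_attempts} attempts"
    )


def generate_survey(config: SurveyConfig) -> SurveyResult:
    """Generate proteomes, manifest, references, outgroup, and the truth table.

    Deterministic given ``config`` (including its seeds). Clade ancestors
    descend from one root, or from ``n_root_lineages`` diverged lineage
    ancestors when a two-clan structure is wanted; clade members then evolve
    at the within-clade rate.
    """
    rng = np.random.default_rng(config.seed)
    template = default_template(config.template_seed)
    root, root_mask = make_root_domain_with_mask(template)

    def subseed() -> int:
        return int(rng.integers(2**31 - 1))

    # lineage ancestors (clan structure); a single lineage is the root itself
    if config.n_root_lineages > 1:
        lineage_ancestors, lineage_masks = [], []
        for _ in range(config.n_root_lineages):
            s, m = evolve_with_mask(root, config.lineage_divergence, subseed(), root_mask, config.indel_rate)
            lineage_ancestors.append(s)
            lineage_masks.append(m)
    else:
        lineage_ancestors, lineage_masks = [root], [root_mask]

    clade_ancestors: list[str] = []
    clade_masks: list[np.ndarray] = []
    clade_lineage: list[int] = []
    for ci in range(config.n_clades):
        # contiguous blocks of clades per lineage, so sister clades share ancestry
        li = ci * config.n_root_lineages // config.n_clades
        s, m = evolve_with_mask(
            lineage_ancestors[li], config.between_clade_divergence, subseed(),
            lineage_masks[li], config.indel_rate,
        )
        clade_ancestors.append(s)
        clade_masks.append(m)
        clade_lineage.append(li)

    groups = config.group_names or DEFAULT_GROUPS
    group_list = [groups[i % len(groups)] if config.group_names is None else groups[i]
                  for i in range(config.n_groups)]

    counts = sorted(config.gene_count_distribution)
    probs = np.array([config.gene_count_distribution[c] for c in counts], dtype=float)
    classes = sorted(config.position_class_probs)
    class_probs = np.array([config.position_class_probs[c] for c in classes], dtype=float)
    aa = list(AMINO_ACIDS)

    proteomes: dict[str, list[tuple[str, str]]] = {}
    manifest_rows = []
    truth_rows = []
    gi = 0
    for group in group_list:
        for _ in range(config.genomes_per_group):
            genome_id = f"G{gi:04d}"
            gi += 1
            manifest_rows.append({"genome_id": genome_id, "group": group})
            proteins: list[tuple[str, str]] = []
            n_genes = int(rng.choice(counts, p=probs))
            if n_genes <= config.n_clades:
                clade_choice = rng.choice(config.n_clades, size=n_genes, replace=False)
            else:
                clade_choice = np.concatenate(
                    [np.arange(config.n_clades)] * (n_genes // config.n_clades + 1)
                )[:n_genes]
            for k, ci in enumerate(sorted(int(c) for c in clade_choice)):
                member, _ = evolve_with_mask(
                    clade_ancestors[ci], config.within_clade_divergence, subseed(),
                    clade_masks[ci], config.indel_rate,
                )
                cls = str(rng.choice(classes, p=class_probs))
                left, right = _sample_flanks(rng, cls, config.flank_length_ranges, len(member))
                lflank = "".join(rng.choice(aa, size=left))
                rflank = "".join(rng.choice(aa, size=right))
                seq = lflank + member + rflank
                pid = f"{genome_id}_g{k}"
                proteins.append((pid, seq))
                truth_rows.append({
                    "protein_id": pid, "genome_id": genome_id, "group": group,
                    "clade_index": ci, "domain_start": left + 1,
                    "domain_end": left + len(member), "true_position_class": cls,
                })
            # composition-shuffled decoys: same residue makeup, no domain
            n_dec = int(config.decoys_per_genome)
            if rng.random() < config.decoys_per_genome - n_dec:
                n_dec += 1
            for k in range(n_dec):
                if proteins:
                    src = proteins[int(rng.integers(len(proteins)))][1]
                    dseq = "".join(rng.permutation(list(src)))
                else:
                    dseq = "".join(rng.choice(aa, size=400))
                pid = f"{genome_id}_d{k}"
                proteins.append((pid, dseq))
                truth_rows.append({
                    "protein_id": pid, "genome_id": genome_id, "group": group,
                    "clade_index": -1, "domain_start": -1, "domain_end": -1,
                    "true_position_class": "none",
                })
            proteomes[genome_id] = proteins

    references: dict[str, tuple[str, str]] = {}
    for ci in range(min(config.n_clades, len(REFERENCE_ANCHORS))):
        anchor = REFERENCE_ANCHORS[ci]
        seq, _ = evolve_with_mask(
            clade_ancestors[ci], config.within_clade_divergence / 2.0, subseed(),
            clade_masks[ci], 0.0,
        )
        references[anchor] = (f"ref_{anchor}", seq)
    og_seq, _ = evolve_with_mask(root, config.outgroup_divergence, subseed(), root_mask, 0.0)
    outgroup = ("outgroup", og_seq)

    return SurveyResult(
        config=config, template=template, root_domain=root, root_mask=root_mask,
        clade_ancestors=clade_ancestors, clade_ancestor_masks=clade_masks,
        clade_lineage=clade_lineage, lineage_ancestors=lineage_ancestors,
        proteomes=proteomes,
        manifest=pd.DataFrame(manifest_rows),
        truth=pd.DataFrame(truth_rows),
        references=references, outgroup=outgroup,
    )


def write_survey(result: SurveyResult, outdir: str | Path) -> dict[str, Path]:
    """Write per-genome FASTA, manifest TSV, truth TSV and references FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_dir = outdir / "proteomes"
    genome_dir.mkdir(exist_ok=True)
    for genome_id, proteins in result.proteomes.items():
        with open(genome_dir / f"{genome_id}.fasta", "w") as fh:
            for pid, seq in proteins:
                fh.write(f">{pid} {genome_id}\n{seq}\n")
    manifest_path = outdir / "manifest.tsv"
    result.manifest.to_csv(manifest_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    ref_path = outdir / "references.fasta"
    with open(ref_path, "w") as fh:
        for anchor, (rid, seq) in result.references.items():
            fh.write(f">{rid} anchor={anchor}\n{seq}\n")
        fh.write(f">{result.outgroup[0]} outgroup\n{result.outgroup[1]}\n")
    return {
        "proteomes": genome_dir, "manifest": manifest_path,
        "truth": truth_path, "references": ref_path,
    }
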