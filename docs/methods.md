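# Methods

This document describes the model implemented by `famsurvey`, the meaning
and defaults of its parameters, what the synthetic generator does and does
not emulate, and the numerical conventions chosen. Nothing here asserts an
empirical result that is not recomputed by the test suite or by
`scripts/acceptance.py`.

## 1. Synthetic family generator (`famsurvey.synthetic`)

### Domain template

The planted domain is three motifs joined by two unconserved stretches:

| segment | length | role |
|---|---|---|
| motif 1 | 33 columns | conserved block |
| linker | 60–90 columns (uniform) | free, unconserved, variable length |
| motif 2 | 44 columns | conserved block |
| spacer | 6–12 columns (uniform) | short free stretch |
| motif 3 | 36 columns | conserved block |

Motif residues are drawn uniformly from the 20 canonical amino acids,
deterministically from `template_seed` (default 0). The overall domain is
~200 residues, mirroring a typical conserved DNA-binding domain with one
long internal insertion-tolerant region.

### Evolution model

`evolve_with_mask(parent, rate, seed, mask, indel_rate)` substitutes each
position independently with probability `rate`, reduced to `rate/4` at
masked (motif) positions to emulate purifying selection on the motifs; the
replacement is uniform over the 19 alternative residues. Insertions and
deletions occur only at unmasked positions at `indel_rate` per site
(default 0.01, split evenly between insertion and deletion), so motif
columns never shift relative to one another except through linker-length
change — this keeps match-state recovery well-posed, which is what a
curated profile of a real family also assumes.

This is a per-edge Bernoulli model, not a continuous-time substitution
process: "divergence 0.3" means each site flips once with probability 0.3
on that edge, there is no rate heterogeneity beyond the motif/linker split,
no back-substitution bookkeeping, and no codon or chemistry-aware exchange
preferences. It emulates the *structure* of a domain family (conserved
blocks, free linker, clade hierarchy, decoys) rather than a realistic
substitution process.

### Survey structure

`generate_survey(SurveyConfig)` produces, deterministically from
`config.seed` (all derived seeds are drawn below 2^31):

- One root domain; optionally `n_root_lineages` lineage ancestors evolved
  from it at `lineage_divergence` (0.40) — this plants the two-clan
  structure. Clades map to lineages in contiguous blocks so anchored sister
  clades share ancestry.
- `n_clades` (4) clade ancestors at `between_clade_divergence` (0.30), each
  spawning members at `within_clade_divergence` (0.05). The 6× ratio
  comfortably exceeds the 4× separation needed for clean clade recovery.
- `n_groups` (5) × `genomes_per_group` (10) genomes; per genome a gene
  count drawn from `gene_count_distribution` ({3: 0.2, 4: 0.6, 5: 0.2},
  mean 4 → ~200 domain proteins), each gene assigned a clade without
  replacement where possible.
- Each domain is framed by random flanks sampled so the protein realizes a
  planted position class (N / middle / C, uniform by default), with
  rejection sampling against the midpoint rule.
- `decoys_per_genome` (0.4 in expectation, ~10% of proteins) decoys built
  by composition-shuffling a real protein of the same genome: same residue
  makeup, no domain — the hardest negative for a composition-sensitive
  scorer.
- Four reference sequences (VeA, VelB, VelC, VosA anchors), one per clade,
  evolved from the clade ancestors at half the within-clade rate; one
  outgroup evolved from the root at `outgroup_divergence` (0.70).
- A truth table with clade index, domain coordinates and position class per
  protein.

## 2. Profile and scan (`famsurvey.profile_scan`)

Match columns are seed-alignment columns with occupancy ≥ 0.5. Emission
scores are per-column log-odds in bits with pseudocount α = 1 and a uniform
background: `e(c,a) = log2(((n_ca + α·bg_a)/(N_c + α))/bg_a)`. With α = 0 an
unobserved residue receives a large finite sentinel (−10⁴) instead of −∞ so
arithmetic stays finite. Non-canonical letters (X, B, Z, …) score as the
column's background expectation and are logged, never fatal.

Scanning is Smith–Waterman over profile columns × residues with affine
gaps: the first site of a gap costs `gap_open` (−4 bits) and each further
site `gap_extend` (−0.5 bits); deletion and insertion runs may not be
adjacent. The insertion recurrence is evaluated in closed form with a
running maximum, making the fill O(L·n). Multiple hits per protein are
found greedily: best hit first, previously claimed spans masked, stopping
below 15 bits.

Reported coordinates are *envelope* coordinates: the aligned span extended
by one residue for each unaligned terminal profile column (clamped to the
sequence and to earlier hits). Without this, a clade-level substitution in
the last motif column would trim the reported end by several residues;
score, coverage and the match string always describe the alignment itself.
The completeness filter keeps hits with coverage ≥ 0.8 and score ≥ 15 bits;
on the synthetic survey, coverage is the active criterion (decoy chance
alignments reach tens of bits but only ~5% coverage).

Threshold defaults (0.5 occupancy, 0.8 coverage, 15 bits, −4/−0.5 gaps) are
declared conventions of this package, chosen a priori in the range used by
standard domain-annotation practice; they are not fitted to data.

## 3. Survey statistics (`famsurvey.survey`)

Per genome: number of family-positive genes, lengths of those proteins and
their domains, and position classes. The midpoint rule is strict:
`frac = ((start+end)/2)/protein_length`, `frac < 0.40` → N, `frac > 0.60` →
C, otherwise middle — exactly 0.40/0.60 classify as middle. Per group:
percentage of genomes with any gene (zero-hit genomes count in the
denominator), the per-genome count mode over positive genomes only (ties
resolved to the smaller count and flagged), the count histogram, mean
protein/domain lengths, and the N/middle/C percentages.

## 4. Phylogeny and clades (`famsurvey.clades`)

Match strings form an implicit alignment, so distances need no realignment:
p = mismatches / co-occupied columns, Poisson-corrected as −ln(1−p), capped
at 5.0 as p → 1. Pairs sharing fewer than 20 columns are flagged; zero
shared columns is an error naming the pair.

Neighbor-joining is the canonical Saitou–Nei algorithm:
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, minimal pair joined, ties broken
toward the smallest index pair for determinism; negative branch lengths are
clamped to zero with the deficit moved to the sister edge; the last three
nodes join at a trifurcation via the three-point formulas. Bootstrap
support resamples match columns with replacement and counts bipartition
recurrence (canonical side: the one not containing the alphabetically
first leaf).

Clade assignment roots on the outgroup, then gives each reference the
largest rooted subtree containing it and no other reference. Leaves in no
anchored clade form maximal reference-free subtrees with parent-edge
support ≥ 50, named Velvet1, Velvet2, … by decreasing size. Clade names
prefix the anchor with three-letter abbreviations of the taxonomic groups
spanned (`Pez-VosA`, `Sac-Tap-VelB`). The clade-consensus tree, midpoint
rooted, splits into the VelB and VosA clans; if both anchors land in one
root subtree the partition is refused rather than guessed.

## 5. Consensus and motifs (`famsurvey.consensus`)

Column frequencies exclude gaps (occupancy is reported separately);
information content is `log2(20) − H` bits. The small-sample correction
`e_n = 19/(2·ln2·n)` is available but off by default so closed-form tests
stay exact. The consensus residue is the modal residue (alphabetical on
ties), `x` below 0.5 occupancy.

Cross-clade analysis treats each clade's consensus as one row of a
"kingdom" logo. A column is a conserved site when every clade reaches 2.0
bits and 0.5 occupancy, and a dominant site when all clades also share the
modal residue. Motif segmentation instead uses a cross-clade *agreement*
mask — modal frequency × occupancy ≥ 0.6, i.e. the fraction of clade
consensuses showing the modal residue — because a fixed information-content
cutoff cannot separate conserved from free columns when the number of
clades is small (column entropy is bounded by log2 of the clade count).
Runs of agreeing columns merge across gaps of ≤ 3 columns; runs spanning
< 5 columns are dropped as isolated chance agreements (a motif is tens of
columns long; a lone agreeing column is a site, not a block).

**Why block recovery is measured at kingdom depth.** At the default survey
depth (between-clade divergence 0.30, 4 clades) each linker column keeps
the root residue in ~70% of clades, so the linker is *genuinely* still
conserved across clades and the three blocks merge — the pipeline warns
rather than errs. `motif_block_study` therefore measures segmentation in
the regime the three-block architecture describes: 20 clades at
between-divergence 0.8 with 4 gaplessly evolved members each. There the
per-column chance that a linker column passes the agreement threshold is
~1×10⁻⁴ (binomial: ≥ 12 of 20 clades keeping a residue each kept with
probability 0.2) while motif columns pass at ~0.99, giving a per-seed
failure probability of order 10⁻³. These parameters were fixed from that
error budget, not tuned on outcomes.

## 6. Statistics (`famsurvey.stats`)

Box summaries: quartiles by linear interpolation (numpy default, the
"type 7" rule), whiskers at the most extreme points within 1.5·IQR of the
box (Tukey), notches at median ± 1.58·IQR/√n, outliers listed sorted.
Two-group comparisons default to the pooled-variance Student t-test
(`welch=True` for Welch), flagged at p < 0.05 and p < 0.001; pairwise
tables include a Bonferroni-adjusted column for transparency while flags
use raw p values. Degenerate inputs follow declared conventions: equal
constant groups → t = 0, p = 1; zero variance with unequal means → t = ±∞,
p = 0, both flagged degenerate.

## 7. Numerical choices

- All randomness flows through `numpy.random.default_rng`; derived seeds
  are drawn below 2^31. Every pipeline product is deterministic given the
  config, and report files are byte-identical across reruns.
- −∞ log-odds are replaced by the −10⁴ sentinel; DP tracebacks compare with
  absolute tolerance 10⁻⁹.
- Distance matrices are symmetrized as (D + Dᵀ)/2 to remove float noise
  before neighbor-joining; NJ ties use `isclose` at absolute tolerance
  10⁻¹² and resolve to the lexicographically first pair.
- The Poisson correction caps at 5.0 substitutions/site rather than
  overflowing as p → 1.

## 8. Limitations

- The substitution process is Bernoulli-per-edge and uniform over
  alternatives: no Γ rate heterogeneity, no empirical exchange matrix, no
  site-specific profiles. Distances are therefore comparable within a
  simulation but are not calibrated evolutionary times.
- Indels are restricted to unmasked positions; real motifs tolerate some
  indels.
- The profile is a PSSM with affine gaps, not a full profile HMM: no
  per-state insert/delete probabilities, no local/glocal posterior
  decoding.
- Clade delimitation assumes the references are truly inside their clades
  and the outgroup is outside everything; violations degrade to singleton
  clades or errors rather than being repaired.
- Decoys are composition-shuffles; other negative classes (repeat
  proteins, partial-domain pseudogenes) are not modeled.
- At shallow cross-clade divergence the three motif blocks are not
  identifiable from conservation alone (see §5); this is a property of the
  data, not of the segmentation.
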