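# Methods

## Coordinate model

All coordinates are 1-based with closed intervals. Protospacer positions
run 1–20 with position 20 PAM-proximal and the PAM at positions 21–23; the
PAM is recorded for provenance but never used as a filter, because
near-PAMless editors (SpRY) are used interchangeably with NG-PAM editors
in this setting. Guide placement searches both strands and demands a
unique match; minus-strand placements report all coordinates in
protospacer orientation.

Windows are defined relative to the protospacer 3' end: a window with
centre offset `c` and size `s` covers protospacer positions
`[20 + c − floor((s−1)/2), 20 + c + ceil((s−1)/2)]`, so the default
quantification window (centre −10, size 15) is protospacer 3–17 and even
sizes extend one base 3' of the centre. This convention is a documented,
tested constant of this package: the upstream tool whose outputs it
mirrors does not restate its own convention, so we fix one rather than
assert equivalence.

The codon map ties amplicon positions to protein residue numbers through a
CDS anchor `(amplicon position, residue, frame offset)` and covers every
codon lying completely inside the amplicon; minus-strand CDS is handled by
complementation. This is what lets substitutions be named in receptor
coordinates (`K352E`) regardless of amplicon design.

## Allele quantification

Reads are assumed pre-merged and quality-trimmed (read QC is upstream of
this package). Filters, all logged with counts: minimum length (default:
the window span), at most 5% N, and a global alignment score of at least
0.6 of the perfect score (unalignable reads are dropped). Alignment is
global Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`; default scores are match +2, mismatch −1, gap open −8,
gap extend −1 (a gap of length k costs `open + (k−1)·extend`). The gap
penalty is deliberately stiff so substitution-only editing alleles are not
explained away by spurious indels. Ties take the first alignment in the
aligner's deterministic enumeration order.

A read's window allele is the bases aligned to the window, in protospacer
orientation. Any gap column inside the window classifies the read as
`INDEL`: since base editing is substitution-centric, indel reads are
reported as one class rather than genotyped, and they **stay in the
denominator** so allele frequencies are fractions of all kept reads.
Alleles below the `other` threshold (0.8% of total reads) pool into one
row. How window-overlapping indels should enter the allele table is not
externally specified; the conventions above are this package's own and are
exercised by tests.

## Substitution profiling

Window alleles are spliced back into the reference and every codon
overlapping the window is re-translated, so partially covered codons are
completed with reference bases (edits outside the window are unobservable
by construction). Substitutions are named `<refAA><residue><altAA>` and
joined with `+` in residue order. Purely synonymous alleles are reported
as `silent`, not merged into `WT`, which keeps dominant-genotype claims
conservative. Alleles with ambiguous bases route to `others`.

The 0.8% threshold is applied **after** merging alleles that translate to
the same genotype (merge-first), because the rule is defined on reads
rather than on distinct sequences; the opposite order is available as a
flag (`merge_first=False`) for sensitivity analysis.

## Editor model

An editor is a chemistry (ABE: A→G, CBE: C→T, defined on the protospacer
strand) plus an activity window, default protospacer 3–10 — a conventional
adenine-editor window, configurable per editor. Outcome enumeration walks
all 2^k subsets of the k editable bases (capped, default 16, as a guard
against degenerate windows), translates each genotype with the same
machinery as read profiling, and deduplicates by substitution set. An
independent test oracle mutates the full amplicon per subset and
re-translates globally.

The screening score is `log10((Σf / n_edited) + 1)` with `f` per-position
editing frequencies in percent and `n_edited` the number of positions with
frequency above a noise floor (default 0: any measured signal). It is 0
when nothing is edited, bounded by `log10(101)`, monotone in every
position's frequency and permutation-invariant. The log base is not
externally fixed; base 10 is the default and the base only rescales a
ranking, so the choice is immaterial to how the score is used.

## Off-target validation

Editing frequency per site is `100 × edited/total` where a read counts as
edited iff it carries at least one source→target conversion within
protospacer positions 4–10 (reads not covering the window are excluded
from numerator and denominator). Treated and control samples form a 2×2
edited/unedited table tested with Pearson's χ², 1 df, no continuity
correction (a Yates option exists for sensitivity analysis); a table with
a zero margin carries no signal and is assigned (χ²=0, p=1). P-values are
Benjamini–Hochberg adjusted across all sites of one treated-vs-control
comparison — not pooled across samples. A site validates iff FDR ≤ 0.05
and the treated-minus-control difference is ≥ 1 percentage point. The Δ
guard dominates the operating characteristics at deep coverage: in a null
simulation (58 sites, 0.1% background, depth 20,000, 500 replicates) no
replicate validates any site, while a single site with a true 2-point
increase validates in ≥ 95% of replicates (both re-measured by
`scripts/acceptance.py`).

## Epitope calling

From a variants × antibodies matrix of residual binding (% of wild type),
a residue is a candidate for antibody *m* iff binding ≤ 20% for *m* and
> 70% for at least one other antibody; the panel needs at least two
antibodies so the others can serve as folding/expression controls.
Residues low for all antibodies are excluded as global (structural or
expression) effects. Thresholds are inclusive (≤ 20, > 70) by default with
a strict (< 20) flag, since the two phrasings in circulation differ at the
boundary. Prioritisation removes cysteines (disulfide bridges) and
PTM/interface residues and flags candidates with surface accessibility
below 10% as likely indirect; the 10% cut-off is this package's choice of
a round bound above the classic ~4% exemplar of a buried false positive,
and is configurable.

## Chimerism

A marker is informative for a donor pair iff exactly one donor carries its
allele (direction recorded). The donor fraction is the unweighted mean of
per-marker donor-specific read proportions — matching the "average
proportion" definition used with commercial indel panels — with a
depth-weighted (pooled) alternative as an option; the per-marker standard
deviation is reported as a dispersion diagnostic. Host-species reads are
assumed excluded upstream; implausibly low marker depths (< 50 reads)
trigger a warning. On binomial simulations the estimator is unbiased
(|bias| < 0.005 at depth 10,000 across the fraction grid) and recovers a
90% mixture within ±0.03 from 10 markers at depth 1,000.

## Synthetic data

Generators are deterministic given a seed (single `numpy` Generator per
call, fixed iteration order; identical seeds give byte-identical files).
Reads are drawn multinomially from the genotype spectrum and copied from
the variant sequence with uniform per-base substitution errors (default
0.1%, typical of merged high-quality amplicon data); no indels by default
— the analysis surface is substitution-centric — with a 1-bp-deletion rate
knob to exercise the `INDEL` class. Off-target counts are binomial at
background (control) and background+Δ (treated). Binding matrices plant
each antibody's epitope residues at ≤ 10% residual binding and everything
else at ≥ 85%, with optional Gaussian noise. Marker counts are binomial at
the mixture fraction.

The demo amplicons derive from the CD45 D1–D2 extracellular construct
(UniProt P08575; the synthetic CDS is a reverse translation with fixed
codon choices, with the base-editable codons pinned to their genomic
codons: K352=AAG, N351=AAT, I283=ATA, H285=CAT, N286=AAT, E259=GAA). The
construct carries a short N-terminal linker, so receptor residue *r* maps
to string index *r − 218*; the numbering offset is a documented constant,
not an assertion about any external artifact. Default study conditions
baked into the examples: a four-genotype spectrum
(WT 45%, K352E 30%, K352G 20%, N351S+K352G 5%) at 10,000 reads — a
realistic day-5 editing outcome with a dominant intended edit and a minor
bystander — 58-site off-target panels at depth 20,000 with 0.1%
background, and 24-marker chimerism panels with 10 informative markers at
depth 1,000.

What the simulations do **not** model: paired-end merging artefacts,
quality-score structure, PCR duplicates and chimeras, context-dependent
editing efficiency, structural variation at off-target loci, and host-read
contamination in chimerism data. Passing the benchmarks therefore
demonstrates correctness of the quantification, translation and decision
machinery under the stated error model — not robustness to every failure
mode of real libraries, which is what the logged filters and dispersion
diagnostics are for.

## Numerical and degenerate-case choices

- Frequencies are exact ratios of integer counts; profile and allele-table
  invariants are checked to 1e−9.
- χ² with any zero margin → (0, 1); zero sequencing depth → `Uncallable`
  rather than 0%.
- BE score with no edited positions → 0 by definition.
- Window alleles containing N → `others` (untranslatable), never silently
  dropped.
- All enumeration and aggregation orders are fixed (sorted keys), so
  outputs are platform-independent for a given seed.

## Problem sizes

The test suite and acceptance script use the defaults above (10,000-read
recovery, 500-replicate operating characteristics at 58 sites × depth
20,000, 10,000 random 2×2 tables, 1,000 random alleles, 500 random
alignment pairs, 200-replicate bias grids) — sizes at which the binomial
tolerances quoted above are meaningful while a full run stays in the
minutes range on one CPU.
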