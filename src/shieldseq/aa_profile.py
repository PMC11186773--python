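"""Translate window alleles into named amino-acid substitution genotypes.

Each window allele is substituted back into the reference amplicon and
every codon overlapping the window is re-translated, so codons only
partially covered by the window are completed with reference bases (edits
cannot be observed outside the window by construction). Substitutions are
named ``<refAA><residue><altAA>`` (e.g. ``K352E``) and joined with ``+``
in residue order for multi-substitution genotypes. Alleles whose DNA
differs from the reference but whose protein does not are reported as
``silent`` rather than folded into ``WT``, so a dominant-genotype claim
is never inflated by synonymous edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import INDEL
from .allele_quant import OTHER, AlleleTable
from .errors import InvalidInputError, UntranslatableAlleleError
from .geometry import AmpliconRef, CodonMap, revcomp

WT = "WT"
SILENT = "silent"
OTHERS = "others"


def translate_allele(
    allele: str,
    amplicon: AmpliconRef,
    window: tuple[int, int],
    strand: str,
    codon_map: CodonMap,
) -> frozenset[str]:
    """Substitution set produced by one window allele.

    ``allele`` is the window sequence in protospacer orientation and must
    match the window span. Returns the (possibly empty) set of
    substitutions; an empty set with changed DNA means a silent allele.
    Raises :class:`UntranslatableAlleleError` on ambiguous bases.
    """
    lo, hi = window
    if len(allele) != hi - lo + 1:
        raise InvalidInputError(
            f"allele length {len(allele)} does not match window span {hi - lo + 1}"
        )
    if "N" in allele:
        raise UntranslatableAlleleError("allele contains N")

    amplicon_oriented = allele if strand == "+" else revcomp(allele)
    mutated = amplicon.sequence[: lo - 1] + amplicon_oriented + amplicon.sequence[hi:]

    residues = set()
    for pos in range(lo, hi + 1):
        if pos in codon_map.pos_to_residue:
            residues.add(codon_map.pos_to_residue[pos][0])

    subs = set()
    for r in sorted(residues):
        ref_aa = codon_map.amino_acid_from(amplicon.sequence, r)
        alt_aa = codon_map.amino_acid_from(mutated, r)
        if alt_aa != ref_aa:
            subs.add(f"{ref_aa}{r}{alt_aa}")
    return frozenset(subs)


def genotype_label(subs: frozenset[str], dna_changed: bool) -> str:
    """Canonical genotype string: ``WT``, ``silent`` or ``+``-joined subs."""
    if subs:
        return "+".join(sorted(subs, key=lambda s: int(s[1:-1])))
    return SILENT if dna_changed else WT


@dataclass
class SubstitutionProfile:
    """Genotype-level substitution spectrum for one sample.

    ``df`` columns: ``genotype``, ``frequency``, ``n_reads``.
    """

    df: pd.DataFrame
    sample: str = ""

    def __post_init__(self) -> None:
        if len(self.df) and abs(self.df["frequency"].sum() - 1.0) > 1e-9:
            raise InvalidInputError("profile frequencies must sum to 1")

    def frequency_of(self, genotype: str) -> float:
        rows = self.df.loc[self.df["genotype"] == genotype, "frequency"]
        return float(rows.iloc[0]) if len(rows) else 0.0

    def genotypes(self) -> list[str]:
        return list(self.df["genotype"])


def aggregate_profile(
    table: AlleleTable,
    amplicon: AmpliconRef,
    codon_map: CodonMap,
    other_threshold: float = 0.008,
    merge_first: bool = True,
    sample: str = "",
) -> SubstitutionProfile:
    """Collapse an allele table into a substitution profile.

    With ``merge_first`` (default) alleles translating to the same
    genotype are merged before the ``others`` threshold is applied, so a
    genotype backed by several sub-threshold alleles can still surface;
    with ``merge_first=False`` the threshold is applied to allele rows
    first. ``INDEL`` keeps its own row; untranslatable alleles and the
    allele-level ``other`` bucket are routed to ``others``.
    """
    if not 0 <= other_threshold < 1:
        raise InvalidInputError(f"other_threshold must be in [0, 1), got {other_threshold}")
    total = table.total_reads

    def label_for(allele: str) -> str:
        if allele == INDEL:
            return INDEL
        if allele == OTHER:
            return OTHERS
        try:
            subs = translate_allele(allele, amplicon, table.window, table.strand, codon_map)
        except UntranslatableAlleleError:
            return OTHERS
        return genotype_label(subs, dna_changed=(allele != table.reference_allele))

    rows = table.df
    if not merge_first:
        keep = (rows["frequency"] >= other_threshold) | (rows["allele"] == INDEL)
        pooled = int(rows.loc[~keep, "reads"].sum())
        rows = rows.loc[keep]

    counts: dict[str, int] = {}
    for _, row in rows.iterrows():
        g = label_for(row["allele"])
        counts[g] = counts.get(g, 0) + int(row["reads"])
    if not merge_first and pooled:
        counts[OTHERS] = counts.get(OTHERS, 0) + pooled

    if merge_first:
        final: dict[str, int] = {}
        for g, n in counts.items():
            if g not in (INDEL, OTHERS) and n / total < other_threshold:
                final[OTHERS] = final.get(OTHERS, 0) + n
            else:
                final[g] = final.get(g, 0) + n
        counts = final

    out = pd.DataFrame(
        [
            {"genotype": g, "frequency": n / total, "n_reads": n}
            for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ],
        columns=["genotype", "frequency", "n_reads"],
    )
    return SubstitutionProfile(df=out, sample=sample)


def write_profile(profile: SubstitutionProfile, path: str) -> None:
    """Write a substitution profile as TSV with a metadata header."""
    with open(path, "w") as fh:
        fh.write("# shieldseq substitution profile (genotype, frequency, n_reads)\n")
        if profile.sample:
            fh.write(f"# sample={profile.sample}\n")
        profile.df.to_csv(path_or_buf=fh, sep="\t", index=False)
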