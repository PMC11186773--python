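"""Coordinate model for amplicons, protospacers, windows and codons.

All coordinates are 1-based and intervals are closed, matching the
protospacer convention in which positions 1-20 are the spacer-matched
bases (position 20 PAM-proximal) and the PAM occupies positions 21-23.
Conversions to 0-based Python indices happen only inside this module.

A base editor's guide may sit on either strand of the amplicon, and the
coding sequence may, too; the :class:`CodonMap` keeps amino-acid residue
numbering consistent in both cases so that substitutions can be named
in protein coordinates (e.g. ``K352E``) regardless of sequencing
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

from .errors import (
    AmbiguousGuideError,
    FrameError,
    GuideNotFoundError,
    InvalidSequenceError,
    OutOfBoundsError,
)

DNA_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Codon -> amino acid (one-letter), stop codons mapped to ``*``.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

Strand = Literal["+", "-"]


def _check_dna(seq: str, *, name: str, alphabet: frozenset[str] = DNA_ALPHABET) -> None:
    if not seq:
        raise InvalidSequenceError(f"{name} is empty")
    bad = set(seq) - alphabet
    if bad:
        raise InvalidSequenceError(f"{name} contains invalid characters: {sorted(bad)}")


@dataclass(frozen=True)
class AmpliconRef:
    """A reference amplicon with an anchor tying it to protein numbering.

    ``cds_anchor`` is a triple ``(amplicon_position, protein_residue,
    frame_offset)``: the base at ``amplicon_position`` (1-based) is codon
    position ``frame_offset + 1`` of ``protein_residue``, reading in the
    direction of ``strand_of_cds``.
    """

    name: str
    sequence: str
    cds_anchor: tuple[int, int, int]
    strand_of_cds: Strand = "+"

    def __post_init__(self) -> None:
        _check_dna(self.sequence, name=f"amplicon {self.name!r}")
        pos, _residue, frame = self.cds_anchor
        if not 1 <= pos <= len(self.sequence):
            raise FrameError(
                f"cds_anchor position {pos} outside amplicon of length {len(self.sequence)}"
            )
        if frame not in (0, 1, 2):
            raise FrameError(f"frame_offset must be 0-2, got {frame}")
        if self.strand_of_cds not in ("+", "-"):
            raise InvalidSequenceError(f"strand_of_cds must be '+' or '-', got {self.strand_of_cds!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at a 1-based amplicon position."""
        if not 1 <= pos <= len(self.sequence):
            raise OutOfBoundsError(f"position {pos} outside amplicon {self.name!r}")
        return self.sequence[pos - 1]

    def slice(self, lo: int, hi: int) -> str:
        """Subsequence for the closed interval [lo, hi]."""
        if not (1 <= lo <= hi <= len(self.sequence)):
            raise OutOfBoundsError(f"[{lo}, {hi}] outside amplicon {self.name!r}")
        return self.sequence[lo - 1 : hi]


@dataclass(frozen=True)
class ProtospacerSpec:
    """Placement of a 20-nt protospacer on an amplicon.

    ``amplicon_start`` is the amplicon coordinate of protospacer position 1;
    on the minus strand protospacer coordinates run toward smaller amplicon
    coordinates. ``pam_seq`` holds the bases at protospacer positions 21-23
    (may be shorter when the PAM runs off the amplicon edge); it is recorded
    for provenance and never used as a filter, since near-PAMless editors
    (SpRY) are in routine use.
    """

    guide_seq: str
    amplicon_start: int
    strand: Strand
    pam_seq: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.guide_seq, name="guide")
        if len(self.guide_seq) != 20:
            raise InvalidSequenceError(f"guide must be 20 nt, got {len(self.guide_seq)}")

    def to_amplicon(self, proto_pos: int) -> int:
        """Map a protospacer coordinate (1-based) to an amplicon coordinate."""
        if self.strand == "+":
            return self.amplicon_start + (proto_pos - 1)
        return self.amplicon_start - (proto_pos - 1)

    def protospacer_base(self, amplicon: AmpliconRef, proto_pos: int) -> str:
        """Amplicon base at a protospacer position, in protospacer orientation."""
        base = amplicon.base(self.to_amplicon(proto_pos))
        return base if self.strand == "+" else _COMPLEMENT[base]


@dataclass(frozen=True)
class WindowSpec:
    """A window defined relative to the protospacer 3' end (position 20).

    ``center_offset`` is in nucleotides relative to position 20 (so -10
    places the centre at protospacer position 10); ``size`` is the window
    width in nucleotides. For even sizes the extra base goes 3' of the
    centre: the window covers ``[c - floor((size-1)/2), c + ceil((size-1)/2)]``
    in protospacer coordinates.
    """

    center_offset: int
    size: int
    kind: Literal["quantification", "editing", "offtarget-scoring"] = "quantification"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise InvalidSequenceError(f"window size must be >= 1, got {self.size}")

    def protospacer_interval(self) -> tuple[int, int]:
        """Closed interval in protospacer coordinates."""
        center = 20 + self.center_offset
        lo = center - (self.size - 1) // 2
        hi = center + self.size // 2
        return lo, hi


def locate_protospacer(amplicon: AmpliconRef, guide: str) -> ProtospacerSpec:
    """Place a 20-nt guide on the amplicon, on either strand.

    Raises :class:`GuideNotFoundError` when the guide matches nowhere and
    :class:`AmbiguousGuideError` when it matches more than once across the
    two strands combined.
    """
    _check_dna(guide, name="guide")
    if len(guide) != 20:
        raise InvalidSequenceError(f"guide must be 20 nt, got {len(guide)}")

    seq = amplicon.sequence
    hits: list[tuple[int, Strand]] = []  # (amplicon coord of proto position 1, strand)

    start = seq.find(guide)
    while start != -1:
        hits.append((start + 1, "+"))
        start = seq.find(guide, start + 1)

    rc = reverse_complement(guide)
    start = seq.find(rc)
    while start != -1:
        # rc occupies amplicon 0-based [start, start+19]; protospacer
        # position 1 sits at the 3' end of the match on the minus strand.
        hits.append((start + 20, "-"))
        start = seq.find(rc, start + 1)

    if not hits:
        raise GuideNotFoundError(f"guide {guide} not found in amplicon {amplicon.name!r}")
    if len(hits) > 1:
        raise AmbiguousGuideError(
            f"guide {guide} matches amplicon {amplicon.name!r} at {len(hits)} loci"
        )

    start1, strand = hits[0]
    pam_chars = []
    for p in (21, 22, 23):
        apos = start1 + (p - 1) if strand == "+" else start1 - (p - 1)
        if 1 <= apos <= len(seq):
            base = seq[apos - 1]
            pam_chars.append(base if strand == "+" else _COMPLEMENT[base])
        else:
            break
    return ProtospacerSpec(
        guide_seq=guide, amplicon_start=start1, strand=strand, pam_seq="".join(pam_chars)
    )


def resolve_window(
    spec: WindowSpec, proto: ProtospacerSpec, amplicon: AmpliconRef
) -> tuple[int, int]:
    """Resolve a protospacer-relative window to a closed amplicon interval.

    Returns ``(lo, hi)`` with ``lo <= hi`` in amplicon coordinates.
    Raises :class:`OutOfBoundsError` if any part falls off the amplicon.
    """
    p_lo, p_hi = spec.protospacer_interval()
    a, b = proto.to_amplicon(p_lo), proto.to_amplicon(p_hi)
    lo, hi = min(a, b), max(a, b)
    if lo < 1 or hi > len(amplicon):
        raise OutOfBoundsError(
            f"window [{lo}, {hi}] exceeds amplicon {amplicon.name!r} (length {len(amplicon)})"
        )
    return lo, hi


@dataclass(frozen=True)
class CodonMap:
    """Bijection between amplicon positions and (residue, codon position).

    Covers every codon that lies completely inside the amplicon in the
    frame implied by the CDS anchor. ``codon position`` is 1-3 in reading
    order of the CDS; on a minus-strand CDS codons are read toward smaller
    amplicon coordinates and bases are complemented.
    """

    strand: Strand
    pos_to_residue: dict[int, tuple[int, int]] = field(repr=False)
    residue_to_positions: dict[int, tuple[int, int, int]] = field(repr=False)

    def residues(self) -> list[int]:
        return sorted(self.residue_to_positions)

    def residue_at(self, amplicon_pos: int) -> tuple[int, int]:
        """(residue number, codon position 1-3) covering an amplicon position."""
        try:
            return self.pos_to_residue[amplicon_pos]
        except KeyError:
            raise OutOfBoundsError(f"amplicon position {amplicon_pos} not codon-mapped") from None

    def codon_positions(self, residue: int) -> tuple[int, int, int]:
        """Amplicon positions of a residue's codon, in CDS reading order."""
        try:
            return self.residue_to_positions[residue]
        except KeyError:
            raise OutOfBoundsError(f"residue {residue} not covered by the codon map") from None

    def codon_from(self, sequence: str, residue: int) -> str:
        """Extract a residue's codon from an amplicon-oriented sequence."""
        codon = "".join(sequence[p - 1] for p in self.codon_positions(residue))
        if self.strand == "-":
            codon = "".join(_COMPLEMENT[b] for b in codon)
        return codon

    def amino_acid_from(self, sequence: str, residue: int) -> str:
        """Translate a residue's codon from an amplicon-oriented sequence."""
        return CODON_TABLE[self.codon_from(sequence, residue)]


def build_codon_map(amplicon: AmpliconRef) -> CodonMap:
    """Derive the codon map from the amplicon's CDS anchor.

    Raises :class:`FrameError` when the anchor does not admit at least one
    complete codon within the amplicon.
    """
    anchor_pos, anchor_res, frame = amplicon.cds_anchor
    n = len(amplicon.sequence)
    pos_to_residue: dict[int, tuple[int, int]] = {}
    residue_to_positions: dict[int, tuple[int, int, int]] = {}

    if amplicon.strand_of_cds == "+":
        first_codon_start = anchor_pos - frame

        def codon_start(r: int) -> int:
            return first_codon_start + 3 * (r - anchor_res)

        step = 1
    else:
        first_codon_start = anchor_pos + frame

        def codon_start(r: int) -> int:
            return first_codon_start - 3 * (r - anchor_res)

        step = -1

    # Scan residue numbers whose codons fit entirely on the amplicon.
    # The residue range is bounded by the amplicon length.
    r_span = n // 3 + 2
    for r in range(anchor_res - r_span, anchor_res + r_span + 1):
        s = codon_start(r)
        triple = (s, s + step, s + 2 * step)
        if all(1 <= p <= n for p in triple):
            residue_to_positions[r] = triple
            for cp, p in enumerate(triple, start=1):
                pos_to_residue[p] = (r, cp)

    if not residue_to_positions:
        raise FrameError(
            f"no complete codon fits amplicon {amplicon.name!r} with anchor {amplicon.cds_anchor}"
        )
    return CodonMap(
        strand=amplicon.strand_of_cds,
        pos_to_residue=pos_to_residue,
        residue_to_positions=residue_to_positions,
    )


def revcomp(seq: str) -> str:
    """Reverse complement, tolerating N."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))
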