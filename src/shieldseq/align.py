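"""Global alignment of merged amplicon reads to the reference.

A thin, deterministic wrapper around Biopython's ``PairwiseAligner``
(Needleman-Wunsch with affine gap penalties). A gap of length ``k`` costs
``gap_open + (k - 1) * gap_extend``; end gaps are penalised like internal
ones (true global alignment). When several alignments are co-optimal the
first alignment in Biopython's deterministic enumeration order is used,
so identical inputs always produce identical window alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .errors import EmptyInputError
from .geometry import revcomp

#: Default affine scoring. Chosen so that a single gap (open -8) costs more
#: than several mismatches, which keeps substitution-only base-editing
#: alleles from being explained away by spurious indels.
DEFAULT_SCORING = {"match": 2.0, "mismatch": -1.0, "gap_open": -8.0, "gap_extend": -1.0}

INDEL = "INDEL"  # window-allele class for any read gapped inside the window


@dataclass(frozen=True)
class Alignment:
    """A global read-to-reference alignment as two gapped strings."""

    ref_aligned: str
    read_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.read_aligned):
            raise ValueError("gapped strings must have equal length")

    def columns_for_ref(self) -> list[int]:
        """Column index (0-based) of each reference base, in order."""
        return [i for i, c in enumerate(self.ref_aligned) if c != "-"]


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(read: str, ref: str, scoring: dict[str, float] | None = None) -> Alignment:
    """Optimal global alignment of ``read`` against ``ref``.

    Parameters
    ----------
    read, ref
        Plain DNA strings (read may contain N; N scores as a mismatch
        against every base).
    scoring
        Mapping with keys ``match``, ``mismatch``, ``gap_open``,
        ``gap_extend``; defaults to :data:`DEFAULT_SCORING`.
    """
    if not read or not ref:
        raise EmptyInputError("global_align requires non-empty read and reference")
    s = {**DEFAULT_SCORING, **(scoring or {})}
    aligner = _aligner(s["match"], s["mismatch"], s["gap_open"], s["gap_extend"])
    if read == ref:  # fast path: the dominant case in deep amplicon data
        return Alignment(ref_aligned=ref, read_aligned=read, score=s["match"] * len(ref))
    best = aligner.align(ref, read)[0]
    return Alignment(
        ref_aligned=str(best[0]),
        read_aligned=str(best[1]),
        score=float(best.score),
    )


def extract_window_allele(
    aln: Alignment, window: tuple[int, int], strand: str = "+"
) -> str:
    """Read bases aligned to the reference window, in protospacer orientation.

    ``window`` is a closed 1-based interval in reference (amplicon)
    coordinates. Any alignment gap inside the window - a read base deleted,
    or an insertion between window positions - classifies the read as
    :data:`INDEL` rather than a substitution allele.
    """
    lo, hi = window
    cols = aln.columns_for_ref()
    if not (1 <= lo <= hi <= len(cols)):
        raise EmptyInputError(f"window [{lo}, {hi}] outside aligned reference span")
    col_lo, col_hi = cols[lo - 1], cols[hi - 1]
    ref_block = aln.ref_aligned[col_lo : col_hi + 1]
    read_block = aln.read_aligned[col_lo : col_hi + 1]
    if "-" in ref_block or "-" in read_block:
        return INDEL
    return read_block if strand == "+" else revcomp(read_block)
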