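"""Base-editing outcome enumeration and the editor screening score.

An adenine base editor (ABE) deaminates A to (effectively) G on the
protospacer strand within a window of protospacer positions; a cytosine
base editor (CBE) converts C to T. Enumerating every subset of editable
bases in the window yields the complete catalogue of codon-level outcomes
- the intended substitution plus all bystander combinations - which is
how, e.g., a lysine codon AAG under ABE yields E (GAG), R (AGG) or
G (GGG).

The screening score ranks editor x guide conditions by
``log10(mean editing frequency over edited positions + 1)``; a condition
with no edited positions scores 0. Frequencies are percentages (0-100),
the scale on which Sanger/NGS editing quantification is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import pandas as pd

from .aa_profile import genotype_label, translate_allele
from .errors import InvalidInputError, TooManyOutcomesError
from .geometry import CODON_TABLE, AmpliconRef, CodonMap, ProtospacerSpec

#: chemistry -> (source base, target base) on the protospacer strand
CHEMISTRY = {"ABE": ("A", "G"), "CBE": ("C", "T")}

#: Conventional ABE activity window in protospacer coordinates.
DEFAULT_EDIT_WINDOW = (3, 10)


@dataclass(frozen=True)
class EditorSpec:
    """A base editor: chemistry plus activity window (protospacer coords)."""

    chemistry: str = "ABE"
    edit_window: tuple[int, int] = DEFAULT_EDIT_WINDOW

    def __post_init__(self) -> None:
        if self.chemistry not in CHEMISTRY:
            raise InvalidInputError(f"unknown chemistry {self.chemistry!r}; use ABE or CBE")
        lo, hi = self.edit_window
        if not 1 <= lo <= hi <= 20:
            raise InvalidInputError(f"edit window must lie within protospacer 1-20, got {self.edit_window}")

    @property
    def conversion(self) -> tuple[str, str]:
        return CHEMISTRY[self.chemistry]


@dataclass(frozen=True)
class EditOutcome:
    """One distinct substitution set with the genotypes that generate it."""

    genotype: str  # canonical label, e.g. "K352E" or "WT"
    substitutions: frozenset[str]
    window_alleles: tuple[str, ...]  # generating protospacer-window sequences
    min_edits: int  # fewest base conversions that yield this outcome


def editable_positions(
    amplicon: AmpliconRef, proto: ProtospacerSpec, editor: EditorSpec
) -> list[int]:
    """Protospacer positions in the edit window carrying the source base."""
    src, _ = editor.conversion
    lo, hi = editor.edit_window
    return [p for p in range(lo, hi + 1) if proto.protospacer_base(amplicon, p) == src]


def enumerate_edit_outcomes(
    amplicon: AmpliconRef,
    proto: ProtospacerSpec,
    editor: EditorSpec,
    codon_map: CodonMap,
    max_editable: int = 16,
) -> list[EditOutcome]:
    """All codon-level outcomes over subsets of editable window bases.

    Enumerates 2^k genotypes for the k editable positions, translates each
    via the same machinery as read profiling, and deduplicates by
    substitution set. Raises :class:`TooManyOutcomesError` when
    ``k > max_editable``.
    """
    positions = editable_positions(amplicon, proto, editor)
    k = len(positions)
    if k > max_editable:
        raise TooManyOutcomesError(f"{k} editable positions exceed cap {max_editable}")
    _, target = editor.conversion

    lo_p, hi_p = editor.edit_window
    # translate over the protospacer-window interval in amplicon coordinates
    a, b = proto.to_amplicon(lo_p), proto.to_amplicon(hi_p)
    window = (min(a, b), max(a, b))
    ref_window = "".join(proto.protospacer_base(amplicon, p) for p in range(lo_p, hi_p + 1))

    by_subs: dict[frozenset[str], list[tuple[int, str]]] = {}
    for n_edit in range(k + 1):
        for subset in combinations(positions, n_edit):
            chars = list(ref_window)
            for p in subset:
                chars[p - lo_p] = target
            allele = "".join(chars)
            subs = translate_allele(allele, amplicon, window, proto.strand, codon_map)
            by_subs.setdefault(subs, []).append((n_edit, allele))

    outcomes = []
    for subs, gens in by_subs.items():
        gens.sort()
        outcomes.append(
            EditOutcome(
                genotype=genotype_label(subs, dna_changed=gens[0][1] != ref_window),
                substitutions=subs,
                window_alleles=tuple(a for _, a in gens),
                min_edits=gens[0][0],
            )
        )
    outcomes.sort(key=lambda o: (o.min_edits, o.genotype))
    return outcomes


def enumerate_codon_outcomes(
    codon: str, residue: int, chemistry: str = "ABE"
) -> dict[str, tuple[str, ...]]:
    """Outcomes for a single codon in isolation (all positions editable).

    Returns ``{substitution or 'WT'/'silent': (codons,)}``; e.g. ``AAG``
    under ABE maps K->E (GAG), K->R (AGG) and K->G (GGG).
    """
    if chemistry not in CHEMISTRY:
        raise InvalidInputError(f"unknown chemistry {chemistry!r}")
    src, tgt = CHEMISTRY[chemistry]
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise InvalidInputError(f"invalid codon {codon!r}")
    ref_aa = CODON_TABLE[codon]
    positions = [i for i, b in enumerate(codon) if b == src]
    out: dict[str, list[str]] = {}
    for n in range(len(positions) + 1):
        for subset in combinations(positions, n):
            chars = list(codon)
            for i in subset:
                chars[i] = tgt
            mutant = "".join(chars)
            alt_aa = CODON_TABLE[mutant]
            if mutant == codon:
                label = "WT"
            elif alt_aa == ref_aa:
                label = "silent"
            else:
                label = f"{ref_aa}{residue}{alt_aa}"
            out.setdefault(label, []).append(mutant)
    return {k: tuple(sorted(set(v))) for k, v in out.items()}


def be_score(
    frequencies: Iterable[float], log_base: float = 10.0, min_frequency: float = 0.0
) -> float:
    """Editor screening score from per-position editing frequencies (percent).

    ``log_base((sum of frequencies / number of edited positions) + 1)``,
    where a position counts as edited when its measured frequency exceeds
    ``min_frequency`` (default: any nonzero signal). Defined as 0 when no
    position is edited. The log base only rescales the ranking; base 10 is
    the documented default.
    """
    freqs = [float(f) for f in frequencies]
    if any(f < 0 or f > 100 for f in freqs):
        raise InvalidInputError("editing frequencies must be percentages in [0, 100]")
    edited = [f for f in freqs if f > min_frequency]
    if not edited:
        return 0.0
    return math.log(sum(edited) / len(edited) + 1.0, log_base)


def score_conditions(
    table: pd.DataFrame, condition_col: str = "condition", frequency_col: str = "frequency"
) -> pd.DataFrame:
    """BE score per condition from a long-format per-position frequency table."""
    rows = [
        {"condition": cond, "be_score": be_score(grp[frequency_col])}
        for cond, grp in table.groupby(condition_col, sort=True)
    ]
    return pd.DataFrame(rows, columns=["condition", "be_score"])
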