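"""Window-restricted allele counting from merged amplicon reads.

Reads are globally aligned to the reference amplicon and reduced to the
allele they carry inside the quantification window (reported in
protospacer orientation). Alleles below the ``other`` threshold (default
0.8% of total reads) are pooled into a single ``other`` row; reads gapped
inside the window form their own ``INDEL`` class and stay in the
denominator, so reported frequencies are fractions of all kept reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .align import INDEL, Alignment, extract_window_allele, global_align
from .errors import EmptyInputError, InvalidInputError
from .geometry import READ_ALPHABET, AmpliconRef, ProtospacerSpec, revcomp

OTHER = "other"

#: Reads scoring below this fraction of a perfect self-alignment are
#: considered unalignable (wrong amplicon, chimeras) and dropped.
MIN_SCORE_FRACTION = 0.6


@dataclass(frozen=True)
class Read:
    """A merged, quality-trimmed amplicon read."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"read {self.id!r} has empty sequence")
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise InvalidInputError(f"read {self.id!r} contains {sorted(bad)}")


@dataclass
class FilterLog:
    """Read-count bookkeeping across filters, for end-to-end auditability."""

    n_input: int = 0
    n_too_short: int = 0
    n_too_many_n: int = 0
    n_unalignable: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_too_short": self.n_too_short,
            "n_too_many_n": self.n_too_many_n,
            "n_unalignable": self.n_unalignable,
            "n_kept": self.n_kept,
        }


@dataclass
class AlleleTable:
    """Allele spectrum inside one quantification window.

    ``df`` has columns ``allele`` (window DNA in protospacer orientation,
    or the ``INDEL``/``other`` class labels), ``reads``, ``frequency`` and
    ``is_indel``. Frequencies are fractions of ``total_reads``.
    """

    df: pd.DataFrame
    total_reads: int
    window: tuple[int, int]
    strand: str
    reference_allele: str
    filter_log: FilterLog = field(default_factory=FilterLog)

    def __post_init__(self) -> None:
        if self.total_reads > 0:
            if abs(self.df["frequency"].sum() - 1.0) > 1e-9:
                raise InvalidInputError("allele frequencies must sum to 1")
            if int(self.df["reads"].sum()) != self.total_reads:
                raise InvalidInputError("allele read counts must sum to total_reads")
        if self.df["allele"].duplicated().any():
            raise InvalidInputError("duplicate allele keys in table")

    def frequency_of(self, allele: str) -> float:
        rows = self.df.loc[self.df["allele"] == allele, "frequency"]
        return float(rows.iloc[0]) if len(rows) else 0.0


def _pool_other(counts: dict[str, int], total: int, threshold: float) -> pd.DataFrame:
    rows = []
    other_reads = 0
    for allele, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        freq = n / total
        if allele != INDEL and freq < threshold:
            other_reads += n
        else:
            rows.append({"allele": allele, "reads": n, "frequency": freq, "is_indel": allele == INDEL})
    if other_reads:
        rows.append(
            {"allele": OTHER, "reads": other_reads, "frequency": other_reads / total, "is_indel": False}
        )
    return pd.DataFrame(rows, columns=["allele", "reads", "frequency", "is_indel"])


def build_allele_table(
    reads: Iterable[Read],
    amplicon: AmpliconRef,
    proto: ProtospacerSpec,
    window: tuple[int, int],
    other_threshold: float = 0.008,
    scoring: dict[str, float] | None = None,
    min_length: int | None = None,
    max_n_fraction: float = 0.05,
    min_score_fraction: float = MIN_SCORE_FRACTION,
) -> AlleleTable:
    """Align reads and tabulate window alleles.

    ``window`` is the resolved quantification interval in amplicon
    coordinates (see :func:`shieldseq.geometry.resolve_window`).
    ``min_length`` defaults to the window span; shorter reads cannot cover
    the window and are dropped.
    """
    if not 0 <= other_threshold < 1:
        raise InvalidInputError(f"other_threshold must be in [0, 1), got {other_threshold}")
    lo, hi = window
    if min_length is None:
        min_length = hi - lo + 1
    match_score = (scoring or {}).get("match", 2.0)

    log = FilterLog()
    counts: dict[str, int] = {}
    for read in reads:
        log.n_input += 1
        if len(read.sequence) < min_length:
            log.n_too_short += 1
            continue
        if read.sequence.count("N") > max_n_fraction * len(read.sequence):
            log.n_too_many_n += 1
            continue
        aln = global_align(read.sequence, amplicon.sequence, scoring)
        if aln.score < min_score_fraction * match_score * len(read.sequence):
            log.n_unalignable += 1
            continue
        allele = extract_window_allele(aln, window, proto.strand)
        counts[allele] = counts.get(allele, 0) + 1
        log.n_kept += 1

    if log.n_input == 0:
        raise EmptyInputError("no reads supplied")
    if log.n_kept == 0:
        raise EmptyInputError("all reads removed by filters")

    df = _pool_other(counts, log.n_kept, other_threshold)
    ref_allele = amplicon.slice(lo, hi)
    if proto.strand == "-":
        ref_allele = revcomp(ref_allele)
    return AlleleTable(
        df=df,
        total_reads=log.n_kept,
        window=window,
        strand=proto.strand,
        reference_allele=ref_allele,
        filter_log=log,
    )


def import_crispresso_alleles(
    path: str,
    window: tuple[int, int],
    strand: str = "+",
    reference_allele: str | None = None,
) -> AlleleTable:
    """Import an allele-frequency table in the CRISPResso2 dialect.

    Expects a tab-separated file with gapped ``Aligned_Sequence`` and
    ``Reference_Sequence`` columns plus a read-count column (``#Reads`` or
    ``n_reads``). Window alleles are re-extracted from the stored pairwise
    alignment, so the import path shares the INDEL convention of the
    native one. No ``other`` pooling is applied on import.
    """
    # note: no comment='#' here -- the dialect's count column is '#Reads'
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().lstrip("#"): c for c in df.columns}
    try:
        seq_col = cols["aligned_sequence"]
        ref_col = cols["reference_sequence"]
    except KeyError as exc:
        raise InvalidInputError(f"missing CRISPResso-style column in {path}: {exc}") from None
    reads_col = cols.get("reads") or cols.get("n_reads")
    if reads_col is None:
        raise InvalidInputError(f"no read-count column (#Reads/n_reads) in {path}")

    counts: dict[str, int] = {}
    total = 0
    for _, row in df.iterrows():
        aln = Alignment(
            ref_aligned=str(row[ref_col]).upper(),
            read_aligned=str(row[seq_col]).upper(),
            score=0.0,
        )
        allele = extract_window_allele(aln, window, strand)
        n = int(row[reads_col])
        counts[allele] = counts.get(allele, 0) + n
        total += n
    if total == 0:
        raise EmptyInputError(f"no reads in {path}")
    table = _pool_other(counts, total, threshold=0.0)
    if reference_allele is None:
        ref_gapped = str(df[ref_col].iloc[0]).upper()
        aln0 = Alignment(ref_aligned=ref_gapped, read_aligned=ref_gapped, score=0.0)
        reference_allele = extract_window_allele(aln0, window, strand)
    return AlleleTable(
        df=table,
        total_reads=total,
        window=window,
        strand=strand,
        reference_allele=reference_allele,
    )


def write_allele_table(table: AlleleTable, path: str, sample: str = "") -> None:
    """Write an allele table as TSV with a self-describing metadata header."""
    lo, hi = table.window
    with open(path, "w") as fh:
        fh.write(f"# shieldseq allele table; window={lo}-{hi} (1-based closed, amplicon coords)\n")
        fh.write(f"# orientation=protospacer strand={table.strand} total_reads={table.total_reads}\n")
        if sample:
            fh.write(f"# sample={sample}\n")
        table.df.to_csv(path_or_buf=fh, sep="\t", index=False)


def read_fastq(path: str) -> list[Read]:
    """Read merged reads from a (possibly gzipped) FASTQ file."""
    import gzip

    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [
            Read(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fastq")
        ]
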