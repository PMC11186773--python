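"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study's sequencing
experiments so each stage can be exercised and benchmarked offline:

* merged amplicon reads drawn multinomially from a known allele spectrum
  (a dominant wild-type allele plus base-edited alleles) with uniform
  per-base substitution errors;
* paired treated/control off-target count tables with binomial sampling
  around a low background editing rate;
* alanine-scan binding matrices with a planted epitope per antibody;
* two-donor marker read mixtures at a known mixture fraction.

The demo amplicons derive from the CD45 D1-D2 extracellular construct
(UniProt P08575, residues ~225-394 plus short terminal tags) by reverse
translation with fixed codon choices; the codons at the residues targeted
by the base editor are pinned to the genomic codons (K352 = AAG,
N351 = AAT, I283 = ATA, H285 = CAT, N286 = AAT) so that the editable
adenines and the resulting substitutions match the biology. Everything is
deterministic given a seed: identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import gzip

import numpy as np
import pandas as pd

from .allele_quant import Read
from .editor_model import EditorSpec, enumerate_edit_outcomes
from .errors import InvalidSpecError
from .geometry import (
    AmpliconRef,
    CodonMap,
    ProtospacerSpec,
    build_codon_map,
    locate_protospacer,
    revcomp,
)

#: CD45 D1-D2 construct protein sequence (extracellular domains 1-2 with
#: short N-terminal linker and C-terminal His tag). Residue numbering of
#: the mature receptor maps to this string as index = residue - RESIDUE_OFFSET.
CD45_D1D2_PROTEIN = (
    "ETGIEGRKPTCDEKYANITVDYLYNKETKLFTAKLNVNENVECGNNTCTNNEVHNLTECKNASVSISHNSC"
    "TAPDKTLILDVPPGVEKFQLHDCTQVEKADTTICLKWKNIETFTCDTQNITYRFQCGNMIFDNKEIKLENL"
    "EPEHEYKCDSEILYNNHKFTNASKIIKTDFGSPGEGTKHHHHHH"
)

#: index(residue r) = r - RESIDUE_OFFSET in :data:`CD45_D1D2_PROTEIN`
#: (the 7-residue N-terminal linker precedes mature residue 225).
RESIDUE_OFFSET = 218

#: One codon per amino acid (common human codons); used for deterministic
#: reverse translation of synthetic CDS fixtures.
PREFERRED_CODONS = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "AGA", "S": "TCC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

#: Residue-specific codon pins reproducing the editable genomic codons.
CODON_OVERRIDES = {
    259: "GAA",  # E259; A at codon position 2 gives E->G under ABE
    283: "ATA",  # I283; A at position 3 gives I->M
    284: "TCC",  # S284; adenine-free so it cannot contribute bystanders
    285: "CAT",  # H285; A at position 2 gives H->R
    286: "AAT",  # N286; A at position 1 gives N->D
    351: "AAT",  # N351; positions 1/2 give N->D / N->S
    352: "AAG",  # K352; positions 1/2 give K->E / K->R (both: K->G)
}


def reverse_translate(protein: str, start_residue: int, overrides: dict[int, str] | None = None) -> str:
    """Deterministic CDS for a protein segment, honouring codon pins."""
    overrides = CODON_OVERRIDES if overrides is None else overrides
    codons = []
    for i, aa in enumerate(protein):
        residue = start_residue + i
        codons.append(overrides.get(residue, PREFERRED_CODONS[aa]))
    return "".join(codons)


# Demo regions: (key residue, protospacer start expressed as the codon
# whose first base is protospacer position 1). The placements put the
# editable adenines inside the conventional ABE window (protospacer 3-10):
#   K352 region: N351 codon at protospacer 3-5, K352 at 6-8
#   N286 region: I283 codon at protospacer 1-3, H285 at 7-9, N286 at 10-12
_DEMO_REGIONS = {
    "K352": {"anchor_residue": 351, "anchor_proto_pos": 3},
    "N286": {"anchor_residue": 283, "anchor_proto_pos": 1},
}


def demo_amplicon(region: str = "K352", flank_codons: int = 25) -> tuple[AmpliconRef, str]:
    """Synthetic amplicon around a demo edit site, plus its 20-nt guide.

    Returns ``(amplicon, guide_seq)``. The amplicon covers
    ``flank_codons`` codons on each side of the guide-anchored codon, with
    a CDS anchor so residue numbering matches the receptor.
    """
    if region not in _DEMO_REGIONS:
        raise InvalidSpecError(f"unknown demo region {region!r}; options: {sorted(_DEMO_REGIONS)}")
    cfg = _DEMO_REGIONS[region]
    anchor_res = cfg["anchor_residue"]
    first_res = anchor_res - flank_codons
    last_res = anchor_res + flank_codons
    lo_idx = first_res - RESIDUE_OFFSET
    hi_idx = last_res - RESIDUE_OFFSET + 1
    if lo_idx < 0 or hi_idx > len(CD45_D1D2_PROTEIN):
        raise InvalidSpecError(f"flank_codons={flank_codons} exceeds the construct for region {region!r}")
    protein = CD45_D1D2_PROTEIN[lo_idx:hi_idx]
    cds = reverse_translate(protein, start_residue=first_res)
    amplicon = AmpliconRef(
        name=f"demo_{region}",
        sequence=cds,
        cds_anchor=(1, first_res, 0),
        strand_of_cds="+",
    )
    # protospacer position 1 sits (anchor_proto_pos - 1) nt before the
    # anchored codon's first base
    anchor_codon_start = 3 * (anchor_res - first_res) + 1
    guide_start = anchor_codon_start - (cfg["anchor_proto_pos"] - 1)
    guide = amplicon.slice(guide_start, guide_start + 19)
    return amplicon, guide


def demo_geometry(region: str = "K352") -> tuple[AmpliconRef, ProtospacerSpec, CodonMap]:
    """Amplicon, located protospacer and codon map for a demo region."""
    amplicon, guide = demo_amplicon(region)
    proto = locate_protospacer(amplicon, guide)
    return amplicon, proto, build_codon_map(amplicon)


def variant_sequences(
    amplicon: AmpliconRef,
    proto: ProtospacerSpec,
    editor: EditorSpec,
    codon_map: CodonMap,
    genotypes: list[str],
) -> dict[str, str]:
    """Full amplicon sequence for each requested genotype label.

    Labels are canonical genotype strings (``WT``, ``K352E``,
    ``N351S+K352G`` ...) drawn from the editor's outcome catalogue; when
    several window alleles generate a genotype the one with fewest edits
    is used.
    """
    outcomes = {o.genotype: o for o in enumerate_edit_outcomes(amplicon, proto, editor, codon_map)}
    lo_p, hi_p = editor.edit_window
    a, b = proto.to_amplicon(lo_p), proto.to_amplicon(hi_p)
    lo, hi = min(a, b), max(a, b)

    out: dict[str, str] = {}
    for label in genotypes:
        if label == "WT":
            out[label] = amplicon.sequence
            continue
        if label not in outcomes:
            raise InvalidSpecError(f"genotype {label!r} is not an outcome of this editor/guide")
        allele = outcomes[label].window_alleles[0]
        oriented = allele if proto.strand == "+" else revcomp(allele)
        out[label] = amplicon.sequence[: lo - 1] + oriented + amplicon.sequence[hi:]
    return out


_BASES = np.array(list("ACGT"))


def simulate_amplicon_reads(
    variants: dict[str, tuple[str, float]],
    n_reads: int,
    error_rate: float = 0.001,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[list[Read], pd.DataFrame]:
    """Draw merged reads from an allele spectrum with sequencing errors.

    ``variants`` maps a genotype label to ``(full amplicon sequence,
    true frequency)``; frequencies must sum to 1. Each read is a full-
    length copy of its source allele with uniform per-base substitution
    errors at ``error_rate`` and, optionally, a single 1-bp deletion with
    probability ``indel_rate`` (to exercise the INDEL class). Returns the
    reads and a truth table (``read_id``, ``true_genotype``).
    """
    if n_reads < 1:
        raise InvalidSpecError("n_reads must be >= 1")
    labels = sorted(variants)
    freqs = np.array([variants[k][1] for k in labels], dtype=float)
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise InvalidSpecError("variant frequencies must be non-negative and sum to 1")
    if not (0 <= error_rate <= 1 and 0 <= indel_rate <= 1):
        raise InvalidSpecError("rates must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, freqs)

    reads: list[Read] = []
    truth_rows = []
    read_no = 0
    for label, count in zip(labels, counts):
        template = np.frombuffer(variants[label][0].encode(), dtype="S1")
        for _ in range(count):
            read_no += 1
            seq = template.copy()
            if error_rate > 0:
                err_pos = np.flatnonzero(rng.random(seq.size) < error_rate)
                for i in err_pos:
                    current = seq[i].decode()
                    choices = [b for b in "ACGT" if b != current]
                    seq[i] = choices[rng.integers(3)].encode()
            s = seq.tobytes().decode()
            if indel_rate > 0 and rng.random() < indel_rate:
                cut = int(rng.integers(len(s)))
                s = s[:cut] + s[cut + 1 :]
            rid = f"read{read_no:06d}"
            reads.append(Read(id=rid, sequence=s))
            truth_rows.append({"read_id": rid, "true_genotype": label})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "true_genotype"])
    return reads, truth


def write_fastq(reads: list[Read], path: str) -> None:
    """Write reads as FASTQ (constant Q40 qualities); gz-aware."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def simulate_offtarget_counts(
    n_sites: int = 58,
    depth: int = 20_000,
    background: float = 0.001,
    deltas: "list[float] | float" = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired treated/control edited-read counts for nominated sites.

    ``background`` is the control editing probability per read (fraction);
    ``deltas`` adds true editing (fraction) to the treated sample, either
    one value for all sites or one per site. Counts are binomial at the
    given depth. Defaults mirror a validation panel: tens of nominated
    sites at deep coverage with ~0.1% background.
    """
    if np.isscalar(deltas):
        deltas = [float(deltas)] * n_sites
    if len(deltas) != n_sites:
        raise InvalidSpecError(f"need {n_sites} deltas, got {len(deltas)}")
    if not 0 <= background <= 1 or any(not 0 <= background + d <= 1 for d in deltas):
        raise InvalidSpecError("editing probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i, delta in enumerate(deltas):
        rows.append(
            {
                "site_id": f"site{i + 1:03d}",
                "treated_edited": int(rng.binomial(depth, background + delta)),
                "treated_total": depth,
                "control_edited": int(rng.binomial(depth, background)),
                "control_total": depth,
                "true_delta": delta,
            }
        )
    return pd.DataFrame(rows)


def simulate_binding_matrix(
    residues: list[str],
    antibodies: list[str],
    epitopes: dict[str, list[str]],
    seed: int = 0,
    noise_sd: float = 0.0,
    low_range: tuple[float, float] = (0.0, 10.0),
    high_range: tuple[float, float] = (85.0, 110.0),
) -> pd.DataFrame:
    """Alanine-scan binding matrix with planted epitopes.

    Residues in ``epitopes[mab]`` get residual binding drawn from
    ``low_range`` for that antibody and ``high_range`` for the others;
    non-epitope residues are high everywhere. Gaussian noise with
    ``noise_sd`` is added and values clipped at 0.
    """
    unknown = {m for m in epitopes if m not in antibodies}
    if unknown:
        raise InvalidSpecError(f"epitope antibodies not in panel: {sorted(unknown)}")
    planted = {r for residues_ in epitopes.values() for r in residues_}
    if not planted <= set(residues):
        raise InvalidSpecError("planted epitope residues must be in the residue list")
    rng = np.random.default_rng(seed)
    values = np.empty((len(residues), len(antibodies)))
    for i, r in enumerate(residues):
        for j, m in enumerate(antibodies):
            if r in epitopes.get(m, []):
                values[i, j] = rng.uniform(*low_range)
            else:
                values[i, j] = rng.uniform(*high_range)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    return pd.DataFrame(np.clip(values, 0.0, None), index=pd.Index(residues, name="residue"), columns=antibodies)


def simulate_chimerism_reads(
    fraction: float, n_markers: int = 10, depth: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Marker read counts for a two-donor mixture at a known fraction.

    Each informative marker receives ``depth`` total reads of which the
    target-donor-specific count is binomial at ``fraction``.
    """
    if not 0 <= fraction <= 1:
        raise InvalidSpecError(f"fraction must lie in [0, 1], got {fraction}")
    if n_markers < 1 or depth < 1:
        raise InvalidSpecError("need >= 1 marker and depth >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "marker": [f"marker{i + 1:02d}" for i in range(n_markers)],
            "donor_specific_reads": rng.binomial(depth, fraction, size=n_markers).astype(int),
            "total_reads": depth,
        }
    )


def demo_marker_panel(n_markers: int = 24, n_informative: int = 10, seed: int = 0) -> pd.DataFrame:
    """A two-donor genotype panel with a known number of informative markers.

    Mirrors the shape of a commercial indel-marker chimerism panel:
    ``n_markers`` markers of which exactly ``n_informative`` discriminate
    the donor pair.
    """
    if not 0 <= n_informative <= n_markers:
        raise InvalidSpecError("n_informative must be <= n_markers")
    rng = np.random.default_rng(seed)
    informative_idx = set(rng.choice(n_markers, size=n_informative, replace=False).tolist())
    rows = []
    for i in range(n_markers):
        if i in informative_idx:
            a = int(rng.integers(2))
            b = 1 - a
        else:
            a = b = int(rng.integers(2))
        rows.append({"marker": f"marker{i + 1:02d}", "chromosome": f"chr{i % 16 + 1}", "donor_a": a, "donor_b": b})
    return pd.DataFrame(rows)
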