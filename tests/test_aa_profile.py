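"""Translation of window alleles into named substitution genotypes."""

import random

import pandas as pd
import pytest
from Bio.Seq import Seq

from shieldseq.aa_profile import (
    SILENT,
    WT,
    aggregate_profile,
    genotype_label,
    translate_allele,
)
from shieldseq.allele_quant import AlleleTable
from shieldseq.errors import UntranslatableAlleleError
from shieldseq.geometry import revcomp


def _window_ref(amplicon, window, strand="+"):
    s = amplicon.slice(*window)
    return s if strand == "+" else revcomp(s)


def _sub(allele, i, base):
    return allele[:i] + base + allele[i + 1 :]


class TestTranslateAllele:
    def test_k352e_from_single_a_to_g(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        # window covers protospacer 3-17; K352 codon AAG sits at proto 6-8,
        # i.e. window offsets 3-5; editing its first adenine gives GAG = E
        allele = _sub(ref, 3, "G")
        subs = translate_allele(allele, amplicon, k352_window, proto.strand, cmap)
        assert subs == frozenset({"K352E"})

    def test_double_substitution_names_both(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        # N351 AAT -> GAT (N351D) and K352 AAG -> GAG (K352E)
        allele = _sub(_sub(ref, 0, "G"), 3, "G")
        subs = translate_allele(allele, amplicon, k352_window, proto.strand, cmap)
        assert subs == frozenset({"N351D", "K352E"})

    def test_reference_allele_is_wild_type(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        assert translate_allele(ref, amplicon, k352_window, proto.strand, cmap) == frozenset()

    def test_synonymous_change_is_silent(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        # K352 codon AAG -> AAA still encodes lysine
        allele = _sub(ref, 5, "A")
        subs = translate_allele(allele, amplicon, k352_window, proto.strand, cmap)
        assert subs == frozenset()
        assert genotype_label(subs, dna_changed=True) == SILENT

    def test_ambiguous_base_raises(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        with pytest.raises(UntranslatableAlleleError):
            translate_allele(_sub(ref, 0, "N"), amplicon, k352_window, proto.strand, cmap)

    def test_agrees_with_full_amplicon_codon_walk(self, k352_site, k352_window):
        """Independent oracle: splice the allele into the amplicon, translate
        the whole CDS with Biopython and diff residue by residue."""
        amplicon, proto, cmap = k352_site
        lo, hi = k352_window
        ref = _window_ref(amplicon, k352_window)
        first_res = cmap.residues()[0]
        rng = random.Random(42)
        for _ in range(300):
            allele = "".join(rng.choice("ACGT") for _ in ref)
            subs = translate_allele(allele, amplicon, k352_window, proto.strand, cmap)
            mutated = amplicon.sequence[: lo - 1] + allele + amplicon.sequence[hi:]
            ref_prot = str(Seq(amplicon.sequence).translate())
            alt_prot = str(Seq(mutated).translate())
            expected = frozenset(
                f"{a}{first_res + i}{b}"
                for i, (a, b) in enumerate(zip(ref_prot, alt_prot))
                if a != b
            )
            assert subs == expected


class TestGenotypeLabel:
    def test_ordering_by_residue_number(self):
        assert genotype_label(frozenset({"K352G", "N351S"}), True) == "N351S+K352G"

    def test_wild_type_and_silent(self):
        assert genotype_label(frozenset(), False) == WT
        assert genotype_label(frozenset(), True) == SILENT


def _table(rows, window, reference_allele, strand="+"):
    df = pd.DataFrame(rows, columns=["allele", "reads", "frequency", "is_indel"])
    return AlleleTable(
        df=df,
        total_reads=int(df["reads"].sum()),
        window=window,
        strand=strand,
        reference_allele=reference_allele,
    )


class TestAggregateProfile:
    def test_pure_reference_gives_wt_only(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        table = _table([(ref, 100, 1.0, False)], k352_window, ref)
        profile = aggregate_profile(table, amplicon, cmap)
        assert profile.genotypes() == [WT]
        assert profile.frequency_of(WT) == pytest.approx(1.0)

    def test_merge_before_threshold(self, k352_site, k352_window):
        """Two alleles with the same substitution set merge into one row."""
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        k352e = _sub(ref, 3, "G")  # AAG -> GAG
        k352e_silent = _sub(k352e, 5, "A")  # GAG -> GAA, still E
        table = _table(
            [(ref, 50, 0.5, False), (k352e, 30, 0.3, False), (k352e_silent, 20, 0.2, False)],
            k352_window,
            ref,
        )
        profile = aggregate_profile(table, amplicon, cmap)
        assert profile.frequency_of("K352E") == pytest.approx(0.5)

    def test_sub_threshold_genotypes_pool_into_others(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        rare = _sub(ref, 0, "G")  # N351D at 0.5%
        table = _table(
            [(ref, 995, 0.995, False), (rare, 5, 0.005, False)], k352_window, ref
        )
        profile = aggregate_profile(table, amplicon, cmap)
        assert set(profile.genotypes()) == {WT, "others"}
        assert profile.frequency_of("others") == pytest.approx(0.005)

    def test_threshold_order_flag(self, k352_site, k352_window):
        """merge-first rescues a genotype split across sub-threshold alleles."""
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        k352e = _sub(ref, 3, "G")
        k352e_syn = _sub(k352e, 5, "A")
        rows = [(ref, 9900, 0.99, False), (k352e, 60, 0.006, False), (k352e_syn, 40, 0.004, False)]
        table = _table(rows, k352_window, ref)
        merged = aggregate_profile(table, amplicon, cmap, merge_first=True)
        split = aggregate_profile(table, amplicon, cmap, merge_first=False)
        assert merged.frequency_of("K352E") == pytest.approx(0.01)
        assert split.frequency_of("K352E") == 0.0
        assert split.frequency_of("others") == pytest.approx(0.01)

    def test_row_order_and_split_invariance(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        k352e = _sub(ref, 3, "G")
        base = _table([(ref, 70, 0.7, False), (k352e, 30, 0.3, False)], k352_window, ref)
        reordered = _table([(k352e, 30, 0.3, False), (ref, 70, 0.7, False)], k352_window, ref)
        p1 = aggregate_profile(base, amplicon, cmap)
        p2 = aggregate_profile(reordered, amplicon, cmap)
        assert sorted(zip(p1.df["genotype"], p1.df["frequency"])) == sorted(
            zip(p2.df["genotype"], p2.df["frequency"])
        )

    def test_profile_frequencies_sum_to_one(self, k352_site, k352_window):
        amplicon, proto, cmap = k352_site
        ref = _window_ref(amplicon, k352_window)
        from shieldseq.align import INDEL

        table = _table(
            [(ref, 80, 0.8, False), (INDEL, 15, 0.15, True), (_sub(ref, 3, "G"), 5, 0.05, False)],
            k352_window,
            ref,
        )
        profile = aggregate_profile(table, amplicon, cmap)
        assert profile.df["frequency"].sum() == pytest.approx(1.0)
        assert profile.frequency_of(INDEL) == pytest.approx(0.15)
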