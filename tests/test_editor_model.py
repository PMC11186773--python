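"""Codon-level outcome enumeration and the editor screening score."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shieldseq.editor_model import (
    EditorSpec,
    be_score,
    editable_positions,
    enumerate_codon_outcomes,
    enumerate_edit_outcomes,
    score_conditions,
)
from shieldseq.errors import InvalidInputError, TooManyOutcomesError
from shieldseq.geometry import AmpliconRef, build_codon_map, locate_protospacer
from Bio.Seq import Seq


class TestCodonOutcomes:
    def test_lysine_aag_under_abe(self):
        outcomes = enumerate_codon_outcomes("AAG", 352, "ABE")
        assert outcomes == {
            "WT": ("AAG",),
            "K352E": ("GAG",),
            "K352R": ("AGG",),
            "K352G": ("GGG",),
        }

    def test_lysine_aaa_under_abe(self):
        # AAA reaches the same substitutions via the /A codons, plus a
        # silent AAA->AAG edit at the wobble position
        outcomes = enumerate_codon_outcomes("AAA", 352, "ABE")
        assert set(outcomes) == {"WT", "silent", "K352E", "K352R", "K352G"}
        assert outcomes["K352E"] == ("GAA", "GAG")
        assert outcomes["K352G"] == ("GGA", "GGG")
        assert outcomes["K352R"] == ("AGA", "AGG")

    def test_codon_without_source_base(self):
        assert enumerate_codon_outcomes("CCC", 10, "ABE") == {"WT": ("CCC",)}

    def test_cbe_chemistry(self):
        # CCA under CBE: C->T conversions give P->S (TCA), P->L (CTA), P->F? (TTA=L)
        outcomes = enumerate_codon_outcomes("CCA", 5, "CBE")
        assert "P5S" in outcomes and "P5L" in outcomes


class TestEnumerateEditOutcomes:
    def test_k352_site_contains_paper_genotypes(self, k352_site, abe):
        amplicon, proto, cmap = k352_site
        outcomes = {o.genotype for o in enumerate_edit_outcomes(amplicon, proto, abe, cmap)}
        assert {"K352E", "K352R", "K352G", "N351S", "N351D", "N351S+K352G", "N351D+K352E"} <= outcomes

    def test_bystander_triple_present(self, n286_site, abe):
        amplicon, proto, cmap = n286_site
        outcomes = {o.genotype for o in enumerate_edit_outcomes(amplicon, proto, abe, cmap)}
        assert "I283M+H285R+N286D" in outcomes
        assert {"I283M", "H285R", "N286D", "H285R+N286D"} <= outcomes

    def test_total_genotype_count_is_two_to_the_k(self, k352_site, abe):
        amplicon, proto, cmap = k352_site
        k = len(editable_positions(amplicon, proto, abe))
        outcomes = enumerate_edit_outcomes(amplicon, proto, abe, cmap)
        assert sum(len(o.window_alleles) for o in outcomes) == 2**k

    def test_window_without_source_bases_gives_only_wt(self):
        # guide/window over a G/C/T-only stretch: nothing for ABE to edit
        seq = "GCGCTGCGGCCGTCGCTGGT" + "GGG" + "ACGTACGTAC"
        amp = AmpliconRef(name="gc", sequence=seq, cds_anchor=(1, 1, 0))
        proto = locate_protospacer(amp, seq[:20])
        cmap = build_codon_map(amp)
        outcomes = enumerate_edit_outcomes(amp, proto, EditorSpec("ABE"), cmap)
        assert [o.genotype for o in outcomes] == ["WT"]

    def test_editable_cap(self, k352_site, abe):
        amplicon, proto, cmap = k352_site
        with pytest.raises(TooManyOutcomesError):
            enumerate_edit_outcomes(amplicon, proto, abe, cmap, max_editable=1)

    def test_agrees_with_whole_amplicon_mutation_oracle(self, k352_site, abe):
        """Independent oracle: mutate the full amplicon per subset of
        editable positions and re-translate the CDS globally."""
        from itertools import combinations

        amplicon, proto, cmap = k352_site
        positions = editable_positions(amplicon, proto, abe)
        first_res = cmap.residues()[0]
        ref_prot = str(Seq(amplicon.sequence).translate())
        expected = set()
        for n in range(len(positions) + 1):
            for subset in combinations(positions, n):
                seq = list(amplicon.sequence)
                for p in subset:
                    seq[proto.to_amplicon(p) - 1] = "G"  # plus-strand site
                alt_prot = str(Seq("".join(seq)).translate())
                subs = frozenset(
                    f"{a}{first_res + i}{b}"
                    for i, (a, b) in enumerate(zip(ref_prot, alt_prot))
                    if a != b
                )
                expected.add(subs)
        got = {o.substitutions for o in enumerate_edit_outcomes(amplicon, proto, abe, cmap)}
        assert got == expected


class TestBeScore:
    def test_degenerate_all_zero(self):
        assert be_score([0.0, 0.0, 0.0]) == 0.0
        assert be_score([]) == 0.0

    def test_single_position(self):
        assert be_score([30.0]) == pytest.approx(math.log10(31.0))

    def test_two_positions(self):
        assert be_score([10.0, 20.0]) == pytest.approx(math.log10(16.0))

    def test_zero_positions_do_not_dilute(self):
        # unedited positions are excluded from the denominator
        assert be_score([10.0, 20.0, 0.0, 0.0]) == be_score([10.0, 20.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            be_score([120.0])
        with pytest.raises(InvalidInputError):
            be_score([-1.0])

    def test_alternative_log_base_preserves_ranking(self):
        a10, b10 = be_score([5.0, 40.0]), be_score([70.0, 80.0])
        a2, b2 = be_score([5.0, 40.0], log_base=2), be_score([70.0, 80.0], log_base=2)
        assert (a10 < b10) == (a2 < b2)

    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=8))
    @settings(max_examples=100)
    def test_bounded_and_permutation_invariant(self, freqs):
        s = be_score(freqs)
        assert 0.0 <= s <= math.log10(101.0)
        shuffled = list(reversed(freqs))
        assert be_score(shuffled) == pytest.approx(s)

    @given(
        st.lists(st.floats(min_value=0, max_value=90), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100)
    def test_monotone_in_any_single_frequency(self, freqs, idx, bump):
        idx = idx % len(freqs)
        bumped = list(freqs)
        bumped[idx] = min(100.0, bumped[idx] + bump)
        assert be_score(bumped) >= be_score(freqs) - 1e-12


def test_score_conditions_groups_by_condition():
    import pandas as pd

    table = pd.DataFrame(
        {
            "condition": ["e1", "e1", "e2", "e2"],
            "position": [5, 6, 5, 6],
            "frequency": [10.0, 20.0, 0.0, 0.0],
        }
    )
    scores = score_conditions(table)
    assert dict(zip(scores["condition"], scores["be_score"])) == pytest.approx(
        {"e1": math.log10(16.0), "e2": 0.0}
    )
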