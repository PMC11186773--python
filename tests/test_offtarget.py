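"""Off-target validation: windowed read classification, chi-square, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shieldseq.align import global_align
from shieldseq.errors import InvalidInputError, UncallableError
from shieldseq.offtarget import (
    analyze_sites,
    bh_fdr,
    chisq_2x2,
    classify_read_edited,
    editing_frequency,
)
from shieldseq.simulate import simulate_offtarget_counts


def closed_form_chi2(a, b, c, d):
    """Pearson chi-square for a 2x2 table: n(ad-bc)^2 / row/col products."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


class TestClassifyReadEdited:
    def _aligned(self, k352_site, read_seq):
        amplicon, proto, _ = k352_site
        return global_align(read_seq, amplicon.sequence), amplicon, proto

    def _edit_at_proto(self, k352_site, proto_pos, base="G"):
        amplicon, proto, _ = k352_site
        apos = proto.to_amplicon(proto_pos)
        return amplicon.sequence[: apos - 1] + base + amplicon.sequence[apos:]

    def test_conversion_inside_window_is_edited(self, k352_site):
        read = self._edit_at_proto(k352_site, 6)  # A->G at protospacer 6
        aln, amplicon, proto = self._aligned(k352_site, read)
        assert classify_read_edited(aln, amplicon, proto) is True

    def test_conversion_outside_window_not_edited(self, k352_site):
        amplicon, proto, _ = k352_site
        # protospacer position 3 carries an A at this site but lies
        # outside the 4-10 scoring window
        assert proto.protospacer_base(amplicon, 3) == "A"
        read = self._edit_at_proto(k352_site, 3)
        aln, amplicon, proto = self._aligned(k352_site, read)
        assert classify_read_edited(aln, amplicon, proto) is False

    def test_non_target_mismatch_not_edited(self, k352_site):
        read = self._edit_at_proto(k352_site, 6, base="C")  # A->C, wrong chemistry
        aln, amplicon, proto = self._aligned(k352_site, read)
        assert classify_read_edited(aln, amplicon, proto) is False

    def test_gapped_window_uncallable(self, k352_site):
        amplicon, proto, _ = k352_site
        apos = proto.to_amplicon(6)
        read = amplicon.sequence[: apos - 1] + amplicon.sequence[apos:]
        aln = global_align(read, amplicon.sequence)
        with pytest.raises(UncallableError):
            classify_read_edited(aln, amplicon, proto)


class TestEditingFrequency:
    @pytest.mark.parametrize("edited,total,expected", [(0, 1000, 0.0), (30, 1000, 3.0), (1000, 1000, 100.0)])
    def test_percent_scale(self, edited, total, expected):
        assert editing_frequency(edited, total) == expected

    def test_zero_depth_uncallable(self):
        with pytest.raises(UncallableError):
            editing_frequency(0, 0)


class TestChisq2x2:
    def test_worked_example(self):
        chi2, p = chisq_2x2((30, 970), (5, 995))
        assert chi2 == pytest.approx(closed_form_chi2(30, 970, 5, 995), rel=1e-12)
        assert chi2 == pytest.approx(18.17, abs=0.01)
        assert p == pytest.approx(stats.chi2.sf(chi2, df=1), rel=1e-12)
        assert p == pytest.approx(2.0e-5, abs=0.5e-5)

    def test_equal_proportions_null(self):
        chi2, p = chisq_2x2((10, 990), (10, 990))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert chisq_2x2((0, 1000), (0, 1000)) == (0.0, 1.0)
        assert chisq_2x2((1000, 0), (1000, 0)) == (0.0, 1.0)

    def test_sample_swap_symmetry(self):
        assert chisq_2x2((30, 970), (5, 995)) == chisq_2x2((5, 995), (30, 970))

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(2000):
            a, b, c, d = rng.integers(0, 5000, size=4)
            if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            chi2, _ = chisq_2x2((int(a), int(b)), (int(c), int(d)))
            assert chi2 == pytest.approx(closed_form_chi2(a, b, c, d), abs=1e-9, rel=1e-9)

    def test_yates_correction_is_more_conservative(self):
        _, p_plain = chisq_2x2((12, 988), (4, 996))
        _, p_yates = chisq_2x2((12, 988), (4, 996), yates=True)
        assert p_yates > p_plain


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_checked_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100)
    def test_monotone_along_sorted_p_and_dominates_p(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        sorted_q = np.asarray(q)[order]
        assert np.all(np.diff(sorted_q) >= -1e-12)
        assert np.all(np.asarray(q) + 1e-12 >= np.asarray(pvals))
        assert np.all(np.asarray(q) <= 1.0 + 1e-12)

    def test_constant_vectors_are_fixed_points(self):
        # the step-up map leaves an all-equal vector unchanged
        # (min over j >= i of m*c/j is attained at j = m)
        for c in (0.0, 0.2, 1.0):
            q = [c] * 6
            assert bh_fdr(q) == pytest.approx(q)


class TestValidateSites:
    @pytest.mark.parametrize(
        "treated,control,expect",
        [
            ((300, 10_000), (5, 10_000), True),   # fdr tiny, delta ~3 points
            ((60, 10_000), (10, 10_000), False),  # significant but delta 0.5
            ((110, 10_000), (100, 10_000), False),  # delta small, p large
        ],
    )
    def test_dual_criterion(self, treated, control, expect):
        df = pd.DataFrame(
            [
                {
                    "site_id": "s1",
                    "treated_edited": treated[0],
                    "treated_total": treated[1],
                    "control_edited": control[0],
                    "control_total": control[1],
                }
            ]
        )
        verdict = analyze_sites(df).iloc[0]
        assert bool(verdict["validated"]) is expect

    def test_fdr_within_comparison(self):
        counts = simulate_offtarget_counts(n_sites=20, depth=10_000, background=0.001, seed=1)
        verdicts = analyze_sites(counts)
        assert list(verdicts["fdr"]) == pytest.approx(list(bh_fdr(verdicts["p"])))
        assert len(verdicts) == 20

    def test_on_target_like_site_validated(self):
        deltas = [0.0] * 9 + [0.5]
        counts = simulate_offtarget_counts(n_sites=10, depth=10_000, background=0.001, deltas=deltas, seed=2)
        verdicts = analyze_sites(counts)
        assert bool(verdicts.iloc[9]["validated"]) is True
        assert verdicts["validated"].sum() == 1
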