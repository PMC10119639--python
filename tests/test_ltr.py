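import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genomedyn import ltr_dynamics as ltr, synthetic_data as syn
from genomedyn._align import needleman_wunsch
from genomedyn.errors import EstimationError, SaturationError
from genomedyn.io_formats import LtrElementRow

from _oracles import best_alignment_score

RNG = np.random.default_rng(20260928)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        s = random_seq(100)
        a5, a3 = ltr.align_ltr_pair(s, s)
        assert a5 == a3 == s

    def test_single_substitution(self):
        s = random_seq(100)
        mutated = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        a5, a3 = ltr.align_ltr_pair(s, mutated)
        assert "-" not in a5 and "-" not in a3
        mismatches = sum(1 for x, y in zip(a5, a3) if x != y)
        assert mismatches == 1

    def test_internal_deletion_gap_columns(self):
        s = random_seq(100)
        deleted = s[:40] + s[43:]
        a5, a3 = ltr.align_ltr_pair(s, deleted)
        assert len(a5) == 100
        gap_cols = sum(1 for x, y in zip(a5, a3) if x == "-" or y == "-")
        matched = sum(1 for x, y in zip(a5, a3) if x == y and x != "-")
        assert gap_cols == 3
        assert matched == 97

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_score_matches_exhaustive_oracle_on_short_strings(self, data):
        bases = st.sampled_from("ACGT")
        a = "".join(data.draw(st.lists(bases, min_size=1, max_size=7)))
        b = "".join(data.draw(st.lists(bases, min_size=1, max_size=7)))
        _, _, score = needleman_wunsch(a, b)
        assert score == pytest.approx(best_alignment_score(a, b))

    def test_score_matches_biopython_on_medium_strings(self):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=60))
            b = list(a)
            for pos in rng.choice(60, size=6, replace=False):
                b[pos] = "ACGT"[rng.integers(4)]
            b = "".join(b)[:55]  # also trim to force terminal gaps
            _, _, score = needleman_wunsch(a, b)
            assert score == pytest.approx(aligner.score(a, b))


class TestDivergence:
    def test_zero_distance_zero_time(self):
        s = random_seq(200)
        d = ltr.ltr_divergence((s, s), r=1.33e-9)
        assert d.p_distance == 0 and d.K == 0 and d.T == 0

    def test_jc_formula_worked_example(self):
        # p = 0.05 -> K = -(3/4) ln(1 - 4*0.05/3); T = K / (2 * 1.33e-9)
        aln = ("A" * 95 + "C" * 5, "A" * 95 + "G" * 5)
        d = ltr.ltr_divergence(aln, r=1.33e-9)
        assert d.p_distance == pytest.approx(0.05)
        assert d.K == pytest.approx(0.051744, abs=1e-6)
        assert d.T == pytest.approx(1.9453e7, rel=1e-4)

    def test_t_equals_k_over_2r(self):
        # K = 2.66e-3 at r = 1.33e-9 -> exactly 1 My (T = K / 2r arithmetic)
        n, mism = 100_000, 266  # p = 2.66e-3 exactly
        aln = ("A" * n, "A" * (n - mism) + "C" * mism)
        d = ltr.ltr_divergence(aln, r=1.33e-9, correction="raw")
        assert d.K == pytest.approx(2.66e-3)
        assert d.T == pytest.approx(1e6)

    def test_gap_and_n_columns_excluded(self):
        aln = ("ACGT-NAC", "ACCTGNAC")
        d = ltr.ltr_divergence(aln)
        assert d.aligned_sites == 6
        assert d.mismatches == 1

    def test_saturation_raises(self):
        aln = ("A" * 100, "C" * 80 + "A" * 20)
        with pytest.raises(SaturationError):
            ltr.ltr_divergence(aln)

    def test_raw_correction_reports_p(self):
        aln = ("A" * 90 + "C" * 10, "A" * 100)
        d = ltr.ltr_divergence(aln, correction="raw")
        assert d.K == pytest.approx(0.10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=74))
    def test_k_monotone_in_p_and_k_geq_p(self, mismatches):
        aln = ("A" * 100, "C" * mismatches + "A" * (100 - mismatches))
        d = ltr.ltr_divergence(aln)
        assert d.K >= d.p_distance
        if mismatches:
            smaller = ltr.ltr_divergence(
                ("A" * 100, "C" * (mismatches - 1) + "A" * (101 - mismatches))
            )
            assert d.K > smaller.K


class TestSoloClassification:
    def element(self, eid, start, end):
        third = max((end - start) // 3, 1)
        return LtrElementRow(
            element_id=eid, chrom="chr1", element_start=start, element_end=end,
            ltr5_start=start, ltr5_end=start + third,
            ltr3_start=end - third, ltr3_end=end,
        )

    def test_candidate_inside_element_not_solo(self):
        full = [self.element("e1", 1000, 2000)]
        cands = [("chr1", 1200, 1400), ("chr1", 5000, 5200), ("chr1", 100, 300)]
        solo, paired = ltr.classify_solo_ltrs(cands, full)
        assert len(solo) == 2
        assert paired == 1

    def test_empty_element_list_all_solo(self):
        cands = [("chr1", 0, 100), ("chr2", 50, 80)]
        solo, paired = ltr.classify_solo_ltrs(cands, [])
        assert solo == cands and paired == 0

    def test_classification_invariant_to_candidate_order(self):
        full = [self.element("e1", 1000, 2000), self.element("e2", 5000, 6000)]
        cands = [("chr1", 1500, 1700), ("chr1", 3000, 3200),
                 ("chr1", 5500, 5600), ("chr1", 8000, 8100)]
        solo_fwd, _ = ltr.classify_solo_ltrs(cands, full)
        solo_rev, _ = ltr.classify_solo_ltrs(cands[::-1], full)
        assert set(solo_fwd) == set(solo_rev)
        assert ltr.solo_paired_ratio(len(solo_fwd), 2) == ltr.solo_paired_ratio(
            len(solo_rev), 2
        )

    def test_abutting_candidate_is_solo(self):
        # half-open intervals: touching at the boundary is not an overlap
        full = [self.element("e1", 1000, 2000)]
        solo, _ = ltr.classify_solo_ltrs([("chr1", 2000, 2300)], full)
        assert len(solo) == 1
        solo, _ = ltr.classify_solo_ltrs([("chr1", 1999, 2300)], full)
        assert len(solo) == 0


class TestRatiosAndMasses:
    @pytest.mark.parametrize(
        "n_solo, n_paired, expected",
        [(28714, 18445, 1.56), (12766, 9889, 1.29), (100, 100, 1.00)],
    )
    def test_solo_paired_ratio(self, n_solo, n_paired, expected):
        assert ltr.solo_paired_ratio(n_solo, n_paired) == expected

    def test_zero_paired_undefined(self):
        with pytest.raises(EstimationError):
            ltr.solo_paired_ratio(10, 0)

    def test_superfamily_fold_and_percent(self):
        masses, fold = ltr.superfamily_masses(
            {"Gypsy": 1672.59e6, "Copia": 287.66e6}, 3028e6
        )
        assert fold == 5.81
        by_sf = {m.superfamily: m for m in masses}
        assert by_sf["Copia"].fraction_of_genome == 9.50
        assert by_sf["Gypsy"].fraction_of_genome == 55.24  # 1672.59/3028
        _, fold_eq = ltr.superfamily_masses({"Gypsy": 5.0, "Copia": 5.0}, 100.0)
        assert fold_eq == 1.00

    def test_zero_copia_fold_undefined(self):
        _, fold = ltr.superfamily_masses({"Gypsy": 10.0}, 100.0)
        assert fold is None


class TestRateCurve:
    def test_direct_bin_counting(self):
        times = [0.05e6, 0.15e6, 0.15e6, 1.05e6]
        curve = ltr.transposition_rate_curve(times)
        assert curve.counts[0] == 1
        assert curve.counts[1] == 2
        assert curve.counts[10] == 1
        assert curve.counts.sum() == 4
        assert curve.n_excluded == 0

    def test_empty_input_all_zero(self):
        curve = ltr.transposition_rate_curve([])
        assert curve.counts.sum() == 0
        assert len(curve.counts) == 100

    def test_accumulation_non_decreasing_and_conserved(self):
        times = np.random.default_rng(3).uniform(0, 15e6, size=200)
        curve = ltr.transposition_rate_curve(times)
        assert np.all(np.diff(curve.accumulation) >= 0)
        assert curve.counts.sum() + curve.n_excluded == 200

    def test_uniform_simulated_ages_fill_bins_uniformly(self):
        _, rows, _, truth = syn.simulate_ltr_landscape(
            genome_length=2_000_000, n_elements=500, ltr_length=100,
            internal_length=50,
            time_sampler=lambda g, n: g.uniform(0, 2e6, size=n), seed=9,
        )
        times = [t.true_insertion_time for t in truth]
        curve = ltr.transposition_rate_curve(times)
        occupied = curve.counts[:20]
        expected = 500 / 20
        assert np.all(np.abs(occupied - expected) < 3 * math.sqrt(expected))
        assert curve.counts[20:].sum() == 0


class TestDateElements:
    def test_small_landscape_recovery(self):
        genome, rows, _, truth = syn.simulate_ltr_landscape(
            genome_length=1_500_000, n_elements=50, ltr_length=2000,
            internal_length=500,
            time_sampler=lambda g, n: g.uniform(1e6, 3e6, size=n), seed=21,
        )
        dated, undatable = ltr.date_elements([genome], rows)
        assert not undatable
        tmap = {t.element_id: t.true_insertion_time for t in truth}
        est = np.array([d.T for d in dated])
        true = np.array([tmap[d.element_id] for d in dated])
        assert abs(est.mean() - true.mean()) / true.mean() < 0.05
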