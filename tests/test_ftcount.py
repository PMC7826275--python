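import numpy as np
import pytest

import tandemcount as tc
from tandemcount.ftcount import _orientation_votes


class TestLiteralMatrix:
    def test_no_matching_nucleotide(self):
        assert tc.literal_matrix_profile("AAAA", "CC", 1).c.tolist() == [0, 0, 0, 0]

    def test_single_full_phase_run(self):
        # only the phase-0 column matches, as one run of 4
        assert tc.literal_matrix_profile("ACGT", "ACGT", 4).c.tolist() == [4, 4, 4, 4]

    def test_dinucleotide_regression_vector(self):
        # frozen output of the explicit M/M2/M3/M4 construction:
        # every even column matches all 8 rows (run value 8, 4 such columns)
        assert tc.literal_matrix_profile("ATATATAT", "AT", 2).c.tolist() == [32] * 8

    def test_threshold_zeroes_short_runs(self):
        c_low = tc.literal_matrix_profile("ACGT", "ACGT", 5).c
        assert c_low.tolist() == [0, 0, 0, 0]

    def test_oversize_input_directs_to_fast_path(self, rng):
        seq = tc.random_dna(2001, rng)
        with pytest.raises(ValueError, match="match_run_profile"):
            tc.literal_matrix_profile(seq, "ACGT", 3)

    def test_ambiguous_read_bases_never_match(self):
        c = tc.literal_matrix_profile("ANAN", "AA", 1).c
        assert c.tolist() == [4, 0, 4, 0]


class TestMatchRunProfile:
    def test_equals_oracle_on_tandem_array(self, rng):
        unit = tc.random_dna(100, rng)
        seq1 = unit * 10
        a = tc.literal_matrix_profile(seq1, unit, 20).c
        b = tc.match_run_profile(seq1, unit, 20).c
        assert (a == b).all()
        assert (b > 0).all()  # strictly positive across the array body

    def test_unit_longer_than_read(self, rng):
        seq1 = tc.random_dna(50, rng)
        seq2 = seq1 + tc.random_dna(100, rng)
        a = tc.literal_matrix_profile(seq1, seq2, 10).c
        b = tc.match_run_profile(seq1, seq2, 10).c
        assert (a == b).all()

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            tc.match_run_profile("ACGT", "", 1)

    def test_unit_with_ambiguity_rejected(self):
        with pytest.raises(ValueError, match="A/C/G/T"):
            tc.match_run_profile("ACGT", "ACNT", 1)


class TestSmoothing:
    def test_constant_vector_unchanged(self):
        prof = tc.MatchRunProfile(np.full(50, 5), 50, 10, 1)
        assert np.allclose(tc.smooth_profile(prof, 3).v_ave, 5.0)

    def test_interior_impulse_spreads_to_window(self):
        c = np.zeros(21, dtype=int)
        c[10] = 1
        prof = tc.MatchRunProfile(c, 21, 5, 1)
        v = tc.smooth_profile(prof, 2).v_ave
        assert np.allclose(v[8:13], 0.2)
        assert np.allclose(v[:8], 0.0) and np.allclose(v[13:], 0.0)

    def test_edges_copy_through(self):
        c = np.arange(11)
        prof = tc.MatchRunProfile(c, 11, 3, 1)
        v = tc.smooth_profile(prof, 2).v_ave
        assert (v[:2] == c[:2]).all() and (v[-2:] == c[-2:]).all()

    def test_matches_naive_windowed_mean(self, rng):
        c = rng.integers(0, 100, size=200)
        L = 7
        v = tc.smooth_profile(tc.MatchRunProfile(c, 200, 10, 1), L).v_ave
        for i in range(L, 200 - L):
            assert np.isclose(v[i], c[i - L : i + L + 1].mean())

    def test_window_larger_than_profile_rejected(self):
        prof = tc.MatchRunProfile(np.ones(5, dtype=int), 5, 2, 1)
        with pytest.raises(ValueError):
            tc.smooth_profile(prof, 3)


class TestRegionFinding:
    params = tc.DetectorParams(alpha=0.5, gap_tolerance=0, split_gap=1)

    @staticmethod
    def _smoothed(values):
        return tc.SmoothedProfile(np.asarray(values, dtype=float), 1)

    def test_single_block_found_exactly(self):
        v = [0] * 10 + [1] * 20 + [0] * 10
        region = tc.find_repeat_region(self._smoothed(v), self.params)
        assert (region.start, region.end) == (10, 30)

    def test_longer_block_wins(self):
        v = [0] * 5 + [1] * 10 + [0] * 5 + [1] * 20 + [0] * 5
        region = tc.find_repeat_region(self._smoothed(v), self.params)
        assert (region.start, region.end) == (20, 40)

    def test_tie_goes_leftmost(self):
        v = [0] * 5 + [1] * 10 + [0] * 5 + [1] * 10 + [0] * 5
        region = tc.find_repeat_region(self._smoothed(v), self.params)
        assert (region.start, region.end) == (5, 15)

    def test_gap_tolerance_merges_blocks(self):
        v = [0] * 5 + [1] * 10 + [0] * 3 + [1] * 10 + [0] * 5
        params = tc.DetectorParams(alpha=0.5, gap_tolerance=3, split_gap=1)
        region = tc.find_repeat_region(self._smoothed(v), params)
        assert (region.start, region.end) == (5, 28)

    def test_all_zero_profile_is_no_repeat_not_exception(self):
        region = tc.find_repeat_region(self._smoothed([0.0] * 30), self.params)
        assert region is None

    def test_region_near_true_array_interval(self, unit2k, flanks1k, clean):
        spec = tc.ArraySpec(unit2k, 16, flanks1k)
        molecule, truth = tc.build_array_molecule(spec)
        read, _ = tc.simulate_read(molecule, truth, clean, strand="+")
        params = tc.DetectorParams().resolved(unit2k.length_m)
        profile = tc.match_run_profile(read.sequence, unit2k.sequence, params.X)
        smoothed = tc.smooth_profile(profile, params.L)
        region = tc.find_repeat_region(smoothed, params)
        assert abs(region.start - 1000) < unit2k.length_m
        assert abs(region.end - (len(molecule) - 1000)) < unit2k.length_m


class TestSpectralCount:
    def test_single_spectral_line(self):
        i = np.arange(1000)
        v = 1 + np.cos(2 * np.pi * 5 * i / 1000)
        smoothed = tc.SmoothedProfile(v, 1)
        res = tc.count_repeats_dft(smoothed, tc.RepeatRegion(0, 1000), 200, tc.DetectorParams())
        assert res.count == 5
        assert res.method == "dft"

    def test_constant_profile_falls_back_to_length_ratio(self):
        v = np.full(1000, 3.0)
        smoothed = tc.SmoothedProfile(v, 1)
        res = tc.count_repeats_dft(smoothed, tc.RepeatRegion(0, 1000), 200, tc.DetectorParams())
        assert res.count == 5
        assert "flat_spectrum" in res.flags

    def test_empty_region_flagged(self):
        smoothed = tc.SmoothedProfile(np.zeros(10), 1)
        res = tc.count_repeats_dft(smoothed, None, 5, tc.DetectorParams())
        assert res.count == 0
        assert "no_repeat" in res.flags

    def test_short_region_is_single_copy(self):
        v = np.ones(120)
        smoothed = tc.SmoothedProfile(v, 1)
        res = tc.count_repeats_dft(smoothed, tc.RepeatRegion(0, 120), 100, tc.DetectorParams())
        assert res.count == 1
        assert "single_copy_rule" in res.flags

    def test_scale_invariance(self):
        i = np.arange(1000)
        v = 1 + np.cos(2 * np.pi * 7 * i / 1000)
        region = tc.RepeatRegion(0, 1000)
        base = tc.count_repeats_dft(tc.SmoothedProfile(v, 1), region, 140, tc.DetectorParams())
        for scale in (0.25, 3.0, 1e4):
            res = tc.count_repeats_dft(
                tc.SmoothedProfile(v * scale, 1), region, 140, tc.DetectorParams()
            )
            assert res.count == base.count == 7


class TestCountRead:
    def test_seeded_reads_recover_copy_number(self, unit2k, flanks1k, error8):
        from conftest import make_reads

        for k in (1, 7):
            for read, truth in make_reads(unit2k, flanks1k, k, error8, 3, seed=k):
                res = tc.count_read(read, unit2k)
                assert res.count == truth.copy_number

    def test_strand_invariance(self, unit2k, flanks1k, error8):
        from conftest import make_reads

        for read, _ in make_reads(unit2k, flanks1k, 5, error8, 2, seed=55):
            fwd = tc.count_read(read, unit2k)
            rev = tc.count_read(read.reverse_complement(), unit2k)
            assert fwd.count == rev.count

    def test_read_without_repeat_flagged(self, unit2k, rng):
        read = tc.ReadRecord("bare", tc.random_dna(5000, rng))
        res = tc.count_read(read, unit2k)
        assert res.count == 0
        assert "no_repeat" in res.flags

    def test_orientation_vote_swaps_under_revcomp(self, unit2k, flanks1k, clean):
        from conftest import make_reads

        (read, _), = make_reads(unit2k, flanks1k, 3, clean, 1, seed=5)
        fwd = _orientation_votes(read.sequence, unit2k.sequence)
        rev = _orientation_votes(tc.reverse_complement(read.sequence), unit2k.sequence)
        assert fwd == (rev[1], rev[0])
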