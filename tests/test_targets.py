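"""miRNA binding-site prediction: seed scan, aligner, energies, thresholds."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circnet.callers import CircRNACandidate
from circnet.models import Transcript
from circnet.sequences import revcomp_rna
from circnet.targets import (
    AlignmentParams,
    MiRNA,
    duplex_energy,
    extract_circ_sequence,
    miranda_like_score,
    predict_pair,
    seed_scan,
)

rna = st.text(alphabet="ACGU", min_size=0, max_size=80)


def make_mirna(seq, name="mir-t"):
    return MiRNA(name, seq)


class TestMiRNAType:
    def test_seed_is_positions_two_to_seven(self):
        m = make_mirna("UGGAAGACUAGUGAUUUUGUUGU")  # hsa-miR-7-5p
        assert m.seed == "GGAAGA"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter than 8"):
            make_mirna("ACGUACG")

    def test_dna_letters_normalized_to_rna(self):
        assert make_mirna("ACGTACGTT").seq == "ACGUACGUU"

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            make_mirna("ACGUACGX")


class TestSeedScan:
    def test_single_hand_checked_complement(self):
        # reverse complement of seed GGAAGA is UCUUCC
        m = make_mirna("UGGAAGACUAGUGAUUUUGUUGU")
        assert seed_scan("AAUCUUCCAA", m) == [2]

    def test_no_occurrence_gives_empty_list(self):
        m = make_mirna("UGGAAGACUAGUGAUUUUGUUGU")
        assert seed_scan("AAAAAAAAAAAA", m) == []

    def test_overlapping_occurrences_all_reported(self):
        m = make_mirna("AUUUUUUCG")  # seed UUUUUU -> complement AAAAAA
        assert seed_scan("AAAAAAAA", m) == [0, 1, 2]

    @settings(max_examples=200, deadline=None)
    @given(seq=rna, mirna_seq=st.text(alphabet="ACGU", min_size=8, max_size=25))
    def test_equals_exhaustive_six_mer_oracle(self, seq, mirna_seq):
        m = make_mirna(mirna_seq)
        motif = revcomp_rna(m.seed)
        oracle = [
            i for i in range(len(seq) - 5) if seq[i : i + 6] == motif
        ]
        assert seed_scan(seq, m) == oracle


class TestAligner:
    def test_perfect_complement_closed_form_score(self):
        # ungapped perfect complement: every position matches at +5, doubled
        # at miRNA positions 2-8  =>  5 * L + 35
        for L in (8, 22, 23):
            m = make_mirna(("ACGU" * 7)[:L])
            target = revcomp_rna(m.seq)
            score, span = miranda_like_score(target, m)
            assert score == pytest.approx(5 * L + 35)
            assert span == (0, L)

    def test_empty_window_scores_zero(self):
        m = make_mirna("ACGUACGUACGU")
        assert miranda_like_score("", m) == (0.0, (0, 0))

    def test_random_windows_never_reach_threshold(self):
        rng = np.random.default_rng(42)
        m = make_mirna("".join(rng.choice(list("ACGU"), 22)))
        best = 0.0
        for _ in range(200):
            window = "".join(rng.choice(list("ACGU"), 50))
            score, _ = miranda_like_score(window, m)
            best = max(best, score)
        assert best < 150

    def test_gu_wobble_scores_between_match_and_mismatch(self):
        m = make_mirna("AAAACCCCGGGG")
        perfect = miranda_like_score(revcomp_rna(m.seq), m)[0]
        # replace one unweighted-region complement base with a wobble partner
        target = list(revcomp_rna(m.seq))
        assert target[0] == "C"  # pairs G at miRNA 3' end (position 12)
        target[0] = "U"  # G:U wobble
        wobbled = miranda_like_score("".join(target), m)[0]
        assert perfect - 5 + 2 == pytest.approx(wobbled)

    def test_invariant_under_simultaneous_revcomp_unweighted(self):
        # holds for position-unweighted, wobble-free scoring: seed doubling
        # privileges the 5' end, and G:U wobbles complement to A:C
        # mismatches, so both intentionally break the symmetry
        params = AlignmentParams(seed_weight=1.0, wobble=-3.0)
        rng = np.random.default_rng(7)
        for _ in range(20):
            m_seq = "".join(rng.choice(list("ACGU"), 20))
            t_seq = "".join(rng.choice(list("ACGU"), 60))
            s1, _ = miranda_like_score(t_seq, make_mirna(m_seq), params)
            s2, _ = miranda_like_score(
                revcomp_rna(t_seq), make_mirna(revcomp_rna(m_seq)), params
            )
            assert s1 == pytest.approx(s2)


class TestDuplexEnergy:
    def test_full_duplex_more_favorable_than_truncated(self):
        m = make_mirna(("ACGU" * 6)[:22])
        full = duplex_energy(revcomp_rna(m.seq), m)
        trimmed = duplex_energy(revcomp_rna(m.seq[3:]), m)
        assert full < trimmed < 0

    def test_all_mismatch_pairing_has_zero_energy(self):
        m = make_mirna("AAAAAAAAAA")
        assert duplex_energy("AAAAAAAAAA", m) == 0.0  # A:A never pairs

    def test_gc_rich_duplex_more_stable_than_au_rich(self):
        gc = make_mirna("GCGCGCGCGCGC")
        au = make_mirna("AUAUAUAUAUAU")
        e_gc = duplex_energy(revcomp_rna(gc.seq), gc)
        e_au = duplex_energy(revcomp_rna(au.seq), au)
        assert e_gc < e_au < 0


def _exonic_candidate_setup():
    genome = {"chr1": "A" * 50 + "ACGGCAUACGGUCAGGAAAC".replace("U", "T")
              + "G" * 30 + "TTTACGATCG" + "C" * 40}
    t = Transcript(
        name="NM_X", chrom="chr1", start=50, end=110, strand="+",
        exons=[(50, 70), (100, 110)], thick_start=50, thick_end=110,
    )
    cand = CircRNACandidate(
        chrom="chr1", start=50, end=110, strand="+",
        per_sample_reads={"s1": 5}, tools_by_sample={"s1": {"ciri"}},
    )
    return genome, t, cand


class TestSequenceExtraction:
    def test_single_exon_plus_strand_is_exact_substring_plus_window(self):
        genome = {"chr1": "ACGTACGTACGTACGTACGT"}
        t = Transcript(
            name="NM_1", chrom="chr1", start=4, end=12, strand="+",
            exons=[(4, 12)], thick_start=4, thick_end=12,
        )
        cand = CircRNACandidate(
            chrom="chr1", start=4, end=12, strand="+",
            per_sample_reads={}, tools_by_sample={},
        )
        seq = extract_circ_sequence(cand, genome, t, junction_window=3)
        assert seq == "ACGUACGU" + "ACG"

    def test_spliced_extraction_concatenates_exons(self):
        genome, t, cand = _exonic_candidate_setup()
        seq = extract_circ_sequence(cand, genome, t, junction_window=0)
        expected = (genome["chr1"][50:70] + genome["chr1"][100:110]).replace(
            "T", "U"
        )
        assert seq == expected

    def test_minus_strand_is_reverse_complement_involution(self):
        genome, t, cand = _exonic_candidate_setup()
        plus = extract_circ_sequence(cand, genome, t, junction_window=0)
        cand.strand = "-"
        minus = extract_circ_sequence(cand, genome, t, junction_window=0)
        assert minus == revcomp_rna(plus)
        assert revcomp_rna(minus) == plus

    def test_out_of_bounds_coordinates_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        cand = CircRNACandidate(
            chrom="chr1", start=10, end=100, strand="+",
            per_sample_reads={}, tools_by_sample={},
        )
        with pytest.raises(ValueError, match="outside"):
            extract_circ_sequence(cand, genome)

    def test_junction_spanning_site_needs_appended_window(self):
        m = make_mirna(("ACGU" * 7)[:23])
        site = revcomp_rna(m.seq)
        # split the site across the back-splice junction: last 11 nt at the
        # sequence start, first 12 at the end
        filler = "AAAAAGGGGGAAAAAGGGGGAAAAA"
        circ = site[12:] + filler + site[:12]
        genome = {"chr1": circ.replace("U", "T")}
        cand = CircRNACandidate(
            chrom="chr1", start=0, end=len(circ), strand="+",
            per_sample_reads={}, tools_by_sample={},
        )
        without = extract_circ_sequence(cand, genome, junction_window=0)
        with_win = extract_circ_sequence(cand, genome, junction_window=22)
        p_no = predict_pair("c", without, m)
        p_yes = predict_pair("c", with_win, m)
        assert p_no.n_sites == 0
        assert p_yes.n_sites == 1


class TestPairPrediction:
    def _sponge(self, m, n_sites, spacer="AAGAG"):
        site = revcomp_rna(m.seq)
        return (spacer.join([site] * n_sites))

    def test_planted_strong_sites_are_counted(self):
        m = make_mirna(("ACGU" * 7)[:23])
        seq = self._sponge(m, 120)
        pred = predict_pair("sponge", seq, m)
        assert pred.n_sites >= 100
        assert pred.predicted_by_both
        assert all(s.seed_matched for s in pred.sites)

    def test_infinite_score_threshold_gives_no_sites(self):
        m = make_mirna(("ACGU" * 7)[:23])
        seq = self._sponge(m, 5)
        pred = predict_pair("c", seq, m, score_threshold=float("inf"))
        assert pred.n_sites == 0

    def test_raising_score_threshold_never_increases_sites(self):
        m = make_mirna(("ACGU" * 7)[:23])
        seq = self._sponge(m, 10)
        n150 = predict_pair("c", seq, m, score_threshold=150).n_sites
        n180 = predict_pair("c", seq, m, score_threshold=180).n_sites
        n100 = predict_pair("c", seq, m, score_threshold=100).n_sites
        assert n180 <= n150 <= n100

    def test_loosening_energy_threshold_never_decreases_sites(self):
        m = make_mirna(("ACGU" * 7)[:23])
        seq = self._sponge(m, 10)
        strict = predict_pair("c", seq, m, energy_threshold=-60).n_sites
        default = predict_pair("c", seq, m, energy_threshold=-20).n_sites
        loose = predict_pair("c", seq, m, energy_threshold=0).n_sites
        assert strict <= default <= loose

    def test_sites_are_non_overlapping(self):
        m = make_mirna(("ACGU" * 7)[:23])
        seq = self._sponge(m, 8)
        pred = predict_pair("c", seq, m, score_threshold=60)
        spans = sorted((s.target_start, s.target_end) for s in pred.sites)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
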