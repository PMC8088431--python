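"""Global aligner correctness and conserved-pair calling."""

import itertools

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

import hrescan as hs
from hrescan.scanner import CoreHit, HREWindow

DNA4 = st.text(alphabet="ACGT", min_size=1, max_size=8)


def exhaustive_best_score(a, b, match, mismatch, gap):
    """Oracle: recursively enumerate the whole alignment space."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] else mismatch
    return max(
        sub + exhaustive_best_score(a[1:], b[1:], match, mismatch, gap),
        gap + exhaustive_best_score(a[1:], b, match, mismatch, gap),
        gap + exhaustive_best_score(a, b[1:], match, mismatch, gap),
    )


def make_window(seq_id, pos, window_seq, strand="+", confident=True):
    return HREWindow(
        core=CoreHit(seq_id, pos, strand, window_seq[8]),
        window_seq=window_seq,
        raw_prob=1e-6,
        norm_score=1.0,
        confident=confident,
    )


def make_report(seq_id, windows):
    return hs.ScanReport(
        seq_id=seq_id,
        n_core_hits=len(windows),
        n_windows=len(windows),
        n_boundary_dropped=0,
        n_unscorable=0,
        n_confident=sum(w.confident for w in windows),
        windows=list(windows),
    )


class TestPairwiseAlign:
    def test_identical_33mers(self):
        w = "T" * 8 + "ACGTG" + "T" * 20
        aln = hs.pairwise_align(w, w)
        assert aln.score == 33.0
        assert aln.identity == 1.0
        assert aln.aligned_a == aln.aligned_b == w

    def test_hand_computed_dp_table(self):
        # 4x4 table by hand: one mismatch, no gaps
        aln = hs.pairwise_align("ACGT", "AGGT", match=1, mismatch=-1, gap=-2)
        assert aln.score == 2.0
        assert aln.identity == pytest.approx(0.75)

    def test_gap_preferred_when_cheaper(self):
        aln = hs.pairwise_align("AAAA", "AA", match=1, mismatch=-1, gap=-1)
        assert aln.score == 0.0
        assert aln.aligned_b.count("-") == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hs.pairwise_align("", "ACGT")

    def test_n_matches_nothing(self):
        aln = hs.pairwise_align("AN", "AN", match=1, mismatch=-1, gap=-5)
        assert aln.score == 0.0  # N-N scores as a mismatch
        assert aln.identity == pytest.approx(0.5)

    @given(DNA4, DNA4)
    def test_score_symmetry(self, a, b):
        assert (
            hs.pairwise_align(a, b).score == hs.pairwise_align(b, a).score
        )

    @pytest.mark.parametrize(
        "scheme", [(1, -1, -2), (2, -1, -1), (1, -2, -3)]
    )
    def test_matches_exhaustive_enumeration(self, scheme):
        match, mismatch, gap = scheme
        rng = np.random.default_rng(17)
        for _ in range(40):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            assert hs.pairwise_align(a, b, match, mismatch, gap).score == (
                exhaustive_best_score(a, b, match, mismatch, gap)
            )

    def test_matches_biopython_global_aligner(self):
        """Independent cross-check against Bio.Align.PairwiseAligner."""
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-2,
        )
        rng = np.random.default_rng(23)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 34)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 34)))
            assert hs.pairwise_align(a, b).score == aligner.score(a, b)

    def test_degapped_alignment_reproduces_inputs(self):
        aln = hs.pairwise_align("ACGTACGT", "AGTAGT")
        assert aln.aligned_a.replace("-", "") == "ACGTACGT"
        assert aln.aligned_b.replace("-", "") == "AGTAGT"

    def test_identity_excludes_terminal_gaps(self):
        from hrescan.conserve import _identity

        # leading/trailing overhang columns are excluded from the denominator
        assert _identity("--ACGT--", "TTACGTTT") == pytest.approx(1.0)
        assert _identity("ACG-T", "ACGTT") == pytest.approx(4 / 5)


class TestFindConserved:
    def test_shared_identical_window_pairs_at_identity_one(self):
        w = "GATTAGGA" + "ACGTG" + "C" * 20
        ra = make_report("a", [make_window("a", 100, w)])
        rb = make_report("b", [make_window("b", 220, w)])
        pairs = hs.find_conserved(ra, rb, min_identity=0.9)
        assert len(pairs) == 1
        assert pairs[0].alignment.identity == 1.0
        assert pairs[0].core_match

    def test_core_mismatch_excludes_pair(self):
        flanks = ("GATTAGGA", "C" * 20)
        wa = flanks[0] + "ACGTG" + flanks[1]
        wb = flanks[0] + "GCGTG" + flanks[1]
        ra = make_report("a", [make_window("a", 9, wa)])
        rb = make_report("b", [make_window("b", 9, wb)])
        # identity 32/33 clears the bar, but the cores differ
        assert hs.find_conserved(ra, rb, min_identity=0.9) == []

    def test_only_confident_windows_considered(self):
        w = "GATTAGGA" + "ACGTG" + "C" * 20
        ra = make_report("a", [make_window("a", 9, w, confident=False)])
        rb = make_report("b", [make_window("b", 9, w)])
        assert hs.find_conserved(ra, rb) == []

    def test_one_to_one_greedy_matching(self):
        w = "GATTAGGA" + "ACGTG" + "C" * 20
        # two copies in A, one in B: B's window may join only one pair
        ra = make_report("a", [make_window("a", 9, w), make_window("a", 120, w)])
        rb = make_report("b", [make_window("b", 50, w)])
        pairs = hs.find_conserved(ra, rb)
        assert len(pairs) == 1

    def test_output_bounded_by_confident_counts(self, illustrative):
        cfg = hs.SimulationConfig(n_planted=4, shared_fraction=1.0,
                                  flank_divergence=0.0, seed=9)
        a, b, _ = hs.make_species_pair(cfg, illustrative)
        thr = hs.divergence_threshold(illustrative, 16)
        ra = hs.scan_promoter(a, illustrative, hs.ScanConfig(threshold=thr))
        rb = hs.scan_promoter(b, illustrative, hs.ScanConfig(threshold=thr))
        pairs = hs.find_conserved(ra, rb)
        assert len(pairs) <= min(ra.n_confident, rb.n_confident)

    def test_raising_min_identity_never_adds_pairs(self, illustrative):
        cfg = hs.SimulationConfig(n_planted=5, shared_fraction=1.0,
                                  flank_divergence=0.15, seed=4)
        a, b, _ = hs.make_species_pair(cfg, illustrative)
        thr = hs.divergence_threshold(illustrative, 16)
        ra = hs.scan_promoter(a, illustrative, hs.ScanConfig(threshold=thr))
        rb = hs.scan_promoter(b, illustrative, hs.ScanConfig(threshold=thr))
        counts = [
            len(hs.find_conserved(ra, rb, min_identity=mi))
            for mi in (0.0, 0.5, 0.7, 0.8, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_disjoint_random_windows_give_no_pairs(self):
        rng = np.random.default_rng(31)

        def rand_window():
            flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
            return flank(8) + "ACGTG" + flank(20)

        ra = make_report("a", [make_window("a", 9 + 40 * i, rand_window())
                               for i in range(6)])
        rb = make_report("b", [make_window("b", 9 + 40 * i, rand_window())
                               for i in range(6)])
        assert hs.find_conserved(ra, rb, min_identity=0.9) == []
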