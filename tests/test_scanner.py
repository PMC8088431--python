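"""Core-motif scanning, window extraction, and scan reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hrescan as hs
from hrescan.matrix import ILLUSTRATIVE_CONSENSUS
from hrescan.scanner import CoreHit, extract_window


def brute_force_hits(seq: str, strand_mode: str):
    """Independent oracle: enumerate every 5-mer on the requested strands."""
    out = []
    for i in range(len(seq) - 4):
        mer = seq[i : i + 5]
        if mer in ("ACGTG", "GCGTG"):
            out.append((i + 1, "+", mer[0]))
        if strand_mode == "both":
            try:
                rc = hs.reverse_complement(mer)
            except Exception:
                continue
            if rc in ("ACGTG", "GCGTG"):
                out.append((i + 1, "-", rc[0]))
    return sorted(out)


class TestFindCoreHits:
    def test_single_forward_hit(self):
        hits = hs.find_core_hits(hs.PromoterSequence("x", "ACGTG"), "forward")
        assert [(h.pos, h.strand, h.variant) for h in hits] == [(1, "+", "A")]

    def test_no_hits(self):
        assert hs.find_core_hits(hs.PromoterSequence("x", "TTTTT")) == []

    def test_reverse_strand_hit(self):
        hits = hs.find_core_hits(hs.PromoterSequence("x", "CACGT"), "both")
        assert [(h.pos, h.strand, h.variant) for h in hits] == [(1, "-", "A")]

    def test_overlapping_cores_all_reported(self):
        hits = hs.find_core_hits(hs.PromoterSequence("x", "GCGTGCGTG"), "forward")
        assert [(h.pos, h.variant) for h in hits] == [(1, "G"), (5, "G")]

    @pytest.mark.parametrize("strand_mode", ["forward", "both"])
    def test_equals_brute_force_on_random_sequences(self, strand_mode):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            p = hs.PromoterSequence("r", seq)
            got = sorted(
                (h.pos, h.strand, h.variant)
                for h in hs.find_core_hits(p, strand_mode)
            )
            assert got == brute_force_hits(seq, strand_mode)

    @given(st.text(alphabet="ACGTN", min_size=5, max_size=200))
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement mirrors the hit set."""
        L = len(seq)
        fwd = hs.find_core_hits(hs.PromoterSequence("x", seq), "both")
        rev = hs.find_core_hits(
            hs.PromoterSequence("x", hs.reverse_complement(seq)), "both"
        )
        mirrored = sorted(
            (L - h.pos - 3, "+-"[h.strand == "+"], h.variant) for h in rev
        )
        assert sorted((h.pos, h.strand, h.variant) for h in fwd) == mirrored


class TestExtractWindow:
    def test_exact_fit_is_whole_sequence(self):
        seq = "T" * 8 + "ACGTG" + "T" * 20
        p = hs.PromoterSequence("x", seq)
        w = extract_window(p, CoreHit("x", 9, "+", "A"))
        assert w.window_seq == seq
        assert w.core_seq == "ACGTG"

    def test_boundary_drop_near_start(self):
        p = hs.PromoterSequence("x", "ACGTG" + "T" * 40)
        assert extract_window(p, CoreHit("x", 1, "+", "A")) is None

    def test_boundary_drop_near_end(self):
        p = hs.PromoterSequence("x", "T" * 40 + "ACGTG")
        assert extract_window(p, CoreHit("x", 41, "+", "A")) is None

    def test_minus_strand_matches_independent_slicing(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        # plant a minus-strand core mid-sequence
        seq = seq[:99] + "CACGT" + seq[104:]
        p = hs.PromoterSequence("x", seq)
        hit = CoreHit("x", 100, "-", "A")
        w = extract_window(p, hit)
        # oracle: reverse complement the forward slice pos-20 .. pos+12
        assert w.window_seq == hs.reverse_complement(seq[79:112])
        assert w.core_seq == "ACGTG"

    def test_window_positions_9_to_13_are_the_core(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        p = hs.PromoterSequence("x", seq)
        for h in hs.find_core_hits(p, "both"):
            w = extract_window(p, h)
            if w is None:
                continue
            assert w.core_seq in ("ACGTG", "GCGTG")
            assert w.core_seq[0] == h.variant

    def test_mismatched_sequence_rejected(self):
        p = hs.PromoterSequence("x", "A" * 50)
        with pytest.raises(ValueError):
            extract_window(p, CoreHit("other", 10, "+", "A"))


class TestScanPromoter:
    def test_zero_motifs_zero_counts(self, illustrative):
        rep = hs.scan_promoter(hs.PromoterSequence("x", "TTTATTTATT" * 10), illustrative)
        assert (rep.n_core_hits, rep.n_windows, rep.n_confident) == (0, 0, 0)

    def test_count_accounting(self, illustrative):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            rep = hs.scan_promoter(hs.PromoterSequence("x", seq), illustrative)
            assert rep.n_core_hits == rep.n_windows + rep.n_boundary_dropped
            assert rep.n_confident <= rep.n_windows <= rep.n_core_hits

    def test_threshold_extremes(self, illustrative):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        p = hs.PromoterSequence("x", seq)
        rep_all = hs.scan_promoter(p, illustrative, hs.ScanConfig(threshold=0.0))
        assert rep_all.n_confident == rep_all.n_windows - rep_all.n_unscorable
        rep_none = hs.scan_promoter(p, illustrative, hs.ScanConfig(threshold=1.0))
        assert rep_none.n_confident <= rep_all.n_confident

    def test_raising_threshold_never_increases_confident(self, illustrative):
        cfg = hs.SimulationConfig(n_planted=5, seed=2)
        seq, _ = hs.plant_sites(
            hs.generate_background(cfg), illustrative, cfg
        )
        previous = None
        for t in (1e-30, 1e-12, 1e-4, 0.05, 0.5, 1.0):
            n = hs.scan_promoter(
                seq, illustrative, hs.ScanConfig(threshold=t)
            ).n_confident
            if previous is not None:
                assert n <= previous
            previous = n

    def test_planted_consensus_recovered(self, illustrative, consensus_matrix):
        cfg = hs.SimulationConfig(n_planted=10, seed=3)
        seq, truth = hs.plant_sites(
            hs.generate_background(cfg), consensus_matrix, cfg
        )
        rep = hs.scan_promoter(seq, illustrative)
        confident_pos = {w.core.pos for w in rep.confident_windows()}
        assert set(truth.core_positions("A")) <= confident_pos
        assert rep.n_confident >= 10

    def test_windows_with_n_flagged_unscorable(self, illustrative):
        seq = "T" * 8 + "ACGTG" + "N" + "T" * 19
        rep = hs.scan_promoter(hs.PromoterSequence("x", seq), illustrative)
        assert rep.n_windows == 1
        assert rep.n_unscorable == 1
        assert rep.n_confident == 0

    def test_width_mismatch_propagates(self):
        m = hs.build_psfm(["ACGT", "ACGT"], pseudocount=0.5)
        with pytest.raises(ValueError, match="width"):
            hs.scan_promoter(hs.PromoterSequence("x", "A" * 50), m)


class TestDivergenceThreshold:
    def test_decreases_with_budget(self, illustrative):
        ts = [hs.divergence_threshold(illustrative, k) for k in range(0, 10)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_budget_zero_admits_both_core_purines(self, illustrative):
        t = hs.divergence_threshold(illustrative, 0)
        cons = ILLUSTRATIVE_CONSENSUS
        g_core = cons[:8] + "G" + cons[9:]
        assert hs.score_window(illustrative, g_core).norm >= t
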