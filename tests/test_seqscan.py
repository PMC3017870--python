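"""Sequence scanners: homopolymers, dnaA boxes, GC skew, palindromes."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reducta.genome_io import GeneFeature, GenomeRecord
from reducta.seqscan import (cluster_boxes, count_long_tracts_in_cds,
                             find_dnaa_boxes, find_homopolymers,
                             find_palindromes, gc_profile, predict_origin,
                             revcomp)

dna = st.text(alphabet="ACGT", min_size=1, max_size=5000)


def rle_runs(seq, bases, min_len):
    """Independent run-length-encoding oracle."""
    out = []
    for m in re.finditer(r"(.)\1*", seq):
        if m.group(1) in bases and len(m.group(0)) >= min_len:
            out.append((m.group(1), m.start(), len(m.group(0))))
    return out


class TestHomopolymers:
    def test_no_tracts_in_alternating_sequence(self):
        assert find_homopolymers("ACGT" * 5, min_len=9) == []

    def test_constructed_tracts_found_with_exact_bounds(self):
        seq = "CC" + "A" * 9 + "GG" + "T" * 12 + "C"
        got = [(t.base, t.start, t.length)
               for t in find_homopolymers(seq, min_len=9)]
        assert got == [("A", 2, 9), ("T", 13, 12)]

    def test_min_len_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            find_homopolymers("AAAA", min_len=1)

    @given(dna)
    @settings(max_examples=200, deadline=None)
    def test_matches_run_length_oracle(self, seq):
        got = [(t.base, t.start, t.length)
               for t in find_homopolymers(seq, bases="AT", min_len=4)]
        assert got == rle_runs(seq, "AT", 4)

    def test_coding_strand_convention_counts_genomic_polyT_in_minus_cds(self):
        # minus-strand gene whose coding strand has a polyA run
        coding = "ATG" + "A" * 10 + "CGTCGT" + "TAA"
        genomic = revcomp(coding)
        rec = GenomeRecord("t", "CC" + genomic + "GG", False,
                           [GeneFeature("g1", "", "CDS", 2,
                                        2 + len(genomic), "-")])
        tracts = count_long_tracts_in_cds(rec, min_len=9, strand="coding")
        assert len(tracts) == 1 and tracts[0].base == "A"
        assert count_long_tracts_in_cds(rec, min_len=9, strand="genomic") == []

    def test_tract_must_lie_fully_inside_a_cds(self):
        rec = GenomeRecord("t", "A" * 40, False,
                           [GeneFeature("g1", "", "CDS", 0, 12, "+")])
        # the A-run extends past the gene: the in-CDS portion is reported
        tracts = count_long_tracts_in_cds(rec, min_len=9)
        assert [(t.start, t.length) for t in tracts] == [(0, 12)]


class TestGcProfile:
    def test_pure_composition_windows(self):
        prof = gc_profile("G" * 50, window=10, step=5, circular=False)
        assert np.all(prof.gc_skew == 1.0)
        prof = gc_profile("C" * 50, window=10, step=5, circular=False)
        assert np.all(prof.gc_skew == -1.0)
        prof = gc_profile("GC" * 25, window=10, step=5, circular=False)
        assert np.all(prof.gc_skew == 0.0)

    def test_window_counts_match_direct_summation(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        prof = gc_profile(seq, window=50, step=7, circular=False)
        for k, start in enumerate(range(0, len(seq) - 50 + 1, 7)):
            w = seq[start : start + 50]
            g, c = w.count("G"), w.count("C")
            expect = 0.0 if g + c == 0 else (g - c) / (g + c)
            assert prof.gc_skew[k] == pytest.approx(expect)
            assert prof.gc_content[k] == pytest.approx((g + c) / 50)

    def test_skew_antisymmetric_under_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = gc_profile(seq, window=60, step=60, circular=False)
        rev = gc_profile(revcomp(seq), window=60, step=60, circular=False)
        assert np.allclose(fwd.gc_skew, -rev.gc_skew[::-1])

    def test_empty_gc_window_flagged_not_dropped(self):
        prof = gc_profile("AT" * 30 + "GC" * 30, window=20, step=20,
                          circular=False)
        assert prof.empty_windows[0]
        assert prof.gc_skew[0] == 0.0

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_profile("ACGT", window=10)

    def test_cumulative_extremum_at_composition_switch(self):
        # G-biased first half, C-biased second half: the cumulative skew
        # peaks where the composition flips
        rng = np.random.default_rng(2)
        half = 10_000
        first = rng.choice(list("ACGT"), size=half, p=[0.3, 0.1, 0.3, 0.3])
        second = rng.choice(list("ACGT"), size=half, p=[0.3, 0.3, 0.1, 0.3])
        seq = "".join(first) + "".join(second)
        prof = gc_profile(seq, window=1000, step=10, circular=False)
        peak = prof.centers[int(np.argmax(prof.cumulative_skew))]
        assert abs(peak - half) < 2000


class TestPredictOrigin:
    def test_planted_origin_recovered(self, planted_skew_genome):
        rec, origin = planted_skew_genome
        prof = gc_profile(rec.sequence, circular=True)
        call = predict_origin(prof, rec)
        assert call.confident
        n = len(rec.sequence)
        err = min(abs(call.origin_pos - origin), n - abs(call.origin_pos - origin))
        assert err <= 2000

    def test_uniform_sequence_gives_no_confident_origin(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=120_000))
        rec = GenomeRecord("u", seq, True, [])
        call = predict_origin(gc_profile(seq, circular=True), rec)
        assert not call.confident and call.origin_pos is None


@pytest.fixture(scope="module")
def planted_skew_genome():
    from reducta.synthsim import SimConfig, ancestor_record, simulate_ancestor

    cfg = SimConfig(seed=9, n_genes=120, n_rna=8, origin_frac=0.4,
                    skew_amplitude=0.05)
    sim = simulate_ancestor(cfg)
    return ancestor_record(sim), sim.manifest["origin_pos"]


class TestDnaaBoxes:
    def test_consensus_hit_on_plus_strand(self):
        hits = find_dnaa_boxes("TTATACACA")
        assert [(h.start, h.strand) for h in hits] == [(0, "+")]

    def test_consensus_hit_on_minus_strand(self):
        hits = find_dnaa_boxes(revcomp("TTATACACA"))
        assert [(h.start, h.strand) for h in hits] == [(0, "-")]

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError):
            find_dnaa_boxes("ACGT", pattern="TTQT")

    def test_matches_exhaustive_iupac_scan(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=10_000,
                                 p=[0.36, 0.14, 0.14, 0.36]))
        pattern = "TTWTNCACA"
        from reducta.seqscan import IUPAC

        def match_at(s, i):
            return all(s[i + k] in IUPAC[p] for k, p in enumerate(pattern))

        expect = set()
        m = len(pattern)
        for i in range(len(seq) - m + 1):
            if match_at(seq, i):
                expect.add((i, "+"))
        rc = revcomp(seq)
        for i in range(len(rc) - m + 1):
            if match_at(rc, i):
                expect.add((len(seq) - i - m, "-"))
        got = {(h.start, h.strand) for h in find_dnaa_boxes(seq, pattern)}
        assert got == expect

    def test_cluster_detection(self):
        from reducta.seqscan import DnaaBoxHit

        hits = [DnaaBoxHit(p, "+", "TTATACACA")
                for p in (10, 60, 150, 250, 5000)]
        clusters = cluster_boxes(hits, window=300, min_count=4)
        assert len(clusters) == 1
        assert clusters[0][2] == 4


def brute_force_palindromes(seq, min_arm, max_arm, max_gap, max_mismatch):
    """Naive per-(position, gap) outward arm extension oracle."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    n = len(seq)
    cands = []
    for gap in range(max_gap + 1):
        for i in range(1, n - gap):
            best_len = best_mm = 0
            mm = 0
            k = 0
            while k < min(max_arm, (n - gap) // 2):
                lo, hi = i - 1 - k, i + gap + k
                if lo < 0 or hi >= n:
                    break
                match = seq[lo] == comp[seq[hi]]
                if k == 0 and not match:
                    break
                if not match:
                    mm += 1
                    if mm > max_mismatch:
                        break
                elif k > 0 or match:
                    best_len, best_mm = k + 1, mm
                k += 1
            if best_len >= min_arm:
                cands.append((i - best_len, i + gap, best_len, gap, best_mm))
    # same non-redundancy rule: longest arm, fewer mismatches, leftmost
    cands.sort(key=lambda c: (-c[2], c[4], c[0], c[3]))
    kept = []
    out = []
    for c in cands:
        s, e = c[0], c[1] + c[2]
        if all(e <= ks or s >= ke for ks, ke in kept):
            kept.append((s, e))
            out.append(c)
    return out


class TestPalindromes:
    def test_constructed_exact_inverted_repeat(self):
        rng = np.random.default_rng(5)
        arm = "".join(rng.choice(list("ACGT"), size=30))
        gapseq = "".join(rng.choice(list("ACGT"), size=5))
        flank1 = "".join(rng.choice(list("AC"), size=100))
        flank2 = "".join(rng.choice(list("GT"), size=100))
        seq = flank1 + arm + gapseq + revcomp(arm) + flank2
        hits = find_palindromes(seq, min_arm=30, max_gap=20, max_mismatch=0)
        assert len(hits) == 1
        h = hits[0]
        assert h.span >= 65 and h.mismatches == 0
        assert h.check(seq)

    def test_mismatch_budget_is_a_hard_cutoff(self):
        rng = np.random.default_rng(6)
        arm = "".join(rng.choice(list("ACGT"), size=40))
        arm2 = list(revcomp(arm))
        for p in (5, 15, 25, 35):  # 4 substitutions
            arm2[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[p]]
        seq = ("".join(rng.choice(list("AC"), size=80)) + arm + "TTTTT"
               + "".join(arm2) + "".join(rng.choice(list("GT"), size=80)))
        at3 = find_palindromes(seq, min_arm=38, max_gap=20, max_mismatch=3)
        at4 = find_palindromes(seq, min_arm=38, max_gap=20, max_mismatch=4)
        assert at3 == []
        assert len(at4) == 1 and at4[0].mismatches == 4

    def test_every_hit_verifies_its_own_constraints(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=3000,
                                 p=[0.36, 0.14, 0.14, 0.36]))
        for h in find_palindromes(seq, min_arm=6, max_gap=8, max_mismatch=2):
            assert h.check(seq)
            assert h.gap <= 8 and h.mismatches <= 2 and h.arm_length >= 6

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_short_sequences(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=800,
                                 p=[0.36, 0.14, 0.14, 0.36]))
        got = [(p.arm1_start, p.arm2_start, p.arm_length, p.gap, p.mismatches)
               for p in find_palindromes(seq, min_arm=5, max_arm=100,
                                         max_gap=6, max_mismatch=2)]
        expect = sorted(brute_force_palindromes(seq, 5, 100, 6, 2))
        assert sorted(got) == expect

    def test_igs_overlap_annotation(self):
        arm = "ACGTACGTACGTACGTACGT"
        seq = "A" * 50 + arm + revcomp(arm) + "A" * 50
        rec = GenomeRecord("t", seq, False,
                           [GeneFeature("g", "", "CDS", 0, 30, "+")])
        hits = find_palindromes(seq, min_arm=10, max_gap=2, max_mismatch=0,
                                record=rec)
        assert hits and all(h.igs_overlap == "fully_igs" for h in hits)
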