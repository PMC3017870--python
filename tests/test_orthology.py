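"""Protein similarity, reciprocal best hits, ortholog table, screen rules."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from reducta.orthology import (SimilarityHit, align_proteins,
                               build_ortholog_table, classify_hit,
                               classify_trna, reciprocal_best_hits, sw_score)

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a, b, open_=11.0, ext=1.0):
    """Quadratic Gotoh local alignment; first gapped position costs open_."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - open_, E[i - 1][j] - ext)
            F[i][j] = max(H[i][j - 1] - open_, F[i][j - 1] - ext)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestAlignProteins:
    def test_identical_sequences_fully_covered(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        hit = align_proteins(seq, seq)
        assert hit.subject_coverage == pytest.approx(1.0)
        assert hit.evalue_like < 1e-10

    def test_unrelated_sequences_score_near_background(self):
        rng = np.random.default_rng(0)
        a, b = random_protein(rng, 100), random_protein(rng, 100)
        hit = align_proteins(a, b)
        assert hit.subject_coverage < 0.5
        assert hit.evalue_like > 1e-5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "MK")

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_dp_oracle_on_short_pairs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(5, 31)))
        b = random_protein(rng, int(rng.integers(5, 31)))
        assert sw_score(a, b) == pytest.approx(sw_oracle(a, b))


class TestReciprocalBestHits:
    PROTS = {
        "p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 2,
        "p2": "MSERADLVVSNALLVDHQGVYKADIGIKNGKIA" * 2,
        "p3": "MTDKLSVKDVLNLPQVAGEWQIRGSNGAHLEVN" * 2,
    }

    def test_identical_proteomes_map_identically(self):
        pairs = reciprocal_best_hits(self.PROTS, dict(self.PROTS),
                                     prescreen_min_kmers=None)
        assert pairs == [("p1", "p1"), ("p2", "p2"), ("p3", "p3")]

    def test_symmetry(self):
        ab = reciprocal_best_hits(self.PROTS, dict(self.PROTS))
        ba = reciprocal_best_hits(dict(self.PROTS), self.PROTS)
        assert sorted((y, x) for x, y in ab) == sorted(ba)

    def test_deleted_gene_left_unpaired(self):
        smaller = {k: v for k, v in self.PROTS.items() if k != "p2"}
        pairs = reciprocal_best_hits(self.PROTS, smaller,
                                     prescreen_min_kmers=None)
        assert ("p2", "p2") not in pairs
        assert ("p1", "p1") in pairs and ("p3", "p3") in pairs

    def test_every_pair_is_mutual_best_by_exhaustive_scoring(self):
        rng = np.random.default_rng(1)
        pa = {f"a{i}": random_protein(rng, 60) for i in range(5)}
        pb = {k.replace("a", "b"): _mutate(rng, v, 6) for k, v in pa.items()}
        pairs = reciprocal_best_hits(pa, pb, prescreen_min_kmers=None)
        for la, lb in pairs:
            assert all(sw_score(pa[la], pb[lb]) >= sw_score(pa[la], pb[x])
                       for x in pb)
            assert all(sw_score(pa[la], pb[lb]) >= sw_score(pa[x], pb[lb])
                       for x in pa)


def _mutate(rng, seq, k):
    out = list(seq)
    for i in rng.choice(len(seq), size=k, replace=False):
        out[i] = rng.choice(list(AA))
    return "".join(out)


class TestOrthologTable:
    def test_identical_genomes_give_full_families(self, small_triad):
        _, genomes, _ = small_triad
        rec = genomes["pen"]
        import copy

        g2 = copy.deepcopy(rec)
        g2.id = "b"
        g3 = copy.deepcopy(rec)
        g3.id = "c"
        for r in (g2, g3):
            for f in r.features:
                f.locus_tag = r.id + "_" + f.locus_tag.split("_", 1)[1]
        table = build_ortholog_table([rec, g2, g3])
        sizes = [len(f.members) for f in table.families]
        assert sizes and all(s == 3 for s in sizes)

    def test_input_order_does_not_change_families(self, small_triad):
        _, genomes, _ = small_triad
        recs = [genomes[g] for g in ("vaf", "flo", "pen")]
        t1 = build_ortholog_table(recs)
        t2 = build_ortholog_table(recs[::-1])
        fams1 = {frozenset(f.members.items()) for f in t1.families}
        fams2 = {frozenset(f.members.items()) for f in t2.families}
        assert fams1 == fams2

    def test_planted_deletions_absent_exactly_where_planted(self, small_triad):
        _, genomes, manifest = small_triad
        table = build_ortholog_table([genomes[g] for g in sorted(genomes)])
        by_locus = {l: f for f in table.families for l in f.members.values()}
        for tfam, d in manifest["families"].items():
            lost_in = {e["branch"] for e in d["events"]
                       if e["event"] == "LOSS"}
            expanded = set()
            for b in lost_in:
                expanded |= set(b.split("+"))
            coords = d["coordinates"]
            if not coords:
                continue
            fam = by_locus.get(next(iter(coords.values()))["locus"])
            assert fam is not None
            assert set(fam.members) == set(coords)
            assert expanded.isdisjoint(fam.members)


class TestScreenRules:
    def test_good_coverage_and_evalue_is_present(self):
        hit = SimilarityHit("q", "s", 300, 0.75, 1e-10)
        assert classify_hit(hit) == "present"

    def test_coverage_just_below_threshold_is_absent(self):
        hit = SimilarityHit("q", "s", 500, 0.59, 1e-40)
        assert classify_hit(hit) == "absent"

    def test_per_gene_exception_relaxes_coverage(self):
        hit = SimilarityHit("q", "ftsY", 200, 0.55, 1e-8)
        assert classify_hit(hit) == "absent"
        assert classify_hit(hit, exceptions={"ftsY": 0.50}) == "present"

    @pytest.mark.parametrize("primary,secondary,expect", [
        (8, 28, "functional"),   # low HMM score rescued by fold score
        (50, 50, "functional"),  # never flagged
        (12, 4, "flagged_pseudo"),
        (9, 4.9, "flagged_pseudo"),
        (9.9, 5.0, "functional"),
    ])
    def test_trna_pseudogene_rule(self, primary, secondary, expect):
        assert classify_trna(primary, secondary) == expect
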