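"""Gene states, Dollo reconstruction, hotspots, rank-sum, IGS classes."""

import itertools

import numpy as np
import pytest
import scipy.stats

from reducta.reduction import (ABSENT, EventRow, EventTable,
                               FRAMESHIFT_SLIPPAGE, INTACT, PSEUDOGENE,
                               RootedTree, classify_cds_state,
                               dollo_reconstruct, flag_convergent,
                               hotspot_scan, rank_sum_test,
                               self_rescue_frameshift, summarize_events)

TREE = RootedTree("((v:0.05,f:0.05):0.03,p:0.08);")
STATES = (INTACT, FRAMESHIFT_SLIPPAGE, PSEUDOGENE, ABSENT)
SEV = {INTACT: 0, FRAMESHIFT_SLIPPAGE: 0, PSEUDOGENE: 1, ABSENT: 2}


def make_cds(rng, n_codons, tract=None):
    """Random stop-free CDS; optionally embed a polyA tract (codon-aligned
    AAA codons so no stop can arise)."""
    from reducta.synthsim import _base_freqs, _sample_cds

    seq = _sample_cds(rng, n_codons, _base_freqs(0.275))
    if tract:
        at, ln = tract
        k = (ln + 2) // 3
        seq = seq[: 3 * at] + "A" * (3 * k) + seq[3 * (at + k) :]
    return seq


class TestClassifyCdsState:
    def test_identical_gene_intact(self):
        rng = np.random.default_rng(0)
        cds = make_cds(rng, 120)
        assert classify_cds_state("f", "g", cds, cds).state == INTACT

    def test_single_indel_in_long_tract_is_slippage(self):
        rng = np.random.default_rng(1)
        ref = make_cds(rng, 120, tract=(50, 11))
        pos = 3 * 50 + 4
        mutated = ref[:pos] + "A" + ref[pos:]  # A11 -> A12 insertion
        call = classify_cds_state("f", "g", mutated, ref)
        assert call.state == FRAMESHIFT_SLIPPAGE
        assert call.frameshift.indel_sign == +1
        assert call.frameshift.tract.base == "A"
        deleted = ref[:pos] + ref[pos + 1 :]
        call = classify_cds_state("f", "g", deleted, ref)
        assert call.state == FRAMESHIFT_SLIPPAGE
        assert call.frameshift.indel_sign == -1

    def test_single_indel_outside_tract_is_pseudogene(self):
        rng = np.random.default_rng(2)
        ref = make_cds(rng, 120)
        # find a position with no A/T run nearby
        pos = next(3 * i for i in range(20, 100)
                   if len(set(ref[3 * i - 4 : 3 * i + 4])) >= 3)
        mutated = ref[:pos] + ref[pos + 1 :]
        assert classify_cds_state("f", "g", mutated, ref).state == PSEUDOGENE

    def test_two_separate_indels_are_pseudogene_not_slippage(self):
        rng = np.random.default_rng(3)
        ref = make_cds(rng, 150, tract=(40, 10))
        s = ref[:123] + "A" + ref[123:]
        s = s[:300] + s[301:]
        s = s[:260] + s[261:]  # net -1, two+ disruptions
        assert classify_cds_state("f", "g", s, ref).state == PSEUDOGENE

    def test_internal_stop_is_pseudogene(self):
        rng = np.random.default_rng(4)
        ref = make_cds(rng, 120)
        mutated = ref[: 3 * 60] + "TAA" + ref[3 * 61 :]
        assert classify_cds_state("f", "g", mutated, ref).state == PSEUDOGENE

    def test_heavy_truncation_is_pseudogene(self):
        rng = np.random.default_rng(5)
        ref = make_cds(rng, 150)
        assert classify_cds_state("f", "g", ref[: 3 * 60], ref).state \
            == PSEUDOGENE

    def test_self_rescue_requires_clean_corrected_frame(self):
        rng = np.random.default_rng(6)
        ref = make_cds(rng, 120, tract=(50, 11))
        pos = 3 * 50 + 2
        slipped = ref[:pos] + "A" + ref[pos:]
        got = self_rescue_frameshift("f", "g", slipped)
        assert got is not None
        corrected, call = got
        assert corrected == ref and call.indel_sign == +1
        assert self_rescue_frameshift("f", "g", ref[:-1]) is None


def dollo_oracle(states):
    """Exhaustive minimal-event search on the 3-leaf tree ((v,f),p)."""
    sev = {k: SEV[v] for k, v in states.items()}
    best = None
    for root in range(3):
        for vf in range(root, 3):
            cost = 0
            cost += vf != root
            cost += sev["p"] != root and sev["p"] > root
            if sev["p"] < root:
                continue
            if sev["v"] < vf or sev["f"] < vf:
                continue
            cost += sev["v"] != vf
            cost += sev["f"] != vf
            if best is None or cost < best:
                best = cost
    return best


class TestDollo:
    def test_all_intact_no_events(self):
        present, ev = dollo_reconstruct(
            {"v": INTACT, "f": INTACT, "p": INTACT}, TREE)
        assert present and ev == []

    def test_convergent_double_loss(self):
        # intact only in one leaf: two independent losses, not a stem loss
        present, ev = dollo_reconstruct(
            {"v": INTACT, "f": ABSENT, "p": ABSENT}, TREE, "yggS")
        assert present
        assert sorted((r.branch_id, r.event) for r in ev) \
            == [("f", "LOSS"), ("p", "LOSS")]
        flag_convergent(ev, TREE)
        assert all(r.convergent for r in ev)

    def test_erosion_and_loss_on_different_lineages(self):
        present, ev = dollo_reconstruct(
            {"v": PSEUDOGENE, "f": INTACT, "p": ABSENT}, TREE)
        assert present
        assert sorted((r.branch_id, r.event) for r in ev) \
            == [("p", "LOSS"), ("v", "EROSION")]

    def test_shared_absence_in_sisters_is_one_stem_loss(self):
        present, ev = dollo_reconstruct(
            {"v": ABSENT, "f": ABSENT, "p": INTACT}, TREE)
        assert present
        assert [(r.branch_id, r.event) for r in ev] == [("f+v", "LOSS")]

    @pytest.mark.parametrize("combo",
                             list(itertools.product(STATES, repeat=3)))
    def test_matches_exhaustive_minimal_event_search(self, combo):
        states = dict(zip("vfp", combo))
        _, ev = dollo_reconstruct(states, TREE)
        assert len(ev) == dollo_oracle(states)
        # reconstruction respects Dollo: severity never decreases
        path_events = {}
        for leaf in "vfp":
            path = TREE.path_branches(leaf)
            sev = 0
            for b in path:
                for r in ev:
                    if r.branch_id == b:
                        new = 1 if r.event == "EROSION" else 2
                        assert new > sev
                        sev = new
            assert sev <= SEV[states[leaf]]


class TestSummarize:
    def test_lineage_counts_include_stem_events(self):
        rows = [EventRow("f1", "f+v", "LOSS"), EventRow("f2", "v", "EROSION"),
                EventRow("f3", "p", "LOSS")]
        s = summarize_events(EventTable(rows), TREE)
        assert s["missing_or_eroded_per_lineage"] == {"v": 2, "f": 1, "p": 1}

    def test_zero_events(self):
        s = summarize_events(EventTable([]), TREE)
        assert all(v == 0 for v in
                   s["missing_or_eroded_per_lineage"].values())
        assert s["convergent_families"] == []


class TestHotspot:
    def test_evenly_spread_positions_not_significant(self):
        pos = list(range(0, 700_000, 70_000))
        res = hotspot_scan(pos, 700_000, window=32_000, n_perm=999, seed=7)
        assert all(r.p_perm >= 0.05 for r in res)

    def test_planted_cluster_detected(self):
        rng = np.random.default_rng(8)
        scattered = sorted(rng.integers(0, 700_000, size=23))
        planted = sorted(rng.integers(200_000, 230_000, size=8))
        res = hotspot_scan(list(scattered) + planted, 700_000,
                           window=32_000, n_perm=9_999, seed=9)
        assert res, "no window reported"
        top = res[0]
        assert top.p_perm < 0.01
        assert top.window_start <= 230_000 and top.window_end >= 200_000

    def test_near_origin_flag(self):
        planted = list(range(100_000, 103_000, 400))
        res = hotspot_scan(planted, 500_000, window=30_000, n_perm=999,
                           seed=1, origin_pos=95_000)
        assert res and res[0].near_origin

    def test_empty_positions_give_empty_result(self):
        assert hotspot_scan([], 500_000, n_perm=999, seed=0) == []

    def test_p_values_valid_under_uniform_null(self):
        """P(p <= alpha) should not exceed alpha by much under the null."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 120
        for _ in range(reps):
            pos = rng.integers(0, 600_000, size=25)
            res = hotspot_scan(pos, 600_000, window=32_000, n_perm=999,
                               seed=int(rng.integers(2**31)), alpha=1.1)
            pmin = min((r.p_perm for r in res), default=1.0)
            hits += pmin <= 0.05
        assert hits / reps <= 0.10


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p_two_sided == 1.0

    def test_fully_separated_small_samples_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.1)

    def test_exact_agrees_with_scipy_on_untied_data(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = list(rng.normal(size=6))
            y = list(rng.normal(0.5, size=7))
            ours = rank_sum_test(x, y)
            ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approx_close_to_exact_at_n10(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = list(rng.normal(0, 1, size=10))
            y = list(rng.normal(0.7, 1, size=10))
            exact = rank_sum_test(x, y, exact_limit=20)
            approx = rank_sum_test(x, y, exact_limit=0)
            assert approx.method == "normal_approx"
            assert abs(exact.p_two_sided - approx.p_two_sided) <= 0.01

    def test_large_shifted_samples_tiny_p(self):
        rng = np.random.default_rng(13)
        x = list(rng.normal(0, 1, 200))
        y = list(rng.normal(1, 1, 200))
        assert rank_sum_test(x, y).p_two_sided < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


@pytest.fixture(scope="module")
def lossy_triad_result():
    from reducta.pipeline import analyze_triad
    from reducta.synthsim import SimConfig, simulate_triad

    rates = {"vaf": (0.12, 0.0, 0.0), "flo": (0.12, 0.0, 0.0),
             "pen": (0.04, 0.0, 0.0), "flo+vaf": (0.02, 0.0, 0.0)}
    cfg = SimConfig(seed=77, n_genes=80, n_rna=6, event_rates=rates,
                    n_palindromes=0)
    genomes, _ = simulate_triad(cfg)
    return analyze_triad(genomes, cfg.tree, seed=1, hotspot_nperm=999,
                         with_rates=False)


class TestIgsComparison:
    def test_spanning_class_longer_and_significant(self, lossy_triad_result):
        res = lossy_triad_result
        found_signal = False
        for gid, entry in res.igs_comparison["per_genome"].items():
            if entry["n_spanning"] >= 5 and "rank_sum" in entry:
                assert entry["median_spanning"] > entry["median_conserved"]
                assert entry["rank_sum"].p_two_sided < 0.01
                found_signal = True
        assert found_signal, "no genome had enough spanning spacers"

    def test_identical_genomes_have_no_spanning_class(self, small_triad):
        from reducta.genome_io import extract_igs
        from reducta.reduction import igs_classify_and_compare

        _, genomes, _ = small_triad
        igs = {g: extract_igs(r) for g, r in genomes.items()}
        out = igs_classify_and_compare(igs, {})
        for entry in out["per_genome"].values():
            assert entry["n_spanning"] == 0
            assert "rank_sum" not in entry
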