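"""Gene-state classification and loss/erosion reconstruction.

Classifies each ortholog family in each genome as INTACT,
FRAMESHIFT_SLIPPAGE (a single 1-bp indel inside a homopolymeric tract,
potentially corrected by transcriptional slippage), PSEUDOGENE or ABSENT;
polarises loss and erosion events on a rooted tree under Dollo parsimony
(gene gain forbidden, degradation irreversible); flags convergent events;
scans for deletion hotspots with a circular permutation test; and compares
intergenic spacer (IGS) length classes with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .genome_io import GenomeRecord, IgsRecord
from .orthology import OrthologFamily, align_proteins, classify_hit
from .seqscan import HomopolymerTract, revcomp

# gene states in increasing severity
INTACT = "INTACT"
FRAMESHIFT_SLIPPAGE = "FRAMESHIFT_SLIPPAGE"
PSEUDOGENE = "PSEUDOGENE"
ABSENT = "ABSENT"
SEVERITY = {INTACT: 0, FRAMESHIFT_SLIPPAGE: 0, PSEUDOGENE: 1, ABSENT: 2}

LOSS = "LOSS"
EROSION = "EROSION"
FRAMESHIFT = "FRAMESHIFT"

_NT_ALIGNER = Align.PairwiseAligner()
_NT_ALIGNER.mode = "global"
_NT_ALIGNER.match_score = 2.0
_NT_ALIGNER.mismatch_score = -3.0
_NT_ALIGNER.open_gap_score = -7.0
_NT_ALIGNER.extend_gap_score = -2.0


@dataclass
class FrameshiftCall:
    family_id: str
    genome_id: str
    tract: HomopolymerTract
    indel_sign: int  # +1 insertion, -1 deletion relative to reference
    downstream_in_frame: bool
    cds_indel_pos: int  # position of the indel within the CDS
    aligned_pos: int  # reference coordinate of the indel (for sharing)


@dataclass
class EventRow:
    family_id: str
    branch_id: str
    event: str  # LOSS | EROSION | FRAMESHIFT
    convergent: bool = False


@dataclass
class EventTable:
    rows: list[EventRow] = field(default_factory=list)

    def for_family(self, family_id: str) -> list[EventRow]:
        return [r for r in self.rows if r.family_id == family_id]

    def to_tsv(self) -> str:
        lines = ["family_id\tbranch_id\tevent\tconvergent"]
        for r in self.rows:
            lines.append(f"{r.family_id}\t{r.branch_id}\t{r.event}\t"
                         f"{int(r.convergent)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Per-genome gene-state classification
# ---------------------------------------------------------------------------

def _gap_runs(aligned_ref: str, aligned_qry: str):
    """(start_col, length, which) runs of gap columns; which='ref'/'qry'."""
    runs = []
    i = 0
    n = len(aligned_ref)
    while i < n:
        if aligned_ref[i] == "-":
            j = i
            while j < n and aligned_ref[j] == "-":
                j += 1
            runs.append((i, j - i, "ref"))
            i = j
        elif aligned_qry[i] == "-":
            j = i
            while j < n and aligned_qry[j] == "-":
                j += 1
            runs.append((i, j - i, "qry"))
            i = j
        else:
            i += 1
    return runs


def _tract_at(seq: str, pos: int, base: str) -> HomopolymerTract | None:
    """The maximal run of ``base`` touching ``pos`` in ``seq``, if any."""
    if not (0 <= pos <= len(seq)):
        return None
    s = pos
    while s > 0 and seq[s - 1] == base:
        s -= 1
    e = pos
    while e < len(seq) and seq[e] == base:
        e += 1
    if e == s:
        return None
    return HomopolymerTract(base, s, e - s)


def _has_internal_stop(cds: str) -> bool:
    aa = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    return "*" in aa[:-1]


@dataclass
class StateCall:
    state: str
    frameshift: FrameshiftCall | None = None


def classify_cds_state(family_id: str, genome_id: str, cds: str,
                       ref_cds: str, min_tract: int = 7,
                       truncation_fraction: float = 0.60) -> StateCall:
    """Classify one annotated CDS against an intact reference ortholog.

    FRAMESHIFT_SLIPPAGE requires exactly one 1-bp indel located inside a
    homopolymer tract of at least ``min_tract`` bp whose conceptual
    correction restores a full-length, internally stop-free reading frame.
    PSEUDOGENE: two or more frame-disrupting indels, an internal stop not
    attributable to a single tract indel, or aligned length below
    ``truncation_fraction`` of the reference.  Otherwise INTACT.
    """
    if len(cds) < truncation_fraction * len(ref_cds):
        return StateCall(PSEUDOGENE)

    # A codon-multiple length with a clean translation is intact: pairwise
    # nucleotide alignments at appreciable divergence can invent
    # compensating gap pairs, so the reading frame itself is the arbiter.
    if len(cds) % 3 == 0:
        if _has_internal_stop(cds):
            return StateCall(PSEUDOGENE)
        return StateCall(INTACT)

    aln = _NT_ALIGNER.align(ref_cds, cds)[0]
    a_ref, a_qry = str(aln[0]), str(aln[1])
    runs = _gap_runs(a_ref, a_qry)
    frame_runs = [r for r in runs if r[1] % 3 != 0]

    if len(frame_runs) == 1 and frame_runs[0][1] == 1:
        col, _, which = frame_runs[0]
        qry_pos = col - a_qry[:col].count("-")
        ref_pos = col - a_ref[:col].count("-")
        # The indel must sit in a polyA/polyT tract; the alignment may slide
        # a gap to the tract edge, so both tract bases are tried and the
        # tract is located by touching the indel position in either
        # sequence.
        best: tuple[int, str, HomopolymerTract] | None = None
        for b in "AT":
            t_q = _tract_at(cds, qry_pos, b)
            t_r = _tract_at(ref_cds, ref_pos, b)
            tlen = max(t.length if t else 0 for t in (t_q, t_r))
            if tlen < min_tract or t_q is None:
                continue
            if best is None or tlen > best[0]:
                best = (tlen, b, t_q)
        if best is not None:
            _, base, tract = best
            p = tract.start
            sign = +1 if which == "ref" else -1
            if sign == +1:  # query carries an inserted base: remove one
                corrected = cds[:p] + cds[p + 1 :]
            else:  # query lost a base: re-insert the tract base
                corrected = cds[:p] + base + cds[p:]
            if not _has_internal_stop(corrected):
                call = FrameshiftCall(
                    family_id, genome_id,
                    HomopolymerTract(base, tract.start, tract.length),
                    sign, True, p, ref_pos)
                return StateCall(FRAMESHIFT_SLIPPAGE, call)

    # the aligner may scatter a single net 1-bp indel across compensating
    # gaps; fall back to direct tract-by-tract correction, anchored to the
    # aligned gap positions so an unrelated distant tract cannot rescue a
    # genuinely eroded gene
    gap_qry_positions = [col - a_qry[:col].count("-") for col, _, _ in runs]
    rescue = self_rescue_frameshift(family_id, genome_id, cds,
                                    min_tract=min_tract,
                                    near_positions=gap_qry_positions)
    if rescue is not None:
        return StateCall(FRAMESHIFT_SLIPPAGE, rescue[1])
    return StateCall(PSEUDOGENE)


def self_rescue_frameshift(family_id: str, genome_id: str, cds: str,
                           min_tract: int = 7,
                           near_positions: list[int] | None = None,
                           tolerance: int = 15,
                           ) -> tuple[str, FrameshiftCall] | None:
    """Reference-free recognition of a single slippage indel.

    For a CDS whose length is not a codon multiple, try undoing one 1-bp
    indel inside each polyA/polyT tract of at least ``min_tract`` bp; if
    exactly that correction yields a clean full-length reading frame
    (ATG ... stop, no internal stop) the gene is called
    FRAMESHIFT_SLIPPAGE without needing an intact ortholog — the situation
    of a family whose only surviving member is itself frameshifted.
    Returns (corrected_cds, call) or None.
    """
    rem = len(cds) % 3
    if rem == 0:
        return None
    sign = +1 if rem == 1 else -1  # one extra base vs one missing base
    i = 0
    while i < len(cds):
        j = i
        while j < len(cds) and cds[j] == cds[i]:
            j += 1
        run_len = j - i
        anchored = near_positions is None or any(
            i - tolerance <= p <= j + tolerance for p in near_positions)
        if anchored and cds[i] in "AT" and run_len >= min_tract \
                and i >= 3 and j < len(cds) - 3:
            if sign == +1:
                corrected = cds[:i] + cds[i + 1 :]
            else:
                corrected = cds[:i] + cds[i] + cds[i:]
            aa_ok = (corrected.startswith("ATG")
                     and corrected[-3:] in ("TAA", "TAG", "TGA")
                     and not _has_internal_stop(corrected))
            if aa_ok:
                call = FrameshiftCall(
                    family_id, genome_id,
                    HomopolymerTract(cds[i], i, run_len), sign, True, i, i)
                return corrected, call
        i = j
    return None


def _sixframe(seq: str) -> list[str]:
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off:]
            sub = sub[: len(sub) // 3 * 3]
            if sub:
                frames.append(str(Seq(sub).translate()))
    return frames


def scan_igs_for_relict(region: str, ref_protein: str,
                        min_coverage: float = 0.60,
                        max_e: float = 1e-5) -> bool:
    """True if an intergenic region retains detectable homology to a protein.

    The reference protein is aligned against all six conceptual translation
    frames of the region; the hit is judged by the same coverage/e-value
    rule as the gene-content screen.  Used to distinguish an eroded but
    recognisable pseudogene relict from outright absence.
    """
    if len(region) < 9 or not ref_protein:
        return False
    for frame in _sixframe(region):
        if len(frame) < 5:
            continue
        hit = align_proteins(frame, ref_protein)
        if classify_hit(hit, min_coverage=min_coverage, max_e=max_e) == "present":
            return True
    return False


def assign_gene_state(family: OrthologFamily, genome: GenomeRecord,
                      reference_cds: str | None, igs_region: str | None = None,
                      min_tract: int = 7) -> StateCall:
    """Gene state of one family in one genome.

    ABSENT when the genome has no locus for the family and the
    corresponding intergenic region (if supplied) shows no residual
    homology; PSEUDOGENE when the annotation says so, when the region only
    holds an eroded relict, or when the CDS fails the intactness rules;
    FRAMESHIFT_SLIPPAGE / INTACT per :func:`classify_cds_state`.
    """
    locus = family.locus(genome.id)
    if locus is None:
        if igs_region and reference_cds:
            ref_prot = str(Seq(reference_cds).translate()).rstrip("*")
            if scan_igs_for_relict(igs_region, ref_prot):
                return StateCall(PSEUDOGENE)
        return StateCall(ABSENT)
    feat = genome.feature_by_locus(locus)
    if feat.kind == "pseudogene":
        return StateCall(PSEUDOGENE)
    if feat.kind != "CDS" or reference_cds is None:
        return StateCall(INTACT)
    cds = feat.extract(genome.sequence)
    if cds == reference_cds:
        return StateCall(INTACT)
    return classify_cds_state(family.family_id, genome.id, cds,
                              reference_cds, min_tract=min_tract)


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

class RootedTree:
    """Thin wrapper over a dendropy rooted tree with stable branch ids.

    Each non-root node defines the branch above it; leaf branches are named
    by the taxon label, internal branches by the sorted '+'-joined labels
    of the subtree's leaves.
    """

    def __init__(self, newick: str):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.tree.is_rooted = True
        self.branch_of: dict = {}
        for node in self.tree.preorder_node_iter():
            leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
            node.branch_id = leaves[0] if node.is_leaf() else "+".join(leaves)
        self.leaf_labels = sorted(t.label for t in self.tree.taxon_namespace)

    def branch_ids(self) -> list[str]:
        return [n.branch_id for n in self.tree.preorder_node_iter()
                if n.parent_node is not None]

    def path_branches(self, leaf_label: str) -> list[str]:
        """Branch ids on the path from the root to a leaf."""
        node = next(lf for lf in self.tree.leaf_node_iter()
                    if lf.taxon.label == leaf_label)
        out = []
        while node.parent_node is not None:
            out.append(node.branch_id)
            node = node.parent_node
        return out[::-1]

    def mrca_stem(self, leaf_labels: set[str]) -> str | None:
        """Branch id above the MRCA of the labels, if they form a clade."""
        node = self.tree.mrca(taxon_labels=sorted(leaf_labels))
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        if clade != set(leaf_labels) or node.parent_node is None:
            return None
        return node.branch_id


def dollo_reconstruct(states: dict[str, str], tree: RootedTree,
                      family_id: str = "") -> tuple[bool, list[EventRow]]:
    """Minimal loss/erosion scenario for one family under Dollo parsimony.

    ``states`` maps leaf label to a gene state; FRAMESHIFT_SLIPPAGE counts
    as functionally intact.  Gains are forbidden, severity can only
    increase root-to-leaf, and each state change on a branch is one event
    (to PSEUDOGENE: EROSION; to ABSENT: LOSS).  Among minimal solutions
    ties go to later, leafward event placement.  Returns (ancestor present,
    event rows).
    """
    sev = {label: SEVERITY[s] for label, s in states.items()}
    INF = math.inf

    # Sankoff DP over severity states 0 <= 1 <= 2, cost 1 per increase step
    cost: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s = sev[node.taxon.label]
            cost[node] = [0 if k == s else INF for k in range(3)]
        else:
            c = [0.0, 0.0, 0.0]
            for child in node.child_nodes():
                cc = cost[child]
                for k in range(3):
                    c[k] += min(cc[t] + (1 if t != k else 0)
                                for t in range(3) if t >= k)
            cost[node] = c

    root = tree.tree.seed_node
    # leafward tie-break: keep ancestors as intact as possible
    root_state = min(range(3), key=lambda k: (cost[root][k], k))
    assign = {root: root_state}
    events: list[EventRow] = []
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        k = assign[node.parent_node]
        best = min((cost[node][t] + (1 if t != k else 0), t)
                   for t in range(3) if t >= k)
        t = best[1]
        assign[node] = t
        if t != k:
            ev = EROSION if t == 1 else LOSS
            events.append(EventRow(family_id, node.branch_id, ev))
    ancestor_present = root_state < 2
    return ancestor_present, events


def _same_inherited_indel(cds_a: str, cds_b: str) -> bool:
    """True when two frameshifted orthologs carry the same inherited indel.

    Both sequences then have identical length and align with no
    frame-disrupting gaps between each other (each carries the indel at the
    same inherited position); two independent indels at different tracts
    leave a compensating gap pair in their pairwise alignment.
    """
    if len(cds_a) != len(cds_b):
        return False
    aln = _NT_ALIGNER.align(cds_a, cds_b)[0]
    runs = _gap_runs(str(aln[0]), str(aln[1]))
    return not any(r[1] % 3 for r in runs)


def place_frameshift_events(calls: list[FrameshiftCall], tree: RootedTree,
                            position_tolerance: int = 6,
                            carrier_cds: dict | None = None,
                            ) -> list[EventRow]:
    """Map per-genome frameshift calls onto branches.

    Calls in different genomes whose indels fall in the same tract (their
    reference positions agree to within the tract length plus
    ``position_tolerance`` bp — the aligner may slide a 1-bp gap anywhere
    inside the homopolymer) are treated as one inherited event placed on
    the stem branch of the smallest clade holding all carriers, when the
    carriers form a clade; otherwise, and for genome-private calls, the
    event sits on the leaf branch.
    """
    out: list[EventRow] = []
    by_family: dict[str, list[FrameshiftCall]] = {}
    for c in calls:
        by_family.setdefault(c.family_id, []).append(c)
    for fam, fam_calls in sorted(by_family.items()):
        groups: list[list[FrameshiftCall]] = []
        for c in sorted(fam_calls, key=lambda c: c.aligned_pos):
            prev = groups[-1][-1] if groups else None
            shared = False
            if prev is not None and prev.indel_sign == c.indel_sign:
                near = abs(prev.aligned_pos - c.aligned_pos) <= (
                    max(prev.tract.length, c.tract.length)
                    + position_tolerance)
                if near:
                    shared = True
                elif carrier_cds is not None:
                    # the aligner may have parked one call's gap at a
                    # different nearby tract; compare the carriers directly
                    a = carrier_cds.get((fam, prev.genome_id))
                    b = carrier_cds.get((fam, c.genome_id))
                    shared = (a is not None and b is not None
                              and _same_inherited_indel(a, b))
            if shared:
                groups[-1].append(c)
            else:
                groups.append([c])
        for grp in groups:
            carriers = {c.genome_id for c in grp}
            branch = None
            if len(carriers) > 1:
                branch = tree.mrca_stem(carriers)
            if branch is not None:
                out.append(EventRow(fam, branch, FRAMESHIFT))
            else:
                for gid in sorted(carriers):
                    out.append(EventRow(fam, gid, FRAMESHIFT))
    return out


def flag_convergent(events: list[EventRow], tree: RootedTree) -> None:
    """Set ``convergent`` on families with events on incomparable branches."""
    anc: dict[str, set[str]] = {}
    for leaf in tree.leaf_labels:
        path = tree.path_branches(leaf)
        for i, b in enumerate(path):
            anc.setdefault(b, set()).update(path[: i + 1])

    def comparable(b1: str, b2: str) -> bool:
        return b1 in anc.get(b2, set()) or b2 in anc.get(b1, set())

    by_family: dict[str, list[EventRow]] = {}
    for r in events:
        by_family.setdefault(r.family_id, []).append(r)
    for rows in by_family.values():
        conv = any(not comparable(a.branch_id, b.branch_id)
                   for a, b in combinations(rows, 2))
        if conv:
            for r in rows:
                r.convergent = True


def summarize_events(table: EventTable, tree: RootedTree) -> dict:
    """Per-lineage missing-or-eroded counts and the convergent gene list.

    A family counts as missing-or-eroded in a terminal lineage when it has
    at least one LOSS or EROSION event anywhere on the path from the root
    to that leaf (shared stem events count in every descendant lineage).
    """
    per_lineage = {}
    for leaf in tree.leaf_labels:
        path = set(tree.path_branches(leaf))
        fams = {r.family_id for r in table.rows
                if r.event in (LOSS, EROSION) and r.branch_id in path}
        per_lineage[leaf] = len(fams)
    per_branch: dict[str, int] = {}
    for r in table.rows:
        if r.event in (LOSS, EROSION):
            per_branch[r.branch_id] = per_branch.get(r.branch_id, 0) + 1
    convergent = sorted({r.family_id for r in table.rows if r.convergent})
    return {
        "missing_or_eroded_per_lineage": per_lineage,
        "events_per_branch": per_branch,
        "convergent_families": convergent,
    }


# ---------------------------------------------------------------------------
# Deletion hotspot scan
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    window_start: int
    window_end: int
    n_missing_in_window: int
    n_missing_total: int
    p_perm: float
    near_origin: bool = False


def _window_counts(positions: np.ndarray, starts: np.ndarray, window: int,
                   genome_length: int) -> np.ndarray:
    """Missing-gene counts of circular windows [start, start+window)."""
    pos = np.sort(positions % genome_length)
    ext = np.concatenate([pos, pos + genome_length])
    lo = np.searchsorted(ext, starts)
    hi = np.searchsorted(ext, starts + window)
    return hi - lo


def hotspot_scan(missing_positions, genome_length: int, window: int = 32_000,
                 n_perm: int = 9_999, seed: int = 0, step: int | None = None,
                 origin_pos: int | None = None,
                 alpha: float = 0.05) -> list[HotspotResult]:
    """Circular scan for clusters of missing genes with a permutation null.

    Windows of ``window`` bp slide every ``step`` bp (window/16 by
    default).  The null re-places the same number of positions uniformly on
    the circle; each window's p-value is the fraction of permutations whose
    *maximum* window count reaches the observed count, so the scan is
    corrected for having searched every window.  Overlapping windows at
    p < ``alpha`` are merged; a merged window gets ``near_origin`` when it
    lies within ``window`` bp of a supplied origin position.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    if window >= genome_length:
        raise ValueError("window must be smaller than the genome")
    positions = np.asarray(sorted(missing_positions), dtype=np.int64)
    n = len(positions)
    if n == 0:
        return []
    step = step or max(1, window // 16)
    starts = np.arange(0, genome_length, step)
    obs = _window_counts(positions, starts, window, genome_length)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        sim = rng.integers(0, genome_length, size=n)
        null_max[i] = _window_counts(sim, starts, window, genome_length).max()

    results: list[HotspotResult] = []
    sig: list[tuple[int, int, int, float]] = []
    for s, c in zip(starts, obs):
        if c == 0:
            continue
        p = (1 + int((null_max >= c).sum())) / (1 + n_perm)
        if p < alpha:
            sig.append((int(s), int(s) + window, int(c), p))
    # merge overlapping significant windows, keep the best p / max count
    sig.sort()
    merged: list[list] = []
    for s, e, c, p in sig:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], c)
            merged[-1][3] = min(merged[-1][3], p)
        else:
            merged.append([s, e, c, p])
    for s, e, c, p in merged:
        near = False
        if origin_pos is not None:
            d = min((s - origin_pos) % genome_length,
                    (origin_pos - e) % genome_length)
            near = (s - window <= origin_pos <= e + window) or d <= window
        results.append(HotspotResult(s, e, c, n, p, near))
    results.sort(key=lambda r: (r.p_perm, -r.n_missing_in_window))
    return results


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # exact | normal_approx


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def rank_sum_test(x, y, exact_limit: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic W is the sum of (mid)ranks of the first sample in the
    pooled ordering.  For n1+n2 <= ``exact_limit`` the null distribution is
    enumerated exactly over all C(N, n1) rank assignments (ties handled by
    midranks) and p = min(1, 2*min(P(W<=w), P(W>=w))).  Larger samples use
    the normal approximation with tie correction and continuity
    correction.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = x + y
    ranks = _midranks(pooled)
    w = sum(ranks[:n1])
    N = n1 + n2
    if len(set(pooled)) == 1:
        return RankSumResult(w, n1, n2, 1.0, "exact")
    if N <= exact_limit:
        lo = hi = 0
        total = 0
        eps = 1e-9
        for idx in combinations(range(N), n1):
            ws = sum(ranks[i] for i in idx)
            total += 1
            if ws <= w + eps:
                lo += 1
            if ws >= w - eps:
                hi += 1
        p = min(1.0, 2 * min(lo, hi) / total)
        return RankSumResult(w, n1, n2, p, "exact")
    mean = n1 * (N + 1) / 2
    tie_counts = {}
    for r in ranks:
        tie_counts[r] = tie_counts.get(r, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values())
    var = n1 * n2 / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return RankSumResult(w, n1, n2, 1.0, "normal_approx")
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2 * (1 - _phi(z)))
    return RankSumResult(w, n1, n2, max(p, 0.0), "normal_approx")


def _phi(z: float) -> float:
    return 0.5 * (1 + math.erf(z / math.sqrt(2)))


# ---------------------------------------------------------------------------
# IGS classes
# ---------------------------------------------------------------------------

def igs_classify_and_compare(igs_by_genome: dict[str, list[IgsRecord]],
                             spanning_loci: dict[str, set[tuple[str, str]]],
                             ) -> dict:
    """Median IGS lengths by class and rank-sum comparisons.

    ``spanning_loci[genome]`` holds (left_locus, right_locus) pairs that
    bracket at least one gene absent from this genome but present in
    another (computed by the pipeline from the ortholog table).  Spacers
    matching such a pair are the 'spanning' class; all others are the
    'conserved' class.  Returns per-genome class medians, the within-genome
    spanning-vs-conserved test, and cross-genome spanning-vs-spanning
    tests.
    """
    out: dict = {"per_genome": {}, "cross_genome": {}}
    spanning_lengths: dict[str, list[int]] = {}
    for gid, igs in igs_by_genome.items():
        marked = spanning_loci.get(gid, set())
        span, cons = [], []
        for r in igs:
            if (r.left_locus, r.right_locus) in marked:
                r.spans_missing = True
                span.append(r.length)
            else:
                cons.append(r.length)
        spanning_lengths[gid] = span
        entry: dict = {
            "n_spanning": len(span),
            "n_conserved": len(cons),
            "median_spanning": float(np.median(span)) if span else None,
            "median_conserved": float(np.median(cons)) if cons else None,
        }
        if span and cons:
            t = rank_sum_test(span, cons)
            entry["rank_sum"] = t
        out["per_genome"][gid] = entry
    for ga, gb in combinations(sorted(spanning_lengths), 2):
        sa, sb = spanning_lengths[ga], spanning_lengths[gb]
        if sa and sb:
            out["cross_genome"][(ga, gb)] = rank_sum_test(sa, sb)
    return out
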