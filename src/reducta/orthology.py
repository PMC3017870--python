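"""Cross-genome gene correspondence.

Reciprocal-best-hit (RBH) ortholog assignment between annotated genomes,
optionally reinforced by the strict gene-order conservation typical of
reduced endosymbiont genomes (hybrid mode), plus the coverage/e-value
homology screen and the tRNA pseudogene re-evaluation rule.

Protein similarity is scored by Smith-Waterman local alignment with
BLOSUM62 and affine gaps (open 11, extend 1), with an e-value-like
Karlin-Altschul statistic used purely as a ranking and filtering device.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_io import GenomeRecord

log = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

# ungapped Karlin-Altschul constants for BLOSUM62
_KA_LAMBDA = 0.267
_KA_K = 0.041

ABSENT = "ABSENT"


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    if mode == "global":
        # do not penalise terminal gaps so fragments align in place
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_LOCAL = _make_aligner("local")


@dataclass
class SimilarityHit:
    query_locus: str
    subject_locus: str
    score: float
    subject_coverage: float
    evalue_like: float


_SANITIZE_RX = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYBZX*]")


def _sanitize(seq: str) -> str:
    # PairwiseAligner rejects letters outside the matrix alphabet
    seq = seq.upper()
    return _SANITIZE_RX.sub("X", seq)


def align_proteins(a: str, b: str, query_locus: str = "a",
                   subject_locus: str = "b") -> SimilarityHit:
    """Local protein alignment summarised as a similarity hit.

    ``subject_coverage`` is the fraction of the subject (second) sequence
    inside the aligned block; ``evalue_like`` is K*m*n*exp(-lambda*S) with
    fixed BLOSUM62 constants — adequate for thresholding at the coarse
    cutoffs used in homology screens, with no claim of BLAST bit-exactness.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    a, b = _sanitize(a), _sanitize(b)
    alns = _LOCAL.align(a, b)
    score = alns.score
    if score <= 0:
        return SimilarityHit(query_locus, subject_locus, 0.0, 0.0, math.inf)
    aln = alns[0]
    sub_aligned = sum(e - s for s, e in aln.aligned[1])
    coverage = sub_aligned / len(b)
    evalue = _KA_K * len(a) * len(b) * math.exp(-_KA_LAMBDA * score)
    return SimilarityHit(query_locus, subject_locus, float(score), coverage,
                         evalue)


def sw_score(a: str, b: str) -> float:
    """Raw Smith-Waterman score only (no traceback)."""
    return _LOCAL.score(_sanitize(a), _sanitize(b))


# ---------------------------------------------------------------------------
# k-mer prescreen + reciprocal best hits
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def reciprocal_best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                         prescreen_min_kmers: int | None = 10,
                         positions_a: dict[str, int] | None = None,
                         positions_b: dict[str, int] | None = None,
                         ) -> list[tuple[str, str]]:
    """Reciprocal best hits between two locus->protein maps.

    A pair (a, b) is reported iff b is a's highest-scoring subject and a is
    b's.  Score ties are broken by closest positional index when gene-order
    indices are supplied, then by lexical locus order.  A shared-4-mer
    prescreen (``prescreen_min_kmers`` shared 4-mers required before a pair
    is aligned) keeps all-vs-all cost down on genome-scale proteomes; pass
    ``None`` to align every pair.
    """
    loci_a = sorted(proteome_a)
    loci_b = sorted(proteome_b)
    if prescreen_min_kmers is not None:
        kb = {lb: _kmers(proteome_b[lb]) for lb in loci_b}
    by_query: dict[str, list[tuple[str, float]]] = {}
    by_subject: dict[str, list[tuple[str, float]]] = {}
    for la in loci_a:
        sa = proteome_a[la]
        if prescreen_min_kmers is not None:
            ka = _kmers(sa)
            cands = [lb for lb in loci_b
                     if len(ka & kb[lb]) >= prescreen_min_kmers]
        else:
            cands = loci_b
        for lb in cands:
            s = sw_score(sa, proteome_b[lb])
            if s > 0:
                by_query.setdefault(la, []).append((lb, s))
                by_subject.setdefault(lb, []).append((la, s))

    def tiebreak(locus: str, positions: dict[str, int] | None,
                 other_positions: dict[str, int] | None, anchor: str):
        def key(cand_and_score):
            cand, s = cand_and_score
            dist = 0
            if positions is not None and other_positions is not None:
                dist = abs(other_positions.get(cand, 0)
                           - positions.get(anchor, 0))
            return (-s, dist, cand)
        return key

    best_ab: dict[str, str] = {}
    for la, cand in by_query.items():
        best_ab[la] = min(
            cand, key=tiebreak(la, positions_a, positions_b, la))[0]
    best_ba: dict[str, str] = {}
    for lb, cand in by_subject.items():
        best_ba[lb] = min(
            cand, key=tiebreak(lb, positions_b, positions_a, lb))[0]
    pairs = [(la, lb) for la, lb in best_ab.items()
             if best_ba.get(lb) == la]
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------

@dataclass
class OrthologFamily:
    family_id: str
    members: dict[str, str]  # genome id -> locus tag (missing genome = absent)
    positions: dict[str, int] = field(default_factory=dict)

    def locus(self, genome_id: str) -> str | None:
        return self.members.get(genome_id)


@dataclass
class OrthologTable:
    genome_ids: list[str]
    families: list[OrthologFamily]

    def to_tsv(self) -> str:
        header = "family_id\t" + "\t".join(self.genome_ids)
        lines = [header]
        for fam in self.families:
            cells = [fam.members.get(g, ABSENT) for g in self.genome_ids]
            lines.append(fam.family_id + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"

    def family_by_id(self, family_id: str) -> OrthologFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)


def proteome_of(record: GenomeRecord) -> dict[str, str]:
    """Translations of annotated CDS (first-stop truncated, no terminal *)."""
    out = {}
    for f in record.cds_features():
        nt = f.extract(record.sequence)
        aa = str(Seq(nt[: len(nt) // 3 * 3]).translate())
        aa = aa.split("*")[0] if "*" in aa else aa
        if aa:
            out[f.locus_tag] = aa
    return out


def gene_positions(record: GenomeRecord) -> dict[str, int]:
    """Rank of each gene along the genome (gene-order index)."""
    return {f.locus_tag: i for i, f in enumerate(record.features)}


def _merge_pairwise(genome_ids, pairs_by_pair):
    """Single-linkage merge of pairwise RBH graphs into families."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for (ga, gb), pairs in pairs_by_pair.items():
        for la, lb in pairs:
            union((ga, la), (gb, lb))
    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in list(parent):
        groups.setdefault(find(node), []).append(node)
    return list(groups.values())


def build_ortholog_table(genomes: list[GenomeRecord], mode: str = "hybrid",
                         prescreen_min_kmers: int | None = 10) -> OrthologTable:
    """Merge pairwise RBH graphs into an ortholog table.

    ``mode='rbh'`` uses reciprocal best hits only.  ``mode='hybrid'``
    (default, appropriate when gene order is conserved) additionally
    assigns loci the RBH pass left unmatched to families whose gene-order
    neighbourhood brackets them, and is the mode the reduction pipeline
    uses.  Inconsistent RBH triangles (two loci of one genome pulled into
    one family) are split back into consistent subfamilies and logged.
    Non-CDS genes (tRNA/rRNA/other RNA) are matched by gene name across
    genomes.  Loci that remain unmatched become singleton families.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if mode not in ("rbh", "synteny", "hybrid"):
        raise ValueError(f"unknown mode {mode!r}")
    gids = [g.id for g in genomes]
    by_id = {g.id: g for g in genomes}
    proteomes = {g.id: proteome_of(g) for g in genomes}
    positions = {g.id: gene_positions(g) for g in genomes}

    pairs_by_pair = {}
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            ga, gb = gids[i], gids[j]
            pairs_by_pair[(ga, gb)] = reciprocal_best_hits(
                proteomes[ga], proteomes[gb], prescreen_min_kmers,
                positions[ga], positions[gb])

    groups = _merge_pairwise(gids, pairs_by_pair)

    families: list[OrthologFamily] = []
    counter = 0

    def new_family(members: dict[str, str]) -> None:
        nonlocal counter
        counter += 1
        pos = {g: positions[g][l] for g, l in members.items()}
        families.append(OrthologFamily(f"F{counter:05d}", members, pos))

    for group in groups:
        members: dict[str, list[str]] = {}
        for gid, locus in group:
            members.setdefault(gid, []).append(locus)
        if all(len(v) == 1 for v in members.values()):
            new_family({g: v[0] for g, v in members.items()})
        else:
            log.warning("inconsistent RBH triangle split: %s", group)
            for gid, loci in members.items():
                for locus in loci:
                    new_family({gid: locus})

    # RNA genes and pseudogenes: match by gene name (annotation-level identity)
    named: dict[tuple[str, str], dict[str, str]] = {}
    assigned = {(g, l) for fam in families for g, l in fam.members.items()}
    for g in genomes:
        for f in g.features:
            if f.kind == "CDS" or not f.gene_name:
                continue
            named.setdefault((f.kind, f.gene_name), {})[g.id] = f.locus_tag
    for (_kind, _name), members in sorted(named.items()):
        new_family(members)
        assigned |= {(g, l) for g, l in members.items()}

    # leftover loci become singleton families
    for g in genomes:
        for f in g.features:
            if (g.id, f.locus_tag) not in assigned:
                new_family({g.id: f.locus_tag})
                assigned.add((g.id, f.locus_tag))

    if mode in ("hybrid", "synteny"):
        seqs = {(g.id, f.locus_tag): f.extract(g.sequence)
                for g in genomes for f in g.features}
        _merge_syntenic_families(families, seqs)

    families.sort(key=lambda fam: min(fam.positions.values(), default=10**9))
    for i, fam in enumerate(families, 1):
        fam.family_id = f"F{i:05d}"
    return OrthologTable(gids, families)


_NT_LOCAL = Align.PairwiseAligner()
_NT_LOCAL.mode = "local"
_NT_LOCAL.match_score = 2.0
_NT_LOCAL.mismatch_score = -3.0
_NT_LOCAL.open_gap_score = -7.0
_NT_LOCAL.extend_gap_score = -2.0


def _merge_syntenic_families(families: list[OrthologFamily],
                             seqs: dict[tuple[str, str], str]) -> None:
    """Merge families split by sequence-level divergence using gene order.

    A family can fracture when every homology signal between two genome
    subsets is degraded (e.g. a frameshift near the start codon garbles
    both translations).  Two families with disjoint genome sets whose
    member positions fall between the same bracketing neighbour families
    describe the same locus and are merged — provided their nucleotide
    sequences still align well locally, so an eroded *neighbouring* gene
    sitting in the same bracket (position alone is ambiguous when two
    adjacent families both lack the genome) cannot be absorbed into the
    wrong family.
    """
    changed = True
    passes = 0
    while changed and passes < 4:
        changed = False
        passes += 1
        for a in list(families):
            if a not in families:
                continue
            for g in {g for b in families for g in b.members} - set(a.members):
                ref_gid = next(iter(a.members))
                ref_pos = a.positions[ref_gid]
                lo = hi = None
                for other in families:
                    if other is a or g not in other.members \
                            or ref_gid not in other.members:
                        continue
                    p = other.positions[ref_gid]
                    if p < ref_pos and (lo is None or p > lo[0]):
                        lo = (p, other.positions[g])
                    if p > ref_pos and (hi is None or p < hi[0]):
                        hi = (p, other.positions[g])
                if lo is None or hi is None:
                    continue
                cands = [b for b in families
                         if b is not a
                         and not (set(b.members) & set(a.members))
                         and g in b.members
                         and lo[1] < b.positions[g] < hi[1]]
                cands = [b for b in cands
                         if _nt_similar(seqs[(ref_gid, a.members[ref_gid])],
                                        seqs[(g, b.members[g])])]
                if len(cands) == 1:
                    b = cands[0]
                    a.members.update(b.members)
                    a.positions.update(b.positions)
                    families.remove(b)
                    changed = True
                    log.info("merged split families at %s/%s",
                             a.family_id, b.family_id)


def _nt_similar(a: str, b: str) -> bool:
    """Local nucleotide similarity well above the AT-rich random background.

    Random AT-biased pairs reach local scores of a few tens (negative
    drift); homologous genes at the divergences where family fracture
    happens score near 1-2 per base, so half the maximal score of the
    shorter sequence separates the two cleanly.
    """
    if not a or not b:
        return False
    score = _NT_LOCAL.score(a, b)
    return score >= 0.5 * min(len(a), len(b))


# ---------------------------------------------------------------------------
# Screen rules
# ---------------------------------------------------------------------------

def classify_hit(hit: SimilarityHit, min_coverage: float = 0.60,
                 max_e: float = 1e-5,
                 exceptions: dict[str, float] | None = None) -> str:
    """Presence call from a homology hit.

    A gene is ``present`` iff the alignment covers at least ``min_coverage``
    of the subject protein and the e-value-like statistic is below
    ``max_e``.  ``exceptions`` maps gene/locus names to a relaxed per-gene
    coverage threshold (the screen's ftsY-style exemption).
    """
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    threshold = min_coverage
    if exceptions:
        threshold = exceptions.get(hit.subject_locus, min_coverage)
    ok = hit.subject_coverage >= threshold and hit.evalue_like < max_e
    return "present" if ok else "absent"


def classify_trna(primary_score: float, secondary_score: float,
                  primary_cutoff: float = 10.0,
                  secondary_cutoff: float = 5.0) -> str:
    """tRNA pseudogene call with the AT-bias rescue.

    A tRNA is flagged as a potential pseudogene when the primary-structure
    (HMM) score is below 10 bits or the secondary-structure score below
    5 bits; extreme AT bias depresses primary scores of perfectly folded
    tRNAs, so a flagged tRNA is rescued to functional whenever its
    secondary-structure score clears the 5-bit cutoff.
    """
    flagged = primary_score < primary_cutoff or secondary_score < secondary_cutoff
    if not flagged:
        return "functional"
    return "functional" if secondary_score >= secondary_cutoff else "flagged_pseudo"
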