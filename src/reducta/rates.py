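"""Nonsynonymous rate analysis on ortholog triads.

Codon-aware alignment of orthologous CDS, pairwise nonsynonymous distance
dN by Nei-Gojobori (1986) counting with Jukes-Cantor correction, additive
three-point decomposition of the pairwise distances into the two branch
lengths K1 and K2 since the ingroup pair's common ancestor, and the
per-gene fold-increase statistic K1/K2.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from itertools import permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STOPS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
BASES = "ACGT"

_PROT_ALIGNER = Align.PairwiseAligner()
_PROT_ALIGNER.mode = "global"
_PROT_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_PROT_ALIGNER.open_gap_score = -11.0
_PROT_ALIGNER.extend_gap_score = -1.0


def translate(codons: str) -> str:
    return str(Seq(codons).translate())


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    family_id: str
    sequences: dict[str, str]  # genome id -> gap-padded codon sequence
    frameshift_corrected: bool = False

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return self.sequences[a], self.sequences[b]


def codon_align(family_id: str, cds: dict[str, str],
                frameshift_corrected: bool = False) -> CodonAlignment:
    """Protein-level multiple alignment back-translated to codons.

    Each CDS must already be in frame (single-indel tract frameshifts
    corrected beforehand).  Terminal stop codons are stripped; an internal
    stop raises ``ValueError`` so callers can exclude the family from rate
    estimation.  Alignment is progressive against the longest member using
    global Needleman-Wunsch on the translations (BLOSUM62, affine gaps).
    """
    clean: dict[str, str] = {}
    for gid, seq in cds.items():
        seq = seq[: len(seq) // 3 * 3]
        if seq[-3:] in STOPS:
            seq = seq[:-3]
        aa = translate(seq)
        if "*" in aa:
            raise ValueError(f"{family_id}/{gid}: internal stop codon")
        clean[gid] = seq
    ref = max(clean, key=lambda g: len(clean[g]))
    ref_aa = translate(clean[ref])

    # align every member to the reference, then merge on reference columns
    per_member: dict[str, dict[int, str]] = {}  # gid -> ref_col -> codon
    inserts: dict[str, dict[int, str]] = {}
    for gid, seq in clean.items():
        aa = translate(seq)
        aln = _PROT_ALIGNER.align(ref_aa, aa)[0]
        colmap: dict[int, str] = {}
        ins: dict[int, str] = {}
        for (rs, re_), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(re_ - rs):
                colmap[rs + k] = seq[3 * (qs + k) : 3 * (qs + k) + 3]
        per_member[gid] = colmap
        inserts[gid] = ins
    padded = {
        gid: "".join(per_member[gid].get(c, "---")
                     for c in range(len(ref_aa)))
        for gid in clean
    }
    return CodonAlignment(family_id, padded, frameshift_corrected)


def correct_frameshift(cds: str, indel_pos: int, indel_sign: int) -> str:
    """Conceptually undo a single-base slippage indel.

    ``indel_sign`` +1 means the sequence carries an inserted base at
    ``indel_pos`` (remove it); -1 means a deleted base (re-insert a copy of
    the tract base).
    """
    if indel_sign == +1:
        return cds[:indel_pos] + cds[indel_pos + 1 :]
    base = cds[indel_pos] if indel_pos < len(cds) else cds[-1]
    return cds[:indel_pos] + base + cds[indel_pos:]


# ---------------------------------------------------------------------------
# Nei-Gojobori dN
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> float:
    """Nonsynonymous site count of one codon (stops excluded as mutations)."""
    aa = translate(codon)
    n = 0.0
    for i in range(3):
        paths = 0
        nonsyn = 0
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in STOPS:
                continue
            paths += 1
            if translate(mut) != aa:
                nonsyn += 1
        if paths:
            n += nonsyn / paths
    return n


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsyn, syn) differences between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    nd = sd = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = c1
        path_nd = path_sd = 0
        ok = True
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                path_sd += 1
            else:
                path_nd += 1
            cur = nxt
        if ok:
            nd += path_nd
            sd += path_sd
            n_paths += 1
    if n_paths == 0:
        # all pathways pass through a stop; fall back to unweighted count
        return float(len(diff)), 0.0
    return nd / n_paths, sd / n_paths


_SITES_CACHE: dict[str, float] = {}
_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def pairwise_dn(a: str, b: str, min_codons: int = 10) -> float:
    """Nonsynonymous distance between two aligned codon sequences.

    Gapped or ambiguous codon columns are dropped pairwise.  Sites follow
    NG86 (averaged over both sequences), differences are pathway-averaged,
    and the proportion is Jukes-Cantor corrected:
    dN = -(3/4) ln(1 - (4/3) pN).  Returns ``math.inf`` when pN >= 3/4
    (saturation).
    """
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("aligned codon sequences of equal length required")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in STOPS or cb in STOPS:
            continue
        pairs.append((ca, cb))
    if len(pairs) < min_codons:
        raise ValueError(f"fewer than {min_codons} comparable codons")
    n_sites = 0.0
    nd = 0.0
    for ca, cb in pairs:
        for c in (ca, cb):
            if c not in _SITES_CACHE:
                _SITES_CACHE[c] = _codon_sites(c)
        n_sites += (_SITES_CACHE[ca] + _SITES_CACHE[cb]) / 2
        key = (ca, cb) if ca <= cb else (cb, ca)
        if key not in _DIFF_CACHE:
            _DIFF_CACHE[key] = _pair_differences(*key)
        nd += _DIFF_CACHE[key][0]
    p = nd / n_sites if n_sites else 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# Branch decomposition and fold statistics
# ---------------------------------------------------------------------------

@dataclass
class RateTriple:
    family_id: str
    d12: float  # ingroup pair distance
    d13: float  # taxon1 vs outgroup
    d23: float  # taxon2 vs outgroup
    k1: float | None = None
    k2: float | None = None
    clipped: bool = False
    saturated: bool = False

    @property
    def fold(self) -> float | None:
        if self.k1 is None or self.k2 is None or self.k2 <= 0:
            return None
        return self.k1 / self.k2


def branch_decompose(d12: float, d13: float, d23: float) -> tuple[float | None, float | None, bool]:
    """Three-point branch lengths of the ingroup pair given an outgroup.

    For an additive three-taxon tree, K1 = (d12 + d13 - d23)/2 is the
    branch to taxon 1 from its ancestor with taxon 2 and K2 =
    (d12 + d23 - d13)/2 the branch to taxon 2.  Negative solutions
    (triangle-inequality violations from sampling noise) are clipped to 0
    and flagged.  Saturated inputs give (None, None, True).
    """
    if any(map(math.isinf, (d12, d13, d23))):
        return None, None, True
    if min(d12, d13, d23) < 0:
        raise ValueError("distances must be nonnegative")
    k1 = (d12 + d13 - d23) / 2
    k2 = (d12 + d23 - d13) / 2
    clipped = k1 < 0 or k2 < 0
    return max(k1, 0.0), max(k2, 0.0), clipped


def rate_triple(family_id: str, aln: CodonAlignment, taxon1: str, taxon2: str,
                outgroup: str) -> RateTriple:
    """Pairwise dN values and branch decomposition for one family."""
    d12 = pairwise_dn(*aln.pair(taxon1, taxon2))
    d13 = pairwise_dn(*aln.pair(taxon1, outgroup))
    d23 = pairwise_dn(*aln.pair(taxon2, outgroup))
    t = RateTriple(family_id, d12, d13, d23)
    k1, k2, flag = branch_decompose(d12, d13, d23)
    t.k1, t.k2 = k1, k2
    if k1 is None:
        t.saturated = True
    else:
        t.clipped = flag
    return t


def fold_summary(triples: list[RateTriple]) -> dict:
    """Median / range of the defined per-gene fold-increases K1/K2."""
    folds = [t.fold for t in triples if t.fold is not None]
    if not folds:
        raise ValueError("no defined fold values")
    return {
        "n_genes": len(triples),
        "n_defined": len(folds),
        "n_undefined": len(triples) - len(folds),
        "median_fold": statistics.median(folds),
        "min_fold": min(folds),
        "max_fold": max(folds),
    }


def rates_table_tsv(triples: list[RateTriple]) -> str:
    lines = ["family_id\td12\td13\td23\tK1\tK2\tfold\tflags"]
    for t in triples:
        flags = []
        if t.clipped:
            flags.append("clipped")
        if t.saturated:
            flags.append("saturated")
        fold = f"{t.fold:.4f}" if t.fold is not None else "NA"

        def fmt(x):
            return "inf" if x is None or math.isinf(x) else f"{x:.4f}"

        lines.append("\t".join([
            t.family_id, fmt(t.d12), fmt(t.d13), fmt(t.d23),
            fmt(t.k1), fmt(t.k2), fold, ",".join(flags) or "-"]))
    return "\n".join(lines) + "\n"
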