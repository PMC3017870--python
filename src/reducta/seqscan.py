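"""Pure-sequence scanners.

Homopolymer tracts, dnaA boxes, inverted repeats (palindromes), sliding
window GC content / GC skew, and replication-origin prediction from the
cumulative skew curve.  All scanners work on plain upper-case A/C/G/T/N
strings and use 0-based half-open coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Homopolymer tracts
# ---------------------------------------------------------------------------

@dataclass
class HomopolymerTract:
    base: str
    start: int
    length: int
    containing_locus: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.length


def find_homopolymers(seq: str, bases: str = "AT",
                      min_len: int = 9) -> list[HomopolymerTract]:
    """All maximal single-base runs of length >= ``min_len``.

    ``bases`` restricts which nucleotides count (polyA/polyT by default,
    the slippage-prone tracts of AT-rich genomes).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    out = []
    for m in re.finditer(r"(A+|C+|G+|T+)", seq):
        run = m.group(0)
        if run[0] in bases and len(run) >= min_len:
            out.append(HomopolymerTract(run[0], m.start(), len(run)))
    return out


def count_long_tracts_in_cds(record: GenomeRecord, min_len: int = 9,
                             strand: str = "coding",
                             bases: str = "A") -> list[HomopolymerTract]:
    """PolyA tracts wholly inside protein-coding genes.

    With ``strand='coding'`` (default) A-runs are counted on the coding
    strand of each CDS, so a genomic polyT run inside a minus-strand gene
    counts as a coding-strand polyA — the strand on which transcriptional
    slippage operates.  ``strand='genomic'`` counts runs of ``bases`` on the
    forward genomic strand instead.  Returned tracts carry genomic
    coordinates and the locus tag of the containing gene.
    """
    out: list[HomopolymerTract] = []
    for f in record.cds_features():
        sub = record.sequence[f.start : f.end]
        if strand == "coding" and f.strand == "-":
            sub = revcomp(sub)
        for t in find_homopolymers(sub, bases=bases, min_len=min_len):
            if strand == "coding" and f.strand == "-":
                gstart = f.end - (t.start + t.length)
            else:
                gstart = f.start + t.start
            out.append(HomopolymerTract(t.base, gstart, t.length, f.locus_tag))
    out.sort(key=lambda t: t.start)
    return out


# ---------------------------------------------------------------------------
# GC profile and origin prediction
# ---------------------------------------------------------------------------

@dataclass
class SkewProfile:
    window: int
    step: int
    centers: np.ndarray
    gc_content: np.ndarray
    gc_skew: np.ndarray
    cumulative_skew: np.ndarray
    empty_windows: np.ndarray  # flags windows with G+C == 0


def gc_profile(seq: str, window: int = 1000, step: int = 10,
               circular: bool = True) -> SkewProfile:
    """Sliding-window GC content and GC skew (G-C)/(G+C).

    Windows start every ``step`` bp; on circular sequences they wrap around
    the origin so the profile covers every start position.  The cumulative
    skew is the running sum of the per-window skew; its global extrema mark
    the replication origin and terminus on genomes with strand-biased
    composition.  Windows without any G or C get skew 0 and a flag.
    """
    n = len(seq)
    if window > n:
        raise ValueError("window larger than sequence")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    if circular:
        starts = np.arange(0, n, step)
        g_ext = np.concatenate([is_g, is_g[: window - 1]])
        c_ext = np.concatenate([is_c, is_c[: window - 1]])
    else:
        starts = np.arange(0, n - window + 1, step)
        g_ext, c_ext = is_g, is_c
    gcum = np.concatenate([[0], np.cumsum(g_ext)])
    ccum = np.concatenate([[0], np.cumsum(c_ext)])
    g = gcum[starts + window] - gcum[starts]
    c = ccum[starts + window] - ccum[starts]
    tot = g + c
    empty = tot == 0
    skew = np.zeros(len(starts))
    np.divide(g - c, tot, out=skew, where=~empty)
    centers = (starts + window // 2) % n if circular else starts + window // 2
    return SkewProfile(window, step, centers, tot / window, skew,
                       np.cumsum(skew), empty)


@dataclass
class OriginCall:
    origin_pos: int | None
    terminus_pos: int | None
    flanking_loci: tuple[str, str] | None
    method: str = "skew_matched_filter"
    confident: bool = True
    leading_strand_g_rich: bool = True


def predict_origin(profile: SkewProfile, record: GenomeRecord | None = None,
                   min_amplitude: float = 0.05) -> OriginCall:
    """Replication origin and terminus from the cumulative GC skew.

    The origin is placed where the genome-half matched filter
    ``D(v) = sum(skew[v : v+n/2]) - sum(skew[v+n/2 : v+n])`` is maximal —
    with a G-rich leading strand and roughly balanced replichores the
    G-rich half starts at the origin — and the terminus antipodally where
    D is minimal.  The filter pools the whole profile, so vertex
    localisation is far more stable than the raw extremum of the
    cumulative-skew random walk.  Confidence is the mean per-window skew
    difference between the two halves (about twice the per-replichore skew
    amplitude when the bias is real); below ``min_amplitude`` the call is
    returned as not confident.
    """
    sk = profile.gc_skew
    n = len(sk)
    half = n // 2
    if half < 2:
        return OriginCall(None, None, None, confident=False)
    cum2 = np.concatenate([[0.0], np.cumsum(np.concatenate([sk, sk]))])
    first = cum2[half : half + n] - cum2[:n]  # sum over [v, v+half)
    second = cum2[n : 2 * n] - cum2[half : half + n]  # [v+half, v+n)
    D = first / half - second / (n - half)  # mean-skew contrast per v
    origin_i = int(np.argmax(D))
    term_i = int(np.argmin(D))
    contrast = float(D[origin_i])
    if contrast < min_amplitude:
        return OriginCall(None, None, None, confident=False)
    g_rich = True

    origin_pos = int(profile.centers[origin_i])
    term_pos = int(profile.centers[term_i])
    flanking = None
    if record is not None and record.features:
        flanking = flanking_genes(record, origin_pos)
    return OriginCall(origin_pos, term_pos, flanking,
                      leading_strand_g_rich=g_rich)


def flanking_genes(record: GenomeRecord, pos: int) -> tuple[str, str]:
    """Names (or locus tags) of the genes bracketing a genomic position."""
    feats = record.features
    n = len(record.sequence)
    left = right = None
    best_l = best_r = n + 1
    for f in feats:
        dl = (pos - f.end) % n
        dr = (f.start - pos) % n
        if f.start <= pos < f.end:
            name = f.gene_name or f.locus_tag
            return (name, name)
        if dl < best_l:
            best_l, left = dl, f
        if dr < best_r:
            best_r, right = dr, f
    return (left.gene_name or left.locus_tag,
            right.gene_name or right.locus_tag)


# ---------------------------------------------------------------------------
# dnaA boxes
# ---------------------------------------------------------------------------

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class DnaaBoxHit:
    start: int
    strand: str
    matched_text: str


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def find_dnaa_boxes(seq: str, pattern: str = "TTWTNCACA") -> list[DnaaBoxHit]:
    """All matches of an IUPAC consensus on both strands.

    The default is the dnaA-box consensus TTWTNCACA; minus-strand hits are
    reported at the forward-strand start of the site.
    """
    rx = _iupac_regex(pattern)
    m = len(pattern)
    hits = [DnaaBoxHit(mt.start(), "+", mt.group(0))
            for mt in rx.finditer(seq)]
    rc = revcomp(seq)
    n = len(seq)
    for mt in rx.finditer(rc):
        start = n - mt.start() - m
        hits.append(DnaaBoxHit(start, "-", mt.group(0)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def cluster_boxes(hits: list[DnaaBoxHit], window: int = 300,
                  min_count: int = 4) -> list[tuple[int, int, int]]:
    """Windows holding >= min_count hits, merged: (start, end, n_hits)."""
    if not hits:
        return []
    starts = sorted(h.start for h in hits)
    clusters = []
    i = 0
    while i < len(starts):
        j = i
        while j + 1 < len(starts) and starts[j + 1] - starts[i] < window:
            j += 1
        if j - i + 1 >= min_count:
            clusters.append((starts[i], starts[j] + 1, j - i + 1))
            i = j + 1
        else:
            i += 1
    return clusters


# ---------------------------------------------------------------------------
# Palindromes (inverted repeats)
# ---------------------------------------------------------------------------

@dataclass
class Palindrome:
    arm1_start: int
    arm2_start: int
    arm_length: int
    gap: int
    mismatches: int
    igs_overlap: str = "unknown"  # fully_igs | partial_igs | genic

    @property
    def span(self) -> int:
        return 2 * self.arm_length + self.gap

    @property
    def start(self) -> int:
        return self.arm1_start

    @property
    def end(self) -> int:
        return self.arm2_start + self.arm_length

    def check(self, seq: str) -> bool:
        """Re-verify the inverted-repeat constraints directly."""
        a1 = seq[self.arm1_start : self.arm1_start + self.arm_length]
        a2 = seq[self.arm2_start : self.arm2_start + self.arm_length]
        mm = sum(x != y for x, y in zip(a1, revcomp(a2)))
        return (mm == self.mismatches
                and self.arm2_start - (self.arm1_start + self.arm_length)
                == self.gap)


def _candidate_palindromes(seq: str, min_arm: int, max_arm: int,
                           max_gap: int, max_mismatch: int) -> list[Palindrome]:
    """All maximal arm extensions per (inner position, gap).

    For an arm pair with gap g ending/starting at i (arm1 = seq[i-L:i],
    arm2 = seq[i+g:i+g+L]) the arms are grown outward while the mismatch
    budget lasts; arms must begin and end on matching bases (a leading
    mismatch is the same candidate as a wider gap, a trailing one a shorter
    arm).  Vectorised over all inner positions for one gap at a time.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    out: list[Palindrome] = []

    def emit(i: int, gap: int, L: int, m: int) -> None:
        if L >= min_arm:
            out.append(Palindrome(i - L, i + gap, L, gap, m))

    for gap in range(0, max_gap + 1):
        # positions i = end of arm1; k-th comparison: seq[i-1-k] vs comp(seq[i+gap+k])
        limit = min(max_arm, (n - gap) // 2)
        if limit < min_arm:
            continue
        active = np.arange(1, n - gap)  # need i-1 >= 0 and i+gap <= n-1
        mm = np.zeros(len(active), dtype=np.int64)
        best_len = np.zeros(len(active), dtype=np.int64)  # longest valid arm
        best_mm = np.zeros(len(active), dtype=np.int64)
        for k in range(limit):
            lo = active - 1 - k
            hi = active + gap + k
            inb = (lo >= 0) & (hi < n)
            match = np.zeros(len(active), dtype=bool)
            if inb.any():
                match[inb] = arr[lo[inb]] == comp[arr[hi[inb]]]
            if k == 0:
                # a leading mismatch is the same candidate at a wider gap
                keep = match
                active, mm = active[keep], mm[keep]
                best_len, best_mm = best_len[keep], best_mm[keep]
                best_len[:] = 1
                continue
            mm = mm + (inb & ~match)
            alive = inb & (mm <= max_mismatch)
            # arm of length k+1 is valid only when its outer ends match
            rec = alive & match
            best_len[rec] = k + 1
            best_mm[rec] = mm[rec]
            dead = ~alive
            for i, L, m in zip(active[dead], best_len[dead], best_mm[dead]):
                emit(int(i), gap, int(L), int(m))
            active, mm = active[alive], mm[alive]
            best_len, best_mm = best_len[alive], best_mm[alive]
            if len(active) == 0:
                break
        for i, L, m in zip(active, best_len, best_mm):
            emit(int(i), gap, int(L), int(m))
    return out


def find_palindromes(seq: str, min_arm: int = 30, max_arm: int = 1000,
                     max_gap: int = 20, max_mismatch: int = 3,
                     record: GenomeRecord | None = None) -> list[Palindrome]:
    """Non-redundant inverted repeats.

    Arms between ``min_arm`` and ``max_arm`` bp, loop ("gap") up to
    ``max_gap`` bp, up to ``max_mismatch`` substitutions between arm1 and
    the reverse complement of arm2 (no indels inside arms).  Among
    overlapping candidates the longest arm wins, ties broken by fewer
    mismatches then leftmost start.  When a ``record`` is supplied each hit
    is labelled by its overlap with intergenic space.
    """
    if min_arm < 2 or max_arm < min_arm or max_gap < 0 or max_mismatch < 0:
        raise ValueError("bad palindrome parameters")
    cands = _candidate_palindromes(seq, min_arm, max_arm, max_gap, max_mismatch)
    cands.sort(key=lambda p: (-p.arm_length, p.mismatches, p.start, p.gap))
    kept: list[Palindrome] = []
    for c in cands:
        if all(c.end <= k.start or c.start >= k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda p: p.start)
    if record is not None:
        genic = [(f.start, f.end) for f in record.features]
        for p in kept:
            ov = sum(max(0, min(p.end, e) - max(p.start, s)) for s, e in genic)
            if ov == 0:
                p.igs_overlap = "fully_igs"
            elif ov >= p.span:
                p.igs_overlap = "genic"
            else:
                p.igs_overlap = "partial_igs"
    return kept
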