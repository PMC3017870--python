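"""Genome and annotation I/O.

Reads annotated genomes from GenBank flat files into light-weight records,
computes summary statistics of the kind reported for reduced endosymbiont
genomes (size, GC content, gene-category counts, coding density, intergenic
spacer lengths), and extracts the set of intergenic spacers (IGS).

Coordinates are 0-based half-open everywhere inside the package; GenBank's
1-based inclusive convention is converted at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: GenBank feature keys mapped to our gene kinds.
_KIND_BY_KEY = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ncRNA": "other_RNA",
    "tmRNA": "other_RNA",
    "misc_RNA": "other_RNA",
}

GENE_KINDS = ("CDS", "tRNA", "rRNA", "other_RNA", "pseudogene")


@dataclass
class GeneFeature:
    """A typed, stranded gene annotation in 0-based half-open coordinates."""

    locus_tag: str
    gene_name: str
    kind: str  # one of GENE_KINDS
    start: int
    end: int
    strand: str  # '+' or '-'
    frameshift_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad coordinates [{self.start}, {self.end}) for {self.locus_tag}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def extract(self, sequence: str) -> str:
        """Coding-strand sequence of this feature."""
        sub = sequence[self.start : self.end]
        if self.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclass
class GenomeRecord:
    """A (possibly circular) genome with its ordered gene annotations."""

    id: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    rotation_offset: int = 0  # bp the sequence was rotated at read time

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-ACGTN letters: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.locus_tag} exceeds genome length")
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_locus(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass
class IgsRecord:
    """An intergenic spacer between two adjacent, non-overlapping genes."""

    left_locus: str
    right_locus: str
    start: int
    end: int
    spans_missing: bool = False

    @property
    def length(self) -> int:
        # wrap-around spacers on circular genomes have end < start encoded as
        # end already incremented by genome length by the producer
        return self.end - self.start


@dataclass
class GenomeStats:
    size_bp: int
    gc_fraction: float
    total_genes: int
    protein_coding: int
    trna_count: int
    rrna_count: int
    other_rna: int
    pseudogenes: int
    mean_cds_length: float
    median_igs_length: float
    pct_protein_coding: float
    pct_coding_incl_rna: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# GenBank reading / writing
# ---------------------------------------------------------------------------

def _parse_frameshift_positions(qualifiers: dict) -> list[int]:
    """Frameshift positions recorded in /note qualifiers as 1-based coords."""
    out: list[int] = []
    for note in qualifiers.get("note", []):
        low = note.lower()
        if "frameshift" in low:
            for tok in note.replace(",", " ").split():
                if tok.isdigit():
                    out.append(int(tok) - 1)
    return out


def read_genbank(path) -> GenomeRecord:
    """Read one annotated genome from a GenBank flat file.

    GenBank 1-based inclusive locations become 0-based half-open.  Compound
    (joined) locations are normalised to their full span; a compound location
    that wraps the origin of a circular sequence triggers rotation of the
    whole record so that no feature spans position 0 (the applied offset is
    kept on the record).  Feature keys outside the known gene keys are
    skipped with a warning.
    """
    rec = SeqIO.read(path, "genbank")
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    topology = rec.annotations.get("topology", "linear")
    is_circular = topology == "circular"
    n = len(seq)

    # detect origin-wrapping features and rotate the record away from them
    rotation = 0
    for bf in rec.features:
        parts = bf.location.parts
        if len(parts) > 1 and int(parts[0].end) == n and int(parts[-1].start) == 0:
            rotation = max(rotation, int(parts[-1].end))
    if rotation and is_circular:
        seq = seq[rotation:] + seq[:rotation]

    features: list[GeneFeature] = []
    for bf in rec.features:
        if bf.type == "gene":
            continue  # gene wrappers duplicate CDS/RNA children
        kind = _KIND_BY_KEY.get(bf.type)
        if kind is None:
            if bf.type != "source":
                log.warning("skipping feature of unknown key %r", bf.type)
            continue
        if "pseudo" in bf.qualifiers or "pseudogene" in bf.qualifiers:
            kind = "pseudogene"
        start = (int(bf.location.start) - rotation) % n
        end = (int(bf.location.end) - rotation) % n or n
        if end <= start:
            end += n  # genuinely wrapping even after rotation; clamp below
        strand = "-" if bf.location.strand == -1 else "+"
        quals = bf.qualifiers
        locus = quals.get("locus_tag", quals.get("gene", ["?"]))[0]
        gene_name = quals.get("gene", [""])[0]
        fs = [(p - rotation) % n for p in _parse_frameshift_positions(quals)]
        features.append(
            GeneFeature(locus, gene_name, kind, start, min(end, n), strand, fs)
        )
    return GenomeRecord(rec.id or rec.name, seq, is_circular, features, rotation)


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord back to a GenBank flat file (round-trippable)."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.is_circular else "linear"
    key_by_kind = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "other_RNA": "misc_RNA", "pseudogene": "CDS"}
    for f in record.features:
        quals: dict = {"locus_tag": [f.locus_tag]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        if f.frameshift_positions:
            pos = ",".join(str(p + 1) for p in sorted(f.frameshift_positions))
            quals["note"] = [f"frameshift at {pos}"]
        loc = FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        rec.features.append(SeqFeature(loc, type=key_by_kind[f.kind],
                                       qualifiers=quals))
    SeqIO.write(rec, path, "genbank")


def write_fasta(record: GenomeRecord, path) -> None:
    rec = SeqRecord(Seq(record.sequence), id=record.id, description="")
    SeqIO.write(rec, path, "fasta")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length covered by >=1 interval (each base counted once)."""
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def genome_stats(record: GenomeRecord) -> GenomeStats:
    """Summary statistics in the layout used for endosymbiont genome tables.

    Coding percentages count each genomic base covered by at least one gene
    once (interval union, not a sum over genes), so overlapping genes do not
    inflate the density.  Pseudogenes are tracked separately and excluded
    from the functional gene total.
    """
    n = len(record.sequence)
    gc = sum(record.sequence.count(b) for b in "GC")
    counts = {k: 0 for k in GENE_KINDS}
    for f in record.features:
        counts[f.kind] += 1
    cds_lengths = [f.length for f in record.features if f.kind == "CDS"]
    igs = extract_igs(record)
    igs_lengths = [r.length for r in igs]

    cds_iv = [(f.start, f.end) for f in record.features if f.kind == "CDS"]
    all_iv = [(f.start, f.end) for f in record.features
              if f.kind != "pseudogene"]
    total = sum(counts[k] for k in ("CDS", "tRNA", "rRNA", "other_RNA"))
    return GenomeStats(
        size_bp=n,
        gc_fraction=gc / n,
        total_genes=total,
        protein_coding=counts["CDS"],
        trna_count=counts["tRNA"],
        rrna_count=counts["rRNA"],
        other_rna=counts["other_RNA"],
        pseudogenes=counts["pseudogene"],
        mean_cds_length=statistics.fmean(cds_lengths) if cds_lengths else 0.0,
        median_igs_length=statistics.median(igs_lengths) if igs_lengths else 0.0,
        pct_protein_coding=_union_length(cds_iv) / n,
        pct_coding_incl_rna=_union_length(all_iv) / n,
    )


# ---------------------------------------------------------------------------
# Intergenic spacers
# ---------------------------------------------------------------------------

def extract_igs(record: GenomeRecord) -> list[IgsRecord]:
    """Spacers between adjacent genes of any kind (pseudogenes included).

    Abutting genes yield a zero-length spacer; overlapping genes yield no
    record at all.  On circular genomes the wrap-around spacer between the
    last and first gene is included (its ``end`` is expressed beyond the
    genome length so that ``length`` stays non-negative).
    """
    feats = record.features
    if len(feats) < 2:
        return []
    out: list[IgsRecord] = []
    cur = feats[0]
    cur_end = cur.end
    for nxt in feats[1:]:
        if nxt.start >= cur_end:
            out.append(IgsRecord(cur.locus_tag, nxt.locus_tag, cur_end, nxt.start))
        if nxt.end >= cur_end:
            cur, cur_end = nxt, nxt.end
    if record.is_circular:
        first = feats[0]
        n = len(record.sequence)
        if first.start + n >= cur_end:
            out.append(IgsRecord(cur.locus_tag, first.locus_tag,
                                 cur_end, first.start + n))
    return out


def igs_to_bed(igs: list[IgsRecord], genome_id: str) -> str:
    lines = []
    for r in igs:
        name = f"{r.left_locus}|{r.right_locus}"
        lines.append(f"{genome_id}\t{r.start}\t{r.end}\t{name}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# ORF extension
# ---------------------------------------------------------------------------

STOP_CODONS = ("TAA", "TAG", "TGA")


def extend_orf(record: GenomeRecord, start: int, end: int, strand: str,
               search_limit: int = 600) -> tuple[int, int, bool]:
    """Extend a homology-defined region to full ORF boundaries.

    Moves the 5' boundary upstream to the nearest in-frame ATG and the 3'
    boundary downstream to the first in-frame stop codon, strand-aware.
    Returns ``(start, end, ok)``; when no in-frame ATG or stop exists within
    ``search_limit`` bp the corresponding coordinate is left unchanged and
    ``ok`` is False.
    """
    seq = record.sequence
    n = len(seq)

    def codon(pos: int) -> str:
        if record.is_circular:
            return "".join(seq[(pos + k) % n] for k in range(3))
        if pos < 0 or pos + 3 > n:
            return ""
        return seq[pos : pos + 3]

    ok = True
    if strand == "+":
        if codon(start) != "ATG":
            found = False
            for off in range(3, search_limit + 1, 3):
                p = start - off
                if p < 0 and not record.is_circular:
                    break
                c = codon(p % n if record.is_circular else p)
                if c in STOP_CODONS:
                    break
                if c == "ATG":
                    start = p
                    found = True
                    break
            ok &= found
        if codon(end - 3) not in STOP_CODONS:
            found = False
            for off in range(3, search_limit + 1, 3):
                p = end - 3 + off
                if p + 3 > n and not record.is_circular:
                    break
                if codon(p % n if record.is_circular else p) in STOP_CODONS:
                    end = p + 3
                    found = True
                    break
            ok &= found
    else:
        # minus strand: start codon at the 'end' side, stop at the 'start' side
        def rc_codon(pos: int) -> str:
            c = codon(pos)
            return str(Seq(c).reverse_complement()) if c else ""

        if rc_codon(end - 3) != "ATG":
            found = False
            for off in range(3, search_limit + 1, 3):
                p = end - 3 + off
                if p + 3 > n and not record.is_circular:
                    break
                c = rc_codon(p % n if record.is_circular else p)
                if c in STOP_CODONS:
                    break
                if c == "ATG":
                    end = p + 3
                    found = True
                    break
            ok &= found
        if rc_codon(start) not in STOP_CODONS:
            found = False
            for off in range(3, search_limit + 1, 3):
                p = start - off
                if p < 0 and not record.is_circular:
                    break
                if rc_codon(p % n if record.is_circular else p) in STOP_CODONS:
                    start = p
                    found = True
                    break
            ok &= found
    return start, end, ok
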