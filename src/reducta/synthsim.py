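"""Synthetic endosymbiont genome triads with a planted-event truth manifest.

Emulates the study conditions of reduced ant-endosymbiont genomes: a
circular, extremely AT-biased (~27.5% GC) ancestor of ~600 protein-coding
genes with short intergenic spacers, strand-compositional GC skew switching
sign at a chosen replication origin, naturally arising polyA/polyT tracts,
and planted intergenic palindromes.  The ancestor is evolved along a rooted
tree with per-branch substitutions (F81-style, AT-biased stationary
composition) and planted gene losses, pseudogenizations and single-base
slippage indels in homopolymer tracts.  Everything planted is recorded in a
manifest so every pipeline stage can be tested against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (GeneFeature, GenomeRecord, write_fasta, write_genbank)
from .reduction import RootedTree
from .seqscan import revcomp

STOPS = ("TAA", "TAG", "TGA")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_TREE = "((vaf:0.05,flo:0.05):0.03,pen:0.08);"

#: per-branch (p_loss, p_pseudo, p_slip) per gene; branch ids follow
#: RootedTree naming (leaf label, or sorted '+'-joined leaves for stems).
DEFAULT_EVENT_RATES = {
    "vaf": (0.030, 0.004, 0.012),
    "flo": (0.028, 0.004, 0.006),
    "pen": (0.005, 0.001, 0.006),
    "flo+vaf": (0.008, 0.002, 0.002),
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic triad."""

    seed: int
    n_genes: int = 600
    n_rna: int = 40
    mean_cds_len: int = 1000  # bp, near the ~1 kb average of the genus
    gc_target: float = 0.275
    igs_mean: int = 134  # geometric mean spacer length, bp
    tree: str = DEFAULT_TREE
    event_rates: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    n_palindromes: int = 10
    palindrome_arm: tuple = (30, 70)
    palindrome_gap: tuple = (0, 20)
    skew_amplitude: float = 0.06
    origin_frac: float = 0.0  # origin position as a fraction of genome length
    min_tract_plant: int = 9  # planted slippage tracts at least this long
    scar_fraction: float = 0.3  # deletion scar up to this fraction of gene
    forced_events: list = field(default_factory=list)
    # list of (gene_index, branch_id, event) applied before random draws

    def validate(self) -> None:
        if not (0 < self.gc_target < 1):
            raise ValueError("gc_target must be in (0,1)")
        for rates in self.event_rates.values():
            if any(not (0 <= p <= 1) for p in rates):
                raise ValueError("event probabilities must be in [0,1]")


# ---------------------------------------------------------------------------
# Genome elements (genes kept on the coding strand)
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    family: str  # ancestor gene id == family ground truth
    kind: str  # CDS | tRNA
    name: str
    strand: str
    coding: str  # coding-strand sequence
    state: str = "INTACT"  # INTACT | PSEUDO | SLIPPED
    frameshift: tuple | None = None  # (pos_in_coding, sign, tract_start, tract_len)
    # coding spans held immutable (planted disruptions must not revert)
    locked: tuple = ()

    def forward(self) -> str:
        return self.coding if self.strand == "+" else revcomp(self.coding)


@dataclass
class _Spacer:
    seq: str
    # spans held immutable along branches (planted palindromes: the study
    # system retains intergenic palindromes under selection)
    protected: tuple = ()


def _sample_bases(rng, n, freqs) -> str:
    return bytes(BASES[rng.choice(4, size=n, p=freqs)]).decode()


def _base_freqs(gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])  # A C G T


def _cds_freqs(gc_target: float) -> np.ndarray:
    """Base frequencies for stop-free codon sampling that hit gc_target.

    Rejecting the AT-rich stop codons enriches accepted codons in G+C, so
    the sampling composition is solved (by bisection on the closed-form
    conditional expectation over the 61 sense codons) to make the realized
    coding GC equal the target.
    """
    from itertools import product

    def realized(gc: float) -> float:
        p = _base_freqs(gc)
        bases = "ACGT"
        tot = gcsum = 0.0
        for codon in product(range(4), repeat=3):
            s = "".join(bases[i] for i in codon)
            if s in STOPS:
                continue
            pr = p[codon[0]] * p[codon[1]] * p[codon[2]]
            tot += pr
            gcsum += pr * sum(1 for i in codon if i in (1, 2))
        return gcsum / (3 * tot)

    lo, hi = max(0.01, gc_target - 0.05), gc_target
    for _ in range(40):
        mid = (lo + hi) / 2
        if realized(mid) > gc_target:
            hi = mid
        else:
            lo = mid
    return _base_freqs((lo + hi) / 2)


def _sample_cds(rng, n_codons: int, freqs) -> str:
    """Stop-free random CDS: ATG + interior codons + an AT-biased stop."""
    n_interior = n_codons - 2
    mat = rng.choice(4, size=(n_interior, 3), p=freqs)
    codons = [bytes(BASES[row]).decode() for row in mat]
    for i, c in enumerate(codons):
        while c in STOPS:
            c = _sample_bases(rng, 3, freqs)
        codons[i] = c
    stop = STOPS[rng.choice(3, p=[0.8, 0.1, 0.1])]
    return "ATG" + "".join(codons) + stop


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    config: SimConfig
    elements: list  # ancestor elements
    manifest: dict


def simulate_ancestor(cfg: SimConfig) -> Simulation:
    """Build the ancestral circular genome as an element list.

    Genes alternate with geometric spacers; palindromes are planted into
    randomly chosen spacers; GC skew of the requested amplitude is imposed
    by re-assigning G/C positions by replichore, protecting start/stop
    codons and never creating an in-frame stop.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    freqs = _base_freqs(cfg.gc_target)
    cds_freqs = _cds_freqs(cfg.gc_target)
    elements: list = []
    mean_codons = max(50, cfg.mean_cds_len // 3)

    rna_slots = set()
    if cfg.n_rna:
        step = max(1, (cfg.n_genes + cfg.n_rna) // cfg.n_rna)
        rna_slots = set(range(0, cfg.n_genes + cfg.n_rna, step))
    gene_i = rna_i = 0
    for slot in range(cfg.n_genes + cfg.n_rna):
        elements.append(_Spacer(_sample_bases(
            rng, int(rng.geometric(1 / cfg.igs_mean)), freqs)))
        strand = "+" if rng.random() < 0.5 else "-"
        if slot in rna_slots and rna_i < cfg.n_rna:
            seq = _sample_bases(rng, 76, freqs)
            elements.append(_Gene(f"r{rna_i:03d}", "tRNA", f"trn{rna_i:03d}",
                                  strand, seq))
            rna_i += 1
        else:
            n_codons = max(60, int(rng.normal(mean_codons, mean_codons / 4)))
            seq = _sample_cds(rng, n_codons, cds_freqs)
            elements.append(_Gene(f"g{gene_i:04d}", "CDS", f"gene{gene_i:04d}",
                                  strand, seq))
            gene_i += 1
    elements.append(_Spacer(_sample_bases(
        rng, int(rng.geometric(1 / cfg.igs_mean)), freqs)))

    palindromes, protected = _plant_palindromes(rng, elements, cfg, freqs)
    genome_len = sum(_elem_len(e) for e in elements)
    origin = int(cfg.origin_frac * genome_len) % genome_len
    if cfg.skew_amplitude > 0:
        _impose_skew(rng, elements, origin, genome_len, cfg.skew_amplitude,
                     protected)

    manifest = {
        "origin_pos": origin,
        "genome_length_ancestor": genome_len,
        "planted_palindromes": palindromes,
        "families": {},
        "branches": {},
    }
    for e in elements:
        if isinstance(e, _Gene):
            manifest["families"][e.family] = {
                "kind": e.kind, "events": [], "coordinates": {}}
    return Simulation(cfg, elements, manifest)


def _elem_len(e) -> int:
    return len(e.seq) if isinstance(e, _Spacer) else len(e.coding)


def _plant_palindromes(rng, elements, cfg: SimConfig, freqs):
    """Insert inverted repeats into random spacers.

    Returns the manifest entries plus per-element protected spans that the
    skew transform must leave untouched (G/C reassignment would otherwise
    break arm symmetry).
    """
    spacers = [i for i, e in enumerate(elements)
               if isinstance(e, _Spacer) and len(e.seq) >= 10]
    chosen = rng.choice(len(spacers), size=min(cfg.n_palindromes, len(spacers)),
                        replace=False)
    out = []
    protected: dict[int, list[tuple[int, int]]] = {}
    for si in sorted(int(c) for c in chosen):
        idx = spacers[si]
        arm = int(rng.integers(cfg.palindrome_arm[0], cfg.palindrome_arm[1] + 1))
        gap = int(rng.integers(cfg.palindrome_gap[0], cfg.palindrome_gap[1] + 1))
        arm_seq = _sample_bases(rng, arm, freqs)
        gap_seq = _sample_bases(rng, gap, freqs)
        pal = arm_seq + gap_seq + revcomp(arm_seq)
        sp = elements[idx]
        mid = len(sp.seq) // 2
        sp.seq = sp.seq[:mid] + pal + sp.seq[mid:]
        sp.protected = sp.protected + ((mid, mid + len(pal)),)
        protected.setdefault(idx, []).append((mid, mid + len(pal)))
        out.append({"element_index": idx, "arm": arm, "gap": gap,
                    "span": 2 * arm + gap})
    return out, protected


def _codon_safe(coding: str, pos: int, new_base: str,
                frameshift: tuple | None) -> bool:
    """Would setting coding[pos] = new_base create an in-frame stop?

    For slippage-frameshifted genes the check runs in the conceptually
    corrected frame (the frame transcriptional slippage restores).
    """
    if frameshift is not None:
        fpos, sign = frameshift[0], frameshift[1]
        if sign == +1:
            corr = coding[:fpos] + coding[fpos + 1 :]
            cpos = pos if pos < fpos else pos - 1
            if pos == fpos:
                return True  # the inserted base itself: leave alone
        else:
            corr = coding[:fpos] + coding[fpos] + coding[fpos:]
            cpos = pos if pos < fpos else pos + 1
        seq = corr[:cpos] + new_base + corr[cpos + 1 :]
        pos = cpos
    else:
        seq = coding[:pos] + new_base + coding[pos + 1 :]
    ci = pos // 3 * 3
    return seq[ci : ci + 3] not in STOPS


def _impose_skew(rng, elements, origin: int, genome_len: int,
                 amplitude: float,
                 protected: dict[int, list[tuple[int, int]]] | None = None,
                 ) -> None:
    """Reassign G/C positions so the leading strand is G-rich.

    Forward-strand positions in [origin, terminus) become G with
    probability (1+s)/2, the complementary replichore with (1-s)/2.  Gene
    positions are skipped when the change would touch a start/stop codon or
    create an in-frame stop.
    """
    terminus = (origin + genome_len // 2) % genome_len
    protected = protected or {}
    pos = 0
    for ei, e in enumerate(elements):
        spans = protected.get(ei, [])
        if isinstance(e, _Spacer):
            seq = list(e.seq)
            for i, b in enumerate(seq):
                if any(s <= i < t for s, t in spans):
                    continue
                if b in "GC":
                    seq[i] = _skewed_base(rng, pos + i, origin, terminus,
                                          genome_len, amplitude)
            e.seq = "".join(seq)
            pos += len(seq)
        else:
            fwd = list(e.forward())
            L = len(fwd)
            changed = False
            for i, b in enumerate(fwd):
                if b not in "GC":
                    continue
                cpos = i if e.strand == "+" else L - 1 - i
                if cpos < 3 or cpos >= L - 3:
                    continue  # protect start and stop codons
                tgt = _skewed_base(rng, pos + i, origin, terminus,
                                   genome_len, amplitude)
                if tgt == b:
                    continue
                coding_b = tgt if e.strand == "+" else \
                    {"G": "C", "C": "G"}[tgt]
                if e.kind == "CDS" and not _codon_safe(
                        e.coding, cpos, coding_b, e.frameshift):
                    continue
                fwd[i] = tgt
                e.coding = (e.coding[:cpos] + coding_b + e.coding[cpos + 1 :])
                changed = True
            if changed:
                pass  # coding updated in place above
            pos += L


def _skewed_base(rng, abs_pos: int, origin: int, terminus: int,
                 genome_len: int, amplitude: float) -> str:
    if origin <= terminus:
        leading = origin <= abs_pos < terminus
    else:
        leading = abs_pos >= origin or abs_pos < terminus
    p_g = (1 + amplitude) / 2 if leading else (1 - amplitude) / 2
    return "G" if rng.random() < p_g else "C"


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

def evolve_tree(sim: Simulation) -> tuple[dict[str, GenomeRecord], dict]:
    """Evolve the ancestor along the configured tree.

    Returns leaf-genome records keyed by leaf label, plus the completed
    truth manifest.  Substitutions are applied per branch at the branch
    length (expected substitutions per mutable site) drawing replacement
    bases from the AT-biased stationary composition; start/stop codons are
    immutable and replacements that would create an in-frame stop in an
    intact (or conceptually corrected) gene are re-drawn.  Planted events
    only strike so-far-intact genes; each family suffers at most one event
    per branch and no event after a prior one on the same lineage.
    """
    cfg = sim.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    tree = RootedTree(cfg.tree)
    manifest = sim.manifest

    forced: dict[str, list] = {}
    fam_ids = [e.family for e in sim.elements if isinstance(e, _Gene)]
    for gene_idx, branch_id, event in cfg.forced_events:
        forced.setdefault(branch_id, []).append((fam_ids[gene_idx], event))

    leaves: dict[str, list] = {}

    def descend(node, elements: list) -> None:
        children = node.child_nodes()
        for child in children:
            branch = child.branch_id
            t = child.edge.length or 0.0
            evolved = [_copy_elem(e) for e in elements]
            n_sub, n_sites = _substitute(rng, evolved, t,
                                         _base_freqs(cfg.gc_target))
            rates = cfg.event_rates.get(branch, (0.0, 0.0, 0.0))
            # families already struck on a sibling branch are off limits:
            # a same-family event on both sisters is unpolarizable by
            # parsimony (it collapses to one stem event)
            sibling_hit = set()
            for sib in children:
                if sib is child:
                    continue
                for fam, d in manifest["families"].items():
                    if any(e["branch"] == sib.branch_id for e in d["events"]):
                        sibling_hit.add(fam)
            events = _plant_events(rng, evolved, rates, cfg,
                                   forced.get(branch, []), sibling_hit)
            manifest["branches"][branch] = {
                "length": t, "realized_substitutions": int(n_sub),
                "mutable_sites": int(n_sites),
                "n_events": len(events),
            }
            for fam, ev in events:
                manifest["families"][fam]["events"].append(
                    {"branch": branch, **ev})
            if child.is_leaf():
                leaves[child.taxon.label] = evolved
            else:
                descend(child, evolved)

    descend(tree.tree.seed_node, sim.elements)

    genomes = {}
    for label, elements in leaves.items():
        genomes[label] = _assemble(label, elements, manifest)
    manifest["tree"] = cfg.tree
    manifest["leaf_order"] = sorted(genomes)
    return genomes, manifest


def _copy_elem(e):
    if isinstance(e, _Spacer):
        return _Spacer(e.seq, e.protected)
    return _Gene(e.family, e.kind, e.name, e.strand, e.coding, e.state,
                 e.frameshift, e.locked)


def _substitute(rng, elements: list, t: float,
                freqs: np.ndarray) -> tuple[int, int]:
    """F81 substitutions at expected rate t visible changes per site.

    Mutation events occur at rate t / (1 - sum(pi^2)) per site and the new
    base is drawn from the stationary composition ``freqs`` (a draw equal
    to the current base is a silent event), so the AT-biased composition
    is exactly stationary and the expected number of realized changes per
    mutable site is t.
    """
    if t <= 0:
        return 0, sum(_elem_len(e) for e in elements)
    beta = 1.0 / (1.0 - float(np.sum(freqs**2)))
    p_event = min(1.0, t * beta)
    bases = "ACGT"
    n_sub = 0
    n_sites = 0
    for e in elements:
        if isinstance(e, _Spacer):
            seq = list(e.seq)
            hits = np.flatnonzero(rng.random(len(seq)) < p_event)
            draws = rng.choice(4, size=len(hits), p=freqs)
            for i, d in zip(hits, draws):
                if any(s <= i < t for s, t in e.protected):
                    continue
                if bases[d] != seq[i]:
                    seq[i] = bases[d]
                    n_sub += 1
            n_sites += len(seq) - sum(t - s for s, t in e.protected)
            e.seq = "".join(seq)
            continue
        coding = list(e.coding)
        L = len(coding)
        protected = e.state in ("INTACT", "SLIPPED")
        tract = None
        if e.frameshift is not None:
            tract = (e.frameshift[2], e.frameshift[2] + e.frameshift[3])
        lo, hi = (3, L - 3) if e.kind == "CDS" else (0, L)
        n_sites += max(0, hi - lo)
        hits = np.flatnonzero(rng.random(L) < p_event)
        draws = rng.choice(4, size=len(hits), p=freqs)
        for i, d in zip(hits, draws):
            if not (lo <= i < hi):
                continue
            if tract is not None and tract[0] <= i < tract[1]:
                continue  # keep the diagnostic tract intact
            if any(s <= i < t for s, t in e.locked):
                continue  # planted disruptions must not revert
            new = bases[d]
            if new == coding[i]:
                continue
            if e.kind == "CDS" and protected:
                cur = "".join(coding)
                if not _codon_safe(cur, int(i), new, e.frameshift):
                    # would create an in-frame stop: fall back to another
                    # base so the realized rate stays on target
                    new = None
                    for k in rng.permutation(4):
                        b = bases[k]
                        if b != coding[i] and _codon_safe(cur, int(i), b,
                                                          e.frameshift):
                            new = b
                            break
                    if new is None:
                        continue
            coding[i] = new
            n_sub += 1
        e.coding = "".join(coding)
    return n_sub, n_sites


def _coding_runs(seq: str, min_len: int):
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] in "AT" and j - i >= min_len:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def _plant_events(rng, elements: list, rates, cfg: SimConfig,
                  forced: list, sibling_hit: set | None = None,
                  ) -> list[tuple[str, dict]]:
    p_loss, p_pseudo, p_slip = rates
    out = []
    forced_map = dict(forced)
    sibling_hit = sibling_hit or set()
    for idx, e in enumerate(list(elements)):
        if not isinstance(e, _Gene) or e.kind != "CDS" or e.state != "INTACT":
            continue
        if e.family in sibling_hit and e.family not in forced_map:
            continue
        event = forced_map.pop(e.family, None)
        if event is None:
            u = rng.random()
            if u < p_loss:
                event = "LOSS"
            elif u < p_loss + p_pseudo:
                event = "EROSION"
            elif u < p_loss + p_pseudo + p_slip:
                event = "FRAMESHIFT"
        if event is None:
            continue
        if event == "LOSS":
            scar_len = int(rng.integers(0, max(1,
                int(cfg.scar_fraction * len(e.coding)))))
            freqs = _base_freqs(cfg.gc_target)
            elements[idx] = _Spacer(_sample_bases(rng, scar_len, freqs))
            out.append((e.family, {"event": "LOSS", "scar_len": scar_len}))
        elif event == "EROSION":
            detail = _pseudogenize(rng, e)
            out.append((e.family, {"event": "EROSION", **detail}))
        elif event == "FRAMESHIFT":
            detail = _plant_slip(rng, e, cfg)
            if detail is None:
                continue  # no usable tract; gene left intact
            out.append((e.family, {"event": "FRAMESHIFT", **detail}))
    return out


def _pseudogenize(rng, gene: _Gene) -> dict:
    """1-3 disruptions: optional small deletions, then a nonsense stop.

    The nonsense codon is planted last so it sits in the final reading
    frame: every eroded gene carries an internal stop in its own frame.
    """
    seq = gene.coding
    n_dis = int(rng.integers(1, 4))
    kinds = [("del1" if rng.random() < 0.5 else "del2")
             for _ in range(n_dis - 1)] + ["nonsense"]
    applied = []
    for kind in kinds:
        L = len(seq)
        if kind == "nonsense":
            ci = int(rng.integers(2, max(3, L // 3 - 2)))
            seq = seq[: 3 * ci] + "TAA" + seq[3 * ci + 3 :]
            gene.locked = gene.locked + ((3 * ci, 3 * ci + 3),)
            applied.append({"kind": "nonsense", "codon": ci})
        else:
            k = 1 if kind == "del1" else 2
            for _ in range(50):
                p = int(rng.integers(6, L - 6 - k))
                ctx = seq[max(0, p - 5) : p + k + 5]
                if not _coding_runs(ctx, 5):
                    seq = seq[:p] + seq[p + k :]
                    applied.append({"kind": kind, "pos": p})
                    break
    gene.coding = seq
    gene.state = "PSEUDO"
    return {"disruptions": applied}


def _plant_slip(rng, gene: _Gene, cfg: SimConfig) -> dict | None:
    """Single +/-1 bp indel inside a coding-strand polyA/polyT tract."""
    seq = gene.coding
    runs = _coding_runs(seq[3:-3], cfg.min_tract_plant)
    runs = [(s + 3, l, b) for s, l, b in runs]
    if not runs:
        # upgrade a shorter run to the planting length by substitutions
        shorter = _coding_runs(seq[3:-3], 5)
        shorter = [shorter[k] for k in rng.permutation(len(shorter))]
        for s, l, b in [(s + 3, l, b) for s, l, b in shorter]:
            need = cfg.min_tract_plant - l
            if s + l + need > len(seq) - 3:
                continue
            ext = seq[: s + l] + b * need + seq[s + l + need :]
            window = ext[(s // 3) * 3 : ((s + l + need) // 3 + 1) * 3]
            if any(window[i : i + 3] in STOPS
                   for i in range(0, len(window) - 2, 3)):
                continue
            seq = ext
            runs = [(s, cfg.min_tract_plant, b)]
            break
        if not runs:
            return None
    ri = int(rng.integers(0, len(runs)))
    s, l, b = runs[ri]
    sign = +1 if rng.random() < 0.5 else -1
    pos = s + int(rng.integers(0, l))
    if sign == +1:
        seq = seq[:pos] + b + seq[pos:]
        tract_len = l + 1
    else:
        seq = seq[:pos] + seq[pos + 1 :]
        tract_len = l - 1
    gene.coding = seq
    gene.state = "SLIPPED"
    gene.frameshift = (s, sign, s, tract_len)
    return {"tract_start_in_cds": s, "tract_len": tract_len,
            "tract_base": b, "indel_sign": sign, "indel_pos_in_cds": pos}


# ---------------------------------------------------------------------------
# Assembly and fixture output
# ---------------------------------------------------------------------------

def _assemble(genome_id: str, elements: list, manifest: dict) -> GenomeRecord:
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for e in elements:
        if isinstance(e, _Spacer):
            parts.append(e.seq)
            pos += len(e.seq)
            continue
        fwd = e.forward()
        locus = f"{genome_id}_{e.family}"
        fs_positions = []
        if e.frameshift is not None:
            cpos = e.frameshift[0]
            g = pos + cpos if e.strand == "+" else pos + len(fwd) - 1 - cpos
            fs_positions.append(g)
        features.append(GeneFeature(locus, e.name, e.kind, pos,
                                    pos + len(fwd), e.strand, fs_positions))
        fam = manifest["families"][e.family]
        fam["coordinates"][genome_id] = {
            "locus": locus, "start": pos, "end": pos + len(fwd),
            "strand": e.strand, "state": e.state,
        }
        parts.append(fwd)
        pos += len(fwd)
    return GenomeRecord(genome_id, "".join(parts), True, features)


def ancestor_record(sim: Simulation) -> GenomeRecord:
    """The ancestral genome assembled into a GenomeRecord."""
    return _assemble("ancestor", sim.elements, sim.manifest)


def simulate_triad(cfg: SimConfig) -> tuple[dict[str, GenomeRecord], dict]:
    """Convenience wrapper: ancestor + evolution in one call."""
    sim = simulate_ancestor(cfg)
    return evolve_tree(sim)


def write_fixture(genomes: dict[str, GenomeRecord], manifest: dict,
                  out_dir) -> list[Path]:
    """GenBank + FASTA per genome, manifest JSON and the tree newick."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for gid in sorted(genomes):
        gb = out / f"{gid}.gb"
        fa = out / f"{gid}.fasta"
        write_genbank(genomes[gid], gb)
        write_fasta(genomes[gid], fa)
        written += [gb, fa]
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    tpath = out / "tree.nwk"
    tpath.write_text(manifest["tree"] + "\n")
    return written + [mpath, tpath]
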