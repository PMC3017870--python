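"""End-to-end comparative analysis of an annotated genome set.

Chains the pipeline stages: ortholog table (hybrid RBH + gene order), gene
state classification against an intact reference member, slippage
frameshift detection, Dollo event reconstruction and convergence flags,
per-lineage summaries, deletion-hotspot scan, IGS class comparison, and
the nonsynonymous-rate fold analysis against an outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genome_io import GenomeRecord, extract_igs
from .orthology import OrthologFamily, OrthologTable, build_ortholog_table
from .reduction import (ABSENT, EventRow, EventTable, FRAMESHIFT_SLIPPAGE,
                        FrameshiftCall, INTACT, PSEUDOGENE, RootedTree,
                        assign_gene_state, flag_convergent,
                        dollo_reconstruct, hotspot_scan,
                        igs_classify_and_compare, place_frameshift_events,
                        self_rescue_frameshift, summarize_events)
from .rates import (RateTriple, codon_align, correct_frameshift, fold_summary,
                    rate_triple)
from .seqscan import gc_profile, predict_origin

log = logging.getLogger(__name__)


@dataclass
class TriadResult:
    table: OrthologTable
    states: dict[str, dict[str, str]]  # family -> genome -> state
    frameshift_calls: list[FrameshiftCall]
    events: EventTable
    summary: dict
    ancestral_gene_count: int
    shared_intact_count: int
    hotspots: dict
    igs_comparison: dict
    rate_triples: list[RateTriple] = field(default_factory=list)
    rate_summary: dict | None = None
    origin_calls: dict = field(default_factory=dict)


def _clean_translation(cds: str) -> bool:
    if len(cds) < 60 or len(cds) % 3:
        return False
    aa = str(Seq(cds).translate())
    return "*" not in aa[:-1] and aa.endswith("*") and aa.startswith("M")


def _consensus_order(table: OrthologTable) -> list[OrthologFamily]:
    def key(fam: OrthologFamily) -> float:
        return sum(fam.positions.values()) / max(1, len(fam.positions))
    return sorted(table.families, key=key)


class _AnchorIndex:
    """Find the loci bracketing a family's expected position in any genome.

    Gene order is conserved, so the neighbours of a family in a witness
    genome that still carries it identify the flanking loci in a genome
    that lost it: walk outward along the witness gene order until a family
    with a member in the target genome is found on each side.
    """

    def __init__(self, genomes: dict[str, GenomeRecord], families):
        self.order = {gid: [f.locus_tag for f in rec.features]
                      for gid, rec in genomes.items()}
        self.rank = {gid: {l: i for i, l in enumerate(loci)}
                     for gid, loci in self.order.items()}
        self.fam_of = {(gid, locus): fam
                       for fam in families
                       for gid, locus in fam.members.items()}
        self.circular = {gid: rec.is_circular for gid, rec in genomes.items()}

    def anchors(self, fam, target_gid: str) -> tuple[str | None, str | None]:
        witness = next((g for g in sorted(fam.members) if g != target_gid),
                       None)
        if witness is None:
            return None, None
        loci = self.order[witness]
        n = len(loci)
        pos = self.rank[witness][fam.members[witness]]

        def scan(direction: int) -> str | None:
            for step in range(1, n):
                j = pos + direction * step
                if self.circular[witness]:
                    j %= n
                elif not 0 <= j < n:
                    return None
                f = self.fam_of.get((witness, loci[j]))
                if f is not None and target_gid in f.members:
                    return f.members[target_gid]
            return None

        return scan(-1), scan(+1)


def analyze_triad(genomes: dict[str, GenomeRecord], tree_newick: str,
                  outgroup: str | None = None, focal: str | None = None,
                  min_tract: int = 7,
                  hotspot_window: int = 32_000, hotspot_nperm: int = 9_999,
                  seed: int = 0, with_rates: bool = True,
                  prescreen_min_kmers: int | None = 10) -> TriadResult:
    """Run the full genome-reduction comparison on a genome set.

    ``focal`` selects the lineage whose branch is the numerator of the
    per-gene fold statistic K1/K2 (K1 = dN along the focal branch since
    the ingroup ancestor); it defaults to the first ingroup leaf in tree
    order.
    """
    tree = RootedTree(tree_newick)
    if sorted(genomes) != tree.leaf_labels:
        raise ValueError("genome ids must match tree leaf labels")
    if outgroup is None:
        outgroup = _infer_outgroup(tree)
    # ingroup in tree order so the focal default is the first-listed leaf
    tree_order = [lf.taxon.label for lf in tree.tree.leaf_node_iter()]
    ingroup = [l for l in tree_order if l != outgroup]
    if focal is not None:
        if focal not in ingroup:
            raise ValueError("focal must be an ingroup leaf")
        ingroup = [focal] + [l for l in ingroup if l != focal]

    recs = [genomes[g] for g in sorted(genomes)]
    table = build_ortholog_table(recs, mode="hybrid",
                                 prescreen_min_kmers=prescreen_min_kmers)
    fam_order = _consensus_order(table)
    anchor_index = _AnchorIndex(genomes, table.families)

    states: dict[str, dict[str, str]] = {}
    calls: list[FrameshiftCall] = []
    for i, fam in enumerate(fam_order):
        kinds = set()
        ref_cds = None
        ref_len = 0
        for gid, locus in fam.members.items():
            feat = genomes[gid].feature_by_locus(locus)
            kinds.add(feat.kind)
            if feat.kind == "CDS":
                cds = feat.extract(genomes[gid].sequence)
                if _clean_translation(cds) and len(cds) > ref_len:
                    ref_cds, ref_len = cds, len(cds)
        rescued: dict[str, str] = {}  # genome -> state fixed by self-rescue
        if ref_cds is None and "CDS" in kinds:
            # no clean member: the survivors may themselves be frameshifted
            for gid, locus in sorted(fam.members.items()):
                feat = genomes[gid].feature_by_locus(locus)
                if feat.kind != "CDS":
                    continue
                cds = feat.extract(genomes[gid].sequence)
                res = self_rescue_frameshift(fam.family_id, gid, cds,
                                             min_tract=min_tract)
                if res is not None:
                    corrected, call = res
                    rescued[gid] = FRAMESHIFT_SLIPPAGE
                    calls.append(call)
                    if len(corrected) > ref_len:
                        ref_cds, ref_len = corrected, len(corrected)
        fam_states: dict[str, str] = {}
        if "CDS" not in kinds and "pseudogene" not in kinds:
            # RNA family: presence/absence at the annotation level
            for gid in genomes:
                fam_states[gid] = INTACT if fam.locus(gid) else ABSENT
        elif ref_cds is None:
            log.warning("family %s has no intact reference; skipped",
                        fam.family_id)
            continue
        else:
            for gid in sorted(genomes):
                if gid in rescued:
                    fam_states[gid] = rescued[gid]
                    continue
                igs_region = None
                if fam.locus(gid) is None:
                    igs_region = _region_between_anchors(
                        anchor_index, fam, genomes[gid])
                call = assign_gene_state(fam, genomes[gid], ref_cds,
                                         igs_region, min_tract=min_tract)
                fam_states[gid] = call.state
                if call.frameshift is not None:
                    call.frameshift.family_id = fam.family_id
                    calls.append(call.frameshift)
        states[fam.family_id] = fam_states

    # Dollo reconstruction per family
    rows: list[EventRow] = []
    ancestral = 0
    shared_intact = 0
    for fam_id, fam_states in states.items():
        full = {gid: fam_states.get(gid, ABSENT) for gid in genomes}
        present, ev = dollo_reconstruct(full, tree, fam_id)
        rows.extend(ev)
        if present:
            ancestral += 1
        if all(s in (INTACT, FRAMESHIFT_SLIPPAGE) for s in full.values()):
            shared_intact += 1
    carrier_cds = {}
    for c in calls:
        fam = table.family_by_id(c.family_id)
        locus = fam.members.get(c.genome_id)
        if locus:
            carrier_cds[(c.family_id, c.genome_id)] = genomes[
                c.genome_id].feature_by_locus(locus).extract(
                genomes[c.genome_id].sequence)
    rows.extend(place_frameshift_events(calls, tree, carrier_cds=carrier_cds))
    flag_convergent(rows, tree)
    events = EventTable(rows)
    summary = summarize_events(events, tree)

    # origin calls and deletion hotspots per genome
    origin_calls = {}
    hotspots = {}
    for gid, rec in genomes.items():
        prof = gc_profile(rec.sequence, circular=rec.is_circular)
        origin_calls[gid] = predict_origin(prof, rec)
        missing = _missing_positions(fam_order, anchor_index, states,
                                     genomes, gid)
        if missing:
            window = min(hotspot_window, len(rec.sequence) // 8)
            hotspots[gid] = hotspot_scan(
                missing, len(rec.sequence), window=window,
                n_perm=hotspot_nperm, seed=seed,
                origin_pos=origin_calls[gid].origin_pos)
        else:
            hotspots[gid] = []

    # IGS classes
    igs_by_genome = {gid: extract_igs(rec) for gid, rec in genomes.items()}
    spanning = {gid: set() for gid in genomes}
    for fam in fam_order:
        st = states.get(fam.family_id, {})
        for gid in genomes:
            if fam.locus(gid) is None and st.get(gid) in (ABSENT, PSEUDOGENE) \
                    and any(s in (INTACT, FRAMESHIFT_SLIPPAGE)
                            for g2, s in st.items() if g2 != gid):
                left, right = anchor_index.anchors(fam, gid)
                if left and right:
                    spanning[gid].add((left, right))
    igs_comparison = igs_classify_and_compare(igs_by_genome, spanning)

    # nonsynonymous rates on families intact (or slippage-corrected) everywhere
    triples: list[RateTriple] = []
    rate_sum = None
    if with_rates:
        corrections = {(c.family_id, c.genome_id): c for c in calls}
        for fam in fam_order:
            st = states.get(fam.family_id)
            if st is None or set(st) != set(genomes):
                continue
            if not all(s in (INTACT, FRAMESHIFT_SLIPPAGE) for s in st.values()):
                continue
            if any(genomes[g].feature_by_locus(fam.members[g]).kind != "CDS"
                   for g in genomes):
                continue
            cds = {}
            for gid in genomes:
                seq = genomes[gid].feature_by_locus(
                    fam.members[gid]).extract(genomes[gid].sequence)
                c = corrections.get((fam.family_id, gid))
                if c is not None:
                    seq = correct_frameshift(seq, c.cds_indel_pos, c.indel_sign)
                cds[gid] = seq
            try:
                aln = codon_align(fam.family_id, cds,
                                  frameshift_corrected=bool(
                                      set(cds) & {c.genome_id for c in calls}))
                triples.append(rate_triple(fam.family_id, aln, ingroup[0],
                                           ingroup[1], outgroup))
            except ValueError as exc:
                log.info("family %s excluded from rates: %s",
                         fam.family_id, exc)
        if any(t.fold is not None for t in triples):
            rate_sum = fold_summary(triples)

    return TriadResult(table, states, calls, events, summary, ancestral,
                       shared_intact, hotspots, igs_comparison, triples,
                       rate_sum, origin_calls)


def _infer_outgroup(tree: RootedTree) -> str:
    root = tree.tree.seed_node
    for child in root.child_nodes():
        if child.is_leaf():
            return child.taxon.label
    raise ValueError("cannot infer outgroup; pass one explicitly")


def _region_between_anchors(anchor_index: _AnchorIndex, fam,
                            genome: GenomeRecord) -> str | None:
    left, right = anchor_index.anchors(fam, genome.id)
    if not left or not right:
        return None
    lf = genome.feature_by_locus(left)
    rf = genome.feature_by_locus(right)
    lo, hi = sorted([lf.end, rf.start] if lf.end <= rf.start
                    else [rf.start, lf.end])
    if hi - lo > 20_000:
        return None
    return genome.sequence[lo:hi]


def _missing_positions(fam_order, anchor_index, states, genomes,
                       gid: str) -> list[int]:
    """Genomic positions of missing/eroded genes in one genome.

    Eroded genes with an annotated locus sit at the locus midpoint; absent
    genes at the midpoint of the gap between their nearest annotated
    neighbours.
    """
    rec = genomes[gid]
    out = []
    for fam in fam_order:
        st = states.get(fam.family_id, {}).get(gid)
        other_present = any(
            s in (INTACT, FRAMESHIFT_SLIPPAGE)
            for g2, s in states.get(fam.family_id, {}).items() if g2 != gid)
        if not other_present:
            continue
        if st == PSEUDOGENE and fam.locus(gid):
            f = rec.feature_by_locus(fam.locus(gid))
            out.append((f.start + f.end) // 2)
        elif st in (ABSENT, PSEUDOGENE):
            left, right = anchor_index.anchors(fam, gid)
            if left and right:
                lf = rec.feature_by_locus(left)
                rf = rec.feature_by_locus(right)
                if lf.end <= rf.start:
                    out.append((lf.end + rf.start) // 2)
                else:  # wrap-around gap
                    n = len(rec.sequence)
                    out.append((lf.end + ((rf.start + n - lf.end) % n) // 2) % n)
    return sorted(out)
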