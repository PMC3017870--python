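# Methods

This note records the models, conventions and numerical choices behind
`reducta`, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and I/O

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted only at the I/O boundary (tested
explicitly on hand-written records). Compound (joined) feature locations
are normalised to their full span; a feature wrapping the origin of a
circular record triggers rotation of the whole sequence so no feature spans
position 0, with the rotation offset kept on the record. Ambiguity codes
other than N are rejected at read time because every downstream scanner
assumes a 4-letter alphabet.

Intergenic spacers (IGS) are defined between adjacent annotated genes of
any kind — protein-coding, RNA, or pseudogene. Abutting genes yield a
zero-length spacer; only genuinely overlapping gene coordinates yield no
spacer. The median IGS includes zero-length spacers. Coding-density
percentages count each base covered by at least one gene once (interval
union), so overlapping genes do not inflate the fraction.

## Scanners

**Homopolymer tracts** are maximal single-base runs at or above a length
threshold (default 9 bp for reporting, matching the "long tract" convention
for AT-rich endosymbiont genomes). Tract counting inside protein-coding
genes defaults to the *coding strand* (`--strand coding`): a genomic polyT
run inside a minus-strand gene is a coding-strand polyA. Slippage operates
on the transcribed strand, which makes this the biologically meaningful
convention; the genomic-strand alternative is exposed as an option.

**Palindromes** follow the EMBOSS parameterisation: the 30–1000 bp bounds
are arm-length bounds, the reported length is the total span
2·arm + loop, mismatches are substitutions only (no indels inside arms),
and arms must begin and end on matching bases (a leading mismatch is the
same candidate at a wider loop; a trailing one a shorter arm). Among
overlapping candidates the longest arm wins, ties broken by fewer
mismatches then leftmost position. The finder is vectorised per loop size
but is verified against a naive per-position extension oracle on short
sequences, under the identical candidate and suppression definitions.

**GC skew** is (G−C)/(G+C) in sliding windows (1 kb window, 10 bp step by
default, circular wrap honoured); windows with no G or C get skew 0 and a
flag rather than being dropped, keeping the profile aligned to positions.

**Origin prediction.** The cumulative skew of a genome with a G-rich
leading strand falls over the lagging replichore and rises over the
leading one, so its raw extrema mark origin and terminus — but the raw
extremum of a noisy walk can wander a few kb. The origin is therefore
placed with a genome-half matched filter: D(v) = mean skew over
[v, v+n/2) minus mean skew over the complementary half, maximised over v.
This pools the entire profile and assumes roughly balanced replichores
(true to a good approximation for bacterial chromosomes and exactly true
for the generator). D at the optimum is about twice the per-replichore
skew amplitude and is used as the confidence statistic: calls below 0.05
(i.e. amplitude ≈ 0.025) are returned as not confident. The threshold was
set against the no-skew null, where the maximised D stays below ~0.04 even
on 100 kb genomes and shrinks with length; a planted amplitude of 0.05
gives D ≈ 0.10. On 600-gene genomes the planted origin is recovered to
within ~2 kb at amplitude 0.05.

**dnaA boxes** are IUPAC-consensus matches (default TTWTNCACA) on both
strands; a "cluster" is ≥ 4 hits within 300 bp — the consensus density
typical of bacterial oriC regions; the threshold is configurable and only
used to report presence or absence of a cluster.

## Orthology

Protein similarity is Smith–Waterman local alignment with BLOSUM62 and
affine gaps (open 11, extend 1), computed by Biopython's PairwiseAligner;
the e-value-like statistic is the ungapped Karlin–Altschul form
K·m·n·e^(−λS) with fixed BLOSUM62 constants (λ = 0.267, K = 0.041). It is
a ranking and thresholding device — the screens it feeds use coarse
cutoffs (1e−5) — not a claim of BLAST bit-exactness.

Reciprocal best hits are computed per genome pair behind a shared-4-mer
prescreen (≥ 10 shared protein 4-mers before a pair is aligned; disabled
in oracle tests). Score ties break by closest gene-order index, then
lexical locus order. Pairwise RBH graphs merge into families by single
linkage; inconsistent triangles are split back into consistent
subfamilies and logged. RNA genes are matched across genomes by annotated
gene name.

In the default **hybrid** mode, the strict gene-order conservation of the
genome set is then used twice: loci the RBH pass left unmatched become
singleton families, and any two families with disjoint genome sets whose
members fall between the same bracketing neighbour families are merged.
This recovers families whose every pairwise homology signal is degraded —
the characteristic case is a frameshift near the start codon garbling the
translation in two of three genomes at once. Pure-RBH mode exists for
genome sets without conserved order.

## Gene states

Each family needs one intact reference member (the longest member with a
clean full-length translation). Classification of another member against
it:

* length < 60 % of the reference → PSEUDOGENE (truncation, consistent with
  the 60 % coverage convention of the presence screen);
* codon-multiple length: INTACT if the translation is internally
  stop-free, PSEUDOGENE otherwise. The reading frame itself is the
  arbiter here — pairwise nucleotide alignments at 0.1–0.2
  substitutions/site routinely invent compensating gap pairs, so alignment
  gaps alone are not trusted;
* non-codon-multiple length: the nucleotide alignment (match 2, mismatch
  −3, open −7, extend −2) locates the frame disruption. Exactly one 1-bp
  indel lying in a polyA/polyT tract of ≥ 7 bp (in either sequence;
  the aligner may slide a gap to the tract edge, so both tract bases are
  tried around the indel) whose conceptual correction restores an
  internally stop-free frame → FRAMESHIFT_SLIPPAGE; anything else →
  PSEUDOGENE. When the aligner scatters a single net indel across
  compensating gaps, a direct tract-by-tract correction is attempted, but
  only for tracts near the aligned gap positions — an unrelated distant
  tract must not rescue a genuinely eroded gene.

The default minimum tract of 7 bp is permissive enough for the 8–12 bp
tracts at which slippage frameshifts are observed in endosymbionts and
strict enough to exclude isolated indels; it is configurable.

A family whose only survivors are themselves frameshifted has no clean
reference; a reference-free rescue then tries to undo one 1-bp indel in
each tract of a member whose length is off-frame and accepts the result if
it yields a clean ATG-to-stop frame.

For families with no locus in some genome, the corresponding intergenic
region (located via conserved gene order, capped at 20 kb) is scanned for
residual homology by aligning the reference protein against all six
conceptual translation frames under the same 60 %/1e−5 rule: a hit means
an eroded but recognisable pseudogene relict, no hit means ABSENT.

FRAMESHIFT_SLIPPAGE counts as functionally intact throughout: in the
severity order, in the shared-gene counts, and in the rate analysis (the
indel is corrected before alignment).

## Dollo reconstruction and events

States order INTACT (= FRAMESHIFT_SLIPPAGE) < PSEUDOGENE < ABSENT and may
only increase along root-to-leaf paths; gains are forbidden. Minimal-event
assignments are found by a small Sankoff dynamic programme with unit cost
per state change (a change to PSEUDOGENE is an EROSION event, to ABSENT a
LOSS); ties resolve toward the least-degraded internal states, i.e.
leafward event placement, and the reconstruction is verified against
exhaustive minimal-event search over all 64 three-leaf state combinations.
Frameshifts are not Dollo-ordered states — they are revertible and are
treated as branch annotations: calls in different genomes at the same
reference tract (positions agreeing to within the tract length, same
indel sign) are one inherited event on the stem of the carrier clade;
otherwise each carrier gets a leaf event. A family is convergent when it
has events on two branches neither of which is ancestral to the other.

Per-lineage "missing or eroded" counts the families with at least one
LOSS/EROSION event anywhere on the root-to-leaf path, so stem events count
in every descendant lineage.

The generator never plants the same-family event on both sister branches:
such a pair is provably unpolarizable (parsimony collapses it to one stem
event), so it would make the planted truth unrecoverable by any method
rather than test the pipeline.

## Hotspots and statistics

The deletion-hotspot scan slides windows (32 kb default — the scale of the
origin-adjacent deletion cluster in reduced genomes; step window/16) around
the circle, counts missing-gene positions per window, and builds the null
by uniformly re-placing the same number of positions (seeded). Each
window's p-value is the fraction of permutations whose *maximum* window
count reaches the observed count, so the scan is corrected for searching
every window; under uniform simulations the attained p-values are
verified to be stochastically no smaller than uniform. Overlapping
significant windows are merged; a merged window is flagged near-origin if
it falls within one window length of a supplied origin.

The rank-sum test enumerates the exact null over all C(N, n1) rank
assignments (midranks for ties) when n1+n2 ≤ 20 — the cost cap of 184 756
enumerations — and reports p = min(1, 2·min(P(W≤w), P(W≥w))); larger
samples use the normal approximation with tie correction and a 0.5
continuity correction. The two agree to |Δp| ≤ 0.01 at n1 = n2 = 10 on
continuous data; heavy ties degrade the approximation somewhat, which is
why the exact path covers the small-sample sizes where ties bite.

## Rates

dN is Nei–Gojobori (1986): nonsynonymous site counts averaged over both
sequences, pathway-averaged difference counts (pathways through stop
codons excluded; if all pathways pass through a stop the unweighted count
is used), Jukes–Cantor correction dN = −(3/4)·ln(1 − (4/3)pN), saturation
(pN ≥ 3/4) flagged as infinite. A codon-ML estimator would be the other
natural choice; NG86 is self-contained, deterministic, and fully adequate
for *ratios* of branch lengths at endosymbiont-scale divergence, which is
what the fold statistic needs. Codon alignments come from global protein
alignment back-translated; gapped columns are dropped pairwise
(maximising usable sites per pair); insertions relative to the longest
member are not retained as columns, which loses no pairwise information
used here. Stop codons never count as sites; the standard genetic code is
assumed (the target organisms are gamma-proteobacteria).

Branch decomposition is the three-point formula with the outgroup third:
K1 = (d12 + d13 − d23)/2, K2 = (d12 + d23 − d13)/2; negative solutions —
expected sampling noise at low divergence — are clipped to 0 and flagged
rather than erroring; the fold K1/K2 is undefined when K2 = 0. The
decomposition exactly inverts additive three-taxon metrics (tested to
1e−12).

## The synthetic generator

The generator builds the study conditions directly: a circular ancestor of
600 protein-coding genes (mean CDS ≈ 1 kb, normal sd = mean/4, minimum 60
codons) and 40 tRNA genes, geometric intergenic spacers (mean 134 bp),
27.5 % GC. Codons are sampled i.i.d. with in-frame stops rejected; because
the rejected stops are AT-rich, the sampling composition for coding
regions is solved by bisection so the *realized* coding GC hits the
target. PolyA/polyT tracts arise naturally from the AT bias (i.i.d.
sampling undercounts the longest tracts relative to real slippage-expanded
genomes — the planted-event machinery upgrades a run to ≥ 9 bp when a
frameshift needs one). Ten exact inverted repeats (arms 30–70 bp, loops
0–20 bp) are planted in random spacers. GC skew of amplitude 0.06 is
imposed by re-assigning G/C positions by replichore (G with probability
(1+s)/2 on the leading strand), protecting start/stop codons, never
creating an in-frame stop, and leaving palindrome spans untouched.

Evolution along the rooted tree ((vaf:0.05, flo:0.05):0.03, pen:0.08) —
branch lengths in substitutions per site, chosen to emulate the modest
divergence of a congeneric endosymbiont triad — uses an F81 process at the
AT-biased stationary composition: mutation events at rate t/(1−Σπ²) per
site with the new base drawn from π, so composition is exactly stationary
and the expected realized changes per mutable site equal the branch
length (verified within 3 sd). Start/stop codons are immutable; proposals
creating an in-frame stop in an intact gene are re-drawn among safe bases
(for slippage-frameshifted genes the check runs in the conceptually
corrected frame, and the diagnostic tract itself is immutable); planted
palindrome spans are immutable along branches, emulating selective
retention of intergenic palindromes. Pseudogenes evolve without
constraint.

Planted events strike so-far-intact genes, at most one per family per
branch, with per-branch probabilities defaulting to
(loss, erosion, slippage) = (0.030, 0.004, 0.012) for `vaf`,
(0.028, 0.004, 0.006) for `flo`, (0.005, 0.001, 0.006) for `pen` and
(0.008, 0.002, 0.002) for the stem — magnitudes that reproduce the
asymmetric per-lineage loss counts (tens vs a few) and slippage-gene
counts (≈ 8/4/4) characteristic of the target system. Losses remove the
gene and leave a scar spacer of Uniform(0, 0.3·gene length) of *random*
sequence — the residue of a deletion plus subsequent decay — which makes
spanning spacers recoverably longer than conserved ones while keeping true
absence (no residual homology) distinguishable from erosion.
Pseudogenization plants 1–3 disruptions: optional 1–2 bp deletions placed
away from tracts ≥ 5 bp (so they cannot mimic slippage), then a nonsense
codon last, in the final reading frame, so every eroded gene carries an
in-frame stop; the planted stop is held immutable on descendant branches
(a reverting substitution would silently erase the event from the
sequence record while the manifest still lists it). Slippage events insert or delete one base inside a
coding-strand A/T tract of ≥ 9 bp (upgrading a ≥ 5 bp run by substitution
when necessary). Forced events (`forced_events`) allow deterministic
planting of, e.g., convergent losses or stem frameshifts for targeted
tests.

Everything is driven by one seeded NumPy generator: identical
configurations give byte-identical fixtures.

**What passing on synthetic data does and does not show.** The triads
exercise the full pipeline under conserved gene order, paralog-free
content, uniform rates across sites and genes, indels only at planted
events, and annotations that never miscall gene boundaries. Perfect
planted-event recovery under those conditions validates the logic and the
thresholds' interplay, not performance on real annotation noise, rate
heterogeneity, repeat-induced misassembly, or paralogy — none of which the
generator emulates. Real-data quantities that depend on curation
(annotation-specific gene counts, exact per-lineage totals) should be read
as benchmarks, not unit-testable constants.

## Problem sizes

The test suite runs triads of 20–120 genes (events and statistics scale
per gene, so smaller triads exercise the same code paths), the acceptance
script the full 600-gene condition; the rate-recovery experiments use 200
genes × ~300 codons for the equal-rate and doubled-rate checks.
Oracle suites use 1000×5 kb strings (homopolymers), 100×2 kb strings
(palindromes, against the naive oracle), 200×100-codon pairs (dN, to
1e−9), and all 64 three-leaf state combinations (Dollo).

## Known limitations

* Orthology assumes effectively paralog-free genomes (true of reduced
  endosymbionts, wrong for most free-living bacteria) and conserved gene
  order for the hybrid rescue.
* The origin caller assumes roughly balanced replichores; a severely
  unbalanced genome would bias the matched filter.
* The e-value-like statistic is calibrated for ranking, not for absolute
  significance; screens at much stricter cutoffs than 1e−5 should use a
  real search tool's statistics.
* dN saturates above roughly one substitution per nonsynonymous site;
  triads far more divergent than the target system need a codon-ML
  estimator.
* The rank-sum exact path is O(C(N, n1)) and capped at N = 20.
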