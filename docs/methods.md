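# Methods

This note documents the models and procedures implemented in `cnvpol`, the
choices made where several designs were defensible, and the limits of what
the synthetic system can demonstrate.

## Catalog construction (three-step consensus merge)

Calls are 0-based half-open deletion intervals relative to the reference,
tagged with caller (PE/SR/RD) and accession. The merge proceeds in three
steps:

1. **Per-accession consensus.** Calls are clustered by single-linkage under
   the predicate *reciprocal overlap ≥ 0.5 on the same chromosome*, where
   reciprocal overlap of intervals a, b is `min(o/|a|, o/|b|)` with `o` the
   overlap length. Single linkage (transitive closure) is the standard
   choice for RO-based SV merging and is exactly checkable against an
   all-pairs connected-components oracle. Clusters with ≥ 2 distinct
   callers survive.
2. **Breakpoint refinement.** SR calls carry single-nucleotide junctions,
   so the modal (start, end) pair among SR members wins (ties: smallest
   start, then end). Without SR, the per-endpoint lower median of PE calls
   is used, still flagged precise; RD-only clusters take the widest member
   and are flagged imprecise. This deterministic evidence-priority rule
   replaces local de-novo assembly of the junction, which is an external
   tool wrapped by real pipelines rather than an algorithm; in the
   noise-free limit it preserves the property that essentially the whole
   catalog is at single-nucleotide resolution.
3. **Population merge.** The per-accession consensus calls are clustered
   again under the same predicate (the same 0.5 threshold is used for both
   steps); clusters carried by ≥ 3 distinct accessions become catalog
   events. The representative interval is the precise member whose length
   is the cluster median (lower median; ties: smallest start, then end) —
   any member-based representative works, but this one is reproducible and
   favours typical, precisely resolved breakpoints.

Both thresholds (≥ 2 callers, ≥ 3 accessions) and the RO level are
`MergeParams` fields. Calls on different chromosomes never cluster; strand
is ignored (deletions are unstranded).

## Ancestral-state polarization

A deletion relative to the reference is an **insertion** in the reference
lineage if the outgroup lacks the sequence, a **deletion** if the outgroup
has it. The classifier:

1. **Projection.** Ortholog gene anchors are chained into co-linear blocks
   (same chromosome pair and strand, outgroup order preserved, consecutive
   anchors ≤ 500 kb apart in both genomes; blocks need ≥ 2 anchors).
   Event endpoints are linearly interpolated between the bracketing anchor
   midpoints; beyond a block's terminal anchor the mapping extends by
   constant offset, with the whole extrapolated distance carried as an
   uncertainty margin (between anchors the margin is the inter-anchor
   length distortion |Δref − Δout|). Projection fails off all blocks or
   across a block boundary; such events are `undefined`.
2. **Window and gaps.** The outgroup window is the projected interval
   ± 2 kb flanks, widened by the projection margin for alignment search
   only. Assembly-gap (N-run) cover is judged on the flank-window around
   the *located* junction once the flanks are aligned (see below); > 10%
   gap cover ⇒ `undefined`.
3. **Flank anchoring and span.** The junction-proximal kilobase of each
   2-kb flank must align into the window (probe identity ≥ 0.85, ≥ 50% of
   probes); the distal flank may legitimately cover neighbouring variants,
   which is why the gate is proximal. When both flanks locate (edlib infix
   alignment), the distance between the left flank's end and the right
   flank's start measures how much of the event the outgroup retains:
   span < 20% of the event length ⇒ insertion; span ≥ 80% with the event
   body also ≥ 50% aligned ⇒ deletion; otherwise `undefined`.
4. **Body-alignment fallback.** If a flank cannot be located, the aligned
   fraction of the event body decides with the same 0.2/0.8 thresholds.

The flank-span criterion, rather than body alignment, is the primary
signal because repetitive events defeat presence/absence of sequence
content: a tandem-array expansion leaves copies of its unit in the
outgroup window, and a TE insertion may have family relatives nearby, so
their bodies align even though the event is an insertion. The span is
immune to this. Events > 100 kb would be probed with ten evenly spaced
1-kb probes instead of full tiling (the default generator caps event
sizes well below this).

All thresholds (0.2/0.8 aligned/span fractions, 0.5 flank anchoring, 0.1
gap cover, probe identity 0.85) are `PolarizeParams` fields; they were
chosen to be robust at 2% outgroup divergence, far from both the ~0–5%
probe error of a truly present sequence and the ~35% best-infix identity
noise floor of random DNA.

## Mechanism classification

Signatures are evaluated on the reference interval: the catalog consists
of deletions relative to the reference, so the affected sequence exists in
the reference for both polarity states (an insertion-state event is
reference-private sequence; a deletion-state event is ancestral sequence
the reference retained).

Primitives:

* `junction_microhomology` — longest common prefix of `seq[start:]` and
  `seq[end:]` plus longest common suffix of `seq[:start]` and `seq[:end]`,
  capped at 500 bp; case-insensitive, N never matches.
* `flanking_homology` — substitution-only outward extension on the four
  junction windows while cumulative identity stays ≥ 0.9; a run must end
  on a match, and extension beyond the initial exact-match prefix must
  itself reach the identity threshold (otherwise a long microhomology
  followed by random matches would masquerade as extended homology —
  exactly the case the ambiguous band below must catch). Indel-tolerant
  alignment was not needed for the homologies this system creates and is
  a known limitation for real data.
* `te_coverage` — fraction of the event covered by the union of TE
  annotations; best family = largest single-element overlap (ties:
  lexicographic).
* `vntr_context` — true iff both breakpoints lie inside one annotated
  tandem array and the event length is within 0.1 periods of an integer
  multiple of the array period.

Decision order (first match wins): **VNTR → MEI (TE cover ≥ 0.8) → NAHR
(homology ≥ 50 bp at ≥ 90% identity) → NHR (microhomology ≤ 10 bp,
sub-labelled NHEJ at 0 bp / MMEJ at 1–10 bp) → ambiguous** (this includes
junction homology in the (10, 50) bp no-man's-land, imprecise breakpoints,
and > 50% N in the event body). Body signatures precede junction
signatures because they are more specific; the order is deterministic by
construction. NHEJ and MMEJ are pooled into NHR in all summaries, with the
sub-label preserved per event.

## Gene impact, sharing, enrichment

Overlapping (gene, event) pairs are categorised by precedence: `full` if
the event contains the annotated gene span (UTRs included; a config flag
could narrow this to the CDS span, but whole-span containment is the
stricter and more interpretable reading), else `partial_cds`, else
`utr_only`, else `intron_only`. Summaries count distinct genes (a gene hit
by several events takes its highest-precedence category), and
`cds_disrupted_genes = full + partial_cds` is asserted as an identity.
Population sharing labels each event from its carriers' groups
(cultivated/wild) and, restricted to carriers in those subgroups, the
indica/japonica partition (with `neither` when no carrier belongs to
either). Enrichment is the upper-tail hypergeometric test per term over a
user-supplied gene→term table, BH-adjusted (`scipy`'s step-up procedure);
terms absent from the universe are skipped. Term assignment and the
rice-specific/conserved gene split are inputs, not computations — they
require external annotation resources.

## Non-co-linear genes and duplication origin

A CNV gene is co-linear when ≥ 50% of its exonic probes align into its
projected outgroup window; genes inside reference-lineage insertions fail
this naturally (failed projection also counts as non-co-linear). The
ancestral-copy search seeds with exact 16-mers of the gene span (every
32 bp), clusters seed hits by diagonal band, verifies candidates by edlib
infix alignment of the whole span, and accepts hits at ≥ 80% identity over
≥ 50% of the gene length, excluding any hit overlapping the query
(tandem copies are found by walking edlib's tie locations). Ties break by
identity, then length, then leftmost position.

For pairs at ≥ 90% identity the origin is read from the new copy's
breakpoint context, in precedence order: **TE** if TE annotations lie
within 1 kb on both sides of the gene copy (the most specific signature —
transposon capture physically brackets its cargo), else **NAHR** if the
duplication boundaries carry ≥ 50 bp of ≥ 90% homology, else **NHEJ** if
boundary microhomology ≤ 10 bp, else unresolved. The duplication
boundaries come from the containing polarized CNV's refined breakpoints
when available — the catalog already resolves them to the base pair — with
an aligned-extension estimate (50-bp blocks at ≥ 80% identity) as
fallback when no event is supplied.

## The synthetic system

The generator (`cnvpol.sim`) defines the study conditions; all parameters
are `SimConfig` fields and every byte of output is a deterministic
function of the seed.

* **Genome.** Two 1-Mb chromosomes of i.i.d. background at GC 0.44
  (rice-like); a 6-family TE library (one Mutator-like family, consensus
  lengths 400–7000 bp) with 80 genomic copies at 80–100% identity
  (fragments allowed); 30 exact tandem arrays (period 5–60 bp, 4–12
  copies); 120 gene models (1–5 kb, 2–6 exons, UTRs at both ends).
  Features never overlap each other; events may overlap genes but keep
  1 kb clear of TE/array features so junction signatures stay
  attributable.
* **Events.** 50 per mechanism by default. Sizes are log-normal with
  median 1118 bp and log-sd 1.62 (mean/median ≈ 3.7, ~90% below 10 kb —
  the shape of an intermediate-size NGS catalog), clipped to
  [62 bp, 30 kb]; the cap keeps placement feasible on a feature-fragmented
  1-Mb chromosome (placement is largest-footprint-first rejection
  sampling). MEI events are a full TE consensus at 0.5–2% divergence with
  a 5–20 bp target-site duplication; NAHR events carry a 100–300 bp repeat
  at ~98% identity at both junctions; NHR events get an enforced junction
  microhomology of 0 bp (40%, NHEJ) or 1–10 bp (MMEJ); VNTR events remove
  an integer number of periods from a dedicated array, leaving ≥ 3 copies.
  An exact `insertion_fraction` (default 0.8) of events are
  reference-lineage insertions; carriers are 3–12 accessions drawn
  uniformly.
* **Outgroup.** The ancestral haplotype is the reference minus all
  insertion-state events, materialised explicitly; the outgroup applies
  per-site substitutions (default 2%), small tracked 1–3 bp indels
  (default 10⁻³/site), and Poisson-placed 2–6 kb N-runs (default 1 per
  chromosome). Anchor coordinates and per-event gap-overlap fractions come
  from the generator's exact coordinate maps. Gene duplications (off by
  default) copy a clean gene ± 100 bp to a new locus at 3% divergence
  inside an insertion-state event, flanked by Mutator-like copies (TE
  origin), a 200-bp homologous pair (NAHR), or an enforced 3–8 bp
  microhomology (NHEJ).
* **Callers.** Per truth event × carrier × caller, a call is emitted with
  the (caller, size-class) sensitivity; size classes are 50–500 bp,
  0.5–10 kb, > 10 kb, and the defaults make RD blind below 500 bp and SR
  blind above 10 kb, mimicking the methods' known biases. SR breakpoints
  are exact; PE endpoints get rounded Gaussian jitter (sd 50 bp); RD
  endpoints snap outward to 100-bp bins (bin size 1 disables snapping —
  the noise-free limit). False calls are caller-private, uniform at
  5/Mb/caller/accession with sizes resampled from the truth distribution.

**What passing tests show — and don't.** The system demonstrates that the
integration, polarization, classification and origin logic are correct
under a faithful error model; it does not demonstrate robustness to real
aligner artefacts, segmental-duplication-rich reference errors,
diverged-TE annotation gaps, indel-dominated outgroup divergence, or
caller biases beyond sensitivity/jitter/false-call rates. Event sizes are
capped at 30 kb (real catalogs have rare much larger events), arrays are
exact tandem copies, and the outgroup differs by substitutions, small
indels and gaps only — no rearrangements.

## Problem sizes and numerical choices

The default fixture (200 events, 12 accessions, 2 × 1 Mb, ~4600 calls)
runs the full pipeline in a few seconds; the complete test suite and the
acceptance script each finish in well under a minute on one CPU. The null
calibration experiment uses N = 1000, K = 250, n = 250, where the discrete
achievable level of the upper-tail hypergeometric test is 0.047 — close
enough to the nominal 0.05 for a ±0.02 calibration check; smaller designs
have coarser attainable levels and would fail the check for reasons
unrelated to correctness. Degenerate inputs are defined: empty call sets
produce an empty catalog and a zero report; empty anchor lists make all
projections fail (everything `undefined`); imprecise events are never
assigned a mechanism. All tie-breaks (modal/median representatives,
lexicographic families, leftmost hits) are deterministic, and clustering
output is invariant to input order.
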