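# Methods and design notes

This note documents the models behind `pmhd`, the defaults that matter, what
the synthetic-data generators do and do not emulate, and the numerical
choices a maintainer should know about.

## The element model

The P element is modeled as a 2907-nt consensus bounded by 31-bp terminal
inverted repeats (TIRs); for simulation the interior is seeded-random
sequence and the final 31 nt are the reverse complement of the first 31.
Variants are named deletion-interval sets in 1-based inclusive consensus
coordinates: FP has none; KP is the single interval (808, 2560), leaving a
1154-nt element. Variant typing (`classify_variant`) seeds exact 15-mers,
chains them greedily and reports uncovered internal gaps ≥ 20 bp as
deletions. Junction microhomology — chance identity between the bases just
inside and just beyond a deletion — can shift both reported breakpoints by a
few bases in either direction, which is why the KP call uses a ±3-bp
tolerance on the canonical junctions (the deletion *length* is unaffected).

Amplicon prediction maps a primer pair's annealing windows (20 bp at each
end of the consensus span) onto the typed template: a window overlapping a
deletion yields no product, otherwise the product shrinks by the deleted
bases inside the span. Primer coordinates are configuration, not constants:
published product sizes from the original assays cannot be reconstructed
without the unpublished primer sequences, so no specific pair is hard-coded.
qPCR relative quantification is classical ΔΔCt with amplification efficiency
fixed at 2.0 (perfect doubling), normalized to a single-copy reference gene
and a reference strain.

## The junction library and insertion caller

The simulator reproduces the structure of a restriction-digest /
adapter-ligation junction assay on pooled genomic DNA:

* **Pool and occupancy.** Each library represents a pool (default 40
  individuals). Each planted insertion is carried by each individual with
  probability equal to its occupancy — a Bernoulli model of within-line
  insertional polymorphism. The pool composition of real lines is unknown;
  this independence assumption is the simplest defensible choice.
* **Digest geometry.** For each enzyme (HhaI `GCGC`, TaqI `TCGA`) and each
  element side, the junction fragment runs from the nearest recognition site
  inside the element, across the junction, to the nearest site in the flank.
  Fragments outside the 300–600-bp selection window are discarded. On
  seeded-random sequence, sites occur at ~4⁻⁴ density, giving realistic
  fragment-length variation — and, as in the real protocol, leaving a
  substantial fraction of loci with *no* selectable fragment. Truth
  bookkeeping records per-fragment geometry so detectability is a computable
  property, not an empirical surprise.
* **Reads.** Each selected fragment plus a fixed 30-mer adapter is read as a
  250-bp pair, one mate primed from the element interior, the other from the
  adapter end; sequencing error is uniform substitution. Reads shorter than
  the molecule are truncated, never an error. Nested PCR is not base-level
  simulated; size selection plus element anchoring reproduce its effect.
* **Orientation and the TIR.** The two element termini are identical over
  the 31-bp TIR, so a terminus match alone (default 20 bp, the read filter)
  fixes the junction but not which end of the element it is. The caller
  resolves orientation from subterminal context (up to 60 bp before the
  junction) and drops end-ambiguous reads. The simulator records, per
  fragment, the minimal context that distinguishes the ends, so the
  detectable-truth predicate matches the caller's capability exactly.
* **Calling.** Flanks are mapped by an exact 31-mer anchor at the
  junction-proximal base against a 2-bit packed, sorted k-mer index, then
  extended with ≤ 2 mismatches; multi-best flanks are dropped as ambiguous
  (conservative, in the read-discarding spirit of the assay). Left- and
  right-junction positions of one insertion differ by 1 bp by convention;
  the 10-bp merge window absorbs that and the 8-bp target-site duplication,
  which is not modeled explicitly.

Recall/precision statements are made against *detectable* truth: insertions
with at least one size-selected, orientable fragment that leaves a mappable
flank in one of the mates. Loci the protocol cannot see (no fragment in the
size window, or element context confined to the TIR) are excluded from the
denominator — a deterministic function of digest geometry, computed before
any reads are simulated.

## Small RNAs

Cluster-embedded element copies emit piRNA-class reads, 24–35 nt uniform,
drawn from the copy's variant sequence. For unistrand clusters the primary
reads are on the precursor strand relative to the element; a configurable
fraction (default 0.5) of secondary reads on the opposite strand stands in
for cleavage-derived ping-pong production. Dual-strand clusters emit both
strands at the full rate. Per-insertion rates are Poisson with means set by
cluster activity rank (defaults 400 reads for active, 40 for low-activity
clusters, scaled by occupancy). The decoy miRNA set is 50 synthetic 21–23-nt
sequences generated from a fixed internal seed; it is a stand-in for a miRNA
catalogue and is used only for removal and as the RPM denominator.

Quantification removes miRNAs first (counting them regardless of length),
then size-filters to 24–35 nt inclusive, then maps exactly (0 mismatches by
default, configurable to 3) against the consensus. Multi-hit reads are
counted once at a deterministic position (sense before antisense, lowest
coordinate). Reads spanning a variant's internal deletion junction are
element-derived but not consensus-mappable; the generator records
consensus-mappable truth under the same policy, so conservation checks are
exact. RPM = element reads × 10⁶ / miRNA reads.

**Embryo mode** rescales piRNA rates so the true abundance sits below
10 RPM, reproducing the near-absence of zygotic piRNAs in 0–24-h embryos
against the > 1000 RPM of young F1 ovaries. RPM granularity is 10⁶ divided
by the miRNA count, so resolving a 10-RPM bound requires ≥ ~10⁵ miRNA
reads; embryo-mode scenarios therefore use a 10⁶-read miRNA denominator.

## Strain panels and statistics

Simulated panels draw piRNA RPM and mRNA levels from seeded lognormals and
generate GD percentages through a logistic link:
GD% = 100 · logistic(β₀ + β_pi·z(piRNA) + β_KP·z(KP) + ε), with both betas
negative by default (−3, −1) — piRNA abundance and KP mRNA act as
suppressors of dysgenesis. F2 and cross-A* scores reuse the linear predictor
with independent noise. The generative coefficients are recorded so the
regression layer can be validated on sign and recovery.

The regression reports, per predictor: the coefficient of raw y on z-scored
predictors (exact recovery of planted betas in the noise-free case), the
fully standardized coefficient, the partial correlation `t/√(t² + df)`, t
and two-sided p. Both coefficient flavors are reported because "partial
regression R" is ambiguous between them in common usage; validation asserts
signs and recovery, not a preferred flavor. Small-n fits (5 strains, 2
predictors, 2 residual df) are deliberately accepted. No multiple-testing
correction is applied anywhere.

Hierarchical clustering is hand-rolled complete linkage on z-scored
features with a deterministic tie-break (smallest label pair, clusters named
by their smallest member), making output invariant under input permutation;
scipy's implementation serves as the independent oracle in tests, never as
the implementation. The t test is pooled-variance Student by default with
Welch as an option; zero-variance equal-mean comparisons return (0, 1) by
convention. Phenotype labels are strict: low iff GD < 10.0 %.

## Cluster annotation

Dual-strand iff min(sense %, antisense %) > 20.0 (strict); unistrand
precursor = majority strand. Activity: stable sort by cluster-unique piRNA
count descending, ties by lexicographic cluster id, ranks 1–15 active.
Membership requires the insertion point inside the interval; overlapping
clusters resolve to the smallest (deterministic and conservative).
Orientation is annotated only for unistrand clusters — both strands of a
dual-strand cluster are transcribed, so sense/antisense has no meaning
there. Paper-emulation mode produces exactly 142 clusters, the size of the
published D. melanogaster cluster catalogue.

## Scales, determinism and limitations

Default test and demo scales (two to five chromosomes of 0.2–1 Mb, 8–20
insertions per line, 10⁴–10⁶ small-RNA reads) were chosen so that every
scenario has enough events to exercise its statistics while a full run of
suite plus acceptance script completes in well under a minute each; all
randomness flows from explicit seeds and every generator is bitwise
reproducible.

What passing tests do **not** show about real data: the genome is random
sequence, so there are no repeats beyond the planted duplications — real
multi-mapping is harsher than the ambiguity the tests exercise; sequencing
error is uniform substitution without indels or PCR duplicates; piRNA
production is Poisson around rank-determined means, not the heavy-tailed,
position-structured output of real clusters; and the GD link function is a
convenience, not a mechanistic claim. The pipeline does not attempt
genome-wide TE discovery (split-read/discordant-pair scanning),
ping-pong-signature statistics, or de novo cluster discovery.
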