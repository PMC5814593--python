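# Methods

## Overview

`juncsplice` implements a junction-read based analysis of differential
alternative splicing (AS) for designed stress experiments, of the kind used
to profile drought/heat responses in allopolyploid plants. Every step works
from *junction-supporting reads*: a spliced read whose alignment gap exactly
matches an intron supports that intron's exon–exon junction; a read aligned
contiguously across an exon–intron boundary is evidence for intron
retention. Transcript models (GTF) define the junction universe; no novel
junction discovery is attempted.

## Event model

Each AS event binds two isoform junction signatures within one gene:

* **IR** — an intron of one transcript lies strictly inside an exon of
  another. Isoform 1 (inclusion) is evidenced by the two exon–intron
  boundary junctions, isoform 2 by the spliced exon–exon junction.
* **ES** — consecutive introns (a,b),(c,d) flank a cassette exon in one
  transcript while another carries the skip junction (a,d). Isoform 1 is the
  two flanking junctions, isoform 2 the skip junction.
* **Alt5′SS / Alt3′SS** — two junctions share one boundary and differ at the
  other; the varying boundary's donor/acceptor role is strand-aware.
  Isoform 1 is the variant retaining more exonic sequence (shorter intron).

"Isoform 1 = inclusion form" is a convention; the differential statistic
depends only on its consistency. A junction pair sharing a boundary is *not*
typed as an Alt event when the extension interval is explained by an exon
skip in the same gene, which keeps the four types mutually exclusive for a
given junction pair. Only events whose exon–exon junctions are supported by
at least `min_junction_reads` (default 5) uniquely mapped reads in at least
one sample enter the catalogue. Multi-mapping reads are excluded entirely
(the NH tag when present, else mapping quality 0); this is stricter than
only removing multi-chromosome hits, and deliberate.

## Quantification: isoform expression percentage

For an event with inclusion reads n1 and exclusion reads n2 in a sample,

    IEP = n1 / (n1 + n2),         undefined when n1 + n2 = 0.

Two-junction isoforms (ES flanks, IR boundaries) contribute the *rounded
mean* (half-up) of their two junction counts rather than the sum, so a
single molecule is not counted twice relative to single-junction isoforms
and IEP stays comparable across event types. IR retention accepts support at
either boundary — the mean may rest on one nonzero boundary; requiring both
would discard most low-coverage retention evidence.

## Responsive-event calling

Per comparison (stress condition × timepoint, control-matched at the same
timepoint) and per biological replicate, a two-sided Fisher's exact test is
applied to [[n1_ctrl, n2_ctrl], [n1_stress, n2_stress]], followed by
Benjamini–Hochberg adjustment across all eligible events within that
(comparison, replicate). An event is **responsive** when in *both*
replicates q < 0.05 and |ΔIEP| ≥ 0.30 (ΔIEP = IEP_stress − IEP_control,
threshold inclusive) with agreeing sign. This per-replicate reading of
"same pattern changes in two biological replicates" is strictly
conservative; a pooled mode (summing replicate counts, one test) is also
available. Eligibility requires n1 + n2 > 0 in every compared sample (no
imputation of undefined IEP) and a pooled total ≥ 10. Genes with ≥ 1
responsive event at either timepoint of a condition are differentially
spliced genes (DSGs).

The exact test is computed directly as the hypergeometric sum of tables no
more probable than the observed one (vectorised log-binomial coefficients,
1e-7 relative tie tolerance). It agrees with exhaustive rational enumeration
to < 1e-10 over all tables with row margins ≤ 30 and with
`scipy.stats.fisher_exact` to ~1e-13 on random tables, at ~20 µs/call —
which matters because a catalogue-scale run performs tens of thousands of
tests.

### Power note on the |ΔIEP| ≥ 0.30 gate

At per-sample depth n the sampling sd of ΔIEP is ≈ √(p₁q₁ + p₂q₂)/√n. For a
true effect of 0.40 at n = 100 this is ≈ 0.07, so the probability that a
single replicate's estimate clears 0.30 is ≈ Φ(1.4–1.6) ≈ 0.92, and the
both-replicates rule caps sensitivity near 0.85 regardless of the test's
power. Recovery experiments in this package therefore use mean depth 200,
where the cap is ≈ 0.96; at depth 100 the pooled-replicates mode reaches the
same sensitivity because the pooled ΔIEP estimate has sd ≈ 0.05.

## Event consequences

For each event the gene's representative coding model is the transcript
with the longest annotated CDS. Events not overlapping the CDS span are
**UTR_effect**. For in-CDS events the *alternate* isoform (the one the
representative model does not realise) is substituted structurally —
introns overlapping the event span are merged away, then the isoform's
exon–exon junctions re-split the merged exon — and the resulting transcript
is translated from the annotated start codon (no ORF re-scanning). A stop
codon ≥ 50 nt upstream of the final exon–exon junction (the standard NMD
candidacy rule; configurable) marks **PTC**; any other alteration —
frame-preserving insertion, late stop, lost downstream junction — is
**CDS_change**. The three outcomes partition the responsive events.

## Expression comparison

The DEG caller is deliberately a *stand-in* for a full RNA-seq
differential-expression model: per gene and comparison, log2 fold change
from replicate means (pseudocount 1) and a two-sided exact test of the
gene's pooled counts against the remaining library, BH-adjusted within the
comparison; `up` requires log2FC ≥ 1 and q < 0.05 (`down` symmetric, i.e.
>2-fold and FDR < 0.05, conjunctively). An externally produced DEG table in
the same TSV schema is accepted interchangeably. The exact test assumes
near-Poisson sampling; under strong biological overdispersion it is
anticonservative — a documented limitation, and the reason the synthetic
generator models expression noise with its own mild dispersion (below).

DSG/DEG comparison reports the DSG-specific / overlap / DEG-specific
partition and, on a universe restricted to genes with > 10 pooled junction
reads (to avoid coverage bias), the proportion of DSGs among DEGs vs
non-DEGs with a two-sided Fisher p.

## Homeolog triplets, clustering, enrichment

Triplets pair one gene from each subgenome (A, B, D); triplets with any
member not expressed (mean expression below `expressed_min`, default 1) are
excluded. Per condition a triplet is `consistent` (all three members DSGs),
`partitioned` (one or two) or `none`.

Profiles of |ΔIEP| (mean over replicates) across the six stress × timepoint
comparisons, row-standardised to mean 0 / sd 1 (zero-variance rows dropped),
are clustered with fuzzy c-means — soft memberships in the style of Mfuzz —
with c = 12 and fuzzifier m = 1.25 by default; m close to 1 keeps
memberships crisp for short (6-point) profiles. Updates alternate until the
maximum centroid shift is < 1e-6 (≤ 500 iterations); a seed is mandatory and
fixes the result exactly. Hard assignment is the argmax membership, ties to
the lowest cluster index. No Mfuzz-equivalent package exists in the Python
stack used here, so the standard algorithm is implemented in ~30 lines and
validated on planted profile groups (ARI ≥ 0.9).

GO enrichment follows the simple whole-background rule: per term a
one-sided hypergeometric p with fold = (k/n)/(K/N); a term is significant at
p < 0.05 *and* fold ≥ 1.5, deliberately without multiplicity adjustment (a
BH column is emitted alongside for transparency).

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions
for every validation in this package. It emulates:

* three "subgenome" chromosomes (A/B/D) carrying homeolog triplets and a
  balanced design of 2 biological replicates × {CK, DS, HS, HD} × {1 h, 6 h}
  = 16 samples;
* one planted event per AS gene (60% of genes by default) drawn from the
  type mix IR 0.38 / ES 0.26 / Alt3′SS 0.22 / Alt5′SS 0.14, realised as two
  transcript isoforms with valid GT..AG splice dinucleotides; the fully
  spliced isoform carries a clean reading frame (UTRs, ATG, stop-free sense
  codons, terminal stop) and the annotated CDS, so event consequences vary
  realistically with the random inclusion sequence;
* condition-dependent true IEPs: responsive events (probability 0.05 / 0.35
  / 0.40 for DS / HS / HD, echoing the much weaker drought response) shift
  by ±0.40 at both timepoints;
* per-event, per-sample counts: total depth ~ negative binomial (mean 100,
  dispersion 0.1 by default), inclusion reads ~ binomial(depth, true IEP),
  decomposed to junctions as the exact inverse of the quantification rules
  (both ES flanks and both IR boundaries receive the inclusion draw, so the
  rounded-mean rule is exercised); constitutive introns get their own depth
  plus 3% boundary retention noise;
* gene expression ~ negative binomial with planted 4-fold shifts, coupled
  to AS responses (probability 0.5 when the gene has a responsive event
  under that condition, 0.12 otherwise) so the DSG-in-DEG enrichment has a
  true signal; expression dispersion is a separate parameter (default 0.05)
  because the exact-test DEG stand-in assumes near-Poisson sampling,
  whereas junction-depth dispersion never affects the splicing test, which
  conditions on event totals.

Everything is deterministic given the seed, to the byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: alignment and mapping artefacts (counts are drawn,
not aligned), overlapping or nested events sharing junctions, more than two
isoforms per gene, intron-retention length biases, library-size variation,
batch effects, and correlated biological replicates. Real-data use should
treat the calibration results as model-based sanity checks, not guarantees.

## Problem sizes and numerical choices

Validation runs use: null calibration with 2,000 planted-null events at
depth 100 over 3 seeds (observed responsive rate 0); recovery with 600
events, half carrying |ΔIEP| = 0.40, at depth 200 (sensitivity ≥ 0.96,
observed FDR 0); end-to-end runs with 90–300 genes on the full 16-sample
design. These sizes make every property measurable with comfortable margins
while each suite stage completes in seconds.

Other numerical choices: rounded mean is half-up on .5 ties; BH adjustment
is the step-up formula via statsmodels; hypergeometric survival via scipy;
undefined IEP propagates as NaN and disqualifies the event from the
affected comparison; fuzzy c-means guards zero distances by assigning full
membership to the coincident centroid; manifest checksums are MD5 over
input bytes.

## Known limitations

* The DEG stand-in ignores biological overdispersion (see above); swap in an
  external DEG table for real analyses.
* ES detection is limited to single-cassette skips; a multi-exon skip is
  emitted as separate pairwise events sharing the skip junction.
* PTC prediction uses the annotated start and a single representative model
  per gene; genes whose isoforms use different start codons are outside the
  model.
* GO enrichment treats term ids as a flat vocabulary (no ontology
  traversal or parent propagation).
* All events of a gene are emitted even when they share junctions; tallies
  count events, not merged records.
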