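# Methods

This note documents the models, conventions and design choices behind
`txrefine`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the synthetic
validation does and does not establish.

## Coordinates and data model

All coordinates are 0-based half-open; GTF I/O converts to/from 1-based
closed at the boundary, BED and bedGraph are consumed natively. Strand is
`+`, `-` or `.` (unknown); unknown strand is preserved, never coerced — the
strand filter, not the parser, decides its fate. A transcript is an ordered
tuple of disjoint exons on one chromosome and strand; transcripts reported
with exons on several chromosomes are rejected at parse time (no valid
assembler output contains them). Exonic interval arithmetic (coverage
fractions, Jaccard, unions) uses sorted-block sweeps; the test suite checks
every operation against brute-force per-base set implementations.

## Spike-in calibration

Assumption: spike-in read counts scale linearly with input concentration
over the usable range, so log coverage is approximately affine in log
concentration with curvature captured by a quadratic. Fits are performed in
log₂–log₂ space (both axes are conventionally plotted logged); zero-count
species are excluded rather than floored, since log of zero is undefined
and detected controls carry the calibration information.

Root policy for the degree-2 fit (not uniquely determined by the procedure
itself): the smallest real root of p(x) = log₂(target) inside the observed
concentration range is returned; if both roots fall outside, the nearest is
returned flagged `extrapolated`. Defaults: read length 102 nt (2×102 bp
paired-end chemistry), target coverage 8× (the classical
reliable-assembly floor). Avogadro's number is fixed at 6.022×10²³ so the
copy-number arithmetic reproduces the standard printed worked example to
its displayed precision.

Statistical behaviour: with 12 species log-spaced over 0.01–100 amol/µL and
multiplicative lognormal coverage noise of σ = 0.2, the detection-limit
estimate is unbiased but has an intrinsic per-replicate spread — the
least-squares prediction sd at the threshold abscissa is ≈0.16 log₂-units
(leverage 0.31), i.e. a median per-replicate relative error around 7%.
Averaging across samples (as the per-sample thresholds are used jointly)
reduces this substantially; the acceptance script reports the median
relative error actually achieved.

## The filtering pipeline

Filter order follows the narrative order of a capture-seq curation
workflow: unplaced → probe → expression → strand → repeats → length →
contamination → annotated → degradation → canonical splice → redundancy.
The order is configurable; ablation of any single step is supported and
tested. Boundary conventions, chosen to match the stated rules exactly:

- repeat content: strictly >90% masked exonic bases removes (90.0% stays);
- length: exonic length (not genomic span) <200 nt removes (200 stays);
- expression: below the per-sample floor in *every* sample removes; a
  missing quantification counts as below;
- strandedness: ≥80% in *at least one* sample keeps; the filter touches
  only monoexonic transcripts intergenic to the reference, where
  "intergenic" means no exonic base overlaps any reference gene span on
  either strand;
- annotated: same-strand, split-exon (exon-bodies only), query-denominated
  coverage ≥0.99 removes; antisense copies of known genes survive;
- degradation: "sense intronic" means the transcript span lies fully inside
  one intron of one same-strand reference transcript; CAGE rescue requires
  a same-strand peak within 100 nt of the 5′ end (strand-awareness is a
  deliberate choice — CAGE peaks are stranded TSS evidence — exposed as a
  config flag); enhancer rescue requires ≥80% reciprocal span overlap;
- redundancy: "Jaccard >0.98" is interpreted as the Jaccard *similarity*
  statistic (intersection/union of exonic base sets) exceeding 0.98 — a
  literal distance >0.98 would discard dissimilar isoforms, the opposite of
  collapsing near-duplicates. Within each gene, isoforms are kept greedily
  in descending exonic length (ties by transcript id) and an isoform is
  collapsed when similar above the cutoff to an already-kept one. Which
  member of a redundant pair survives is otherwise arbitrary; longest-first
  is deterministic and keeps the most informative model.

Gene counting in the retention report: a gene counts while at least one of
its transcripts survives. The pipeline is idempotent on its own output
(its survivors overlap the reference below the 0.99 cutoff by
construction).

## Reference comparison

Novelty classes are assigned in priority order: ≥1 same-strand exonic base
shared with reference exons → `extends_known`; otherwise opposite-strand
exonic overlap → `antisense`; otherwise span inside a reference gene span →
`intronic`; else `intergenic`. "Neighboring genes condensed into one
model" (bridging) is operationalised as exonic overlap with ≥2 same-strand
collapsed reference blocks (gene spans merged by transitive same-strand
overlap); adjacency without exonic overlap does not bridge. Boundary
extensions require a one-to-one block match (bridging genes are thereby
excluded) and are measured between gene-level extreme boundaries in
transcription direction, with a 400 nt minimum offset; when isoforms
disagree the gene-level extreme is used.

Coding potential uses a deterministic longest-ORF coverage proxy rather
than a trained classifier: the longest ATG→stop reading frame (sense
strand, three frames, stop included, no-stop ORFs discarded, ties to the
leftmost start) on the spliced sequence. An exon or transcript is labelled
coding when ORF coverage exceeds 70% and noncoding below 20%; the band in
between stays unlabeled. A matched reference transcript *gains* an ORF when
its extended counterpart crosses the coding bound while the reference sat
below the noncoding bound, and vice versa for *disrupted*. This preserves
the testable gain/loss logic without a trained-model dependency and is
documented as a proxy, not a reimplementation of any classifier.

## Profiles

Anchored profiles average per-base signal in fixed windows around stranded
positions, flipping minus-strand windows so downstream is transcription
direction; missing signal scores 0; the spread is the sample (n−1) standard
error, zero for a single anchor by convention. Scaled heatmaps stretch each
feature body onto a fixed bin count by coordinate interpolation (fractional
base weights at bin edges), keep flanks at single-base resolution, and
first collapse overlapping input features to their extreme positions to
avoid double counting. Grouping uses k-means with k = 3, 10 restarts and a
fixed seed (initialisation is otherwise unspecified); rows are displayed
sorted by descending row mean. Display clipping to [0.5, 2] is strictly a
rendering step and never feeds the clustering input — a property the test
suite verifies on constructed data where clipping would merge groups.

## TSS validation

Clustering of transcript 5′ ends uses single linkage at 50 nt for
determinism; the cluster representative is the highest-FPKM isoform (max
across samples, ties by transcript id). TSSs within 400 nt (inclusive) of a
same-strand reference TSS are excluded as redundant with known starts. The
permutation null re-places every TSS uniformly over the allowed genomic
space (strand preserved, placement not confined to the source chromosome) —
the spaces are expected to exclude gaps, unplaced contigs and the
mitochondrial chromosome by construction. The empirical p-value uses the
add-one convention, so p is never 0 and a fully unexceeded observation at
n = 1000 reports p = 1/1001 < 0.001. The permutation-calibration experiment
in the test suite draws TSS sets from the null itself and checks p-value
uniformity by a KS test; its design uses dense CAGE windows (1000 peaks of
300 nt in 1 Mb) so the discrete support count spreads over many values and
the add-one p-value is near-continuous — with sparse support the KS test
would reject on discreteness alone, a property of the test statistic, not
of the shuffle.

## Synthetic study

The generator emulates the full input surface of the pipeline with planted,
recorded ground truth: a 2×1 Mb genome plus a 100 kb unplaced contig,
reference and assembly annotations, probe/control-probe/repeat/CAGE/
enhancer/conserved-element tracks, a signal track, per-sample spike-in
tables and FPKM plus strand-fraction matrices for four brain-like and four
non-brain samples. Canonical introns are physically written into the
sequence as GT..AG (strand-aware); planted non-canonical introns read CC..GG
from either strand. Spike-in counts follow
count = round(c·concentration·length/read_length · lognormal noise) with
c = 400 coverage-folds per amol/µL and σ = 0.2, so log–log linearity holds
and the planted detection limit sits at 8/400 = 0.02 amol/µL, inside the
12-species 0.01–100 amol/µL log-spaced design. Brain-enriched transcripts
are drawn at a 20-fold planted median ratio (8 vs 0.4 FPKM, σ = 0.3), well
clear of the 4-fold selection bound. CAGE peaks are placed within 100 nt of
supported sense-intronic monoexonic transcripts and within 200 nt of 60% of
surviving TSSs.

Planting is single-fault: every violating transcript violates exactly one
rule and satisfies the keep-conditions of all other filters, so per-step
removals are exactly predictable and ablating any one filter releases
exactly its category. Default category counts (~150 assembly transcripts,
~40 reference transcripts) keep the full pipeline under a second.

What this does and does not show: the synthetic data validates the
*decision logic* of every stage exactly — boundaries, strand conventions,
orderings, accounting — but not robustness to real-data pathologies the
generator does not model: ambiguous multi-fault transcripts, fragmented or
chimeric assemblies, FPKM estimation error correlated with structure,
repeat families with partial homology, or CAGE peak density gradients.
Conclusions about real libraries rest on the per-operation contracts, not
on the synthetic end-to-end rates.

## Numerical choices and degenerate inputs

Polynomial fits use ordinary least squares (`numpy.polyfit`); roots via the
companion matrix with a 1e-9 imaginary-part tolerance. Division-by-zero
cases are handled by policy, not by flooring: zero-coverage spike-ins are
excluded from fits; a zero non-brain median with a considered gene counts
as an infinite ratio (enriched); an empty ORF yields coverage 0. Empty
annotation sets, single-anchor profiles, and k exceeding the feature count
raise explicit errors or return defined degenerate values as documented on
each function.

## Known limitations

- The annotated-transcript filter compares against the pooled exonic union
  of the reference per strand, not per-transcript; a query mosaicking two
  reference transcripts of the same strand counts as covered.
- The longest-ORF proxy ignores Kozak context and truncated ORFs at
  sequence ends; it is a structural proxy, not a translation predictor.
- bigWig signal is out of scope; bedGraph (text) carries signal tracks.
- The shuffle null places TSSs uniformly over the allowed space without
  preserving per-chromosome counts; with strongly chromosome-biased CAGE
  density this null is more permissive than a per-chromosome shuffle.
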