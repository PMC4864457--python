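"""The high-quality (HQ) transcript filtering pipeline.

A merged transcriptome assembly contains mapping and assembly artifacts as
well as transcripts already present in the reference annotation. Eleven
ordered filters distil it into a high-quality novel set:

 1. drop transcripts on unplaced contigs
 2. keep only transcripts whose exons overlap a capture probe
    (transcripts overlapping solely control probes are dropped)
 3. drop transcripts consistently below the per-sample FPKM detection floor
 4. drop transcripts with unknown strand
 5. drop transcripts with >90% of exonic bases inside repeat/low-complexity
    masked regions
 6. drop isoforms with exonic length shorter than 200 nt
 7. drop monoexonic intergenic transcripts without >=80% of reads on the
    annotated strand in at least one sample (DNA-contamination guard)
 8. drop transcripts already annotated (>=99% same-strand exonic coverage
    by the reference, split semantics)
 9. drop sense-intronic monoexonic transcripts lacking independent TSS
    evidence (CAGE peak within 100 nt of the 5' end, or >=80% reciprocal
    overlap with an enhancer) — splicing-maturation degradation products
10. drop spliced transcripts with any non-canonical intron
    (outside GT-AG / GC-AG / AT-AC)
11. collapse redundant isoforms within a gene (exonic Jaccard > 0.98)

Each step appends a row to a retention report (genes, transcripts remaining,
transcripts removed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation_core import (
    STRAND_UNKNOWN,
    AnnotationSet,
    IntervalTrack,
    Transcript,
    _intersection_size,
    exonic_overlap_fraction,
    jaccard_similarity,
    merge_blocks,
    splice_dinucleotides,
)

CANONICAL_INTRONS: FrozenSet[Tuple[str, str]] = frozenset(
    {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the filtering pipeline (defaults as published)."""

    placed_chromosomes: FrozenSet[str] = frozenset()
    fpkm_thresholds: Dict[str, float] = field(default_factory=dict)  # per sample
    repeat_fraction_cutoff: float = 0.90  # strict > removes
    min_length: int = 200  # exonic nt; shorter-than removes
    strand_fraction_cutoff: float = 0.80  # >= keeps, in >=1 sample
    annotated_overlap_fraction: float = 0.99  # >= removes
    cage_distance: int = 100  # nt from 5' end
    cage_same_strand: bool = True
    enhancer_reciprocal_coverage: float = 0.80
    canonical_introns: FrozenSet[Tuple[str, str]] = CANONICAL_INTRONS
    redundancy_jaccard_cutoff: float = 0.98  # strict > collapses

    def __post_init__(self) -> None:
        for name in (
            "repeat_fraction_cutoff",
            "strand_fraction_cutoff",
            "annotated_overlap_fraction",
            "enhancer_reciprocal_coverage",
            "redundancy_jaccard_cutoff",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class FilterStep:
    name: str
    genes: int
    transcripts: int
    removed: int


class FilterReport:
    """Ordered per-step retention accounting, convertible to a DataFrame."""

    def __init__(self) -> None:
        self.steps: List[FilterStep] = []

    def record(self, name: str, annotation: AnnotationSet, previous: int) -> None:
        self.steps.append(
            FilterStep(
                name=name,
                genes=annotation.n_genes,
                transcripts=annotation.n_transcripts,
                removed=previous - annotation.n_transcripts,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": [s.name for s in self.steps],
                "genes": [s.genes for s in self.steps],
                "transcripts": [s.transcripts for s in self.steps],
                "removed": [s.removed for s in self.steps],
            }
        )


# ---------------------------------------------------------------------------
# Shared geometry helpers
# ---------------------------------------------------------------------------


def repeat_fraction(t: Transcript, repeats: IntervalTrack) -> float:
    """Fraction of exonic bases covered by repeat features (strand-agnostic)."""
    rep_blocks = merge_blocks(
        (f.start, f.end) for f in repeats.overlapping(t.chrom, t.start, t.end)
    )
    return _intersection_size(t.exon_blocks(), rep_blocks) / t.exonic_length


def _gene_spans(reference: AnnotationSet) -> Dict[str, List[Tuple[int, int, str]]]:
    spans: Dict[str, List[Tuple[int, int, str]]] = {}
    for g in reference.gene_ids():
        s = reference.gene_span(g)
        spans.setdefault(s.chrom, []).append((s.start, s.end, s.strand))
    return spans


def is_intergenic(t: Transcript, reference: AnnotationSet) -> bool:
    """True when no exonic base of t overlaps any reference gene span (either strand)."""
    for g in reference.gene_ids():
        span = reference.gene_span(g)
        if span.chrom != t.chrom:
            continue
        if _intersection_size(t.exon_blocks(), [(span.start, span.end)]) > 0:
            return False
    return True


def is_sense_intronic(t: Transcript, reference: AnnotationSet) -> bool:
    """True when t's span lies fully inside one intron of a same-strand reference transcript."""
    for ref_t in reference.on_chrom(t.chrom):
        if ref_t.strand != t.strand:
            continue
        for intron in ref_t.introns():
            if intron.start <= t.start and t.end <= intron.end:
                return True
    return False


def reciprocal_span_overlap(t: Transcript, feature) -> float:
    """min(overlap/|span|, overlap/|feature|) between transcript span and a feature."""
    lo = max(t.start, feature.start)
    hi = min(t.end, feature.end)
    if feature.chrom != t.chrom or lo >= hi:
        return 0.0
    overlap = hi - lo
    return min(overlap / (t.end - t.start), overlap / (feature.end - feature.start))


def has_cage_support(
    t: Transcript, cage: IntervalTrack, distance: int, same_strand: bool = True
) -> bool:
    """A CAGE peak lies within `distance` nt of the transcript 5' end."""
    pos = t.five_prime
    strand = t.strand if same_strand else None
    return bool(
        cage.overlapping(t.chrom, pos - distance, pos + distance + 1, strand)
    )


# ---------------------------------------------------------------------------
# The eleven filters
# ---------------------------------------------------------------------------


def f01_drop_unplaced(a: AnnotationSet, cfg: PipelineConfig) -> AnnotationSet:
    placed = cfg.placed_chromosomes
    return a.subset(lambda t: t.chrom in placed)


def f02_probe_overlap(
    a: AnnotationSet, probes: IntervalTrack, controls: IntervalTrack
) -> AnnotationSet:
    def keep(t: Transcript) -> bool:
        return any(
            probes.overlapping(t.chrom, e.start, e.end) for e in t.exons
        )

    # Control-probe-only transcripts are implicitly dropped: overlap with a
    # control probe alone never satisfies the capture-probe requirement.
    del controls
    return a.subset(keep)


def f03_expression_floor(
    a: AnnotationSet, fpkm: pd.DataFrame, thresholds: Mapping[str, float]
) -> AnnotationSet:
    missing_samples = set(fpkm.columns) - set(thresholds)
    if missing_samples:
        raise ValueError(f"no FPKM threshold for samples: {sorted(missing_samples)}")

    def keep(t: Transcript) -> bool:
        if t.transcript_id not in fpkm.index:
            raise ValueError(f"no FPKM row for transcript {t.transcript_id}")
        row = fpkm.loc[t.transcript_id]
        # "consistently below" = below threshold in every sample; a missing
        # quantification counts as below.
        for sample in fpkm.columns:
            value = row[sample]
            if pd.notna(value) and value >= thresholds[sample]:
                return True
        return False

    return a.subset(keep)


def f04_known_strand(a: AnnotationSet) -> AnnotationSet:
    return a.subset(lambda t: t.strand != STRAND_UNKNOWN)


def f05_repeat_content(
    a: AnnotationSet, repeats: IntervalTrack, cfg: PipelineConfig
) -> AnnotationSet:
    return a.subset(lambda t: repeat_fraction(t, repeats) <= cfg.repeat_fraction_cutoff)


def f06_min_length(a: AnnotationSet, cfg: PipelineConfig) -> AnnotationSet:
    return a.subset(lambda t: t.exonic_length >= cfg.min_length)


def f07_dna_contamination(
    a: AnnotationSet,
    reference: AnnotationSet,
    strand_fractions: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
) -> AnnotationSet:
    cutoff = cfg.strand_fraction_cutoff if cfg else 0.80

    def keep(t: Transcript) -> bool:
        if not t.is_monoexonic or not is_intergenic(t, reference):
            return True
        if t.transcript_id not in strand_fractions.index:
            raise ValueError(
                f"no stranded-read fractions for transcript {t.transcript_id}"
            )
        row = strand_fractions.loc[t.transcript_id]
        return bool((row >= cutoff).any())

    return a.subset(keep)


def f08_drop_annotated(
    a: AnnotationSet, reference: AnnotationSet, cfg: PipelineConfig
) -> AnnotationSet:
    cutoff = cfg.annotated_overlap_fraction
    return a.subset(
        lambda t: exonic_overlap_fraction(t, reference, same_strand=True) < cutoff
    )


def f09_degradation_products(
    a: AnnotationSet,
    reference: AnnotationSet,
    cage: IntervalTrack,
    enhancers: IntervalTrack,
    cfg: PipelineConfig,
) -> AnnotationSet:
    def keep(t: Transcript) -> bool:
        if not t.is_monoexonic or not is_sense_intronic(t, reference):
            return True
        if has_cage_support(t, cage, cfg.cage_distance, cfg.cage_same_strand):
            return True
        return any(
            reciprocal_span_overlap(t, enh) >= cfg.enhancer_reciprocal_coverage
            for enh in enhancers.overlapping(t.chrom, t.start, t.end)
        )

    return a.subset(keep)


def f10_canonical_splice(
    a: AnnotationSet, genome, cfg: Optional[PipelineConfig] = None
) -> AnnotationSet:
    canonical = cfg.canonical_introns if cfg else CANONICAL_INTRONS

    def keep(t: Transcript) -> bool:
        if t.is_monoexonic:
            return True
        return all(pair in canonical for pair in splice_dinucleotides(t, genome))

    return a.subset(keep)


def f11_collapse_redundant(a: AnnotationSet, cfg: PipelineConfig) -> AnnotationSet:
    cutoff = cfg.redundancy_jaccard_cutoff
    keep_ids: Set[str] = set()
    for gene_id in a.gene_ids():
        isoforms = sorted(
            a.gene_transcripts(gene_id),
            key=lambda t: (-t.exonic_length, t.transcript_id),
        )
        kept: List[Transcript] = []
        for t in isoforms:
            if all(jaccard_similarity(t, k) <= cutoff for k in kept):
                kept.append(t)
        keep_ids.update(t.transcript_id for t in kept)
    return a.subset(lambda t: t.transcript_id in keep_ids)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    """Auxiliary data consumed by the filters."""

    reference: AnnotationSet
    genome: object  # mapping chrom -> sequence, or pyfaidx.Fasta
    probes: IntervalTrack
    control_probes: IntervalTrack
    repeats: IntervalTrack
    cage: IntervalTrack
    enhancers: IntervalTrack
    fpkm: pd.DataFrame  # transcripts x samples
    strand_fractions: pd.DataFrame  # transcripts x samples

    def step_args(self, cfg: PipelineConfig) -> Dict[str, tuple]:
        return {
            "f01_drop_unplaced": (cfg,),
            "f02_probe_overlap": (self.probes, self.control_probes),
            "f03_expression_floor": (self.fpkm, cfg.fpkm_thresholds),
            "f04_known_strand": (),
            "f05_repeat_content": (self.repeats, cfg),
            "f06_min_length": (cfg,),
            "f07_dna_contamination": (self.reference, self.strand_fractions, cfg),
            "f08_drop_annotated": (self.reference, cfg),
            "f09_degradation_products": (
                self.reference,
                self.cage,
                self.enhancers,
                cfg,
            ),
            "f10_canonical_splice": (self.genome, cfg),
            "f11_collapse_redundant": (cfg,),
        }


DEFAULT_FILTER_ORDER: Tuple[str, ...] = (
    "f01_drop_unplaced",
    "f02_probe_overlap",
    "f03_expression_floor",
    "f04_known_strand",
    "f05_repeat_content",
    "f06_min_length",
    "f07_dna_contamination",
    "f08_drop_annotated",
    "f09_degradation_products",
    "f10_canonical_splice",
    "f11_collapse_redundant",
)

_FILTERS = {
    "f01_drop_unplaced": f01_drop_unplaced,
    "f02_probe_overlap": f02_probe_overlap,
    "f03_expression_floor": f03_expression_floor,
    "f04_known_strand": f04_known_strand,
    "f05_repeat_content": f05_repeat_content,
    "f06_min_length": f06_min_length,
    "f07_dna_contamination": f07_dna_contamination,
    "f08_drop_annotated": f08_drop_annotated,
    "f09_degradation_products": f09_degradation_products,
    "f10_canonical_splice": f10_canonical_splice,
    "f11_collapse_redundant": f11_collapse_redundant,
}


def run_pipeline(
    a: AnnotationSet,
    inputs: PipelineInputs,
    cfg: PipelineConfig,
    order: Sequence[str] = DEFAULT_FILTER_ORDER,
) -> Tuple[AnnotationSet, FilterReport]:
    """Apply the filters in order, recording per-step retention.

    `order` may omit steps (ablation experiments) but may not name unknown
    ones. Genes count while at least one of their transcripts survives.
    """
    unknown = set(order) - set(_FILTERS)
    if unknown:
        raise ValueError(f"unknown filter steps: {sorted(unknown)}")
    report = FilterReport()
    report.record("input", a, a.n_transcripts)
    current = a
    args = inputs.step_args(cfg)
    for name in order:
        previous = current.n_transcripts
        current = _FILTERS[name](current, *args[name])
        report.record(name, current, previous)
    return current, report
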