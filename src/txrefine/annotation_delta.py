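"""Comparison of a refined transcript set against a reference annotation.

Classifies each novel transcript (intergenic / intronic / antisense /
extends_known), counts novel exons, exon variants and novel splice
junctions, detects gene models that bridge two or more previously separate
reference genes on the same strand, and finds genes whose boundaries extend
at least a minimum offset beyond the annotated start or end. A deterministic
longest-ORF proxy assesses whether a boundary extension creates or disrupts
an open reading frame in a matched reference transcript.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .annotation_core import (
    STRAND_MINUS,
    AnnotationSet,
    GenomicInterval,
    IntervalTrack,
    Transcript,
    _intersection_size,
    collapse_gene_blocks,
    exonic_union,
    fetch_sequence,
    merge_blocks,
    reverse_complement,
)

NOVELTY_CLASSES = ("extends_known", "antisense", "intronic", "intergenic")

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class DeltaReport:
    """Aggregated comparison results against the reference."""

    novelty: Dict[str, str] = field(default_factory=dict)  # transcript -> class
    bridged: Dict[str, List[str]] = field(default_factory=dict)  # gene -> ref genes
    upstream_offsets: Dict[str, int] = field(default_factory=dict)  # gene -> nt
    downstream_offsets: Dict[str, int] = field(default_factory=dict)
    novel_exons: int = 0
    novel_exon_variants: int = 0
    novel_junctions: int = 0

    def novelty_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": list(self.novelty), "class": list(self.novelty.values())}
        )


# ---------------------------------------------------------------------------
# Novelty classification
# ---------------------------------------------------------------------------


def _exonic_overlap_bases(t: Transcript, reference: AnnotationSet, strand) -> int:
    union = exonic_union(reference.on_chrom(t.chrom), t.chrom, strand)
    return _intersection_size(t.exon_blocks(), union)


def classify_transcript(t: Transcript, reference: AnnotationSet) -> str:
    """One of extends_known / antisense / intronic / intergenic.

    extends_known: >=1 same-strand exonic base shared with reference exons.
    antisense: exonic overlap only with opposite-strand reference exons.
    intronic: no exonic overlap but the transcript span lies inside a
    reference gene span. intergenic: none of the above.
    """
    if _exonic_overlap_bases(t, reference, t.strand) > 0:
        return "extends_known"
    opposite = STRAND_MINUS if t.strand == "+" else "+"
    if _exonic_overlap_bases(t, reference, opposite) > 0:
        return "antisense"
    for g in reference.gene_ids():
        span = reference.gene_span(g)
        if span.chrom == t.chrom and span.start <= t.start and t.end <= span.end:
            return "intronic"
    return "intergenic"


def classify_novelty(hq: AnnotationSet, reference: AnnotationSet) -> Dict[str, str]:
    return {t.transcript_id: classify_transcript(t, reference) for t in hq}


# ---------------------------------------------------------------------------
# Novel structure accounting
# ---------------------------------------------------------------------------


def novel_structure_counts(
    hq: AnnotationSet, reference: AnnotationSet
) -> Tuple[int, int, int]:
    """(novel exons, exon variants, novel junctions) of the HQ set.

    Novel exon: a distinct HQ exon sharing no base with reference exons on
    either strand. Exon variant: overlaps a reference exon but no reference
    exon has identical boundaries. Novel junction: a distinct same-strand
    intron absent from the reference intron set.
    """
    ref_exon_keys: Set[Tuple[str, int, int]] = set()
    for t in reference:
        for e in t.exons:
            ref_exon_keys.add((e.chrom, e.start, e.end))
    ref_union_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in reference.chromosomes():
        ref_union_by_chrom[chrom] = exonic_union(
            reference.on_chrom(chrom), chrom, strand=None
        )
    ref_junctions: Set[Tuple[str, str, int, int]] = set()
    for t in reference:
        for intron in t.introns():
            ref_junctions.add((t.chrom, t.strand, intron.start, intron.end))

    novel_exons: Set[Tuple[str, int, int]] = set()
    variants: Set[Tuple[str, int, int]] = set()
    novel_junctions: Set[Tuple[str, str, int, int]] = set()
    for t in hq:
        ref_union = ref_union_by_chrom.get(t.chrom, [])
        for e in t.exons:
            key = (e.chrom, e.start, e.end)
            overlap = _intersection_size([(e.start, e.end)], ref_union)
            if overlap == 0:
                novel_exons.add(key)
            elif key not in ref_exon_keys:
                variants.add(key)
        for intron in t.introns():
            key4 = (t.chrom, t.strand, intron.start, intron.end)
            if key4 not in ref_junctions:
                novel_junctions.add(key4)
    return len(novel_exons), len(variants), len(novel_junctions)


# ---------------------------------------------------------------------------
# Bridging and boundary extensions
# ---------------------------------------------------------------------------


def _blocks_by_member_exons(
    reference: AnnotationSet, blocks: IntervalTrack
) -> List[Tuple[GenomicInterval, List[Tuple[int, int]]]]:
    """Pair each collapsed block with the merged exonic blocks of its member genes."""
    out = []
    for block in blocks:
        exon_blocks: List[Tuple[int, int]] = []
        for gene_id in block.name.split(","):
            for t in reference.gene_transcripts(gene_id):
                exon_blocks.extend(t.exon_blocks())
        out.append((block, merge_blocks(exon_blocks)))
    return out


def _gene_geometry(hq: AnnotationSet, gene_id: str):
    ts = hq.gene_transcripts(gene_id)
    chrom, strand = ts[0].chrom, ts[0].strand
    exon_blocks = merge_blocks(b for t in ts for b in t.exon_blocks())
    start = min(t.start for t in ts)
    end = max(t.end for t in ts)
    return chrom, strand, exon_blocks, start, end


def _overlapped_blocks(hq: AnnotationSet, reference: AnnotationSet):
    """For each HQ gene, the same-strand collapsed blocks its exons overlap exonically."""
    blocks = collapse_gene_blocks(reference)
    with_exons = _blocks_by_member_exons(reference, blocks)
    result: Dict[str, List[GenomicInterval]] = {}
    geometry = {}
    for gene_id in hq.gene_ids():
        chrom, strand, exon_blocks, start, end = _gene_geometry(hq, gene_id)
        geometry[gene_id] = (chrom, strand, exon_blocks, start, end)
        hits = [
            block
            for block, member_exons in with_exons
            if block.chrom == chrom
            and block.strand == strand
            and _intersection_size(exon_blocks, member_exons) > 0
        ]
        result[gene_id] = hits
    return result, geometry


def detect_bridging(
    hq: AnnotationSet, reference: AnnotationSet
) -> Dict[str, List[str]]:
    """HQ genes whose exons overlap exons of >=2 same-strand collapsed blocks.

    Returns ``{hq_gene_id: sorted reference gene ids bridged}``.
    """
    overlapped, _ = _overlapped_blocks(hq, reference)
    bridged: Dict[str, List[str]] = {}
    for gene_id, hits in overlapped.items():
        if len(hits) >= 2:
            members = sorted({g for b in hits for g in b.name.split(",")})
            bridged[gene_id] = members
    return bridged


def _extension_offsets(
    hq: AnnotationSet,
    reference: AnnotationSet,
    min_offset: int,
    upstream: bool,
) -> Dict[str, int]:
    overlapped, geometry = _overlapped_blocks(hq, reference)
    out: Dict[str, int] = {}
    for gene_id, hits in overlapped.items():
        if len(hits) != 1:  # one-to-one only; bridging genes excluded
            continue
        block = hits[0]
        chrom, strand, _exon_blocks, start, end = geometry[gene_id]
        plus = strand != STRAND_MINUS
        if upstream:
            offset = block.start - start if plus else end - block.end
        else:
            offset = end - block.end if plus else block.start - start
        if offset >= min_offset:
            out[gene_id] = offset
    return out


def detect_upstream_starts(
    hq: AnnotationSet, reference: AnnotationSet, min_offset: int = 400
) -> Dict[str, int]:
    """HQ genes starting >= min_offset nt upstream of their one matched block.

    Offsets are measured in transcription direction (strand-aware); the HQ
    gene must overlap exactly one same-strand collapsed reference block at
    the exon level.
    """
    return _extension_offsets(hq, reference, min_offset, upstream=True)


def detect_downstream_ends(
    hq: AnnotationSet, reference: AnnotationSet, min_offset: int = 400
) -> Dict[str, int]:
    """Mirror image of :func:`detect_upstream_starts` at the 3' boundary."""
    return _extension_offsets(hq, reference, min_offset, upstream=False)


# ---------------------------------------------------------------------------
# ORF gain / loss under boundary extension
# ---------------------------------------------------------------------------


def spliced_sequence(t: Transcript, genome) -> str:
    """5'->3' mRNA-sense spliced sequence of a transcript."""
    seq = "".join(
        fetch_sequence(genome, t.chrom, e.start, e.end) for e in t.exons
    )
    return reverse_complement(seq) if t.strand == STRAND_MINUS else seq


def longest_orf(seq: str) -> Tuple[int, int]:
    """Longest ATG..stop ORF on the given (sense) sequence, all three frames.

    Returns ``(start, end)`` as a half-open span over the sequence, stop codon
    included; ``(0, 0)`` when no complete ORF exists. Ties resolve to the
    leftmost start.
    """
    best = (0, 0)
    n = len(seq)
    for frame in range(3):
        open_start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                span = (open_start, pos + 3)
                length, best_length = span[1] - span[0], best[1] - best[0]
                if length > best_length or (
                    length == best_length and length and span[0] < best[0]
                ):
                    best = span
                open_start = None
        # an ORF still open at the sequence end lacks a stop codon: not counted
    return best


def orf_coverage(seq: str) -> float:
    start, end = longest_orf(seq)
    return (end - start) / len(seq) if seq else 0.0


def match_by_exonic_overlap(
    reference_lnc: AnnotationSet, hq: AnnotationSet
) -> Dict[str, Optional[str]]:
    """Pair each reference transcript with the best same-strand exonic-overlap HQ transcript."""
    pairs: Dict[str, Optional[str]] = {}
    for ref_t in reference_lnc:
        best_id, best_overlap = None, 0
        for hq_t in hq.on_chrom(ref_t.chrom):
            if hq_t.strand != ref_t.strand:
                continue
            overlap = _intersection_size(ref_t.exon_blocks(), hq_t.exon_blocks())
            if overlap > best_overlap:
                best_id, best_overlap = hq_t.transcript_id, overlap
        pairs[ref_t.transcript_id] = best_id
    return pairs


def orf_gain_loss(
    hq: AnnotationSet,
    reference_lnc: AnnotationSet,
    genome,
    coding_threshold: float = 0.70,
    noncoding_threshold: float = 0.20,
) -> Dict[str, str]:
    """Per reference-lncRNA verdict: gained / disrupted / unchanged.

    A lncRNA *gains* an ORF when its matched, structurally extended HQ
    transcript has longest-ORF coverage above the coding threshold while the
    reference itself was below the noncoding threshold; *disrupted* is the
    reverse. Reference transcripts without a same-strand exonic-overlap match
    are skipped with a warning.
    """
    verdicts: Dict[str, str] = {}
    pairs = match_by_exonic_overlap(reference_lnc, hq)
    for ref_t in reference_lnc:
        hq_id = pairs[ref_t.transcript_id]
        if hq_id is None:
            warnings.warn(
                f"no one-to-one HQ match for {ref_t.transcript_id}; skipped",
                stacklevel=2,
            )
            continue
        ref_cov = orf_coverage(spliced_sequence(ref_t, genome))
        hq_cov = orf_coverage(spliced_sequence(hq[hq_id], genome))
        if hq_cov > coding_threshold and ref_cov < noncoding_threshold:
            verdicts[ref_t.transcript_id] = "gained"
        elif ref_cov > coding_threshold and hq_cov < noncoding_threshold:
            verdicts[ref_t.transcript_id] = "disrupted"
        else:
            verdicts[ref_t.transcript_id] = "unchanged"
    return verdicts


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def build_delta_report(hq: AnnotationSet, reference: AnnotationSet) -> DeltaReport:
    exons, variants, junctions = novel_structure_counts(hq, reference)
    return DeltaReport(
        novelty=classify_novelty(hq, reference),
        bridged=detect_bridging(hq, reference),
        upstream_offsets=detect_upstream_starts(hq, reference),
        downstream_offsets=detect_downstream_ends(hq, reference),
        novel_exons=exons,
        novel_exon_variants=variants,
        novel_junctions=junctions,
    )
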