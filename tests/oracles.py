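"""Brute-force per-base reference implementations used as independent oracles.

Everything here works on explicit Python sets of genomic base positions, the
slowest but most transparent formulation, and stays independent of the
interval-sweep code paths it checks.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

from txrefine.annotation_core import AnnotationSet, Transcript


def base_set(t: Transcript) -> Set[int]:
    return {pos for e in t.exons for pos in range(e.start, e.end)}


def brute_overlap_fraction(
    query: Transcript, reference: AnnotationSet, same_strand: bool
) -> float:
    ref_bases: Set[int] = set()
    for rt in reference:
        if rt.chrom != query.chrom:
            continue
        if same_strand and rt.strand != query.strand:
            continue
        ref_bases |= base_set(rt)
    q = base_set(query)
    return len(q & ref_bases) / len(q)


def brute_jaccard(a: Transcript, b: Transcript) -> float:
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    sa, sb = base_set(a), base_set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def brute_classify(t: Transcript, reference: AnnotationSet) -> str:
    tb = base_set(t)
    same = opposite = False
    for rt in reference:
        if rt.chrom != t.chrom:
            continue
        if tb & base_set(rt):
            if rt.strand == t.strand:
                same = True
            else:
                opposite = True
    if same:
        return "extends_known"
    if opposite:
        return "antisense"
    for g in reference.gene_ids():
        span = reference.gene_span(g)
        if span.chrom == t.chrom and span.start <= t.start and t.end <= span.end:
            return "intronic"
    return "intergenic"


def brute_blocks(reference: AnnotationSet) -> List[Tuple[str, str, Set[int], Set[str]]]:
    """Collapsed same-strand gene blocks via transitive closure on span base sets.

    Returns (chrom, strand, member exon base set, member gene ids) per block.
    """
    genes = []
    for g in reference.gene_ids():
        span = reference.gene_span(g)
        span_bases = set(range(span.start, span.end))
        exon_bases: Set[int] = set()
        for t in reference.gene_transcripts(g):
            exon_bases |= base_set(t)
        genes.append((g, span.chrom, span.strand, span_bases, exon_bases))
    blocks: List[Tuple[str, str, Set[int], Set[int], Set[str]]] = []
    for g, chrom, strand, span_bases, exon_bases in genes:
        hits = [
            i
            for i, (bc, bs, bspan, _, _) in enumerate(blocks)
            if bc == chrom and bs == strand and bspan & span_bases
        ]
        merged_span = set(span_bases)
        merged_exons = set(exon_bases)
        members = {g}
        for i in sorted(hits, reverse=True):
            _, _, bspan, bexons, bmembers = blocks.pop(i)
            merged_span |= bspan
            merged_exons |= bexons
            members |= bmembers
        blocks.append((chrom, strand, merged_span, merged_exons, members))
    return [(c, s, exons, members) for c, s, _, exons, members in blocks]


def brute_gene_block_hits(
    hq: AnnotationSet, reference: AnnotationSet
) -> Dict[str, List[Set[str]]]:
    """Per HQ gene: member-gene-id sets of same-strand blocks its exons hit."""
    blocks = brute_blocks(reference)
    hits: Dict[str, List[Set[str]]] = {}
    for gid in hq.gene_ids():
        ts = hq.gene_transcripts(gid)
        chrom, strand = ts[0].chrom, ts[0].strand
        exon_bases: Set[int] = set()
        for t in ts:
            exon_bases |= base_set(t)
        hits[gid] = [
            members
            for bc, bs, bexons, members in blocks
            if bc == chrom and bs == strand and bexons & exon_bases
        ]
    return hits


def brute_bridging(hq: AnnotationSet, reference: AnnotationSet) -> Dict[str, Set[str]]:
    out = {}
    for gid, hits in brute_gene_block_hits(hq, reference).items():
        if len(hits) >= 2:
            out[gid] = set().union(*hits)
    return out


def brute_extensions(
    hq: AnnotationSet, reference: AnnotationSet, min_offset: int, upstream: bool
) -> Dict[str, int]:
    blocks = brute_blocks(reference)
    out: Dict[str, int] = {}
    for gid, hits in brute_gene_block_hits(hq, reference).items():
        if len(hits) != 1:
            continue
        ts = hq.gene_transcripts(gid)
        chrom, strand = ts[0].chrom, ts[0].strand
        start = min(t.start for t in ts)
        end = max(t.end for t in ts)
        members = hits[0]
        block = next(
            b for b in blocks if b[0] == chrom and b[1] == strand and b[3] == members
        )
        bstart, bend = min(block[2]), max(block[2]) + 1
        plus = strand != "-"
        if upstream:
            offset = bstart - start if plus else end - bend
        else:
            offset = end - bend if plus else bstart - start
        if offset >= min_offset:
            out[gid] = offset
    return out


STOPS = {"TAA", "TAG", "TGA"}


def brute_longest_orf(seq: str) -> Tuple[int, int]:
    """Enumerate every in-frame ATG..stop pair with no intervening stop."""
    best = (0, 0)
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            codon = seq[j : j + 3]
            if codon in STOPS:
                length, best_length = j + 3 - i, best[1] - best[0]
                if length > best_length or (
                    length == best_length and length and i < best[0]
                ):
                    best = (i, j + 3)
                break
    return best
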