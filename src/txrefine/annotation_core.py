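"""Genomic data model, standard-format I/O and interval algebra.

All coordinates are internally 0-based, half-open ``[start, end)``.
GTF I/O converts to/from the 1-based closed convention at the boundary.
Strand is one of ``"+"``, ``"-"`` or ``"."`` (unknown); unknown strand is
preserved as-is — downstream filters decide its fate.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_UNKNOWN = "."

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class GenomeLookupError(KeyError):
    """Raised when a sequence for a requested chromosome is unavailable."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional metadata."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )
        if self.strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.score is not None and not math.isfinite(self.score):
            raise ValueError("interval score must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A transcript: ordered disjoint exons on one chromosome and strand."""

    transcript_id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    source: str = "assembly"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes strands {sorted(strands)}"
            )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def five_prime(self) -> int:
        """TSS coordinate: start on + / unknown, end - 1 on - strand."""
        return self.end - 1 if self.strand == STRAND_MINUS else self.start

    @property
    def three_prime(self) -> int:
        return self.start if self.strand == STRAND_MINUS else self.end - 1

    def introns(self) -> List[GenomicInterval]:
        """Genomic intron intervals in coordinate order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def exon_blocks(self) -> List[Tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]


class AnnotationSet:
    """A collection of transcripts indexed by transcript id, gene id and chromosome."""

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self._transcripts: Dict[str, Transcript] = {}
        self._by_gene: Dict[str, List[str]] = defaultdict(list)
        self._by_chrom: Dict[str, List[str]] = defaultdict(list)
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript_id {t.transcript_id}")
        self._transcripts[t.transcript_id] = t
        self._by_gene[t.gene_id].append(t.transcript_id)
        self._by_chrom[t.chrom].append(t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._transcripts == other._transcripts

    @property
    def n_transcripts(self) -> int:
        return len(self._transcripts)

    @property
    def n_genes(self) -> int:
        return len(self._by_gene)

    def transcript_ids(self) -> List[str]:
        return list(self._transcripts)

    def gene_ids(self) -> List[str]:
        return list(self._by_gene)

    def gene_transcripts(self, gene_id: str) -> List[Transcript]:
        return [self._transcripts[tid] for tid in self._by_gene[gene_id]]

    def chromosomes(self) -> List[str]:
        return list(self._by_chrom)

    def on_chrom(self, chrom: str) -> List[Transcript]:
        return [self._transcripts[tid] for tid in self._by_chrom.get(chrom, ())]

    def subset(self, keep: Callable[[Transcript], bool]) -> "AnnotationSet":
        return AnnotationSet(t for t in self if keep(t))

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Genomic span of a gene (min start to max end of its transcripts)."""
        ts = self.gene_transcripts(gene_id)
        return GenomicInterval(
            ts[0].chrom,
            min(t.start for t in ts),
            max(t.end for t in ts),
            ts[0].strand,
            name=gene_id,
        )


@dataclass
class IntervalTrack:
    """A flat feature track (probes, repeats, CAGE peaks, enhancers, elements)."""

    features: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: Dict[Tuple[str, str], List[GenomicInterval]] = {}
        self._reindex()

    def _reindex(self) -> None:
        index: Dict[str, List[GenomicInterval]] = defaultdict(list)
        for f in self.features:
            index[f.chrom].append(f)
        self._by_chrom = {c: sorted(fs, key=lambda f: f.start) for c, fs in index.items()}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.features)

    def on_chrom(self, chrom: str, strand: Optional[str] = None) -> List[GenomicInterval]:
        feats = self._by_chrom.get(chrom, [])
        if strand is None:
            return feats
        return [f for f in feats if f.strand == strand]

    def overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> List[GenomicInterval]:
        return [
            f
            for f in self.on_chrom(chrom, strand)
            if f.start < end and start < f.end
        ]


class SignalTrack:
    """Per-chromosome piecewise-constant signal with bedGraph semantics.

    Positions not covered by any interval have no value; consumers decide
    how to treat missing data (profiling code substitutes 0).
    """

    def __init__(
        self, intervals: Iterable[Tuple[str, int, int, float]] = ()
    ) -> None:
        per_chrom: Dict[str, List[Tuple[int, int, float]]] = defaultdict(list)
        for chrom, start, end, value in intervals:
            if not math.isfinite(value):
                raise ValueError("signal values must be finite")
            if start >= end:
                raise ValueError("signal interval start must precede end")
            per_chrom[chrom].append((start, end, value))
        self._data: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping signal intervals on {chrom}")
            self._data[chrom] = ivs

    def chromosomes(self) -> List[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> List[Tuple[int, int, float]]:
        return list(self._data.get(chrom, []))

    def values(self, chrom: str, start: int, end: int, missing: float = 0.0):
        """Per-base values over ``[start, end)`` as a list of floats."""
        out = [missing] * (end - start)
        for s, e, v in self._data.get(chrom, []):
            if e <= start:
                continue
            if s >= end:
                break
            for pos in range(max(s, start), min(e, end)):
                out[pos - start] = v
        return out


# ---------------------------------------------------------------------------
# Genome sequence access
# ---------------------------------------------------------------------------


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` from a genome store.

    Accepts a plain mapping ``{chrom: sequence}`` or a ``pyfaidx.Fasta``-like
    object supporting ``genome[chrom][start:end]``.
    """
    try:
        record = genome[chrom]
    except KeyError as exc:
        raise GenomeLookupError(f"chromosome {chrom!r} not in genome") from exc
    piece = record[start:end]
    return str(piece).upper()


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------


def _parse_attributes(blob: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in blob.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` features are consulted; transcripts are reconstructed from
    their exon lines. GTF's 1-based closed coordinates are converted to the
    internal 0-based half-open convention. Strand ``"."`` is kept as unknown.
    """
    exons: Dict[str, List[GenomicInterval]] = defaultdict(list)
    gene_of: Dict[str, str] = {}
    source_of: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr_blob = fields
            if feature != "exon":
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in (STRAND_PLUS, STRAND_MINUS, STRAND_UNKNOWN):
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_blob, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon lacks transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon lacks gene_id")
            tid = attrs["transcript_id"]
            try:
                exon = GenomicInterval(chrom, start_1 - 1, end_1, strand)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: {exc}") from exc
            prev_gene = gene_of.setdefault(tid, attrs["gene_id"])
            if prev_gene != attrs["gene_id"]:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} assigned to two genes"
                )
            source_of.setdefault(tid, source)
            exons[tid].append(exon)
    out = AnnotationSet()
    for tid, exon_list in exons.items():
        try:
            out.add(
                Transcript(
                    transcript_id=tid,
                    gene_id=gene_of[tid],
                    exons=tuple(exon_list),
                    source=source_of[tid],
                )
            )
        except ValueError as exc:
            raise GtfParseError(str(exc)) from exc
    return out


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as exon-level GTF (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in sorted(annotation, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            for e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            t.source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA / table I/O
# ---------------------------------------------------------------------------


def read_bed(path) -> IntervalTrack:
    """Read BED3–BED6 into an IntervalTrack; skips comments and track lines."""
    feats: List[GenomicInterval] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else STRAND_UNKNOWN
            feats.append(GenomicInterval(chrom, start, end, strand, name, score))
    return IntervalTrack(feats)


def write_bed(track: IntervalTrack, path) -> None:
    with open(path, "w") as fh:
        for f in sorted(track, key=lambda f: (f.chrom, f.start)):
            score = "." if f.score is None else f"{f.score:g}"
            name = f.name if f.name is not None else "."
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{score}\t{f.strand}\n"
            )


def read_bedgraph(path) -> SignalTrack:
    rows: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return SignalTrack(rows)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chromosomes()):
            for start, end, value in track.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def merge_blocks(blocks: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping ``(start, end)`` blocks into a disjoint union."""
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(blocks):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _intersection_size(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
) -> int:
    """Total overlap between two sorted disjoint block lists (two-pointer sweep)."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def exonic_union(
    transcripts: Iterable[Transcript], chrom: str, strand: Optional[str] = None
) -> List[Tuple[int, int]]:
    """Merged exonic blocks of the given transcripts restricted to one chromosome."""
    blocks = [
        (e.start, e.end)
        for t in transcripts
        if t.chrom == chrom and (strand is None or t.strand == strand)
        for e in t.exons
    ]
    return merge_blocks(blocks)


def exonic_overlap_fraction(
    query: Transcript, reference: AnnotationSet, same_strand: bool = True
) -> float:
    """Fraction of the query's exonic bases covered by reference exonic bases.

    Split semantics: only exon bodies count, introns never do. With
    ``same_strand`` only reference transcripts on the query's strand are
    considered (bedtools ``-s -split -f`` behaviour, query-denominated).
    """
    strand = query.strand if same_strand else None
    ref_union = exonic_union(reference.on_chrom(query.chrom), query.chrom, strand)
    covered = _intersection_size(query.exon_blocks(), ref_union)
    return covered / query.exonic_length


def jaccard_similarity(a: Transcript, b: Transcript) -> float:
    """Exonic-base Jaccard statistic |A∩B| / |A∪B|.

    Returns 0 for transcripts on different chromosomes or strands.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    inter = _intersection_size(a.exon_blocks(), b.exon_blocks())
    union = a.exonic_length + b.exonic_length - inter
    return inter / union if union else 0.0


def splice_dinucleotides(
    t: Transcript, genome
) -> List[Tuple[str, str]]:
    """Donor/acceptor dinucleotide pairs per intron, 5'→3' in transcript order.

    Minus-strand introns are reverse-complemented so a canonical intron
    always reads ("GT", "AG").
    """
    if t.strand == STRAND_UNKNOWN:
        raise ValueError(
            f"transcript {t.transcript_id}: splice sites undefined for unknown strand"
        )
    pairs: List[Tuple[str, str]] = []
    for intron in t.introns():
        left = fetch_sequence(genome, t.chrom, intron.start, intron.start + 2)
        right = fetch_sequence(genome, t.chrom, intron.end - 2, intron.end)
        if t.strand == STRAND_PLUS:
            pairs.append((left, right))
        else:
            pairs.append((reverse_complement(right), reverse_complement(left)))
    if t.strand == STRAND_MINUS:
        pairs.reverse()
    return pairs


def collapse_gene_blocks(reference: AnnotationSet) -> IntervalTrack:
    """Merge same-strand overlapping gene spans into maximal blocks.

    Each block's ``name`` is a comma-joined, sorted list of its member gene
    ids. Overlap is transitive: chains of pairwise-overlapping genes collapse
    into a single block.
    """
    spans = [reference.gene_span(g) for g in reference.gene_ids()]
    by_key: Dict[Tuple[str, str], List[GenomicInterval]] = defaultdict(list)
    for s in spans:
        by_key[(s.chrom, s.strand)].append(s)
    blocks: List[GenomicInterval] = []
    for (chrom, strand), group in by_key.items():
        group.sort(key=lambda s: s.start)
        cur_start, cur_end = group[0].start, group[0].end
        members = [group[0].name]
        for s in group[1:]:
            if s.start < cur_end:
                cur_end = max(cur_end, s.end)
                members.append(s.name)
            else:
                blocks.append(
                    GenomicInterval(
                        chrom, cur_start, cur_end, strand, name=",".join(sorted(members))
                    )
                )
                cur_start, cur_end, members = s.start, s.end, [s.name]
        blocks.append(
            GenomicInterval(
                chrom, cur_start, cur_end, strand, name=",".join(sorted(members))
            )
        )
    return IntervalTrack(blocks)
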