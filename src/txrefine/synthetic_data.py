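"""Synthetic miniature study generator with planted, recorded ground truth.

Builds a small genome (two placed megabase chromosomes plus one unplaced
contig) together with every input the refinement pipeline consumes: a
reference annotation, a raw assembly containing planted artifact categories,
capture-probe / control-probe / repeat / CAGE / enhancer / conserved-element
tracks, a per-base signal track, per-sample spike-in readings whose
coverage is log-log linear in concentration, an FPKM matrix, and
stranded-read fractions. Each planted transcript violates at most one
filtering rule (single-fault construction), so the expected fate of every
transcript under the full pipeline is recorded exactly in a truth table.

Canonical introns are written into the genome sequence as GT..AG
(strand-aware); planted non-canonical introns read CC..GG on either strand.
Brain-enriched transcripts carry a brain-to-nonbrain median FPKM ratio
well above fourfold. CAGE peaks mark the 5' ends of supported sense-intronic
monoexonic transcripts (within 100 nt) and a configurable fraction of the
surviving transcripts' TSSs (within 200 nt).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_core import (
    STRAND_MINUS,
    STRAND_PLUS,
    STRAND_UNKNOWN,
    AnnotationSet,
    GenomicInterval,
    IntervalTrack,
    SignalTrack,
    Transcript,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gtf,
)
from .hq_filter_pipeline import PipelineConfig, PipelineInputs
from .spikein_calibration import (
    SpikeInRecord,
    calibrate_sample,
    write_spikein_table,
)

CATEGORIES = (
    "clean",
    "unplaced",
    "no_probe",
    "low_expression",
    "unstranded",
    "repeat_buried",
    "too_short",
    "contamination",
    "already_annotated",
    "degradation_product",
    "noncanonical",
    "redundant_duplicate",
    "bridging",
    "upstream_extended",
    "downstream_extended",
    "brain_enriched",
)

FATE_KEPT = "kept"


class GenerationError(ValueError):
    """Raised when the requested categories do not fit the synthetic genome."""


@dataclass
class GenerationParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    unplaced_contig: str = "chrUn1"
    unplaced_length: int = 100_000
    brain_samples: Tuple[str, ...] = ("brain", "cortex", "cerebellum", "olfactory")
    nonbrain_samples: Tuple[str, ...] = ("heart", "liver", "kidney", "testis")
    # planted category counts (transcripts unless noted)
    n_clean_spliced: int = 30
    n_clean_multi_isoform_genes: int = 4  # two distinct isoforms each
    n_clean_monoexonic: int = 8
    n_clean_intronic: int = 8  # half CAGE-supported, half enhancer-supported
    n_unplaced: int = 6
    n_no_probe: int = 8  # half without probes, half control-probe-only
    n_low_expression: int = 6
    n_unstranded: int = 6
    n_repeat_buried: int = 6
    n_too_short: int = 6
    n_contamination: int = 6
    n_already_annotated: int = 8
    n_degradation: int = 6
    n_noncanonical: int = 6
    n_redundant_pairs: int = 6
    n_bridging: int = 4
    n_upstream_extended: int = 4
    n_downstream_extended: int = 4
    n_brain_enriched: int = 6
    n_reference_only: int = 4
    # expression model (FPKM)
    base_fpkm: float = 20.0
    low_fpkm: float = 0.02
    brain_fpkm: float = 8.0
    brain_background_fpkm: float = 0.4
    fpkm_sigma: float = 0.3  # lognormal sd of multiplicative noise
    # spike-in model
    n_spikein_species: int = 12
    spikein_conc_range: Tuple[float, float] = (0.01, 100.0)  # amol/µL, log-spaced
    spikein_efficiency: float = 400.0  # coverage folds per amol/µL
    spikein_sigma: float = 0.2
    read_length: int = 102
    fpkm_per_amol: float = 30.0
    # track construction
    cage_tss_fraction: float = 0.6
    locus_spacing: int = 3_000

    @property
    def samples(self) -> Tuple[str, ...]:
        return self.brain_samples + self.nonbrain_samples


@dataclass
class SyntheticBundle:
    genome: Dict[str, str]
    reference: AnnotationSet
    assembly: AnnotationSet
    spikeins: Dict[str, List[SpikeInRecord]]  # per sample
    fpkm: pd.DataFrame  # transcripts x samples
    strand_fractions: pd.DataFrame
    probes: IntervalTrack
    control_probes: IntervalTrack
    repeats: IntervalTrack
    cage: IntervalTrack
    enhancers: IntervalTrack
    conserved_elements: IntervalTrack
    signal: SignalTrack
    allowed_space: IntervalTrack
    truth: pd.DataFrame  # transcript_id, category, fate
    params: GenerationParams
    seed: int

    def fpkm_thresholds(self) -> Dict[str, float]:
        """Per-sample FPKM floors from spike-in calibration."""
        return {
            sample: calibrate_sample(
                records, read_length=self.params.read_length
            ).threshold_fpkm
            for sample, records in self.spikeins.items()
        }

    def pipeline_config(
        self, thresholds: Optional[Dict[str, float]] = None
    ) -> PipelineConfig:
        return PipelineConfig(
            placed_chromosomes=frozenset(self.params.chrom_lengths),
            fpkm_thresholds=thresholds or self.fpkm_thresholds(),
        )

    def pipeline_inputs(self) -> PipelineInputs:
        return PipelineInputs(
            reference=self.reference,
            genome=self.genome,
            probes=self.probes,
            control_probes=self.control_probes,
            repeats=self.repeats,
            cage=self.cage,
            enhancers=self.enhancers,
            fpkm=self.fpkm,
            strand_fractions=self.strand_fractions,
        )

    def expected_kept_ids(self) -> List[str]:
        return list(self.truth.loc[self.truth.fate == FATE_KEPT, "transcript_id"])


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class _GenomeBuilder:
    def __init__(self, rng: np.random.Generator, lengths: Dict[str, int]) -> None:
        self.seqs = {
            chrom: bytearray(
                rng.choice(_BASES, size=length).tobytes()
            )
            for chrom, length in lengths.items()
        }

    def write(self, chrom: str, pos: int, text: str) -> None:
        self.seqs[chrom][pos : pos + len(text)] = text.encode()

    def finalize(self) -> Dict[str, str]:
        return {chrom: seq.decode() for chrom, seq in self.seqs.items()}


class _Layout:
    """Round-robin locus allocator over the placed chromosomes."""

    def __init__(self, lengths: Dict[str, int], spacing: int, margin: int = 5_000):
        self.lengths = lengths
        self.spacing = spacing
        self.margin = margin
        self.cursors = {chrom: margin for chrom in lengths}
        self.order = list(lengths)
        self._next = 0

    def alloc(self, length: int, chrom: Optional[str] = None) -> Tuple[str, int]:
        if chrom is None:
            chrom = self.order[self._next % len(self.order)]
            self._next += 1
        start = self.cursors[chrom]
        end = start + length
        if end + self.margin > self.lengths[chrom]:
            raise GenerationError(
                f"planted categories exceed capacity of {chrom}; "
                "reduce counts or enlarge the genome"
            )
        self.cursors[chrom] = end + self.spacing
        return chrom, start


def _make_exons(
    chrom: str, start: int, strand: str, exon_lens: Sequence[int], intron_lens: Sequence[int]
) -> Tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _span(exon_lens: Sequence[int], intron_lens: Sequence[int]) -> int:
    return sum(exon_lens) + sum(intron_lens)


class _Generator:
    def __init__(self, seed: int, params: GenerationParams) -> None:
        self.params = params
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        lengths = dict(params.chrom_lengths)
        lengths[params.unplaced_contig] = params.unplaced_length
        self.genome = _GenomeBuilder(self.rng, lengths)
        self.layout = _Layout(params.chrom_lengths, params.locus_spacing)
        self.unplaced_cursor = 2_000
        self.reference: List[Transcript] = []
        self.assembly: List[Transcript] = []
        self.truth_rows: List[Tuple[str, str, str]] = []
        self.probes: List[GenomicInterval] = []
        self.control_probes: List[GenomicInterval] = []
        self.repeats: List[GenomicInterval] = []
        self.cage: List[GenomicInterval] = []
        self.enhancers: List[GenomicInterval] = []
        self.conserved: List[GenomicInterval] = []
        self.fpkm_rows: Dict[str, np.ndarray] = {}
        self.frac_rows: Dict[str, np.ndarray] = {}
        self._gene_n = 0
        self._tx_n = 0
        self._ref_gene_n = 0
        self._ref_tx_n = 0

    # -- identifiers --------------------------------------------------------

    def _gene_id(self) -> str:
        self._gene_n += 1
        return f"AG{self._gene_n:04d}"

    def _tx_id(self) -> str:
        self._tx_n += 1
        return f"AT{self._tx_n:04d}"

    def _ref_ids(self) -> Tuple[str, str]:
        self._ref_gene_n += 1
        self._ref_tx_n += 1
        return f"RG{self._ref_gene_n:04d}", f"RT{self._ref_tx_n:04d}"

    def _strand(self, i: int) -> str:
        return STRAND_PLUS if i % 2 == 0 else STRAND_MINUS

    # -- sequence edits -----------------------------------------------------

    def _write_introns(self, t: Transcript, canonical: bool = True) -> None:
        for intron in t.introns():
            if canonical:
                donor, acceptor = ("GT", "AG") if t.strand != STRAND_MINUS else ("CT", "AC")
            else:
                donor, acceptor = "CC", "GG"  # non-canonical read from either strand
            self.genome.write(t.chrom, intron.start, donor)
            self.genome.write(t.chrom, intron.end - 2, acceptor)

    # -- per-transcript bookkeeping -----------------------------------------

    def _register(
        self,
        t: Transcript,
        category: str,
        fate: str,
        fpkm: Optional[np.ndarray] = None,
        strand_fraction: Optional[np.ndarray] = None,
        probe: bool = True,
        control_probe: bool = False,
    ) -> None:
        p = self.params
        n = len(p.samples)
        self.assembly.append(t)
        self.truth_rows.append((t.transcript_id, category, fate))
        if fpkm is None:
            fpkm = p.base_fpkm * self.rng.lognormal(0.0, p.fpkm_sigma, n)
        self.fpkm_rows[t.transcript_id] = fpkm
        if strand_fraction is None:
            strand_fraction = self.rng.uniform(0.90, 0.99, n)
        self.frac_rows[t.transcript_id] = strand_fraction
        first = t.exons[0]
        if probe:
            mid = (first.start + first.end) // 2
            half = min(50, first.length // 2)
            self.probes.append(
                GenomicInterval(t.chrom, mid - half, mid + half, STRAND_UNKNOWN)
            )
        if control_probe:
            self.control_probes.append(
                GenomicInterval(t.chrom, first.start, first.end, STRAND_UNKNOWN)
            )

    def _add_reference(self, exons: Tuple[GenomicInterval, ...]) -> Transcript:
        gid, tid = self._ref_ids()
        t = Transcript(tid, gid, exons, source="reference")
        self.reference.append(t)
        self._write_introns(t)
        return t

    # -- category builders --------------------------------------------------

    def _spliced(
        self,
        strand: str,
        chrom: Optional[str] = None,
        exon_lens=(300, 300, 300),
        intron_lens=(400, 400),
        margin: int = 0,
    ) -> Tuple[GenomicInterval, ...]:
        span = _span(exon_lens, intron_lens)
        c, start = self.layout.alloc(span + 2 * margin, chrom)
        return _make_exons(c, start + margin, strand, exon_lens, intron_lens)

    def build(self) -> SyntheticBundle:
        p = self.params
        nb = len(p.brain_samples)
        nn = len(p.nonbrain_samples)

        # clean spliced transcripts, one per gene
        for i in range(p.n_clean_spliced):
            exons = self._spliced(self._strand(i))
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t)
            self._register(t, "clean", FATE_KEPT)
            if i < 10:  # conserved element over half of the first exon
                e = t.exons[0]
                self.conserved.append(
                    GenomicInterval(
                        e.chrom,
                        e.start,
                        e.start + e.length // 2,
                        STRAND_UNKNOWN,
                        score=float(self.rng.integers(200, 600)),
                    )
                )

        # clean genes with two structurally distinct isoforms (exon skipping)
        for i in range(p.n_clean_multi_isoform_genes):
            strand = self._strand(i)
            exons = self._spliced(strand)
            gid = self._gene_id()
            full = Transcript(self._tx_id(), gid, exons)
            skipped = Transcript(self._tx_id(), gid, (exons[0], exons[2]))
            self._write_introns(full)
            self._write_introns(skipped)  # shares exon boundaries; consistent
            self._register(full, "clean", FATE_KEPT)
            self._register(skipped, "clean", FATE_KEPT)

        # clean monoexonic intergenic
        for i in range(p.n_clean_monoexonic):
            chrom, start = self.layout.alloc(500)
            t = Transcript(
                self._tx_id(),
                self._gene_id(),
                (GenomicInterval(chrom, start, start + 500, self._strand(i)),),
            )
            self._register(t, "clean", FATE_KEPT)

        # sense-intronic monoexonic with independent TSS evidence
        for i in range(p.n_clean_intronic):
            self._intronic_monoexonic(
                supported="cage" if i < p.n_clean_intronic // 2 else "enhancer",
                strand=self._strand(i),
                category="clean",
                fate=FATE_KEPT,
            )

        # unplaced-contig transcripts (violate only placement)
        for i in range(p.n_unplaced):
            start = self.unplaced_cursor
            exons = _make_exons(
                p.unplaced_contig, start, self._strand(i), (300, 300), (400,)
            )
            self.unplaced_cursor = exons[-1].end + p.locus_spacing
            if self.unplaced_cursor > p.unplaced_length - 2_000:
                raise GenerationError("unplaced contig capacity exceeded")
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t)
            self._register(t, "unplaced", "dropped:f01_drop_unplaced")

        # transcripts without capture-probe support
        for i in range(p.n_no_probe):
            control_only = i >= p.n_no_probe // 2
            exons = self._spliced(self._strand(i), exon_lens=(300, 300), intron_lens=(400,))
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t)
            self._register(
                t,
                "no_probe",
                "dropped:f02_probe_overlap",
                probe=False,
                control_probe=control_only,
            )

        # consistently sub-threshold expression
        for i in range(p.n_low_expression):
            exons = self._spliced(self._strand(i), exon_lens=(300, 300), intron_lens=(400,))
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t)
            fpkm = p.low_fpkm * self.rng.lognormal(0.0, p.fpkm_sigma, nb + nn)
            self._register(t, "low_expression", "dropped:f03_expression_floor", fpkm=fpkm)

        # unknown strand (monoexonic, otherwise clean)
        for _ in range(p.n_unstranded):
            chrom, start = self.layout.alloc(500)
            t = Transcript(
                self._tx_id(),
                self._gene_id(),
                (GenomicInterval(chrom, start, start + 500, STRAND_UNKNOWN),),
            )
            self._register(t, "unstranded", "dropped:f04_known_strand")

        # >90% repeat-masked exonic bases
        for i in range(p.n_repeat_buried):
            chrom, start = self.layout.alloc(1_000)
            t = Transcript(
                self._tx_id(),
                self._gene_id(),
                (GenomicInterval(chrom, start, start + 1_000, self._strand(i)),),
            )
            self.repeats.append(
                GenomicInterval(chrom, start, start + 950, STRAND_UNKNOWN)
            )
            self._register(t, "repeat_buried", "dropped:f05_repeat_content")

        # shorter than the minimum isoform length
        for i in range(p.n_too_short):
            chrom, start = self.layout.alloc(150)
            t = Transcript(
                self._tx_id(),
                self._gene_id(),
                (GenomicInterval(chrom, start, start + 150, self._strand(i)),),
            )
            self._register(t, "too_short", "dropped:f06_min_length")

        # DNA-contamination look-alikes: poor strandedness in every sample
        for i in range(p.n_contamination):
            chrom, start = self.layout.alloc(500)
            t = Transcript(
                self._tx_id(),
                self._gene_id(),
                (GenomicInterval(chrom, start, start + 500, self._strand(i)),),
            )
            frac = self.rng.uniform(0.30, 0.60, nb + nn)
            self._register(
                t, "contamination", "dropped:f07_dna_contamination", strand_fraction=frac
            )

        # exact copies of reference transcripts
        for i in range(p.n_already_annotated):
            exons = self._spliced(self._strand(i))
            self._add_reference(exons)
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._register(t, "already_annotated", "dropped:f08_drop_annotated")

        # unsupported sense-intronic monoexonic degradation products
        for i in range(p.n_degradation):
            self._intronic_monoexonic(
                supported=None,
                strand=self._strand(i),
                category="degradation_product",
                fate="dropped:f09_degradation_products",
            )

        # one non-canonical intron
        for i in range(p.n_noncanonical):
            exons = self._spliced(self._strand(i), exon_lens=(300, 300), intron_lens=(400,))
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t, canonical=False)
            self._register(t, "noncanonical", "dropped:f10_canonical_splice")

        # near-identical isoform pairs within one gene
        for i in range(p.n_redundant_pairs):
            strand = self._strand(i)
            exons = self._spliced(
                strand, exon_lens=(600, 600), intron_lens=(500,), margin=20
            )
            gid = self._gene_id()
            short = Transcript(self._tx_id(), gid, exons)
            last = exons[-1]
            extended = exons[:-1] + (
                GenomicInterval(last.chrom, last.start, last.end + 10, strand),
            )
            long = Transcript(self._tx_id(), gid, extended)
            self._write_introns(short)
            self._register(long, "redundant_duplicate", FATE_KEPT)
            self._register(short, "redundant_duplicate", "collapsed:f11_collapse_redundant")

        # transcripts bridging two reference genes
        for i in range(p.n_bridging):
            self._bridging(self._strand(i))

        # boundary extensions of single reference genes
        for i in range(p.n_upstream_extended):
            self._extension(self._strand(i), upstream=True)
        for i in range(p.n_downstream_extended):
            self._extension(self._strand(i), upstream=False)

        # brain-enriched clean transcripts
        for i in range(p.n_brain_enriched):
            exons = self._spliced(self._strand(i))
            t = Transcript(self._tx_id(), self._gene_id(), exons)
            self._write_introns(t)
            fpkm = np.concatenate(
                [
                    p.brain_fpkm * self.rng.lognormal(0.0, p.fpkm_sigma, nb),
                    p.brain_background_fpkm * self.rng.lognormal(0.0, p.fpkm_sigma, nn),
                ]
            )
            self._register(t, "brain_enriched", FATE_KEPT, fpkm=fpkm)

        # reference-only background genes
        for i in range(p.n_reference_only):
            exons = self._spliced(self._strand(i))
            self._add_reference(exons)

        return self._assemble_bundle()

    def _intronic_monoexonic(
        self, supported: Optional[str], strand: str, category: str, fate: str
    ) -> None:
        # host gene: two exons around a 4-kb intron; planted transcript inside
        host_exons = self._spliced(
            strand, exon_lens=(300, 300), intron_lens=(4_000,)
        )
        self._add_reference(host_exons)
        intron_start = host_exons[0].end
        t_start = intron_start + 1_500
        chrom = host_exons[0].chrom
        t = Transcript(
            self._tx_id(),
            self._gene_id(),
            (GenomicInterval(chrom, t_start, t_start + 400, strand),),
        )
        if supported == "cage":
            tss = t.five_prime
            self.cage.append(
                GenomicInterval(chrom, tss - 50, tss - 30, strand)
            )
        elif supported == "enhancer":
            self.enhancers.append(
                GenomicInterval(chrom, t.start - 20, t.end + 20, STRAND_UNKNOWN)
            )
        self._register(t, category, fate)

    def _bridging(self, strand: str) -> None:
        # two reference genes 2 kb apart; an assembly transcript joins their
        # facing exons through a novel middle exon
        chrom, start = self.layout.alloc(2 * 1_000 + 2_000)
        gene_a = _make_exons(chrom, start, strand, (300, 300), (400,))
        gene_b = _make_exons(chrom, start + 3_000, strand, (300, 300), (400,))
        self._add_reference(gene_a)
        self._add_reference(gene_b)
        mid_start = gene_a[-1].end + 600
        exons = (
            GenomicInterval(chrom, gene_a[-1].start, gene_a[-1].end, strand),
            GenomicInterval(chrom, mid_start, mid_start + 300, strand),
            GenomicInterval(chrom, gene_b[0].start, gene_b[0].end, strand),
        )
        t = Transcript(self._tx_id(), self._gene_id(), exons)
        self._write_introns(t)
        self._register(t, "bridging", FATE_KEPT)

    def _extension(self, strand: str, upstream: bool) -> None:
        ext = 600
        exons = self._spliced(
            strand, exon_lens=(300, 300), intron_lens=(400,), margin=ext + 100
        )
        self._add_reference(exons)
        first, last = exons[0], exons[-1]
        # extend in transcription direction: 5' for upstream, 3' for downstream
        grow_left = (strand != STRAND_MINUS) == upstream
        if grow_left:
            new_exons = (
                GenomicInterval(first.chrom, first.start - ext, first.end, strand),
                last,
            )
        else:
            new_exons = (
                first,
                GenomicInterval(last.chrom, last.start, last.end + ext, strand),
            )
        t = Transcript(self._tx_id(), self._gene_id(), new_exons)
        self._write_introns(t)  # same intron as the reference gene
        category = "upstream_extended" if upstream else "downstream_extended"
        self._register(t, category, FATE_KEPT)

    # -- assembly of the final bundle ---------------------------------------

    def _spikein_tables(self) -> Dict[str, List[SpikeInRecord]]:
        p = self.params
        concs = np.geomspace(*p.spikein_conc_range, p.n_spikein_species)
        lengths = self.rng.integers(500, 2_001, p.n_spikein_species)
        tables: Dict[str, List[SpikeInRecord]] = {}
        for sample in p.samples:
            records = []
            for j, (conc, length) in enumerate(zip(concs, lengths)):
                cov_noise = self.rng.lognormal(0.0, p.spikein_sigma)
                count = int(
                    round(p.spikein_efficiency * conc * length / p.read_length * cov_noise)
                )
                fpkm_noise = self.rng.lognormal(0.0, p.spikein_sigma)
                records.append(
                    SpikeInRecord(
                        id=f"ERCC-{j:04d}",
                        concentration=float(conc),
                        length=int(length),
                        read_count=count,
                        fpkm=float(p.fpkm_per_amol * conc * fpkm_noise),
                    )
                )
            tables[sample] = records
        return tables

    def _assemble_bundle(self) -> SyntheticBundle:
        p = self.params
        truth = pd.DataFrame(
            self.truth_rows, columns=["transcript_id", "category", "fate"]
        )
        kept = truth.loc[truth.fate == FATE_KEPT, "transcript_id"]
        assembly = AnnotationSet(self.assembly)

        # CAGE support for a fraction of surviving TSSs (within 200 nt)
        kept_ids = list(kept)
        n_cage = int(round(p.cage_tss_fraction * len(kept_ids)))
        chosen = self.rng.choice(len(kept_ids), size=n_cage, replace=False)
        existing = {(c.chrom, c.start, c.end, c.strand) for c in self.cage}
        for idx in sorted(chosen):
            t = assembly[kept_ids[idx]]
            tss = t.five_prime
            key = (t.chrom, tss - 60, tss - 40, t.strand)
            if key not in existing:
                self.cage.append(GenomicInterval(*key))
                existing.add(key)

        fpkm = pd.DataFrame.from_dict(
            self.fpkm_rows, orient="index", columns=list(p.samples)
        )
        fracs = pd.DataFrame.from_dict(
            self.frac_rows, orient="index", columns=list(p.samples)
        )
        reference = AnnotationSet(self.reference)

        # modest signal over reference gene bodies; elsewhere missing (0)
        signal_rows = []
        for g in reference.gene_ids():
            span = reference.gene_span(g)
            signal_rows.append((span.chrom, span.start, span.end, 1.5))
        signal_rows.sort()
        merged_rows: List[Tuple[str, int, int, float]] = []
        for row in signal_rows:
            if (
                merged_rows
                and row[0] == merged_rows[-1][0]
                and row[1] < merged_rows[-1][2]
            ):
                prev = merged_rows[-1]
                merged_rows[-1] = (prev[0], prev[1], max(prev[2], row[2]), prev[3])
            else:
                merged_rows.append(row)

        allowed = IntervalTrack(
            [
                GenomicInterval(chrom, 0, length, STRAND_UNKNOWN)
                for chrom, length in p.chrom_lengths.items()
            ]
        )
        return SyntheticBundle(
            genome=self.genome.finalize(),
            reference=reference,
            assembly=assembly,
            spikeins=self._spikein_tables(),
            fpkm=fpkm,
            strand_fractions=fracs,
            probes=IntervalTrack(self.probes),
            control_probes=IntervalTrack(self.control_probes),
            repeats=IntervalTrack(self.repeats),
            cage=IntervalTrack(self.cage),
            enhancers=IntervalTrack(self.enhancers),
            conserved_elements=IntervalTrack(self.conserved),
            signal=SignalTrack(merged_rows),
            allowed_space=allowed,
            truth=truth,
            params=p,
            seed=self.seed,
        )


def generate_bundle(
    seed: int, params: Optional[GenerationParams] = None
) -> SyntheticBundle:
    """Generate the full synthetic study; bit-reproducible for a fixed seed."""
    return _Generator(seed, params or GenerationParams()).build()


# ---------------------------------------------------------------------------
# On-disk serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir) -> str:
    """Write every bundle component in its standard text format.

    Returns the path of a JSON manifest listing all files and the seed.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": "genome.fa",
        "reference": "reference.gtf",
        "assembly": "assembly.gtf",
        "probes": "probes.bed",
        "control_probes": "control_probes.bed",
        "repeats": "repeats.bed",
        "cage": "cage.bed",
        "enhancers": "enhancers.bed",
        "conserved_elements": "conserved_elements.bed",
        "signal": "signal.bedgraph",
        "allowed_space": "allowed_space.bed",
        "fpkm": "fpkm.tsv",
        "strand_fractions": "strand_fractions.tsv",
        "truth": "truth.tsv",
    }
    full = {k: os.path.join(outdir, v) for k, v in paths.items()}
    write_fasta(bundle.genome, full["genome"])
    write_gtf(bundle.reference, full["reference"])
    write_gtf(bundle.assembly, full["assembly"])
    for key in (
        "probes",
        "control_probes",
        "repeats",
        "cage",
        "enhancers",
        "conserved_elements",
        "allowed_space",
    ):
        write_bed(getattr(bundle, key), full[key])
    write_bedgraph(bundle.signal, full["signal"])
    bundle.fpkm.rename_axis("transcript_id").to_csv(full["fpkm"], sep="\t")
    bundle.strand_fractions.rename_axis("transcript_id").to_csv(
        full["strand_fractions"], sep="\t"
    )
    bundle.truth.to_csv(full["truth"], sep="\t", index=False)
    spikein_dir = os.path.join(outdir, "spikeins")
    os.makedirs(spikein_dir, exist_ok=True)
    for sample, records in bundle.spikeins.items():
        path = os.path.join(spikein_dir, f"{sample}.tsv")
        write_spikein_table(records, path)
        paths[f"spikeins/{sample}"] = os.path.join("spikeins", f"{sample}.tsv")
    manifest = {"seed": bundle.seed, "files": paths}
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path
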