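"""Data model, GTF round-trips and interval algebra against per-base oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txrefine.annotation_core import (
    AnnotationSet,
    GenomicInterval,
    GtfParseError,
    Transcript,
    collapse_gene_blocks,
    exonic_overlap_fraction,
    jaccard_similarity,
    merge_blocks,
    read_gtf,
    splice_dinucleotides,
    write_gtf,
)

from conftest import make_transcript, random_transcript
from oracles import brute_jaccard, brute_overlap_fraction


class TestDataModel:
    def test_interval_rejects_empty_and_reversed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_transcript_sorts_exons_and_rejects_overlap(self):
        t = make_transcript([(300, 400), (100, 200)])
        assert t.exon_blocks() == [(100, 200), (300, 400)]
        with pytest.raises(ValueError):
            make_transcript([(100, 250), (200, 400)])

    def test_transcript_rejects_mixed_chromosomes(self):
        with pytest.raises(ValueError):
            Transcript(
                "t",
                "g",
                (
                    GenomicInterval("chr1", 0, 100, "+"),
                    GenomicInterval("chr2", 0, 100, "+"),
                ),
            )

    def test_five_prime_is_strand_aware(self):
        plus = make_transcript([(100, 200), (300, 400)], strand="+")
        minus = make_transcript([(100, 200), (300, 400)], strand="-")
        assert plus.five_prime == 100
        assert minus.five_prime == 399

    def test_annotation_set_indexes_genes(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 100)], tid="t1", gid="g1"),
                make_transcript([(200, 300)], tid="t2", gid="g1"),
            ]
        )
        assert a.n_genes == 1 and a.n_transcripts == 2
        with pytest.raises(ValueError):
            a.add(make_transcript([(0, 50)], tid="t1"))


class TestGtfIO:
    def test_coordinates_shift_to_zero_based(self, tmp_path):
        path = tmp_path / "in.gtf"
        attrs = 'gene_id "g1"; transcript_id "t1";'
        path.write_text(
            f"chr1\tsrc\texon\t101\t200\t.\t+\t.\t{attrs}\n"
            f"chr1\tsrc\texon\t301\t400\t.\t+\t.\t{attrs}\n"
        )
        a = read_gtf(path)
        assert a["t1"].exon_blocks() == [(100, 200), (300, 400)]

    def test_two_transcripts_one_gene(self, tmp_path):
        path = tmp_path / "in.gtf"
        path.write_text(
            'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "a";\n'
            'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "b";\n'
        )
        a = read_gtf(path)
        assert a.n_genes == 1 and a.n_transcripts == 2

    def test_round_trip_identity(self, tmp_path, bundle):
        first = tmp_path / "a.gtf"
        second = tmp_path / "b.gtf"
        write_gtf(bundle.assembly, first)
        reread = read_gtf(first)
        assert reread == bundle.assembly
        write_gtf(reread, second)
        assert first.read_text() == second.read_text()

    def test_errors_name_line_numbers(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\ts\texon\t1\t100\t.\t+\t.\n")
        with pytest.raises(GtfParseError, match="line 1"):
            read_gtf(path)
        path.write_text('chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            read_gtf(path)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.gtf"
        write_gtf(AnnotationSet(), path)
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)


class TestOverlapAndJaccard:
    def test_identical_transcript_full_coverage(self):
        t = make_transcript([(0, 100), (200, 300)])
        ref = AnnotationSet([make_transcript([(0, 100), (200, 300)], tid="r")])
        assert exonic_overlap_fraction(t, ref, same_strand=True) == 1.0

    def test_strand_mismatch_scores_zero(self):
        t = make_transcript([(0, 100)], strand="+")
        ref = AnnotationSet([make_transcript([(0, 100)], strand="-", tid="r")])
        assert exonic_overlap_fraction(t, ref, same_strand=True) == 0.0
        assert exonic_overlap_fraction(t, ref, same_strand=False) == 1.0

    def test_partial_coverage_exact_value(self):
        t = make_transcript([(0, 100), (200, 300)])
        ref = AnnotationSet([make_transcript([(0, 100), (200, 250)], tid="r")])
        assert exonic_overlap_fraction(t, ref, same_strand=True) == pytest.approx(0.75)

    def test_split_semantics_ignore_introns(self):
        # reference exon spans the query intron; only exon bodies may count
        t = make_transcript([(0, 100), (900, 1000)])
        ref = AnnotationSet([make_transcript([(0, 1000)], tid="r")])
        assert exonic_overlap_fraction(t, ref, same_strand=True) == 1.0
        t2 = make_transcript([(0, 1000)])
        ref2 = AnnotationSet([make_transcript([(0, 100), (900, 1000)], tid="r")])
        assert exonic_overlap_fraction(t2, ref2, same_strand=True) == pytest.approx(0.2)

    def test_jaccard_exact_value(self):
        a = make_transcript([(0, 1000)], tid="a")
        b = make_transcript([(20, 1000)], tid="b")
        assert jaccard_similarity(a, b) == pytest.approx(0.98)

    def test_jaccard_zero_across_strands_or_chroms(self):
        a = make_transcript([(0, 100)], strand="+", tid="a")
        b = make_transcript([(0, 100)], strand="-", tid="b")
        c = make_transcript([(0, 100)], chrom="chr2", tid="c")
        assert jaccard_similarity(a, b) == 0.0
        assert jaccard_similarity(a, c) == 0.0

    def test_agrees_with_per_base_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for i in range(200):
            a = random_transcript(rng, f"a{i}", max_span=10_000)
            b = random_transcript(rng, f"b{i}", max_span=10_000)
            ref = AnnotationSet([b])
            for same in (True, False):
                assert exonic_overlap_fraction(a, ref, same) == pytest.approx(
                    brute_overlap_fraction(a, ref, same)
                )
            assert jaccard_similarity(a, b) == pytest.approx(brute_jaccard(a, b))
            assert jaccard_similarity(a, b) == pytest.approx(jaccard_similarity(b, a))

    def test_jaccard_one_iff_identical_base_sets(self):
        a = make_transcript([(0, 100), (200, 300)], tid="a")
        same_bases = make_transcript([(0, 100), (200, 300)], tid="b", gid="other")
        near = make_transcript([(0, 100), (200, 301)], tid="c")
        assert jaccard_similarity(a, same_bases) == 1.0
        assert jaccard_similarity(a, near) < 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 5_000), st.integers(1, 500)).map(
            lambda p: (p[0], p[0] + p[1])
        ),
        min_size=1,
        max_size=10,
    )
)
def test_merge_blocks_is_disjoint_sorted_and_idempotent(blocks):
    merged = merge_blocks(blocks)
    assert merged == merge_blocks(merged)
    assert all(a[1] < b[0] for a, b in zip(merged, merged[1:]))
    assert sum(e - s for s, e in merged) == len({p for s, e in blocks for p in range(s, e)})


class TestSpliceDinucleotides:
    GENOME = {"chr1": "A" * 1_000}

    def _genome_with(self, edits):
        seq = list("A" * 1_000)
        for pos, text in edits:
            seq[pos : pos + len(text)] = text
        return {"chr1": "".join(seq)}

    def test_monoexonic_yields_empty(self):
        t = make_transcript([(0, 100)])
        assert splice_dinucleotides(t, self.GENOME) == []

    def test_plus_strand_canonical(self):
        genome = self._genome_with([(100, "GT"), (198, "AG")])
        t = make_transcript([(0, 100), (200, 300)], strand="+")
        assert splice_dinucleotides(t, genome) == [("GT", "AG")]

    def test_minus_strand_reverse_complemented(self):
        # genomic CT..AC reads GT..AG on the minus strand
        genome = self._genome_with([(100, "CT"), (198, "AC")])
        t = make_transcript([(0, 100), (200, 300)], strand="-")
        assert splice_dinucleotides(t, genome) == [("GT", "AG")]

    def test_minus_strand_intron_order_follows_transcription(self):
        genome = self._genome_with([(100, "CT"), (198, "AC"), (400, "GG"), (498, "CC")])
        t = make_transcript([(0, 100), (200, 400), (500, 600)], strand="-")
        pairs = splice_dinucleotides(t, genome)
        # transcription runs right to left: the high-coordinate intron first
        assert pairs == [("GG", "CC"), ("GT", "AG")]

    def test_unknown_strand_rejected(self):
        t = make_transcript([(0, 100), (200, 300)], strand=".")
        with pytest.raises(ValueError):
            splice_dinucleotides(t, self.GENOME)


class TestCollapseGeneBlocks:
    def test_disjoint_genes_stay_separate(self):
        ref = AnnotationSet(
            [
                make_transcript([(0, 100)], tid="t1", gid="A"),
                make_transcript([(500, 600)], tid="t2", gid="B"),
            ]
        )
        blocks = collapse_gene_blocks(ref)
        assert sorted(b.name for b in blocks) == ["A", "B"]

    def test_same_strand_overlap_merges(self):
        ref = AnnotationSet(
            [
                make_transcript([(0, 300)], tid="t1", gid="A"),
                make_transcript([(200, 500)], tid="t2", gid="B"),
            ]
        )
        blocks = collapse_gene_blocks(ref)
        assert [b.name for b in blocks] == ["A,B"]
        assert (blocks.features[0].start, blocks.features[0].end) == (0, 500)

    def test_opposite_strand_overlap_does_not_merge(self):
        ref = AnnotationSet(
            [
                make_transcript([(0, 300)], tid="t1", gid="A", strand="+"),
                make_transcript([(200, 500)], tid="t2", gid="B", strand="-"),
            ]
        )
        assert len(collapse_gene_blocks(ref)) == 2

    def test_transitive_chain_collapses(self):
        # A overlaps B, B overlaps C, A does not touch C
        ref = AnnotationSet(
            [
                make_transcript([(0, 300)], tid="t1", gid="A"),
                make_transcript([(250, 600)], tid="t2", gid="B"),
                make_transcript([(550, 900)], tid="t3", gid="C"),
            ]
        )
        blocks = collapse_gene_blocks(ref)
        assert [b.name for b in blocks] == ["A,B,C"]
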