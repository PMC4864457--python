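"""Unit behaviour of the eleven filters and full-pipeline planted-truth recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from txrefine.annotation_core import AnnotationSet, GenomicInterval, IntervalTrack
from txrefine.hq_filter_pipeline import (
    DEFAULT_FILTER_ORDER,
    PipelineConfig,
    f02_probe_overlap,
    f03_expression_floor,
    f05_repeat_content,
    f06_min_length,
    f07_dna_contamination,
    f08_drop_annotated,
    f09_degradation_products,
    f11_collapse_redundant,
    repeat_fraction,
    run_pipeline,
)

from conftest import make_transcript

CFG = PipelineConfig(placed_chromosomes=frozenset({"chr1"}))
EMPTY = IntervalTrack([])


def track(*blocks, strand=".", chrom="chr1"):
    return IntervalTrack(
        [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
    )


class TestProbeFilter:
    def test_abutting_probe_does_not_count(self):
        a = AnnotationSet([make_transcript([(100, 200)])])
        probes = track((200, 300))  # shares no base with [100, 200)
        assert f02_probe_overlap(a, probes, EMPTY).n_transcripts == 0

    def test_single_base_overlap_keeps(self):
        a = AnnotationSet([make_transcript([(100, 200)])])
        assert f02_probe_overlap(a, track((199, 300)), EMPTY).n_transcripts == 1

    def test_real_plus_control_probe_kept(self):
        a = AnnotationSet([make_transcript([(100, 200)])])
        probes, controls = track((150, 160)), track((100, 110))
        assert f02_probe_overlap(a, probes, controls).n_transcripts == 1

    def test_control_only_dropped(self):
        a = AnnotationSet([make_transcript([(100, 200)])])
        assert f02_probe_overlap(a, EMPTY, track((100, 110))).n_transcripts == 0


class TestExpressionFloor:
    def _matrix(self, values):
        return pd.DataFrame({"s1": [values[0]], "s2": [values[1]]}, index=["t1"])

    def test_above_threshold_in_one_sample_keeps(self):
        a = AnnotationSet([make_transcript([(0, 300)], tid="t1")])
        kept = f03_expression_floor(a, self._matrix([0.1, 5.0]), {"s1": 1.0, "s2": 1.0})
        assert kept.n_transcripts == 1

    def test_below_everywhere_drops(self):
        a = AnnotationSet([make_transcript([(0, 300)], tid="t1")])
        kept = f03_expression_floor(a, self._matrix([0.0, 0.0]), {"s1": 1.0, "s2": 1.0})
        assert kept.n_transcripts == 0

    def test_missing_value_counts_as_below(self):
        a = AnnotationSet([make_transcript([(0, 300)], tid="t1")])
        kept = f03_expression_floor(
            a, self._matrix([np.nan, 0.5]), {"s1": 1.0, "s2": 1.0}
        )
        assert kept.n_transcripts == 0

    def test_missing_row_is_contract_violation(self):
        a = AnnotationSet([make_transcript([(0, 300)], tid="t_absent")])
        with pytest.raises(ValueError, match="no FPKM row"):
            f03_expression_floor(
                a, pd.DataFrame({"s1": [1.0]}, index=["other"]), {"s1": 1.0}
            )


class TestRepeatAndLength:
    def test_exact_ninety_percent_kept(self):
        a = AnnotationSet([make_transcript([(0, 100)], tid="t")])
        kept = f05_repeat_content(a, track((0, 90)), CFG)
        assert kept.n_transcripts == 1  # strict >0.90 removes

    def test_ninety_one_percent_removed(self):
        a = AnnotationSet([make_transcript([(0, 100)], tid="t")])
        assert f05_repeat_content(a, track((0, 91)), CFG).n_transcripts == 0

    def test_repeat_fraction_counts_exonic_bases_only(self):
        t = make_transcript([(0, 100), (900, 1000)])
        assert repeat_fraction(t, track((50, 950))) == pytest.approx(0.5)

    def test_length_boundary_is_exonic_not_span(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 200)], tid="exact"),
                make_transcript([(0, 199)], tid="short"),
                make_transcript([(0, 75), (4_925, 5_000)], tid="spliced_short"),
            ]
        )
        kept = f06_min_length(a, CFG)
        assert kept.transcript_ids() == ["exact"]


class TestContaminationFilter:
    REF = AnnotationSet([make_transcript([(10_000, 11_000)], tid="ref", gid="rg")])

    def _fractions(self, tid, values):
        return pd.DataFrame(
            {f"s{i}": [v] for i, v in enumerate(values)}, index=[tid]
        )

    def test_spliced_transcript_untouched(self):
        a = AnnotationSet([make_transcript([(0, 100), (200, 300)], tid="t")])
        kept = f07_dna_contamination(a, self.REF, self._fractions("t", [0.1]))
        assert kept.n_transcripts == 1

    def test_one_good_sample_suffices(self):
        a = AnnotationSet([make_transcript([(0, 500)], tid="t")])
        kept = f07_dna_contamination(a, self.REF, self._fractions("t", [0.79, 0.81]))
        assert kept.n_transcripts == 1

    def test_poor_strandedness_everywhere_drops(self):
        a = AnnotationSet([make_transcript([(0, 500)], tid="t")])
        kept = f07_dna_contamination(a, self.REF, self._fractions("t", [0.5, 0.79]))
        assert kept.n_transcripts == 0

    def test_genic_monoexonic_untouched(self):
        # overlaps the reference gene span, so not intergenic
        a = AnnotationSet([make_transcript([(10_500, 10_900)], tid="t")])
        kept = f07_dna_contamination(a, self.REF, self._fractions("t", [0.1]))
        assert kept.n_transcripts == 1


class TestAnnotatedFilter:
    def test_exact_copy_removed_antisense_kept(self):
        ref = AnnotationSet([make_transcript([(0, 500)], tid="r", strand="+")])
        a = AnnotationSet(
            [
                make_transcript([(0, 500)], tid="copy", strand="+"),
                make_transcript([(0, 500)], tid="anti", strand="-"),
            ]
        )
        kept = f08_drop_annotated(a, ref, CFG)
        assert kept.transcript_ids() == ["anti"]

    def test_boundary_at_99_percent(self):
        ref = AnnotationSet([make_transcript([(0, 980)], tid="r")])
        a = AnnotationSet([make_transcript([(0, 1000)], tid="t")])  # 98% covered
        assert f08_drop_annotated(a, ref, CFG).n_transcripts == 1
        ref2 = AnnotationSet([make_transcript([(0, 990)], tid="r")])  # exactly 99%
        assert f08_drop_annotated(a, ref2, CFG).n_transcripts == 0


class TestDegradationFilter:
    # host gene with a big intron [1000, 9000)
    REF = AnnotationSet(
        [make_transcript([(500, 1_000), (9_000, 9_500)], tid="host", gid="hg")]
    )

    def test_cage_supported_intronic_kept(self):
        a = AnnotationSet([make_transcript([(4_000, 4_400)], tid="t")])
        cage = IntervalTrack([GenomicInterval("chr1", 3_950, 3_960, "+")])
        kept = f09_degradation_products(a, self.REF, cage, EMPTY, CFG)
        assert kept.n_transcripts == 1

    def test_enhancer_supported_intronic_kept(self):
        a = AnnotationSet([make_transcript([(4_000, 4_400)], tid="t")])
        enhancers = track((3_980, 4_420))  # reciprocal overlap ~0.9
        kept = f09_degradation_products(a, self.REF, EMPTY, enhancers, CFG)
        assert kept.n_transcripts == 1

    def test_unsupported_sense_intronic_removed(self):
        a = AnnotationSet([make_transcript([(4_000, 4_400)], tid="t")])
        assert (
            f09_degradation_products(a, self.REF, EMPTY, EMPTY, CFG).n_transcripts == 0
        )

    def test_antisense_intronic_untouched(self):
        a = AnnotationSet([make_transcript([(4_000, 4_400)], tid="t", strand="-")])
        assert (
            f09_degradation_products(a, self.REF, EMPTY, EMPTY, CFG).n_transcripts == 1
        )

    def test_opposite_strand_cage_does_not_support(self):
        a = AnnotationSet([make_transcript([(4_000, 4_400)], tid="t")])
        cage = IntervalTrack([GenomicInterval("chr1", 3_950, 3_960, "-")])
        assert (
            f09_degradation_products(a, self.REF, cage, EMPTY, CFG).n_transcripts == 0
        )


class TestRedundancyCollapse:
    def test_identical_isoforms_keep_one(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 1_000)], tid="a", gid="g"),
                make_transcript([(0, 1_000)], tid="b", gid="g"),
            ]
        )
        assert f11_collapse_redundant(a, CFG).transcript_ids() == ["a"]

    def test_boundary_similarity_both_kept(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 1_000)], tid="a", gid="g"),
                make_transcript([(20, 1_000)], tid="b", gid="g"),  # J = 0.98
            ]
        )
        assert f11_collapse_redundant(a, CFG).n_transcripts == 2

    def test_longer_isoform_survives(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 1_000)], tid="short", gid="g"),
                make_transcript([(0, 1_010)], tid="long", gid="g"),  # J ≈ 0.990
            ]
        )
        assert f11_collapse_redundant(a, CFG).transcript_ids() == ["long"]

    def test_different_genes_never_collapse(self):
        a = AnnotationSet(
            [
                make_transcript([(0, 1_000)], tid="a", gid="g1"),
                make_transcript([(0, 1_000)], tid="b", gid="g2"),
            ]
        )
        assert f11_collapse_redundant(a, CFG).n_transcripts == 2


class TestFullPipeline:
    def test_planted_truth_recovered_exactly(self, bundle, hq_result):
        hq, report = hq_result
        assert set(hq.transcript_ids()) == set(bundle.expected_kept_ids())

    def test_per_step_removals_match_planted_categories(self, bundle, hq_result):
        _, report = hq_result
        truth = bundle.truth
        planted = truth[truth.fate != "kept"]
        expected = (
            planted.fate.str.split(":").str[1].value_counts().to_dict()
        )
        for step in report.steps[1:]:
            assert step.removed == expected.get(step.name, 0), step.name

    def test_transcript_counts_monotone(self, hq_result):
        _, report = hq_result
        counts = [s.transcripts for s in report.steps]
        assert counts == sorted(counts, reverse=True)

    def test_pipeline_idempotent_on_its_output(self, bundle, thresholds, hq_result):
        hq, _ = hq_result
        cfg = bundle.pipeline_config(thresholds)
        again, _ = run_pipeline(hq, bundle.pipeline_inputs(), cfg)
        assert set(again.transcript_ids()) == set(hq.transcript_ids())

    @pytest.mark.parametrize("ablated", DEFAULT_FILTER_ORDER)
    def test_ablating_one_filter_releases_exactly_its_category(
        self, bundle, thresholds, ablated
    ):
        cfg = bundle.pipeline_config(thresholds)
        order = tuple(s for s in DEFAULT_FILTER_ORDER if s != ablated)
        hq, _ = run_pipeline(bundle.assembly, bundle.pipeline_inputs(), cfg, order)
        truth = bundle.truth.set_index("transcript_id")
        expected = set(
            truth.index[(truth.fate == "kept") | truth.fate.str.endswith(ablated)]
        )
        assert set(hq.transcript_ids()) == expected

    def test_unknown_step_name_rejected(self, bundle, thresholds):
        cfg = bundle.pipeline_config(thresholds)
        with pytest.raises(ValueError, match="unknown filter"):
            run_pipeline(
                bundle.assembly, bundle.pipeline_inputs(), cfg, order=("f99_nope",)
            )
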