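from __future__ import annotations

import sys
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from txrefine.annotation_core import AnnotationSet, GenomicInterval, Transcript
from txrefine.hq_filter_pipeline import run_pipeline
from txrefine.synthetic_data import generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study (seed 1)."""
    return generate_bundle(1)


@pytest.fixture(scope="session")
def thresholds(bundle):
    return bundle.fpkm_thresholds()


@pytest.fixture(scope="session")
def hq_result(bundle, thresholds):
    """(HQ AnnotationSet, FilterReport) of the full pipeline on the bundle."""
    cfg = bundle.pipeline_config(thresholds)
    return run_pipeline(bundle.assembly, bundle.pipeline_inputs(), cfg)


def make_transcript(
    blocks: List[Tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    tid: str = "t1",
    gid: Optional[str] = None,
) -> Transcript:
    return Transcript(
        transcript_id=tid,
        gene_id=gid or f"g_{tid}",
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
    )


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    chrom: str = "chr1",
    strand: Optional[str] = None,
    max_span: int = 50_000,
    gid: Optional[str] = None,
) -> Transcript:
    """A random multi-block transcript with span below ``max_span``."""
    n_exons = int(rng.integers(1, 6))
    start = int(rng.integers(0, max_span // 2))
    blocks = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(50, 2_000))
        blocks.append((pos, pos + length))
        pos += length + int(rng.integers(50, 3_000))
        if pos >= max_span:
            break
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return make_transcript(blocks, strand=strand, chrom=chrom, tid=tid, gid=gid)
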