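"""CAGE-based validation of novel transcription start sites.

Transcript 5' ends are reduced to a nonredundant TSS set (single-linkage
clusters within 50 nt on the same strand, represented by the highest-FPKM
isoform; TSSs within 400 nt of an annotated reference TSS on the same
strand are excluded). A TSS counts as CAGE-supported when a same-strand
CAGE peak lies within 200 nt. Significance of the observed support is
assessed against a null in which the TSSs are uniformly re-placed across
an allowed genomic space (gaps/unplaced/mitochondrial regions excluded by
construction of that space), with the add-one empirical p-value
``(1 + #null >= observed) / (n + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation_core import AnnotationSet, IntervalTrack

TSS = Tuple[str, int, str]  # (chrom, position, strand)


@dataclass(frozen=True)
class ShuffleResult:
    observed: int
    null_counts: np.ndarray
    p_value: float


def transcript_tss(t) -> TSS:
    return (t.chrom, t.five_prime, t.strand)


def _single_linkage_clusters(
    positions: Sequence[Tuple[int, str]], cluster_dist: int
) -> List[List[int]]:
    """Indices of single-linkage clusters of sorted (pos, id) pairs."""
    order = sorted(range(len(positions)), key=lambda i: positions[i][0])
    clusters: List[List[int]] = []
    for idx in order:
        if (
            clusters
            and positions[idx][0] - positions[clusters[-1][-1]][0] <= cluster_dist
        ):
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def select_nonredundant_tss(
    hq: AnnotationSet,
    fpkm: pd.DataFrame,
    reference: AnnotationSet,
    cluster_dist: int = 50,
    ref_exclusion: int = 400,
) -> List[TSS]:
    """Nonredundant novel TSS set.

    5' ends on the same chromosome and strand within ``cluster_dist`` nt of
    each other (single linkage) form one cluster represented by its
    highest-FPKM member (max across samples; ties by transcript id). TSSs
    within ``ref_exclusion`` nt (inclusive) of any same-strand reference TSS
    are then removed.
    """
    per_transcript_fpkm = fpkm.max(axis=1)
    groups: Dict[Tuple[str, str], List[Tuple[int, str]]] = {}
    for t in hq:
        groups.setdefault((t.chrom, t.strand), []).append(
            (t.five_prime, t.transcript_id)
        )

    ref_tss: Dict[Tuple[str, str], List[int]] = {}
    for t in reference:
        ref_tss.setdefault((t.chrom, t.strand), []).append(t.five_prime)

    selected: List[TSS] = []
    for (chrom, strand), members in sorted(groups.items()):
        for cluster in _single_linkage_clusters(members, cluster_dist):
            best = min(
                cluster,
                key=lambda i: (-float(per_transcript_fpkm.get(members[i][1], 0.0)), members[i][1]),
            )
            pos = members[best][0]
            near_ref = any(
                abs(pos - rp) <= ref_exclusion for rp in ref_tss.get((chrom, strand), ())
            )
            if not near_ref:
                selected.append((chrom, pos, strand))
    return selected


class _SupportIndex:
    """Merged per-(chrom, strand) windows within which a TSS counts as supported."""

    def __init__(self, cage: IntervalTrack, window: int) -> None:
        raw: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for peak in cage:
            raw.setdefault((peak.chrom, peak.strand), []).append(
                (peak.start - window, peak.end + window)
            )
        self._merged: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
        for key, spans in raw.items():
            spans.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            self._merged[key] = (starts, ends)

    def supported(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        entry = self._merged.get((chrom, strand))
        if entry is None:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = entry
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        ok[ok] &= positions[ok] < ends[idx[ok]]
        return ok


def is_supported(tss: TSS, cage: IntervalTrack, window: int = 200) -> bool:
    chrom, pos, strand = tss
    # distance 0 when the position falls inside the peak
    index = _SupportIndex(cage, window)
    return bool(index.supported(chrom, strand, np.array([pos]))[0])


def cage_support_count(
    tss: Sequence[TSS], cage: IntervalTrack, window: int = 200
) -> int:
    """Number of TSSs with a same-strand CAGE peak within ``window`` nt."""
    index = _SupportIndex(cage, window)
    return int(
        sum(
            index.supported(chrom, strand, np.array([pos]))[0]
            for chrom, pos, strand in tss
        )
    )


def shuffle_test(
    tss: Sequence[TSS],
    cage: IntervalTrack,
    genome_spaces: IntervalTrack,
    n: int = 1000,
    seed: int = 0,
    window: int = 200,
) -> ShuffleResult:
    """Permutation test of CAGE support against uniform re-placement.

    Each of ``n`` replicates re-places every TSS uniformly at random within
    the allowed genomic space (strand preserved; placement is not confined
    to the original chromosome). The empirical p-value uses the add-one
    convention and therefore never reaches 0.
    """
    spaces = sorted(genome_spaces, key=lambda f: (f.chrom, f.start))
    lengths = np.array([f.length for f in spaces], dtype=np.int64)
    total = int(lengths.sum())
    if total < len(tss):
        raise ValueError("allowed genomic space smaller than the TSS set")
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    observed = cage_support_count(tss, cage, window)
    rng = np.random.default_rng(seed)
    index = _SupportIndex(cage, window)
    strands = np.array([s for (_, _, s) in tss])
    space_chroms = np.array([f.chrom for f in spaces])
    space_starts = np.array([f.start for f in spaces], dtype=np.int64)

    draws = rng.integers(0, total, size=(n, len(tss)))
    space_idx = np.searchsorted(offsets, draws, side="right") - 1
    positions = space_starts[space_idx] + (draws - offsets[space_idx])
    supported = np.zeros(draws.shape, dtype=bool)
    for chrom in np.unique(space_chroms):
        for strand in np.unique(strands):
            mask = (space_chroms[space_idx] == chrom) & (strands == strand)[None, :]
            if mask.any():
                supported[mask] = index.supported(chrom, strand, positions[mask])
    null_counts = supported.sum(axis=1).astype(np.int64)
    exceed = int((null_counts >= observed).sum())
    p = (1 + exceed) / (n + 1)
    return ShuffleResult(observed=observed, null_counts=null_counts, p_value=p)
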