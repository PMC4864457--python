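"""Conservation scoring and anchored/scaled signal profiling.

Transcript-level conservation: the scores of conserved elements are
weighted by the number of exonic bases they overlap and the total is
normalized by exonic length. Metagene-style views come in two flavours:
anchored per-base profiles around a set of stranded positions (e.g. exon
ends or gene starts), and scaled heatmap matrices where each feature body
is stretched to a fixed number of bins with flanking regions kept at
single-base resolution, grouped by k-means. Missing signal is scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .annotation_core import (
    STRAND_MINUS,
    GenomicInterval,
    IntervalTrack,
    SignalTrack,
    Transcript,
    _intersection_size,
    merge_blocks,
)


@dataclass
class ProfileMatrix:
    """Rows = features, columns = fixed-width bins of signal means."""

    values: np.ndarray  # (n_features, n_bins)
    bin_size: int
    flank: int
    body_bins: int  # 0 for purely anchored profiles
    row_ids: List[str]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def transcript_conservation_score(t: Transcript, elements: IntervalTrack) -> float:
    """Sum over elements of score x overlapping exonic bases, / exonic length."""
    total = 0.0
    for el in elements.overlapping(t.chrom, t.start, t.end):
        if el.score is None:
            raise ValueError("conserved element lacks a score")
        bases = _intersection_size(t.exon_blocks(), [(el.start, el.end)])
        total += el.score * bases
    return total / t.exonic_length


# ---------------------------------------------------------------------------
# Anchored per-base profiles
# ---------------------------------------------------------------------------


def _window_values(
    signal: SignalTrack, chrom: str, start: int, end: int, flip: bool
) -> np.ndarray:
    vals = np.asarray(signal.values(chrom, start, end), dtype=float)
    return vals[::-1] if flip else vals


def _bin_means(vals: np.ndarray, bin_size: int) -> np.ndarray:
    return vals.reshape(-1, bin_size).mean(axis=1)


def anchored_profile(
    anchors: Sequence[Tuple[str, int, str]],
    signal: SignalTrack,
    bin_size: int = 1,
    flank: int = 500,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of signal per bin around stranded anchors.

    Each anchor ``(chrom, position, strand)`` contributes the window
    ``[position - flank, position + flank)``; minus-strand windows are
    flipped so the downstream direction is always transcription direction.
    Missing signal scores 0. Returns ``(means, stderrs)`` of length
    ``2 * flank / bin_size``. Standard error is the sample (n-1) convention,
    0 for a single anchor.
    """
    if flank % bin_size != 0:
        raise ValueError("bin_size must divide flank")
    rows = []
    for chrom, pos, strand in anchors:
        vals = _window_values(
            signal, chrom, pos - flank, pos + flank, flip=strand == STRAND_MINUS
        )
        rows.append(_bin_means(vals, bin_size))
    matrix = np.vstack(rows)
    means = matrix.mean(axis=0)
    if matrix.shape[0] > 1:
        stderr = matrix.std(axis=0, ddof=1) / np.sqrt(matrix.shape[0])
    else:
        stderr = np.zeros_like(means)
    return means, stderr


# ---------------------------------------------------------------------------
# Scaled (stretch-to-fit) heatmap matrices
# ---------------------------------------------------------------------------


def merge_overlapping_features(features: IntervalTrack) -> List[GenomicInterval]:
    """Collapse overlapping features to their leftmost/rightmost positions.

    Strand-aware: only same-strand features merge; avoids double counting
    when the same region enters the profile through several features.
    """
    by_key: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for f in features:
        by_key.setdefault((f.chrom, f.strand), []).append((f.start, f.end))
    merged: List[GenomicInterval] = []
    for (chrom, strand), blocks in sorted(by_key.items()):
        for start, end in merge_blocks(blocks):
            merged.append(GenomicInterval(chrom, start, end, strand))
    return merged


def _scaled_row(
    feature: GenomicInterval, signal: SignalTrack, flank: int, body_bins: int
) -> np.ndarray:
    flip = feature.strand == STRAND_MINUS
    up = _window_values(signal, feature.chrom, feature.start - flank, feature.start, flip=False)
    body_vals = np.asarray(
        signal.values(feature.chrom, feature.start, feature.end), dtype=float
    )
    down = _window_values(signal, feature.chrom, feature.end, feature.end + flank, flip=False)
    # Coordinate stretching: body bin j averages the bases mapping into
    # [j*L/B, (j+1)*L/B); short features spread each base over several bins.
    length = len(body_vals)
    edges = np.linspace(0, length, body_bins + 1)
    body = np.empty(body_bins)
    for j in range(body_bins):
        lo, hi = edges[j], edges[j + 1]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        weights = np.clip(np.minimum(np.arange(i0, i1) + 1, hi) - np.maximum(np.arange(i0, i1), lo), 0, None)
        body[j] = float(np.average(body_vals[i0:i1], weights=weights)) if weights.sum() else 0.0
    row = np.concatenate([up, body, down])
    return row[::-1] if flip else row


def scaled_heatmap(
    features: IntervalTrack,
    signal: SignalTrack,
    flank: int = 500,
    body_bins: int = 1000,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> Tuple[ProfileMatrix, np.ndarray, np.ndarray]:
    """Stretch-to-fit profile matrix with k-means grouping.

    Overlapping input features are first collapsed to their extreme
    positions. Each feature body is rescaled to ``body_bins`` bins flanked by
    ``flank`` single-base bins either side. k-means (fixed seed, ``n_init``
    restarts) runs on the raw row vectors — any display clipping is a
    rendering concern and never touches the clustering input. Returns the
    matrix, per-row cluster labels, and the row order sorting rows by
    descending row mean.
    """
    merged = merge_overlapping_features(features)
    if not merged:
        raise ValueError("no features to profile")
    if k > len(merged):
        raise ValueError(f"k={k} exceeds feature count {len(merged)}")
    rows = np.vstack([_scaled_row(f, signal, flank, body_bins) for f in merged])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(rows)
    order = np.argsort(-rows.mean(axis=1), kind="stable")
    matrix = ProfileMatrix(
        values=rows,
        bin_size=1,
        flank=flank,
        body_bins=body_bins,
        row_ids=[f"{f.chrom}:{f.start}-{f.end}({f.strand})" for f in merged],
    )
    return matrix, labels, order


def clip_for_display(
    matrix: ProfileMatrix, lo: float = 0.5, hi: float = 2.0
) -> np.ndarray:
    """Render-side saturation of the colour scale; never feeds clustering."""
    return np.clip(matrix.values, lo, hi)


# ---------------------------------------------------------------------------
# Exon coding labels
# ---------------------------------------------------------------------------


def label_exon_coding(
    exon_spliced_span: Tuple[int, int],
    orf_span: Tuple[int, int],
    coding_threshold: float = 0.70,
    noncoding_threshold: float = 0.20,
) -> str:
    """Label an exon by its ORF coverage on the spliced transcript.

    Both spans are half-open coordinates on the same spliced sequence.
    Coverage > coding_threshold -> "coding"; < noncoding_threshold ->
    "noncoding"; the band in between -> "unlabeled".
    """
    e0, e1 = exon_spliced_span
    if e1 <= e0:
        raise ValueError("empty exon span")
    overlap = max(0, min(e1, orf_span[1]) - max(e0, orf_span[0]))
    coverage = overlap / (e1 - e0)
    if coverage > coding_threshold:
        return "coding"
    if coverage < noncoding_threshold:
        return "noncoding"
    return "unlabeled"


# ---------------------------------------------------------------------------
# Tissue-resolved anchored support profiles
# ---------------------------------------------------------------------------


def tissue_support_profiles(
    anchors: Mapping[str, Tuple[str, int, str]],
    fpkm: pd.DataFrame,  # genes x tissues
    signals: Mapping[str, SignalTrack],  # tissue -> track
    expressed_cutoff: float = 5.0,
    bin_size: int = 10,
    flank: int = 1000,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], np.ndarray]:
    """Three views of per-tissue signal support around gene-start anchors.

    A: per-tissue mean profile over all genes. B: per-tissue mean over the
    genes expressed above ``expressed_cutoff`` FPKM in that tissue (empty
    subsets yield an all-zero profile). C: a single per-bin median profile
    where each gene contributes only the signal of the tissue in which it is
    most highly expressed.
    """
    gene_ids = list(anchors)
    missing = set(gene_ids) - set(fpkm.index)
    if missing:
        raise ValueError(f"FPKM rows missing for genes: {sorted(missing)}")
    n_bins = 2 * flank // bin_size

    def row(gene: str, tissue: str) -> np.ndarray:
        chrom, pos, strand = anchors[gene]
        vals = _window_values(
            signals[tissue], chrom, pos - flank, pos + flank, flip=strand == STRAND_MINUS
        )
        return _bin_means(vals, bin_size)

    mean_all: Dict[str, np.ndarray] = {}
    mean_expressed: Dict[str, np.ndarray] = {}
    for tissue in signals:
        rows_all = np.vstack([row(g, tissue) for g in gene_ids])
        mean_all[tissue] = rows_all.mean(axis=0)
        expressed = [g for g in gene_ids if fpkm.loc[g, tissue] > expressed_cutoff]
        if expressed:
            mean_expressed[tissue] = np.vstack(
                [row(g, tissue) for g in expressed]
            ).mean(axis=0)
        else:
            mean_expressed[tissue] = np.zeros(n_bins)

    argmax_rows = []
    for g in gene_ids:
        best_tissue = fpkm.loc[g, list(signals)].astype(float).idxmax()
        argmax_rows.append(row(g, best_tissue))
    median_best = np.median(np.vstack(argmax_rows), axis=0)
    return mean_all, mean_expressed, median_best
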