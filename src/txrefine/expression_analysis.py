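"""Brain-enrichment selection and count normalization.

A gene is brain-enriched when the log2 ratio of its median FPKM across
brain samples (Mb) to its median across non-brain samples (Ma) exceeds a
cutoff (default 2, i.e. a >4-fold median increase). Genes with both medians
below a floor (default 2 FPKM) are excluded before the ratio test, so a
weakly expressed gene never qualifies on ratio alone. For sensitivity
comparisons on raw counts, cells are normalized as ln((count + 1) / total
mapped reads).
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

GROUP_BRAIN = "brain"
GROUP_NONBRAIN = "nonbrain"


def group_medians(
    expr: pd.DataFrame, groups: Mapping[str, str]
) -> Tuple[pd.Series, pd.Series]:
    """(median over brain samples, median over non-brain samples) per gene."""
    brain = [s for s in expr.columns if groups.get(s) == GROUP_BRAIN]
    nonbrain = [s for s in expr.columns if groups.get(s) == GROUP_NONBRAIN]
    if not brain or not nonbrain:
        raise ValueError("both brain and nonbrain groups must be non-empty")
    return expr[brain].median(axis=1), expr[nonbrain].median(axis=1)


def brain_enrichment(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    log2_cutoff: float = 2.0,
    floor: float = 2.0,
) -> List[str]:
    """Genes whose brain/non-brain median FPKM log2 ratio exceeds the cutoff.

    Genes with both medians below ``floor`` are excluded from consideration
    first. A non-brain median of exactly 0 with a considered gene counts as
    an infinite ratio, hence enriched.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    mb, ma = group_medians(expr, groups)
    enriched: List[str] = []
    for gene in expr.index:
        b, a = float(mb[gene]), float(ma[gene])
        if b < floor and a < floor:
            continue
        if a == 0.0:
            enriched.append(gene)
        elif b > 0 and math.log2(b / a) > log2_cutoff:
            enriched.append(gene)
    return enriched


def normalize_counts(
    counts: pd.DataFrame, totals: Mapping[str, float]
) -> pd.DataFrame:
    """ln((count + 1) / per-sample total mapped reads), cellwise."""
    missing = set(counts.columns) - set(totals)
    if missing:
        raise ValueError(f"no mapped-read total for samples: {sorted(missing)}")
    out = counts.astype(float).copy()
    for sample in counts.columns:
        total = float(totals[sample])
        if total <= 0:
            raise ValueError(f"total for sample {sample} must be > 0")
        out[sample] = np.log((counts[sample].astype(float) + 1.0) / total)
    return out


def read_group_table(path) -> Dict[str, str]:
    """Two-column TSV sample -> group (brain | nonbrain)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    bad = set(df["group"]) - {GROUP_BRAIN, GROUP_NONBRAIN}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return dict(zip(df["sample"].astype(str), df["group"]))
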