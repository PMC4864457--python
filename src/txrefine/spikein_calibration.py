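"""Detection-limit calibration from RNA spike-in controls.

Synthetic spike-in RNAs of known concentration (amol/µL) are sequenced
alongside each sample. Transcript models assembled from less than eightfold
read coverage are unreliable, so for each sample we estimate (i) the spike-in
concentration at which mean coverage reaches a target fold (default 8×), via
a degree-2 polynomial fit in log2–log2 space, and (ii) the FPKM a transcript
at that concentration would show, via a degree-3 polynomial fit of
log2(FPKM) on log2(concentration). The resulting per-sample FPKM value is
the expression floor used by the filtering pipeline.

Concentrations also convert directly to absolute molecule counts
(via Avogadro's number) and to per-cell copy numbers given tissue RNA yield
and cellularity, which is how a detection limit of 0.02 amol/µL in 24 µL of
liver library corresponds to roughly one RNA copy per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

AVOGADRO = 6.022e23  # molecules per mol; matches the printed arithmetic
DEFAULT_READ_LENGTH = 102  # nt, 2 x 102 bp paired-end chemistry
DEFAULT_TARGET_COVERAGE = 8.0


class CalibrationError(ValueError):
    """Raised when a detection limit cannot be derived from the readings."""


class InsufficientDataError(CalibrationError):
    """Raised when too few usable spike-in records are available for a fit."""


@dataclass(frozen=True)
class SpikeInRecord:
    """One spike-in species in one sample."""

    id: str
    concentration: float  # amol/µL, known input concentration
    length: int  # nt
    read_count: int
    fpkm: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("spike-in concentration must be > 0")
        if self.length <= 0:
            raise ValueError("spike-in length must be > 0")
        if self.read_count < 0 or self.fpkm < 0:
            raise ValueError("read_count and fpkm must be non-negative")


@dataclass(frozen=True)
class CalibrationResult:
    threshold_concentration: float  # amol/µL at target coverage
    threshold_fpkm: float  # fitted FPKM at that concentration
    coverage_fit: Tuple[float, ...]  # degree-2 coefficients, highest first
    fpkm_fit: Tuple[float, ...]  # degree-3 coefficients, highest first
    extrapolated: bool  # root fell outside the observed concentration range


def mean_coverage(record: SpikeInRecord, read_length: int = DEFAULT_READ_LENGTH) -> float:
    """Fold coverage: read_count × read_length / species length."""
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    return record.read_count * read_length / record.length


def fit_threshold_concentration(
    records: Sequence[SpikeInRecord],
    read_length: int = DEFAULT_READ_LENGTH,
    target_coverage: float = DEFAULT_TARGET_COVERAGE,
) -> Tuple[float, Tuple[float, ...], bool]:
    """Concentration (amol/µL) at which fitted coverage reaches the target.

    Fits log2(coverage) = p(log2(concentration)) with a degree-2 least-squares
    polynomial over records with nonzero coverage, then solves
    p(x) = log2(target_coverage). The smallest real root inside the observed
    concentration range is returned; if every real root lies outside, the
    nearest one is returned with ``extrapolated=True``.

    Returns ``(threshold_concentration, coefficients, extrapolated)``.
    """
    usable = [r for r in records if mean_coverage(r, read_length) > 0]
    if len({r.concentration for r in usable}) < 4:
        raise InsufficientDataError(
            "need >=4 spike-ins with distinct concentrations and nonzero coverage"
        )
    x = np.log2([r.concentration for r in usable])
    y = np.log2([mean_coverage(r, read_length) for r in usable])
    coeffs = np.polyfit(x, y, deg=2)
    shifted = coeffs.copy()
    shifted[-1] -= np.log2(target_coverage)
    roots = np.roots(shifted)
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    if not real:
        raise CalibrationError(
            "coverage fit never reaches the target coverage (no real root)"
        )
    lo, hi = float(x.min()), float(x.max())
    inside = sorted(r for r in real if lo <= r <= hi)
    if inside:
        root = inside[0]
        extrapolated = False
    else:
        root = min(real, key=lambda r: min(abs(r - lo), abs(r - hi)))
        extrapolated = True
    return float(2.0**root), tuple(float(c) for c in coeffs), extrapolated


def fit_threshold_fpkm(
    records: Sequence[SpikeInRecord], threshold_concentration: float
) -> Tuple[float, Tuple[float, ...]]:
    """Fitted FPKM at the threshold concentration (linear FPKM scale).

    Degree-3 least-squares fit of log2(FPKM) on log2(concentration) over
    records with FPKM > 0, evaluated at log2(threshold_concentration).
    """
    usable = [r for r in records if r.fpkm > 0]
    if len(usable) < 5:
        raise InsufficientDataError("need >=5 spike-ins with FPKM > 0")
    x = np.log2([r.concentration for r in usable])
    y = np.log2([r.fpkm for r in usable])
    coeffs = np.polyfit(x, y, deg=3)
    value = np.polyval(coeffs, np.log2(threshold_concentration))
    return float(2.0**value), tuple(float(c) for c in coeffs)


def calibrate_sample(
    records: Sequence[SpikeInRecord],
    read_length: int = DEFAULT_READ_LENGTH,
    target_coverage: float = DEFAULT_TARGET_COVERAGE,
) -> CalibrationResult:
    """Full per-sample calibration: detection-limit concentration and FPKM floor."""
    conc, cov_fit, extrapolated = fit_threshold_concentration(
        records, read_length, target_coverage
    )
    fpkm, fpkm_fit = fit_threshold_fpkm(records, conc)
    return CalibrationResult(
        threshold_concentration=conc,
        threshold_fpkm=fpkm,
        coverage_fit=cov_fit,
        fpkm_fit=fpkm_fit,
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# Copy-number arithmetic
# ---------------------------------------------------------------------------


def molecules_at(concentration: float, volume: float) -> float:
    """Absolute molecule count in `volume` µL at `concentration` amol/µL."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return concentration * volume * 1e-18 * AVOGADRO


def cells_from_tissue(rna_mass: float, yield_per_mg: float, cellularity: float) -> float:
    """Cell count behind an RNA input.

    rna_mass in µg, yield_per_mg in µg RNA per mg tissue, cellularity in
    cells per g tissue. The mass of source tissue is rna_mass / yield_per_mg
    (mg), converted to g before applying cellularity.
    """
    if rna_mass <= 0 or yield_per_mg <= 0 or cellularity <= 0:
        raise ValueError("all inputs must be > 0")
    tissue_mg = rna_mass / yield_per_mg
    return tissue_mg * 1e-3 * cellularity


def copies_per_cell(molecules: float, cells: float) -> float:
    if cells <= 0:
        raise ValueError("cells must be > 0")
    return molecules / cells


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

SPIKEIN_COLUMNS = ["id", "concentration_amol_per_ul", "length_nt", "read_count", "fpkm"]


def read_spikein_table(path) -> List[SpikeInRecord]:
    """Read a per-sample tab-separated spike-in table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SPIKEIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spike-in table missing columns: {sorted(missing)}")
    return [
        SpikeInRecord(
            id=str(row.id),
            concentration=float(row.concentration_amol_per_ul),
            length=int(row.length_nt),
            read_count=int(row.read_count),
            fpkm=float(row.fpkm),
        )
        for row in df.itertuples()
    ]


def write_spikein_table(records: Sequence[SpikeInRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "concentration_amol_per_ul": [r.concentration for r in records],
            "length_nt": [r.length for r in records],
            "read_count": [r.read_count for r in records],
            "fpkm": [r.fpkm for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
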