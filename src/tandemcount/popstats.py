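"""Population summaries and array-instability statistics.

Aggregates per-read unit counts into population summaries (mean, histogram)
and implements the downstream arithmetic used to quantify array instability:
cell divisions from OD600 change, the variation index (percent copy-number
change per division), qPCR-derived copy number calibrated against nanopore
counts, and marker-loss (5-FOA resistance) frequency.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .ftcount import CopyCount


@dataclass
class PopulationSummary:
    per_read_counts: list[int]
    n_spanning: int
    mean_copies: float
    histogram: dict[int, int]
    flags: tuple[str, ...] = ()


@dataclass
class VIRecord:
    """Variation index: percent copy-number change per cell division.

    Positive VI means contraction (copy number decreased), matching the sign
    convention under which destabilized strains show larger positive values.
    """

    c_start: float
    c_end: float
    divisions: float
    vi: float


@dataclass(frozen=True)
class QpcrMeasurement:
    """Relative quantities from qPCR, normalized to a single-copy gene (ACT1).

    ``calibration`` converts the target/ACT1 quantity ratio into copies; it is
    anchored so that a reference sample returns its nanopore-determined copy
    number.
    """

    target_quantity: float
    act1_quantity: float
    calibration: float

    def __post_init__(self) -> None:
        if self.target_quantity <= 0 or self.act1_quantity <= 0:
            raise ValueError("qPCR quantities must be > 0")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")


@dataclass(frozen=True)
class FoaAssay:
    """Colony counts from a 5-FOA marker-loss plating assay.

    ``dilution`` is the factor by which plated CFU are multiplied to recover
    the per-culture count (e.g. 1e4 for a 10^-4 dilution plated).
    """

    resistant_cfu: int
    resistant_dilution: float
    total_cfu: int
    total_dilution: float

    def __post_init__(self) -> None:
        if self.resistant_cfu < 0 or self.total_cfu < 0:
            raise ValueError("CFU counts must be >= 0")
        if self.resistant_dilution <= 0 or self.total_dilution <= 0:
            raise ValueError("dilutions must be > 0")


@dataclass
class LossFrequency:
    frequency: float
    control_frequency: float
    fold: float
    flags: tuple[str, ...] = ()


def summarize_population(
    counts: Sequence[Union[int, CopyCount]],
) -> PopulationSummary:
    """Mean and histogram of per-read unit counts (spanning reads only)."""
    values = [c.count if isinstance(c, CopyCount) else int(c) for c in counts]
    if not values:
        return PopulationSummary([], 0, math.nan, {}, flags=("empty",))
    histogram = dict(sorted(Counter(values).items()))
    return PopulationSummary(
        per_read_counts=values,
        n_spanning=len(values),
        mean_copies=float(np.mean(values)),
        histogram=histogram,
    )


def divisions_from_od(od_series: Sequence[tuple[float, float]]) -> float:
    """Total cell divisions from daily OD600 growth.

    Each day contributes log2(od_end / od_start_after_dilution); the total is
    the sum over days.
    """
    total = 0.0
    for od_start, od_end in od_series:
        if od_start <= 0 or od_end <= 0:
            raise ValueError("OD600 values must be > 0")
        total += math.log2(od_end / od_start)
    return total


def variation_index(c_start: float, c_end: float, divisions: float) -> VIRecord:
    """VI = 100 * (c_start - c_end) / c_start / divisions (% per division)."""
    if c_start <= 0:
        raise ValueError("c_start must be > 0")
    if divisions <= 0:
        raise ValueError("divisions must be > 0")
    vi = 100.0 * (c_start - c_end) / c_start / divisions
    return VIRecord(c_start=c_start, c_end=c_end, divisions=divisions, vi=vi)


def qpcr_copy_number(meas: QpcrMeasurement) -> float:
    """Copies = (target quantity / ACT1 quantity) x calibration."""
    return meas.target_quantity / meas.act1_quantity * meas.calibration


def marker_loss_frequency(assay: FoaAssay, control: FoaAssay) -> LossFrequency:
    """Frequency of marker loss and its fold change over a control strain."""
    if assay.total_cfu == 0 or control.total_cfu == 0:
        raise ValueError("total_cfu must be > 0 in both assays")
    freq = (assay.resistant_cfu * assay.resistant_dilution) / (
        assay.total_cfu * assay.total_dilution
    )
    ctrl = (control.resistant_cfu * control.resistant_dilution) / (
        control.total_cfu * control.total_dilution
    )
    if ctrl == 0:
        return LossFrequency(freq, ctrl, math.nan, flags=("control_frequency_zero",))
    return LossFrequency(freq, ctrl, freq / ctrl)


def bootstrap_ci(
    values: Sequence[float],
    stat: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: Optional[int] = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap confidence interval for a statistic."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    stats = np.array([stat(arr[row]) for row in idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
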