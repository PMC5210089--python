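"""ABR threshold extraction from intensity–amplitude growth functions.

The auditory brainstem response threshold at a frequency is the minimum
tone-burst intensity (0–100 dB SPL grid, 5 dB steps) eliciting a
well-defined and reproducible wave.  "Well-defined and reproducible" is
operationalized as: wave amplitude exceeds ``criterion_multiplier × noise
floor`` in *every* replicate at the candidate intensity and at every
higher intensity.  Ears with no such intensity receive the ceiling
sentinel (``inf``, printed as ``>100``).  Band summaries average the
extracted thresholds across frequencies (4–32 kHz by default), excluding
ceiling ears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

CEILING_DB = math.inf  #: sentinel for no response up to 100 dB SPL

_GRID = np.arange(0, 105, 5)


@dataclass
class ABRSeries:
    """Replicated amplitude series at one frequency on the 5 dB grid."""

    frequency_khz: float
    intensities_db: np.ndarray
    amplitudes_uv: np.ndarray  # (n_replicates, n_intensities)
    noise_floor_uv: float = 1.0

    def __post_init__(self) -> None:
        self.intensities_db = np.asarray(self.intensities_db, dtype=float)
        self.amplitudes_uv = np.atleast_2d(np.asarray(self.amplitudes_uv, dtype=float))
        d = np.diff(self.intensities_db)
        if len(self.intensities_db) < 2 or not (d > 0).all():
            raise FormatError("intensities must be strictly increasing")
        if (np.abs(d - 5) > 1e-9).any() or (self.intensities_db % 5 != 0).any():
            raise FormatError("intensities must lie on the 5 dB grid")
        if self.amplitudes_uv.shape[0] < 2:
            raise FormatError("at least 2 replicates required")
        if self.amplitudes_uv.shape[1] != len(self.intensities_db):
            raise FormatError("amplitude columns must match intensities")


@dataclass
class ThresholdResult:
    frequency_khz: float
    threshold_db: float  # grid value or CEILING_DB
    criterion_used: float

    @property
    def is_ceiling(self) -> bool:
        return math.isinf(self.threshold_db)


def series_from_table(table: pd.DataFrame, noise_floor_uv: float = 1.0) -> list[ABRSeries]:
    """Build per-frequency series from a tidy table
    (``frequency_khz,intensity_db,replicate,amplitude_uv``)."""
    required = {"frequency_khz", "intensity_db", "replicate", "amplitude_uv"}
    if not required.issubset(table.columns):
        raise FormatError(f"table must have columns {sorted(required)}")
    out = []
    for f, grp in table.groupby("frequency_khz"):
        wide = grp.pivot_table(
            index="replicate", columns="intensity_db", values="amplitude_uv"
        ).sort_index(axis=1)
        out.append(
            ABRSeries(
                frequency_khz=float(f),
                intensities_db=wide.columns.to_numpy(dtype=float),
                amplitudes_uv=wide.to_numpy(),
                noise_floor_uv=noise_floor_uv,
            )
        )
    return out


def extract_threshold(
    series: ABRSeries, criterion_multiplier: float = 4.0
) -> ThresholdResult:
    """Lowest grid intensity with a reproducible suprathreshold response.

    Threshold = lowest intensity I such that in every replicate the
    amplitude exceeds ``criterion_multiplier × noise_floor`` at I *and* at
    all intensities above I; ``CEILING_DB`` if no intensity qualifies.
    """
    if series.noise_floor_uv <= 0:
        raise ValueError("noise_floor must be positive")
    criterion = criterion_multiplier * series.noise_floor_uv
    passes = (series.amplitudes_uv > criterion).all(axis=0)  # all replicates
    # response must persist at every higher intensity
    sustained = np.logical_and.accumulate(passes[::-1])[::-1]
    idx = np.flatnonzero(sustained)
    thr = float(series.intensities_db[idx[0]]) if idx.size else CEILING_DB
    return ThresholdResult(
        frequency_khz=series.frequency_khz,
        threshold_db=thr,
        criterion_used=criterion,
    )


def mean_threshold(
    results: list[ThresholdResult],
    band_khz: tuple[float, float] = (4.0, 32.0),
) -> tuple[float, int]:
    """Arithmetic mean threshold over a frequency band.

    Ceiling ears are excluded (not imputed); the number excluded is
    returned alongside the mean.  Raises if the band selects no
    measurable threshold.
    """
    lo, hi = band_khz
    in_band = [r for r in results if lo <= r.frequency_khz <= hi]
    if not in_band:
        raise ValueError("no thresholds within the requested band")
    usable = [r.threshold_db for r in in_band if not r.is_ceiling]
    n_ceiling = len(in_band) - len(usable)
    if not usable:
        raise ValueError("all thresholds in band are at ceiling")
    return float(np.mean(usable)), n_ceiling
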