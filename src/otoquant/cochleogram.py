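"""Cytocochleograms and spiral-ganglion neuron densities from count tables.

Hair cells are counted in 300-μm segments of the organ of Corti centered
at fixed distances from the cochlear apex; each position maps to a
characteristic frequency via the printed place–frequency pairs
(1.1 mm → 8 kHz, 2.6 → 16, 3.5 → 25, 4.1 → 32).  Survival is the count
as a percentage of the control count, clipped to [0, 100].  In xenograft
animals the extreme basal segment (4.1 mm) is dropped because massive
basal OHC loss occurs there independent of treatment.

SGN density is neurons per μm² of the 3,600 μm² calibrated ocular grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import SurvivalClipWarning

#: printed place→frequency map (mm from apex → kHz); no interpolation
PLACE_FREQUENCY_MAP_KHZ: dict[float, float] = {1.1: 8.0, 2.6: 16.0, 3.5: 25.0, 4.1: 32.0}

SEGMENT_LENGTH_UM = 300.0
SGN_GRID_AREA_UM2 = 3600.0
XENOGRAFT_EXCLUDED_MM = 4.1


@dataclass
class CochlearSegment:
    center_mm_from_apex: float
    ohc_count: int
    ihc_count: int
    control_ohc: int
    control_ihc: int
    length_um: float = SEGMENT_LENGTH_UM

    @property
    def mapped_frequency_khz(self) -> float:
        return map_position_to_frequency(self.center_mm_from_apex)

    @property
    def ohc_survival_pct(self) -> float:
        return percent_survival(self.ohc_count, self.control_ohc)

    @property
    def ihc_survival_pct(self) -> float:
        return percent_survival(self.ihc_count, self.control_ihc)


@dataclass
class Cytocochleogram:
    subject_id: str
    segments: list[CochlearSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        centers = [s.center_mm_from_apex for s in self.segments]
        if len(set(centers)) != len(centers):
            raise ValueError("segment centers must be unique")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject_id,
                "center_mm": s.center_mm_from_apex,
                "frequency_khz": s.mapped_frequency_khz,
                "ohc_survival_pct": s.ohc_survival_pct,
                "ihc_survival_pct": s.ihc_survival_pct,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


@dataclass
class SGNDensity:
    neuron_count: int
    n_grids: int
    density_per_um2: float
    grid_area_um2: float = SGN_GRID_AREA_UM2


def map_position_to_frequency(center_mm: float) -> float:
    """Exact lookup of the 4-point place–frequency map; no interpolation."""
    for pos, freq in PLACE_FREQUENCY_MAP_KHZ.items():
        if abs(center_mm - pos) < 1e-9:
            return freq
    raise KeyError(
        f"{center_mm} mm is not a mapped position "
        f"(expected one of {sorted(PLACE_FREQUENCY_MAP_KHZ)})"
    )


def percent_survival(count: int, control_count: int) -> float:
    """Surviving cells as % of control, clipped to [0, 100] with a warning."""
    if control_count <= 0:
        raise ValueError("control_count must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    pct = 100.0 * count / control_count
    if pct > 100.0:
        warnings.warn(
            f"count {count} exceeds control {control_count}; clipped to 100%",
            SurvivalClipWarning,
        )
        pct = 100.0
    return pct


def sgn_density(neuron_count: int, n_grids: int = 1) -> SGNDensity:
    """Spiral-ganglion neuron density per μm² of calibrated grid area."""
    if n_grids < 1:
        raise ValueError("n_grids must be >= 1")
    if neuron_count < 0:
        raise ValueError("neuron_count must be non-negative")
    return SGNDensity(
        neuron_count=neuron_count,
        n_grids=n_grids,
        density_per_um2=neuron_count / (n_grids * SGN_GRID_AREA_UM2),
    )


def restrict_segments(cochleogram: Cytocochleogram, xenograft_mode: bool) -> Cytocochleogram:
    """Drop the 4.1-mm segment in xenograft mode; otherwise return unchanged."""
    if not xenograft_mode:
        return cochleogram
    kept = [
        s
        for s in cochleogram.segments
        if abs(s.center_mm_from_apex - XENOGRAFT_EXCLUDED_MM) > 1e-9
    ]
    return Cytocochleogram(subject_id=cochleogram.subject_id, segments=kept)


def build_cytocochleograms(
    counts: pd.DataFrame,
    control_group: str,
    xenograft_mode: bool = False,
) -> list[Cytocochleogram]:
    """Build per-subject cytocochleograms from a tidy count table.

    ``counts`` columns: ``subject, group, center_mm, cell_type, count``
    with ``cell_type`` in {"OHC", "IHC"}.  Control counts are the
    per-position means of ``control_group`` (rounded to the nearest
    integer), the group-mean normalization mode.
    """
    required = {"subject", "group", "center_mm", "cell_type", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    ctrl = counts[counts["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"no rows for control group {control_group!r}")
    ctrl_means = ctrl.groupby(["center_mm", "cell_type"])["count"].mean()

    out = []
    for subject, grp in counts.groupby("subject"):
        segments = []
        for center, seg in grp.groupby("center_mm"):
            by_type = seg.set_index("cell_type")["count"]
            segments.append(
                CochlearSegment(
                    center_mm_from_apex=float(center),
                    ohc_count=int(by_type.get("OHC", 0)),
                    ihc_count=int(by_type.get("IHC", 0)),
                    control_ohc=int(round(ctrl_means.get((center, "OHC"), 0))),
                    control_ihc=int(round(ctrl_means.get((center, "IHC"), 0))),
                )
            )
        segments.sort(key=lambda s: s.center_mm_from_apex)
        cg = Cytocochleogram(subject_id=str(subject), segments=segments)
        out.append(restrict_segments(cg, xenograft_mode))
    return out
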