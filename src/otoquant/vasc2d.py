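"""Tumor vascular-area quantification from CD31-stained 2D fields.

Vessel walls are CD31-positive pixels (fixed or Otsu threshold).  Lumens
are the enclosed interior holes of the wall mask after a morphological
closing that seals wall interruptions up to a closable width (1 μm by
default): interiors reachable from outside through a wider gap are not
lumens.  The per-field readout is

    vascular area % = (CD31 area + lumen area) / field area × 100

with areas from pixel counts × pixel area.  Per-tumor summaries average
the five peripheral fields (mean ± SEM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .errors import GapRuleWarning, MaskSaturationWarning
from .types import VesselField


@dataclass
class VesselSegmentation:
    """Wall and lumen pixel masks for one field."""

    cd31_mask: np.ndarray
    lumen_mask: np.ndarray
    threshold_used: float = math.nan

    def __post_init__(self) -> None:
        if (self.cd31_mask & self.lumen_mask).any():
            raise ValueError("cd31 and lumen masks must be disjoint")


@dataclass
class VascularAreaResult:
    cd31_area_um2: float
    lumen_area_um2: float
    vascular_area_um2: float
    vascular_area_pct: float
    n_fields: int = 1


@dataclass
class TumorVascularSummary:
    mean_pct: float
    sem_pct: float | None
    n_fields: int
    field_pcts: list[float] = field(default_factory=list)


def segment_cd31(
    fld: VesselField,
    channel: str | int = 0,
    threshold_rule: float | str = "otsu",
) -> np.ndarray:
    """Threshold the CD31 channel into a wall-pixel mask.

    ``threshold_rule`` is either a fixed intensity value or ``"otsu"``.
    Warns when the result is empty or covers the whole field.
    """
    img = fld.channel(channel)
    if isinstance(threshold_rule, str):
        if threshold_rule.lower() != "otsu":
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        if np.ptp(img) == 0:
            warnings.warn("blank channel; empty CD31 mask", MaskSaturationWarning)
            return np.zeros(img.shape, dtype=bool)
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold_rule)
    mask = img > thr
    if not mask.any() or mask.all():
        warnings.warn(
            "CD31 mask is empty or saturates the field", MaskSaturationWarning
        )
    return mask


def segment_lumens(
    cd31_mask: np.ndarray,
    pixel_size_um: float,
    max_closable_gap_um: float = 1.0,
) -> np.ndarray:
    """Segment lumen pixels as gap-closed enclosed holes of the wall mask.

    A closing with a disk of diameter ``max_closable_gap_um`` seals wall
    interruptions up to that width, so a vessel with a sub-threshold gap
    still encloses its lumen; interiors open to the outside through a
    wider gap, and regions touching the field border, are excluded.
    """
    cd31_mask = np.asarray(cd31_mask, dtype=bool)
    if max_closable_gap_um < pixel_size_um:
        warnings.warn(
            "closable gap below pixel size; gap rule degenerates", GapRuleWarning
        )
    radius_px = max(1, math.ceil(0.5 * max_closable_gap_um / pixel_size_um))
    closed = closing(cd31_mask, disk(radius_px))
    # enclosed holes: background pixels not reachable from the border
    # (4-connected background, dual to the 8-connected walls)
    filled = ndimage.binary_fill_holes(
        closed, structure=ndimage.generate_binary_structure(2, 2)
    )
    lumen = filled & ~closed & ~cd31_mask
    return lumen


def segment_field(
    fld: VesselField,
    channel: str | int = 0,
    threshold_rule: float | str = "otsu",
    max_closable_gap_um: float = 1.0,
) -> VesselSegmentation:
    """Full wall + lumen segmentation of one field."""
    cd31 = segment_cd31(fld, channel, threshold_rule)
    lumen = segment_lumens(cd31, fld.pixel_size_um, max_closable_gap_um)
    thr = threshold_rule if isinstance(threshold_rule, float) else math.nan
    return VesselSegmentation(cd31_mask=cd31, lumen_mask=lumen, threshold_used=thr)


def vascular_area(seg: VesselSegmentation, fld: VesselField) -> VascularAreaResult:
    """Vascular area per field: CD31 area + lumen area, as μm² and % of field."""
    pa = fld.pixel_area_um2
    cd31 = float(seg.cd31_mask.sum()) * pa
    lumen = float(seg.lumen_mask.sum()) * pa
    vasc = cd31 + lumen
    return VascularAreaResult(
        cd31_area_um2=cd31,
        lumen_area_um2=lumen,
        vascular_area_um2=vasc,
        vascular_area_pct=100.0 * vasc / fld.field_area_um2,
    )


def summarize_tumor(results: list[VascularAreaResult]) -> TumorVascularSummary:
    """Mean ± SEM vascular-area % across a tumor's fields."""
    if not results:
        raise ValueError("at least one field result required")
    pcts = [r.vascular_area_pct for r in results]
    mean = float(np.mean(pcts))
    sem = float(np.std(pcts, ddof=1) / math.sqrt(len(pcts))) if len(pcts) > 1 else None
    return TumorVascularSummary(
        mean_pct=mean, sem_pct=sem, n_fields=len(pcts), field_pcts=pcts
    )
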