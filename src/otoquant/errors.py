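"""Exception hierarchy for otoquant."""


class OtoquantError(Exception):
    """Base class for all otoquant errors."""


class PlacementError(OtoquantError):
    """Requested synthetic objects cannot be placed without violating geometry."""


class GeometryError(OtoquantError):
    """Synthetic geometry extends beyond the field or is self-inconsistent."""


class BackgroundEstimationError(OtoquantError):
    """Background statistics cannot be estimated (no background support)."""


class EmptyMaskError(OtoquantError):
    """A nucleus mask with no member voxels was supplied."""


class FormatError(OtoquantError):
    """Tabular input violates the expected layout (e.g. off-grid intensities)."""


class DegenerateFitError(OtoquantError):
    """Model fit is not identifiable from the data supplied."""


class DegenerateThresholdWarning(UserWarning):
    """Zero-spread background makes the k-sigma threshold degenerate."""


class MaskSaturationWarning(UserWarning):
    """A segmentation produced an empty or full mask."""


class GapRuleWarning(UserWarning):
    """The closable-gap width is below the pixel size; the rule degenerates."""


class SurvivalClipWarning(UserWarning):
    """A count exceeded its control count; survival clipped to 100%."""
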