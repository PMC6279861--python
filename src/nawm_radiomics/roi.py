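"""ROI construction and bookkeeping.

The developing-NAWM ROI is built by subtracting the baseline WMH mask from
the follow-up WMH mask of a co-registered image pair; the non-developing
NAWM ROI is placed at the mirror-symmetric position about the image's
vertical midline.  Inputs are assumed pre-registered: no spatial alignment
is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageSlice, MaskedPatch, RoiMask
from .errors import (
    DegenerateRoiError,
    InvalidArgumentError,
    MaskDisagreementWarning,
    OutOfBoundsError,
)

DEFAULT_MIN_PIXELS = 100


@dataclass
class RoiValidation:
    passed: bool
    n_pixels: int
    min_pixels: int

    def __bool__(self) -> bool:
        return self.passed


def subtract_masks(followup_wmh: RoiMask, baseline_wmh: RoiMask) -> RoiMask:
    """Set difference follow-up ∖ baseline, labelled ``dNAWM``.

    The masks need not be nested (manual delineations may disagree); if the
    baseline mask extends outside the follow-up mask a
    :class:`MaskDisagreementWarning` is issued and the stray pixels are
    simply not part of the result.
    """
    if followup_wmh.shape != baseline_wmh.shape:
        raise InvalidArgumentError(
            f"mask shapes differ: {followup_wmh.shape} vs {baseline_wmh.shape}"
        )
    if (
        followup_wmh.subject_id is not None
        and baseline_wmh.subject_id is not None
        and followup_wmh.subject_id != baseline_wmh.subject_id
    ):
        raise InvalidArgumentError("masks belong to different subjects")
    stray = int(np.sum(baseline_wmh.pixels & ~followup_wmh.pixels))
    if stray:
        warnings.warn(
            f"{stray} baseline WMH pixels lie outside the follow-up WMH mask",
            MaskDisagreementWarning,
            stacklevel=2,
        )
    diff = followup_wmh.pixels & ~baseline_wmh.pixels
    if not diff.any():
        raise DegenerateRoiError("follow-up ∖ baseline WMH difference is empty")
    return RoiMask(diff, label="dNAWM", subject_id=followup_wmh.subject_id)


def mirror_mask(
    mask: RoiMask, axis_column: float | None = None, label: str = "non_dNAWM"
) -> RoiMask:
    """Reflect a mask about a vertical axis (default: the image midline).

    ``axis_column`` may be half-integer; the reflected column of ``c`` is
    ``round(2*axis - c)``.  Pixel count is preserved; reflections leaving
    the grid raise :class:`OutOfBoundsError`.
    """
    n_rows, n_cols = mask.shape
    if axis_column is None:
        axis_column = (n_cols - 1) / 2.0
    rr, cc = np.nonzero(mask.pixels)
    mirrored_c = np.rint(2.0 * axis_column - cc).astype(int)
    if mirrored_c.min(initial=0) < 0 or mirrored_c.max(initial=0) >= n_cols:
        raise OutOfBoundsError(
            f"reflection about column {axis_column} exits the image"
        )
    out = np.zeros_like(mask.pixels)
    out[rr, mirrored_c] = True
    return RoiMask(out, label=label, subject_id=mask.subject_id)


def validate_roi(mask: RoiMask, min_pixels: int = DEFAULT_MIN_PIXELS) -> RoiValidation:
    """Check the minimum-size rule (default: at least 100 pixels)."""
    n = mask.n_pixels
    return RoiValidation(passed=n >= min_pixels, n_pixels=n, min_pixels=min_pixels)


def extract_patch(image: ImageSlice, mask: RoiMask) -> MaskedPatch:
    """Pull the masked intensities and their (row, col) coordinates,
    row-major."""
    if image.shape != mask.shape:
        raise InvalidArgumentError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    rr, cc = np.nonzero(mask.pixels)  # nonzero is row-major
    return MaskedPatch(
        values=image.data[rr, cc], rows=rr, cols=cc, spacing=image.spacing
    )
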