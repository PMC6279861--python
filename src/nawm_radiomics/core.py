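"""Core in-memory containers.

Conventions used throughout the package: images and masks are 2D numpy
arrays indexed ``[row, column]``, 0-based, row-major.  Pixel spacing is
isotropic in-plane.  A mask is a boolean array of the same shape as its
image.  ROI class labels are the strings ``WMH_baseline``, ``WMH_followup``,
``dNAWM``, ``non_dNAWM`` and ``NWM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

ROI_LABELS = ("WMH_baseline", "WMH_followup", "dNAWM", "non_dNAWM", "NWM")

#: The three ROI classes that enter the statistical analysis.
ANALYSIS_LABELS = ("dNAWM", "non_dNAWM", "NWM")


@dataclass
class ImageSlice:
    """A single 2D grayscale slice with isotropic in-plane spacing (mm)."""

    data: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("ImageSlice.data must be 2D")
        if self.spacing <= 0:
            raise InvalidArgumentError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class RoiMask:
    """Binary pixel mask tied to an :class:`ImageSlice` by shape."""

    pixels: np.ndarray
    label: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise InvalidArgumentError("RoiMask.pixels must be 2D")
        if self.label not in ROI_LABELS:
            raise InvalidArgumentError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MaskedPatch:
    """Intensities and integer coordinates of the pixels inside one ROI,
    in row-major order."""

    values: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if not (len(self.values) == len(self.rows) == len(self.cols)):
            raise InvalidArgumentError("values/rows/cols must align")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SubjectRecord:
    """One simulated subject: co-registered baseline/follow-up slices,
    the ROI masks drawn on them, and clinical metadata."""

    subject_id: str
    group: str  # "case" | "control"
    baseline: ImageSlice
    followup: ImageSlice
    masks: list[RoiMask] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def mask(self, label: str) -> RoiMask:
        for m in self.masks:
            if m.label == label:
                return m
        raise KeyError(f"subject {self.subject_id} has no {label!r} mask")

    @property
    def analysis_masks(self) -> list[RoiMask]:
        return [m for m in self.masks if m.label in ANALYSIS_LABELS]
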