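"""In-memory containers for OCT-like B-scan images and mask boxes.

Coordinate convention (used throughout the package): row 0 is nearest the
probe (water side) and row indices increase with depth; column 0 is the
upstream edge of the image; all ranges are half-open and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MaskBox:
    """Rectangular image region, rows/cols half-open and 0-based."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("mask box indices must be non-negative")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("mask box must have positive extent")

    def check_bounds(self, n_rows: int, n_cols: int) -> None:
        if self.row_stop > n_rows or self.col_stop > n_cols:
            raise ValueError(
                f"mask box {self} out of bounds for image {n_rows}x{n_cols}"
            )


@dataclass
class BScanImage:
    """A 2D grayscale B-scan (axial rows x lateral columns) with metadata.

    ``truth_surface_rows``/``truth_substratum_rows`` hold the renderer's
    per-column ground-truth interface rows (for synthetic images only); they
    are carried for testing and never consulted by the detector.
    ``artifact_boxes`` are the bounding boxes of simulated floating-debris
    artifacts, the synthetic analogue of regions an operator would mask.
    """

    data: np.ndarray
    axial_pixel_um: float
    lateral_pixel_um: float
    truth_surface_rows: np.ndarray | None = None
    truth_substratum_rows: np.ndarray | None = None
    artifact_boxes: list[MaskBox] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("B-scan data must be a 2D array")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "BScanImage":
        return BScanImage(
            data=self.data.copy(),
            axial_pixel_um=self.axial_pixel_um,
            lateral_pixel_um=self.lateral_pixel_um,
            truth_surface_rows=None
            if self.truth_surface_rows is None
            else self.truth_surface_rows.copy(),
            truth_substratum_rows=None
            if self.truth_substratum_rows is None
            else self.truth_substratum_rows.copy(),
            artifact_boxes=list(self.artifact_boxes),
            label=self.label,
        )
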