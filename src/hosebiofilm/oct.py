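"""Biofilm thickness extraction from B-scan images.

Implements the gray-scale gradient analysis used to quantify biofilm
thickness from OCT cross-sections: per column (A-scan), the biofilm-water
interface (surface) and the hose-biofilm interface (substratum) are located
from the axial intensity gradient, optionally after masking floating-debris
regions and applying manual interface overrides; the interface separation
times the axial pixel size gives the per-column thickness, which is
aggregated to image means and 1.2 cm section means.

Thicknesses below the axial detection limit (4.4 um by default) are flagged
as censored; the default averaging policy counts them at half the detection
limit (configurable to exclude them instead), since sub-limit regions are
real biofilm of unknown sub-resolution thickness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .config import DetectionConfig, HoseLayout, ImagingConfig
from .images import BScanImage, MaskBox

logger = logging.getLogger(__name__)

UNDETECTED = -1  # sentinel row index for columns with no detectable interface


@dataclass
class InterfaceCurves:
    """Per-column interface rows; ``UNDETECTED`` marks failed columns."""

    surface_rows: np.ndarray
    substratum_rows: np.ndarray

    def __post_init__(self) -> None:
        self.surface_rows = np.asarray(self.surface_rows, dtype=int)
        self.substratum_rows = np.asarray(self.substratum_rows, dtype=int)
        if self.surface_rows.shape != self.substratum_rows.shape:
            raise ValueError("surface/substratum curves differ in length")
        both = self.detected
        if np.any(self.surface_rows[both] > self.substratum_rows[both]):
            raise ValueError("surface row below substratum row (probe-side first)")

    @property
    def detected(self) -> np.ndarray:
        return (self.surface_rows != UNDETECTED) & (self.substratum_rows != UNDETECTED)

    @property
    def n_cols(self) -> int:
        return self.surface_rows.size


@dataclass
class ThicknessProfile:
    """Per-column thickness (um) with censoring flags and the image mean.

    ``thickness_um`` is NaN for undetected columns; ``censored`` marks
    detected columns whose thickness falls below the axial detection limit.
    ``mean_um`` is NaN when the image is flagged (too many undetected
    columns) and should then be excluded from section means.
    """

    thickness_um: np.ndarray
    censored: np.ndarray
    mean_um: float
    fraction_censored: float
    fraction_undetected: float
    flagged: bool


def mask_regions(
    image: BScanImage, boxes: Sequence[MaskBox], fill: int | None = None
) -> BScanImage:
    """Return a copy of the image with the given boxes filled.

    The synthetic analogue of manually masking detached floating biofilm:
    masked pixels are set to the water background level (or ``fill``), so
    the gradient detector sees plain water there.  The input is untouched.
    """
    out = image.copy()
    level = int(np.median(image.data[:4])) if fill is None else int(fill)
    for box in boxes:
        box.check_bounds(image.n_rows, image.n_cols)
        out.data[box.row_start : box.row_stop, box.col_start : box.col_stop] = level
    return out


def detect_interfaces(
    image: BScanImage, params: DetectionConfig | None = None
) -> InterfaceCurves:
    """Locate the surface and substratum interface per column.

    Gray-scale gradient analysis: the intensity is smoothed axially with a
    moving average, the centred finite-difference gradient computed, and a
    per-column threshold set from the background gradient noise in the top
    (water) rows.  The surface is the first supra-threshold gradient row
    from the probe side, the substratum the strongest gradient at least
    ``min_separation_rows`` deeper; both are refined to the raw single-pixel
    intensity step within ``refine_halfwidth`` rows, so noise-free step
    edges are recovered exactly.  Columns with no supra-threshold gradient
    are undetected (a value, not an error).
    """
    p = params or DetectionConfig()
    data = image.data.astype(float)
    n_rows, n_cols = data.shape
    if n_rows < 8:
        raise ValueError("image must have at least 8 rows")

    smoothed = uniform_filter1d(data, size=p.smooth_window, axis=0, mode="nearest")
    grad = np.gradient(smoothed, axis=0)
    raw_step = np.diff(data, axis=0, prepend=data[:1])  # raw_step[r] = I[r]-I[r-1]

    bg = grad[1 : max(p.bg_rows, 2)]
    thr = np.maximum(p.sd_factor * bg.std(axis=0), p.min_threshold)

    above = grad > thr[None, :]
    # require `consecutive_rows` successive supra-threshold rows so noise in
    # the long water column cannot fire the first-crossing search
    run = above.copy()
    for k in range(1, max(p.consecutive_rows, 1)):
        run[:-k] &= above[k:]
        run[-k:] = False
    any_above = run.any(axis=0)
    surface_coarse = run.argmax(axis=0)
    surface = _refine(raw_step, surface_coarse, p.refine_halfwidth)

    # substratum: strongest gradient at least min_separation_rows below the
    # surface; if nothing supra-threshold remains, the interfaces coincide
    # (zero measurable biofilm).
    rows = np.arange(n_rows)[:, None]
    deep = np.where(rows >= (surface + p.min_separation_rows)[None, :], grad, -np.inf)
    sub_coarse = deep.argmax(axis=0)
    sub_found = deep.max(axis=0) > thr
    substratum = _refine(raw_step, sub_coarse, p.refine_halfwidth)
    substratum = np.where(sub_found, substratum, surface)
    substratum = np.maximum(substratum, surface)

    surface = np.where(any_above, surface, UNDETECTED)
    substratum = np.where(any_above, substratum, UNDETECTED)
    return InterfaceCurves(surface_rows=surface, substratum_rows=substratum)


def _refine(raw_step: np.ndarray, coarse: np.ndarray, halfwidth: int) -> np.ndarray:
    """Snap coarse gradient locations to the strongest raw intensity step."""
    n_rows, n_cols = raw_step.shape
    offsets = np.arange(-halfwidth, halfwidth + 1)
    idx = np.clip(coarse[None, :] + offsets[:, None], 1, n_rows - 1)
    window = np.take_along_axis(raw_step, idx, axis=0)
    return idx[window.argmax(axis=0), np.arange(n_cols)]


def manual_overrides(
    curves: InterfaceCurves,
    overrides: Iterable[tuple[str, int, int, int]],
) -> InterfaceCurves:
    """Apply hand-drawn interface lines as explicit row assignments.

    ``overrides`` holds ``(which, col_start, col_stop, row)`` entries with
    ``which`` in {"surface", "substratum"} and columns half-open; the
    digital counterpart of drawing repair lines over a misdetected image.
    Rejects assignments that violate surface <= substratum.
    """
    surface = curves.surface_rows.copy()
    substratum = curves.substratum_rows.copy()
    for which, c0, c1, row in overrides:
        if not 0 <= c0 < c1 <= curves.n_cols:
            raise ValueError(f"override columns [{c0}, {c1}) out of bounds")
        if row < 0:
            raise ValueError("override row must be non-negative")
        if which == "surface":
            surface[c0:c1] = row
        elif which == "substratum":
            substratum[c0:c1] = row
        else:
            raise ValueError(f"unknown interface {which!r}")
    both = (surface != UNDETECTED) & (substratum != UNDETECTED)
    if np.any(surface[both] > substratum[both]):
        raise ValueError("override violates surface <= substratum")
    return InterfaceCurves(surface_rows=surface, substratum_rows=substratum)


def binarize(image: BScanImage, curves: InterfaceCurves) -> np.ndarray:
    """Binary biofilm map: True iff surface_row <= row < substratum_row."""
    if curves.n_cols != image.n_cols:
        raise ValueError("curves were computed for a different image width")
    rows = np.arange(image.n_rows)[:, None]
    det = curves.detected[None, :]
    return (
        det
        & (rows >= curves.surface_rows[None, :])
        & (rows < curves.substratum_rows[None, :])
    )


def thickness_profile(
    curves: InterfaceCurves,
    img_cfg: ImagingConfig,
    params: DetectionConfig | None = None,
    censoring: str = "half_limit",
) -> ThicknessProfile:
    """Per-column thickness and the image mean under the censoring policy.

    ``censoring='half_limit'`` counts sub-limit columns at half the axial
    detection limit; ``'exclude'`` drops them from the mean.  Undetected
    columns never contribute; if more than ``max_undetected_frac`` of the
    columns are undetected the image is flagged and its mean set to NaN.
    """
    if censoring not in ("half_limit", "exclude"):
        raise ValueError(f"unknown censoring policy {censoring!r}")
    p = params or DetectionConfig()
    det = curves.detected
    t = np.full(curves.n_cols, np.nan)
    t[det] = (
        curves.substratum_rows[det] - curves.surface_rows[det]
    ) * img_cfg.axial_pixel_um
    censored = det & (t < img_cfg.detection_limit_um)

    frac_undet = 1.0 - det.mean() if curves.n_cols else 1.0
    flagged = frac_undet > p.max_undetected_frac
    if flagged or not det.any():
        mean = np.nan
        flagged = True
    else:
        contrib = t[det].copy()
        if censoring == "half_limit":
            contrib[censored[det]] = img_cfg.detection_limit_um / 2.0
            mean = float(contrib.mean())
        else:
            keep = ~censored[det]
            mean = float(contrib[keep].mean()) if keep.any() else np.nan
    return ThicknessProfile(
        thickness_um=t,
        censored=censored,
        mean_um=mean,
        fraction_censored=float(censored.mean()),
        fraction_undetected=float(frac_undet),
        flagged=flagged,
    )


def measure_image(
    image: BScanImage,
    img_cfg: ImagingConfig,
    params: DetectionConfig | None = None,
    boxes: Sequence[MaskBox] = (),
    censoring: str = "half_limit",
) -> ThicknessProfile:
    """Convenience: mask -> detect -> thickness profile for one image."""
    if boxes:
        image = mask_regions(image, boxes)
    curves = detect_interfaces(image, params)
    return thickness_profile(curves, img_cfg, params, censoring)


def aggregate_sections(
    image_means: Sequence[float], images_per_section: int = 6
) -> np.ndarray:
    """Section means from consecutive image means (6 images per 1.2 cm).

    ``image_means`` is one half of the hose in longitudinal order; flagged
    images enter as NaN and are skipped (a section of only flagged images is
    NaN).  The image count must divide evenly into sections.
    """
    means = np.asarray(image_means, dtype=float)
    if images_per_section <= 0:
        raise ValueError("images_per_section must be positive")
    if means.size == 0 or means.size % images_per_section != 0:
        raise ValueError(
            f"{means.size} image means do not divide into sections of "
            f"{images_per_section}"
        )
    groups = means.reshape(-1, images_per_section)
    all_nan = np.isnan(groups).all(axis=1)
    out = np.full(groups.shape[0], np.nan)
    if (~all_nan).any():
        out[~all_nan] = np.nanmean(groups[~all_nan], axis=1)
    return out


def measure_hose(
    images_by_half: dict[str, Sequence[BScanImage]],
    img_cfg: ImagingConfig,
    layout: HoseLayout | None = None,
    params: DetectionConfig | None = None,
    censoring: str = "half_limit",
) -> dict[str, np.ndarray]:
    """Full extraction pipeline: images -> per-half section thickness means."""
    layout = layout or HoseLayout()
    out = {}
    for half, images in images_by_half.items():
        means = [
            measure_image(im, img_cfg, params, censoring=censoring).mean_um
            for im in images
        ]
        out[half] = aggregate_sections(means, layout.images_per_section)
        n_flagged = int(np.isnan(means).sum()) if means else 0
        if n_flagged:
            logger.warning("half %s: %d flagged images excluded", half, n_flagged)
    return out
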