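"""Biofilm volume, bacterial cell volume, and volume-fraction reconstruction.

All operations are exact arithmetic on the measured summaries:

* biofilm volume per substratum area: ``V_biofilm = T_mean * 1e8 um^2/cm^2``
  (a mean thickness in um spread over 1 cm^2),
* bacterial cell volume per area: ``V_cells = TCC * v_cell`` with a mean
  single-cell volume of 0.3 um^3 by default,
* volume fraction ``V_cells : V_biofilm`` in percent,
* hose totals: the sum of per-section TCC times the section's substratum
  area.  The default ``unit`` area model assigns 1 cm^2 per section (the
  convention in which per-cm^2 results are reported); the ``geometric``
  model uses the actual half-shell area of a 1.2 cm section of a hose of
  0.8 cm inner diameter (1.2 * pi * 0.4 ~ 1.508 cm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

UM2_PER_CM2 = 1e8
DEFAULT_MEAN_CELL_VOLUME_UM3 = 0.3
AREA_MODELS = ("unit", "geometric")
HOSE_INNER_DIAMETER_CM = 0.8

__all__ = [
    "VolumeSummary",
    "biofilm_volume_per_area",
    "cell_volume_per_area",
    "volume_fraction",
    "section_area_cm2",
    "hose_totals",
    "volume_summary",
]


def biofilm_volume_per_area(mean_thickness_um: float) -> float:
    """Biofilm volume per substratum area (um^3/cm^2) from mean thickness (um)."""
    t = float(mean_thickness_um)
    if t < 0:
        raise ValueError("mean thickness must be >= 0")
    return t * UM2_PER_CM2


def cell_volume_per_area(
    tcc_cells_per_cm2: float,
    mean_cell_volume_um3: float = DEFAULT_MEAN_CELL_VOLUME_UM3,
) -> float:
    """Total bacterial cell volume per area (um^3/cm^2) from TCC."""
    tcc = float(tcc_cells_per_cm2)
    v = float(mean_cell_volume_um3)
    if tcc < 0 or v < 0:
        raise ValueError("TCC and mean cell volume must be >= 0")
    return tcc * v


def volume_fraction(v_cells: float, v_biofilm: float) -> float:
    """V_cells : V_biofilm in percent; NaN (flagged) if V_biofilm is 0."""
    if v_cells < 0 or v_biofilm < 0:
        raise ValueError("volumes must be >= 0")
    if v_biofilm == 0:
        return np.nan
    return float(v_cells) / float(v_biofilm) * 100.0


def section_area_cm2(
    area_model: str = "unit",
    section_length_cm: float = 1.2,
    inner_diameter_cm: float = HOSE_INNER_DIAMETER_CM,
) -> float:
    """Substratum area of one half-hose section under the chosen model."""
    if area_model == "unit":
        return 1.0
    if area_model == "geometric":
        return section_length_cm * math.pi * inner_diameter_cm / 2.0
    raise ValueError(f"unknown area model {area_model!r}; choose from {AREA_MODELS}")


def hose_totals(
    section_tcc_cells_per_cm2,
    area_model: str = "unit",
    section_length_cm: float = 1.2,
    inner_diameter_cm: float = HOSE_INNER_DIAMETER_CM,
) -> float:
    """Total bacteria in the hose: sum of per-section TCC times section area."""
    tcc = np.asarray(section_tcc_cells_per_cm2, dtype=float)
    tcc = tcc[~np.isnan(tcc)]
    if tcc.size == 0:
        return 0.0
    if np.any(tcc < 0):
        raise ValueError("TCC values must be >= 0")
    area = section_area_cm2(area_model, section_length_cm, inner_diameter_cm)
    return float(tcc.sum() * area)


@dataclass
class VolumeSummary:
    """Volume reconstruction for one hose (or one half)."""

    v_biofilm_um3_per_cm2: float
    v_cells_um3_per_cm2: float
    fraction_pct: float
    mean_cell_volume_um3: float
    total_cells: float
    area_model: str


def volume_summary(
    mean_thickness_um: float,
    mean_tcc_cells_per_cm2: float,
    section_tcc_cells_per_cm2=None,
    mean_cell_volume_um3: float = DEFAULT_MEAN_CELL_VOLUME_UM3,
    area_model: str = "unit",
) -> VolumeSummary:
    """Assemble the full volume reconstruction from thickness and TCC."""
    v_b = biofilm_volume_per_area(mean_thickness_um)
    v_c = cell_volume_per_area(mean_tcc_cells_per_cm2, mean_cell_volume_um3)
    totals = (
        hose_totals(section_tcc_cells_per_cm2, area_model)
        if section_tcc_cells_per_cm2 is not None
        else np.nan
    )
    return VolumeSummary(
        v_biofilm_um3_per_cm2=v_b,
        v_cells_um3_per_cm2=v_c,
        fraction_pct=volume_fraction(v_c, v_b),
        mean_cell_volume_um3=mean_cell_volume_um3,
        total_cells=totals,
        area_model=area_model,
    )
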