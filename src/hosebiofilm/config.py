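"""Configuration objects for the hose-biofilm simulator and analysis pipeline.

Three dataclasses describe, respectively, the simulated hose biofilm
(:class:`SimulationConfig`), the OCT-like imaging system
(:class:`ImagingConfig`) and the physical sectioning/imaging layout of the
hose (:class:`HoseLayout`).  All of them validate their invariants on
construction, round-trip through plain dictionaries (and hence YAML), and are
hashable to a stable hex digest for provenance tracking.

The default values emulate a 120 cm piece of flexible PVC-P shower hose that
was bisected longitudinally into *top* and *bottom* halves, cut into
1.2 cm sections (100 per half, 200 per hose), and imaged with a spectral
domain OCT system at 2 mm x 1 mm per B-scan (30 images per 6 cm piece,
1,200 per hose).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

HALVES = ("top", "bottom")

__all__ = [
    "HALVES",
    "SimulationConfig",
    "ImagingConfig",
    "DetectionConfig",
    "HoseLayout",
    "control_hose_config",
    "real_hose_config",
    "config_hash",
]


def _per_half(value, name: str) -> dict[str, float]:
    """Normalize a scalar or ``{half: value}`` mapping to a dict over HALVES."""
    if isinstance(value, Mapping):
        missing = set(HALVES) - set(value)
        if missing:
            raise ValueError(f"{name}: missing halves {sorted(missing)}")
        return {h: float(value[h]) for h in HALVES}
    return {h: float(value) for h in HALVES}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic hose biofilm.

    Lengths are in cm, thicknesses in um, TCC in cells/cm^2.  ``baseline``,
    ``trend_slope`` and ``smallscale_cv`` may be scalars (applied to both
    halves) or ``{"top": ..., "bottom": ...}`` mappings.

    The thickness model per half is ``T(x) = baseline + slope*x + eta(x)``
    where ``eta`` is a stationary Gaussian field smoothed to correlation
    length ``topo_wavelength_mm`` and scaled so its standard deviation is
    ``smallscale_cv`` times the mid-hose trend level; the field is clipped
    at zero.
    """

    hose_length_cm: float = 120.0
    section_length_cm: float = 1.2
    baseline_thickness_um: dict[str, float] = field(
        default_factory=lambda: {"top": 202.2, "bottom": 258.2}
    )
    trend_slope_um_per_cm: dict[str, float] = field(
        default_factory=lambda: {"top": 0.83, "bottom": 2.13}
    )
    smallscale_cv: dict[str, float] = field(
        default_factory=lambda: {"top": 0.12, "bottom": 0.24}
    )
    topo_wavelength_mm: float = 6.0
    field_resolution_mm: float = 1.0
    # physical ceiling on local thickness (um); keeps the biofilm inside the
    # 1 mm OCT imaging depth just as a real hose biofilm stays measurable
    max_thickness_um: float = 850.0

    # total cell concentration (flow-cytometry emulation)
    tcc_mean: float = 2.4e7
    tcc_cv: float = 0.2
    tcc_thickness_corr: float = 0.4

    # community (ZOTU count table emulation)
    n_taxa: int = 384
    dominant_profile: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("Cytophagaceae", 0.247),
            ("Bradyrhizobium", 0.234),
            ("TM6_Dependentiae", 0.096),
        ]
    )
    dominant_anticorr_pair: tuple[str, str, float] | None = (
        "Cytophagaceae",
        "Bradyrhizobium",
        0.6,
    )
    # (taxon, half, first_section, last_section, delta) with sections 1-based
    # inclusive; delta is an absolute change in expected relative abundance.
    step_changes: list[tuple[str, str, int, int, float]] = field(
        default_factory=lambda: [("TM6_Dependentiae", "top", 81, 91, 0.081)]
    )
    taxon_wobble_sd: float = 0.55
    wobble_window_sections: int = 5
    geometric_ratio: float = 0.81
    n_geometric: int = 110
    rare_mass: float = 4e-4
    reads_per_section: int = 50_000
    missing_section_prob: float = 0.025

    seed: int = 42

    def __post_init__(self) -> None:
        self.baseline_thickness_um = _per_half(
            self.baseline_thickness_um, "baseline_thickness_um"
        )
        self.trend_slope_um_per_cm = _per_half(
            self.trend_slope_um_per_cm, "trend_slope_um_per_cm"
        )
        self.smallscale_cv = _per_half(self.smallscale_cv, "smallscale_cv")
        self.dominant_profile = [(str(t), float(p)) for t, p in self.dominant_profile]
        if self.dominant_anticorr_pair is not None:
            a, b, s = self.dominant_anticorr_pair
            self.dominant_anticorr_pair = (str(a), str(b), float(s))
        self.step_changes = [
            (str(t), str(h), int(i0), int(i1), float(d))
            for t, h, i0, i1, d in self.step_changes
        ]

        n = self.hose_length_cm / self.section_length_cm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "hose_length_cm must be an integer multiple of section_length_cm "
                f"(got {self.hose_length_cm}/{self.section_length_cm})"
            )
        dom_sum = sum(p for _, p in self.dominant_profile)
        if not dom_sum < 1.0:
            raise ValueError(f"dominant mean abundances must sum to < 1 (got {dom_sum})")
        if any(p <= 0 for _, p in self.dominant_profile):
            raise ValueError("dominant mean abundances must be positive")
        if len({t for t, _ in self.dominant_profile}) != len(self.dominant_profile):
            raise ValueError("duplicate taxon label in dominant_profile")
        if self.n_taxa < len(self.dominant_profile):
            raise ValueError(
                f"n_taxa={self.n_taxa} smaller than number of configured "
                f"dominants ({len(self.dominant_profile)})"
            )
        if not 0.0 <= self.missing_section_prob <= 1.0:
            raise ValueError("missing_section_prob must lie in [0, 1]")
        if not -1.0 <= self.tcc_thickness_corr <= 1.0:
            raise ValueError("tcc_thickness_corr must lie in [-1, 1]")
        if self.tcc_mean <= 0:
            raise ValueError("tcc_mean must be positive")
        if not 0.0 < self.geometric_ratio < 1.0:
            raise ValueError("geometric_ratio must lie in (0, 1)")
        if self.reads_per_section <= 0:
            raise ValueError("reads_per_section must be positive")
        if self.field_resolution_mm <= 0 or self.topo_wavelength_mm <= 0:
            raise ValueError("resolutions/wavelengths must be positive")

    @property
    def sections_per_half(self) -> int:
        return int(round(self.hose_length_cm / self.section_length_cm))

    @property
    def n_sections(self) -> int:
        return 2 * self.sections_per_half

    def section_positions_cm(self):
        """Section midpoints (cm from the upstream end) for one half, 1-based order."""
        import numpy as np

        k = self.sections_per_half
        return (np.arange(k) + 0.5) * self.section_length_cm

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dominant_profile"] = [list(x) for x in d["dominant_profile"]]
        if d["dominant_anticorr_pair"] is not None:
            d["dominant_anticorr_pair"] = list(d["dominant_anticorr_pair"])
        d["step_changes"] = [list(x) for x in d["step_changes"]]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "dominant_profile" in d:
            d["dominant_profile"] = [tuple(x) for x in d["dominant_profile"]]
        if d.get("dominant_anticorr_pair") is not None:
            d["dominant_anticorr_pair"] = tuple(d["dominant_anticorr_pair"])
        if "step_changes" in d:
            d["step_changes"] = [tuple(x) for x in d["step_changes"]]
        return cls(**d)


@dataclass
class ImagingConfig:
    """Geometry and intensity model of the OCT-like B-scan renderer/reader.

    The image is an 8-bit grayscale grid; row 0 is nearest the probe (water
    side) and rows increase with depth.  Intensity levels are fixed so tests
    are stable: water ~30, biofilm ~120 (+speckle), substratum ~220.
    """

    image_length_mm: float = 2.0
    image_height_mm: float = 1.0
    axial_pixel_um: float = 2.0
    lateral_pixel_um: float = 4.0
    noise_sd: float = 6.0
    artifact_rate: float = 0.0
    detection_limit_um: float = 4.4

    water_level: int = 30
    biofilm_level: int = 120
    substratum_level: int = 220
    substratum_depth_frac: float = 0.9

    def __post_init__(self) -> None:
        if self.axial_pixel_um <= 0 or self.lateral_pixel_um <= 0:
            raise ValueError("pixel sizes must be positive")
        rows = self.image_height_mm * 1000.0 / self.axial_pixel_um
        if abs(rows - round(rows)) > 1e-9:
            raise ValueError(
                "image_height_mm * 1000 / axial_pixel_um must be a whole row count"
            )
        cols = self.image_length_mm * 1000.0 / self.lateral_pixel_um
        if abs(cols - round(cols)) > 1e-9:
            raise ValueError(
                "image_length_mm * 1000 / lateral_pixel_um must be a whole column count"
            )
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_rows(self) -> int:
        return int(round(self.image_height_mm * 1000.0 / self.axial_pixel_um))

    @property
    def n_cols(self) -> int:
        return int(round(self.image_length_mm * 1000.0 / self.lateral_pixel_um))

    @property
    def substratum_row(self) -> int:
        return int(round(self.n_rows * self.substratum_depth_frac))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImagingConfig":
        return cls(**dict(d))


@dataclass
class DetectionConfig:
    """Parameters of the gray-scale gradient interface detector.

    ``smooth_window`` axial moving-average width (px) applied before the
    centred finite-difference gradient; the surface is the first row where
    ``consecutive_rows`` successive smoothed-gradient values exceed
    ``sd_factor`` times the background gradient SD (estimated from the top
    ``bg_rows`` water rows, floored at ``min_threshold``); the substratum is
    the largest gradient at least ``min_separation_rows`` deeper.  Both are
    refined by the raw single-pixel difference within ``refine_halfwidth``
    rows.  An A-scan searches hundreds of rows for one edge, so the
    threshold must hold jointly over the whole water column; the consecutive
    requirement plus a 5 sigma factor keeps the per-column false-trigger
    rate negligible while the true edge (a multi-row gradient plateau)
    always qualifies.  Images with more than ``max_undetected_frac``
    undetected columns are flagged and excluded from section means.
    """

    smooth_window: int = 5
    bg_rows: int = 16
    sd_factor: float = 5.0
    min_threshold: float = 4.0
    consecutive_rows: int = 2
    min_separation_rows: int = 3
    refine_halfwidth: int = 3
    max_undetected_frac: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "DetectionConfig":
        return cls(**dict(d))


@dataclass
class HoseLayout:
    """Sectioning and imaging layout of one experimental hose."""

    n_pieces: int = 20
    piece_length_cm: float = 6.0
    halves: tuple[str, str] = HALVES
    sections_per_piece: int = 5
    section_length_cm: float = 1.2
    images_per_piece: int = 30

    def __post_init__(self) -> None:
        self.halves = tuple(self.halves)
        if not math.isclose(
            self.sections_per_piece * self.section_length_cm, self.piece_length_cm
        ):
            raise ValueError(
                "sections_per_piece * section_length_cm must equal piece_length_cm"
            )
        if self.images_per_piece % self.sections_per_piece != 0:
            raise ValueError(
                "images_per_piece must be divisible by sections_per_piece"
            )

    @property
    def hose_length_cm(self) -> float:
        return self.n_pieces * self.piece_length_cm

    @property
    def sections_per_half(self) -> int:
        return self.n_pieces * self.sections_per_piece

    @property
    def n_sections(self) -> int:
        return len(self.halves) * self.sections_per_half

    @property
    def images_per_section(self) -> int:
        return self.images_per_piece // self.sections_per_piece

    @property
    def images_per_half(self) -> int:
        return self.n_pieces * self.images_per_piece

    @property
    def n_images(self) -> int:
        return len(self.halves) * self.images_per_half

    def to_dict(self) -> dict:
        d = asdict(self)
        d["halves"] = list(d["halves"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "HoseLayout":
        return cls(**dict(d))


def control_hose_config(**overrides) -> SimulationConfig:
    """Preset emulating the laboratory-grown (control) hose biofilm."""
    return SimulationConfig(**overrides)


def real_hose_config(**overrides) -> SimulationConfig:
    """Preset emulating the biofilm grown under uncontrolled real-use conditions.

    A roughly ten-fold thinner biofilm, higher and more variable TCC, a
    different dominant trio and a pronounced localized drop of one dominant
    taxon toward the downstream end.
    """
    params = dict(
        baseline_thickness_um={"top": 9.8, "bottom": 9.8},
        trend_slope_um_per_cm={"top": 0.0, "bottom": 0.0},
        smallscale_cv={"top": 0.35, "bottom": 0.35},
        tcc_mean=3.8e7,
        tcc_cv=0.35,
        tcc_thickness_corr=0.6,
        n_taxa=341,
        dominant_profile=[
            ("Caulobacter", 0.347),
            ("Bradyrhizobium", 0.242),
            ("Altererythrobacter", 0.142),
        ],
        dominant_anticorr_pair=("Caulobacter", "Bradyrhizobium", 0.6),
        step_changes=[("Altererythrobacter", "top", 90, 100, -0.10)],
        missing_section_prob=0.085,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def config_hash(*configs) -> str:
    """Stable short hex digest of one or more config objects (provenance)."""
    payload = json.dumps(
        [c.to_dict() for c in configs], sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
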