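"""Synthetic hose-biofilm generator with known ground truth.

Generates the three measurable layers of a sectioned shower-hose biofilm --
a continuous thickness field per longitudinal half, per-section total cell
concentrations (TCC), and a taxa x section read-count table -- plus OCT-like
grayscale B-scans rendered from the thickness field.  Everything is fully
determined by ``SimulationConfig.seed``; each artifact (field, TCC,
community, images) draws from its own RNG stream split from the master seed,
so regenerating one artifact never shifts the others.

Model summary
-------------
Thickness per half:  ``T(x) = baseline + slope*x + eta(x)``, where ``eta``
is Gaussian noise smoothed to correlation length ``topo_wavelength_mm``
(the "hills and dunes" topography) and scaled so that the expected
adjacent-section variation statistic equals ``smallscale_cv``; clipped at 0.

TCC per section:  ``tcc_mean * (1 + cv*(rho*z_T + sqrt(1-rho^2)*z))`` with
``z_T`` the standardized section thickness, so the sample Pearson r between
TCC and thickness approaches ``rho`` and the realized CV approaches ``cv``;
clipped at 0.

Community per section: expected proportions combine a fixed dominant
profile, a geometric rank-abundance tail plus a uniform rare floor, smooth
per-taxon log-normal wobble along the hose (spatial autocorrelation), an
anti-correlated dominant pair, and localized step changes; reads are drawn
multinomially and whole sections are dropped at ``missing_section_prob``
(emulating failed DNA amplification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .config import HALVES, HoseLayout, ImagingConfig, SimulationConfig
from .images import BScanImage, MaskBox

logger = logging.getLogger(__name__)

# fixed stream indices -- one independent RNG stream per artifact
_STREAMS = {"field": 1, "tcc": 2, "community": 3, "images": 4}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, extra)])
    )


def section_ids(cfg_or_layout) -> list[str]:
    """Section identifiers in canonical order: top 1..K then bottom 1..K."""
    k = cfg_or_layout.sections_per_half
    return [f"{h}_{i:03d}" for h in HALVES for i in range(1, k + 1)]


def parse_section_id(sid: str) -> tuple[str, int]:
    half, _, idx = sid.rpartition("_")
    if half not in HALVES:
        raise ValueError(f"malformed section id {sid!r}")
    return half, int(idx)


# ---------------------------------------------------------------------------
# thickness field
# ---------------------------------------------------------------------------

@dataclass
class ThicknessField:
    """Continuous per-position, per-half biofilm thickness (um).

    ``positions_cm`` spans [0, hose_length] at a fixed resolution;
    ``thickness_um[half]`` holds the non-negative field values on that grid.
    """

    positions_cm: np.ndarray
    thickness_um: dict[str, np.ndarray]
    hose_length_cm: float
    section_length_cm: float = 1.2

    def __post_init__(self) -> None:
        for half, t in self.thickness_um.items():
            if len(t) != len(self.positions_cm):
                raise ValueError(f"half {half!r}: length mismatch with positions")
            if np.any(t < 0):
                raise ValueError(f"half {half!r}: negative thickness")

    @property
    def sections_per_half(self) -> int:
        return int(round(self.hose_length_cm / self.section_length_cm))

    def section_means(self, half: str | None = None):
        """Trapezoidal section means of the field (um), 1.2 cm sections.

        Section boundaries must align with the field grid (true for the
        default 1 mm resolution).  Returns an array for one half, or a
        ``{half: array}`` dict when ``half`` is None.
        """
        if half is None:
            return {h: self.section_means(h) for h in self.thickness_um}
        return _grid_section_means(
            self.positions_cm, self.thickness_um[half], self.section_length_cm
        )

    def section_mean_series(self) -> np.ndarray:
        """All section means in canonical order (top 1..K then bottom 1..K)."""
        return np.concatenate([self.section_means(h) for h in HALVES])

    def column_thickness(
        self, half: str, start_mm: float, n_cols: int, lateral_pixel_um: float
    ) -> np.ndarray:
        """Field linearly interpolated at B-scan column centers (um)."""
        pos_cm = (start_mm + (np.arange(n_cols) + 0.5) * lateral_pixel_um / 1000.0) / 10.0
        return np.interp(pos_cm, self.positions_cm, self.thickness_um[half])


def _grid_section_means(
    positions_cm: np.ndarray, values: np.ndarray, section_length_cm: float
) -> np.ndarray:
    step = positions_cm[1] - positions_cm[0]
    per = section_length_cm / step
    if abs(per - round(per)) > 1e-9:
        raise ValueError("section boundaries must align with the field grid")
    per = int(round(per))
    n_sections = (len(positions_cm) - 1) // per
    out = np.empty(n_sections)
    for j in range(n_sections):
        seg = values[j * per : j * per + per + 1]
        out[j] = np.trapezoid(seg, dx=step) / (per * step)
    return out


def generate_thickness_field(cfg: SimulationConfig) -> ThicknessField:
    """Draw the ground-truth thickness field T(x) for both halves.

    The smooth noise component is rescaled per half so that the expected
    adjacent-section variation statistic (|difference|/pair-mean, in
    percent) equals ``100 * smallscale_cv``.  Raises if the configured
    baseline/slope would clip more than half the field to zero.
    """
    res_cm = cfg.field_resolution_mm / 10.0
    n = int(round(cfg.hose_length_cm / res_cm)) + 1
    positions = np.linspace(0.0, cfg.hose_length_cm, n)
    rng = _rng(cfg.seed, "field")
    sigma_samples = (cfg.topo_wavelength_mm / 2.0) / cfg.field_resolution_mm

    thickness: dict[str, np.ndarray] = {}
    for half in HALVES:
        trend = (
            cfg.baseline_thickness_um[half]
            + cfg.trend_slope_um_per_cm[half] * positions
        )
        white = rng.standard_normal(n)
        smooth = gaussian_filter1d(white, sigma=sigma_samples, mode="reflect")
        # noise is proportional to the local trend level (thicker biofilm,
        # larger hills), scaled so E|M_{j+1}-M_j| / pair level of the section
        # means M equals smallscale_cv
        sm_means = _grid_section_means(positions, smooth, cfg.section_length_cm)
        sd_delta = float(np.std(np.diff(sm_means)))
        if sd_delta <= 0:
            scale = 0.0
        else:
            scale = cfg.smallscale_cv[half] * np.sqrt(np.pi / 2.0) / sd_delta
        fieldvals = trend * (1.0 + smooth * scale)
        clipped = fieldvals < 0
        if clipped.mean() > 0.5:
            raise ValueError(
                f"half {half!r}: baseline/slope configuration clips "
                f"{clipped.mean():.0%} of the field to zero "
                f"(baseline={cfg.baseline_thickness_um[half]}, "
                f"slope={cfg.trend_slope_um_per_cm[half]})"
            )
        thickness[half] = np.clip(fieldvals, 0.0, cfg.max_thickness_um)

    return ThicknessField(
        positions_cm=positions,
        thickness_um=thickness,
        hose_length_cm=cfg.hose_length_cm,
        section_length_cm=cfg.section_length_cm,
    )


# ---------------------------------------------------------------------------
# total cell concentrations
# ---------------------------------------------------------------------------

def generate_tcc(field: ThicknessField, cfg: SimulationConfig) -> np.ndarray:
    """Per-section TCC (cells/cm^2) correlated with section thickness.

    Returns values in canonical section order (top then bottom).  The
    configured Pearson correlation ``tcc_thickness_corr`` and coefficient of
    variation ``tcc_cv`` are both realized in expectation.
    """
    if cfg.tcc_mean <= 0:
        raise ValueError("tcc_mean must be positive")
    if field.sections_per_half != cfg.sections_per_half:
        raise ValueError(
            "thickness field and config disagree on section count "
            f"({field.sections_per_half} vs {cfg.sections_per_half})"
        )
    t = field.section_mean_series()
    sd = t.std()
    z_thick = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
    rho = cfg.tcc_thickness_corr
    z_ind = _rng(cfg.seed, "tcc").standard_normal(t.size)
    tcc = cfg.tcc_mean * (
        1.0 + cfg.tcc_cv * (rho * z_thick + np.sqrt(1.0 - rho**2) * z_ind)
    )
    return np.clip(tcc, 0.0, None)


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

def _taxon_labels(cfg: SimulationConfig) -> list[str]:
    labels = [t for t, _ in cfg.dominant_profile]
    labels += [f"ZOTU_{i:04d}" for i in range(len(labels) + 1, cfg.n_taxa + 1)]
    return labels


def base_proportions(cfg: SimulationConfig) -> pd.Series:
    """Mean expected relative abundance per taxon (sums to 1).

    Dominants take their configured means; the remainder is a geometric
    rank-abundance tail (``geometric_ratio``, ``n_geometric`` ranks) plus a
    uniform rare floor of total mass ``rare_mass`` over all leftover taxa.
    """
    labels = _taxon_labels(cfg)
    d = len(cfg.dominant_profile)
    dom_mass = sum(p for _, p in cfg.dominant_profile)
    n_bg = cfg.n_taxa - d
    n_geo = min(cfg.n_geometric, n_bg)
    n_rare = n_bg - n_geo
    rare_mass = cfg.rare_mass if n_rare > 0 else 0.0
    geo_mass = 1.0 - dom_mass - rare_mass
    if geo_mass < 0:
        raise ValueError("dominant masses + rare_mass exceed 1")
    p = np.empty(cfg.n_taxa)
    p[:d] = [q for _, q in cfg.dominant_profile]
    if n_geo > 0:
        w = cfg.geometric_ratio ** np.arange(n_geo)
        p[d : d + n_geo] = geo_mass * w / w.sum()
    if n_rare > 0:
        p[d + n_geo :] = rare_mass / n_rare
    return pd.Series(p, index=labels)


def _smooth_unit_noise(
    rng: np.random.Generator, shape: tuple[int, ...], window: int
) -> np.ndarray:
    """White noise smoothed along the last axis per half, ~unit variance."""
    w = rng.standard_normal(shape)
    if window > 1:
        half_len = shape[-1] // 2
        for sl in (np.s_[..., :half_len], np.s_[..., half_len:]):
            w[sl] = uniform_filter1d(w[sl], size=window, axis=-1, mode="nearest")
        w *= np.sqrt(window)
    return w


def generate_community(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw the taxa x section read-count table.

    Returns an integer DataFrame with taxon labels as the index and section
    ids (``top_001`` ... ``bottom_100``) as columns; sections lost to the
    simulated amplification failure are dropped entirely (no column).
    Column sums equal ``reads_per_section`` for every retained section.
    """
    rng = _rng(cfg.seed, "community")
    base = base_proportions(cfg)
    n_sections = cfg.n_sections
    ids = section_ids(cfg)
    k = cfg.sections_per_half

    # missing mask drawn first so the downstream draws stay aligned
    missing = rng.random(n_sections) < cfg.missing_section_prob

    sigma = cfg.taxon_wobble_sd
    w = _smooth_unit_noise(rng, (cfg.n_taxa, n_sections), cfg.wobble_window_sections)
    m = base.to_numpy()[:, None] * np.exp(sigma * w - sigma**2 / 2.0)

    if cfg.dominant_anticorr_pair is not None:
        a, b, s = cfg.dominant_anticorr_pair
        f = _smooth_unit_noise(rng, (n_sections,), cfg.wobble_window_sections)
        ia, ib = base.index.get_loc(a), base.index.get_loc(b)
        m[ia] *= np.exp(s * f - s**2 / 2.0)
        m[ib] *= np.exp(-s * f - s**2 / 2.0)

    q = m / m.sum(axis=0, keepdims=True)

    for taxon, half, i0, i1, delta in cfg.step_changes:
        if taxon not in base.index:
            raise ValueError(f"step change refers to unknown taxon {taxon!r}")
        offset = 0 if half == HALVES[0] else k
        cols = slice(offset + i0 - 1, offset + i1)
        it = base.index.get_loc(taxon)
        new_t = q[it, cols] + delta
        if np.any(new_t < 0) or np.any(new_t > 1):
            raise ValueError(
                f"step change for {taxon!r} drives an expected proportion "
                "outside [0, 1]"
            )
        others = (1.0 - new_t) / (1.0 - q[it, cols])
        q[:, cols] *= others
        q[it, cols] = new_t

    counts = rng.multinomial(cfg.reads_per_section, q.T).T  # (taxa, sections)
    table = pd.DataFrame(counts, index=list(base.index), columns=ids)
    return table.loc[:, ~missing]


# ---------------------------------------------------------------------------
# B-scan rendering
# ---------------------------------------------------------------------------

def render_bscan(
    column_thickness_um: np.ndarray,
    img_cfg: ImagingConfig,
    seed: int | np.random.Generator | None = None,
    label: str = "",
) -> BScanImage:
    """Render one OCT-like B-scan from true per-column thickness.

    Rows from the probe side: water (low intensity), biofilm band (medium
    intensity plus speckle), substratum (high intensity).  The substratum
    interface sits at a fixed depth; the biofilm-water interface is placed
    ``round(thickness/axial_pixel)`` rows above it.  Ground-truth interface
    rows are stored on the image.  With ``artifact_rate > 0``, floating
    detached-biofilm blobs are added in the water region and their bounding
    boxes recorded.
    """
    t = np.asarray(column_thickness_um, dtype=float)
    if t.ndim != 1 or t.size != img_cfg.n_cols:
        raise ValueError(
            f"segment must supply {img_cfg.n_cols} column thicknesses "
            f"(one image length), got {t.size}"
        )
    if np.any(t < 0):
        raise ValueError("negative thickness in segment")
    max_um = img_cfg.substratum_row * img_cfg.axial_pixel_um
    if np.any(t > max_um):
        raise ValueError(
            f"thickness up to {t.max():.1f} um exceeds the imageable depth "
            f"({max_um:.1f} um above the substratum)"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    b = img_cfg.substratum_row
    s = b - np.round(t / img_cfg.axial_pixel_um).astype(int)
    rows = np.arange(img_cfg.n_rows)[:, None]
    img = np.full((img_cfg.n_rows, img_cfg.n_cols), float(img_cfg.water_level))
    img[(rows >= s[None, :]) & (rows < b)] = img_cfg.biofilm_level
    img[b:, :] = img_cfg.substratum_level

    boxes: list[MaskBox] = []
    if img_cfg.artifact_rate > 0:
        n_art = rng.poisson(img_cfg.artifact_rate)
        top_clearance = int(s.min())
        for _ in range(n_art):
            r_rad = int(rng.integers(4, 12))
            c_rad = int(rng.integers(8, 30))
            if top_clearance - 2 * r_rad - 8 <= 4:
                continue  # no free water column to float in
            cr = int(rng.integers(4 + r_rad, top_clearance - r_rad - 4))
            cc = int(rng.integers(0, img_cfg.n_cols))
            rr = np.arange(img_cfg.n_rows)[:, None]
            ccol = np.arange(img_cfg.n_cols)[None, :]
            blob = ((rr - cr) / r_rad) ** 2 + ((ccol - cc) / c_rad) ** 2 <= 1.0
            img[blob] = img_cfg.biofilm_level
            boxes.append(
                MaskBox(
                    max(cr - r_rad - 1, 0),
                    min(cr + r_rad + 2, img_cfg.n_rows),
                    max(cc - c_rad - 1, 0),
                    min(cc + c_rad + 2, img_cfg.n_cols),
                )
            )

    if img_cfg.noise_sd > 0:
        img += rng.normal(0.0, img_cfg.noise_sd, size=img.shape)

    return BScanImage(
        data=np.clip(np.round(img), 0, 255).astype(np.uint8),
        axial_pixel_um=img_cfg.axial_pixel_um,
        lateral_pixel_um=img_cfg.lateral_pixel_um,
        truth_surface_rows=s,
        truth_substratum_rows=np.full(img_cfg.n_cols, b),
        artifact_boxes=boxes,
        label=label,
    )


def render_hose(
    field: ThicknessField,
    img_cfg: ImagingConfig,
    layout: HoseLayout | None = None,
    seed: int = 0,
) -> Iterator[tuple[str, int, int, BScanImage]]:
    """Yield every B-scan of the hose as (half, piece, image, BScanImage).

    Pieces and images are 1-based; images advance in the flow direction in
    steps of one image length.  Each image has its own RNG substream.
    """
    layout = layout or HoseLayout()
    for hi, half in enumerate(layout.halves):
        for piece in range(1, layout.n_pieces + 1):
            for im in range(1, layout.images_per_piece + 1):
                g = (piece - 1) * layout.images_per_piece + (im - 1)
                start_mm = g * img_cfg.image_length_mm
                t = field.column_thickness(
                    half, start_mm, img_cfg.n_cols, img_cfg.lateral_pixel_um
                )
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), _STREAMS["images"], hi, g])
                )
                yield half, piece, im, render_bscan(
                    t, img_cfg, rng, label=f"{half}_{piece:02d}_{im:02d}"
                )


# ---------------------------------------------------------------------------
# whole-hose simulation
# ---------------------------------------------------------------------------

def simulate_hose(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ThicknessField]:
    """Generate one complete synthetic hose.

    Returns ``(section_table, community_table, thickness_field)``.  The
    section table has one row per 1.2 cm section (200 by default) with the
    true section-mean thickness, the TCC draw, and a ``missing`` flag marking
    sections whose community data was dropped.
    """
    field = generate_thickness_field(cfg)
    tcc = generate_tcc(field, cfg)
    community = generate_community(cfg)

    ids = section_ids(cfg)
    k = cfg.sections_per_half
    pos = cfg.section_positions_cm()
    thickness = field.section_mean_series()
    table = pd.DataFrame(
        {
            "section_id": ids,
            "half": [h for h in HALVES for _ in range(k)],
            "section_index": list(range(1, k + 1)) * 2,
            "position_cm": np.concatenate([pos, pos]),
            "true_thickness_um": thickness,
            "tcc_cells_per_cm2": tcc,
            "missing": [sid not in community.columns for sid in ids],
        }
    )
    logger.info(
        "simulated hose: %d sections, %d taxa, %d sections missing",
        len(table),
        community.shape[0],
        int(table["missing"].sum()),
    )
    return table, community, field
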