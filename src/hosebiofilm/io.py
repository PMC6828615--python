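"""File formats: section tables, taxa tables, configs, and B-scan TIFFs.

All tabular writers emit plain UTF-8 TSV with "." decimals and no thousands
separators; readers validate the declared columns and report malformed cells
by row and column.  Configs round-trip through YAML.  B-scans are single-page
grayscale TIFFs named ``{half}_{piece:02d}_{image:02d}.tif``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import (
    DetectionConfig,
    HoseLayout,
    ImagingConfig,
    SimulationConfig,
)
from .images import BScanImage
from .synthetic import parse_section_id

logger = logging.getLogger(__name__)

SECTION_COLUMNS = [
    "section_id",
    "half",
    "position_cm",
    "true_thickness_um",
    "tcc_cells_per_cm2",
    "missing",
]
_NUMERIC_SECTION_COLUMNS = ["position_cm", "true_thickness_um", "tcc_cells_per_cm2"]


def write_section_table(table: pd.DataFrame, path) -> None:
    """Write a per-section table as TSV (declared columns first, extras kept)."""
    missing = [c for c in SECTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"section table lacks required columns {missing}")
    extras = [c for c in table.columns if c not in SECTION_COLUMNS]
    out = table[SECTION_COLUMNS + extras].copy()
    out["missing"] = out["missing"].astype(bool)
    out.to_csv(path, sep="\t", index=False)


def read_section_table(path) -> pd.DataFrame:
    """Read and validate a per-section TSV table.

    Required columns: section_id, half, position_cm, true_thickness_um,
    tcc_cells_per_cm2, missing.  Unknown columns are preserved.  Malformed
    numeric cells are rejected with a diagnostic naming the cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC_SECTION_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} in column "
                f"{col!r}, row {row + 2} (1-based incl. header)"
            )
        df[col] = parsed
    df["missing"] = df["missing"].str.strip().str.lower().isin(("true", "1", "yes"))
    for col in df.columns:  # best-effort numeric parse of extra columns
        if col in SECTION_COLUMNS:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        if not parsed.isna().any():
            df[col] = parsed
    for sid in df["section_id"]:
        parse_section_id(sid)
    return df


def write_taxa_table(table: pd.DataFrame, path, label: str = "taxon") -> None:
    """Write the taxa x section count table as TSV (first column = labels)."""
    out = table.copy()
    out.index.name = label
    out.to_csv(path, sep="\t")


def read_taxa_table(path) -> pd.DataFrame:
    """Read a taxa x section count TSV (first column taxon label, int counts).

    Rejects duplicate taxon labels and non-integer counts with diagnostics.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate taxon labels {dupes[:5]}")
    for col in df.columns:
        parse_section_id(col)
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            taxon = df.index[int(np.flatnonzero(parsed.isna())[0])]
            raise ValueError(
                f"{path}: non-numeric count for taxon {taxon!r}, section {col!r}"
            )
        df[col] = parsed
    vals = df.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)


_CONFIG_SECTIONS = {
    "simulation": SimulationConfig,
    "imaging": ImagingConfig,
    "detection": DetectionConfig,
    "layout": HoseLayout,
}


def save_config(path, **configs) -> None:
    """Save config objects to one YAML file, keyed by kind.

    Accepts any of ``simulation=``, ``imaging=``, ``detection=``,
    ``layout=``.
    """
    doc = {}
    for key, obj in configs.items():
        if key not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section {key!r}")
        doc[key] = obj.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_config(path) -> dict:
    """Load a YAML config file back into config objects (dict by kind)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out = {}
    for key, payload in doc.items():
        if key not in _CONFIG_SECTIONS:
            raise ValueError(f"{path}: unknown config section {key!r}")
        out[key] = _CONFIG_SECTIONS[key].from_dict(payload)
    return out


def bscan_filename(half: str, piece: int, image: int) -> str:
    return f"{half}_{piece:02d}_{image:02d}.tif"


def write_bscan(image: BScanImage, path) -> None:
    """Write one B-scan as a single-page grayscale TIFF."""
    tifffile.imwrite(path, image.data, photometric="minisblack")


def read_bscan(path, img_cfg: ImagingConfig | None = None) -> BScanImage:
    """Read a grayscale TIFF back into a :class:`BScanImage`.

    Pixel sizes come from ``img_cfg`` (defaults if omitted); ground truth is
    of course absent for images read from disk.
    """
    cfg = img_cfg or ImagingConfig()
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-page grayscale image")
    return BScanImage(
        data=data,
        axial_pixel_um=cfg.axial_pixel_um,
        lateral_pixel_um=cfg.lateral_pixel_um,
        label=Path(path).stem,
    )
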