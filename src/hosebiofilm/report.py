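"""Run report: every statistic of the pipeline for one hose, with provenance.

``run_report`` consumes a section table (and optionally a community table)
and produces a plain nested dict -- trends, adjacent-section variation,
fold ranges, top-vs-bottom contrast, diversity, dominance, adjacent
Bray-Curtis, volume reconstruction, and the sampling-representativeness
curve -- ready to serialize as JSON.  Regenerating with the same config and
seed yields an identical report (provenance records the config hash).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .config import HALVES, SimulationConfig, config_hash
from .community import (
    adjacent_dissimilarity,
    diversity,
    dominant_taxa,
    relative_abundance,
    abundance_covariate_correlation,
)
from .heterogeneity import (
    adjacent_variation,
    fold_range,
    group_compare,
    longitudinal_trend,
    representativeness_curve,
)
from .volume import volume_summary

DEFAULT_WINDOW_SIZES = (1, 2, 5, 10, 25, 50, 100)


def _round(x, nd=6):
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    return x


def _series_stats(values: np.ndarray, positions: np.ndarray) -> dict:
    trend = longitudinal_trend(values, positions)
    av = adjacent_variation(values)
    ok = values[~np.isnan(values)]
    return {
        "mean": _round(float(ok.mean())),
        "sd": _round(float(ok.std(ddof=1))),
        "n": int(ok.size),
        "min": _round(float(ok.min())),
        "max": _round(float(ok.max())),
        "fold_range": _round(fold_range(ok)) if ok.min() > 0 else None,
        "trend": {
            "slope_per_cm": _round(trend.slope),
            "r_squared": _round(trend.r_squared),
            "percent_increase": _round(trend.percent_increase),
        },
        "adjacent_variation_pct": {
            "mean": _round(av.mean),
            "sd": _round(av.sd),
            "n_pairs": av.n_pairs,
        },
    }


def run_report(
    section_table: pd.DataFrame,
    community_table: pd.DataFrame | None = None,
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    thickness_column: str = "true_thickness_um",
    window_sizes=DEFAULT_WINDOW_SIZES,
) -> dict:
    """Compute the full per-hose statistics report as a nested dict."""
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": seed if seed is not None else (cfg.seed if cfg else None),
            "config_hash": config_hash(cfg) if cfg is not None else None,
            "n_sections": int(len(section_table)),
        }
    }

    halves = {
        h: section_table[section_table["half"] == h].sort_values("section_index")
        for h in HALVES
    }
    thick = {h: halves[h][thickness_column].to_numpy(float) for h in HALVES}
    tcc = {h: halves[h]["tcc_cells_per_cm2"].to_numpy(float) for h in HALVES}
    pos = {h: halves[h]["position_cm"].to_numpy(float) for h in HALVES}

    report["thickness_um"] = {
        h: _series_stats(thick[h], pos[h]) for h in HALVES if len(halves[h])
    }
    all_thick = np.concatenate([thick[h] for h in HALVES])
    report["thickness_um"]["overall"] = {
        "mean": _round(float(np.nanmean(all_thick))),
        "sd": _round(float(np.nanstd(all_thick, ddof=1))),
        "n": int(np.sum(~np.isnan(all_thick))),
    }
    cmp_tb = group_compare(thick["bottom"], thick["top"])
    report["thickness_um"]["bottom_vs_top"] = {
        "t": _round(cmp_tb.t),
        "p": _round(cmp_tb.p, 9),
        "mean_bottom": _round(cmp_tb.mean_a),
        "mean_top": _round(cmp_tb.mean_b),
    }

    report["tcc_cells_per_cm2"] = {
        h: _series_stats(tcc[h], pos[h]) for h in HALVES if len(halves[h])
    }
    all_tcc = np.concatenate([tcc[h] for h in HALVES])
    report["tcc_cells_per_cm2"]["overall"] = {
        "mean": _round(float(np.nanmean(all_tcc))),
        "sd": _round(float(np.nanstd(all_tcc, ddof=1))),
        "fold_range": _round(fold_range(all_tcc[~np.isnan(all_tcc)])),
    }
    report["tcc_thickness_correlation"] = {
        h: dict(
            zip(
                ("pearson_r", "r_squared"),
                map(_round, abundance_covariate_correlation(thick[h], tcc[h])),
            )
        )
        for h in HALVES
    }

    rep = representativeness_curve(
        all_thick, [k for k in window_sizes if k <= all_thick.size]
    )
    report["representativeness_thickness"] = {
        str(k): _round(v) for k, v in rep.as_dict().items()
    }

    report["volume"] = {
        "overall": volume_summary(
            float(np.nanmean(all_thick)),
            float(np.nanmean(all_tcc)),
            all_tcc,
        ).__dict__
    }
    for h in HALVES:
        report["volume"][h] = volume_summary(
            float(np.nanmean(thick[h])), float(np.nanmean(tcc[h])), tcc[h]
        ).__dict__
    for v in report["volume"].values():
        for k in v:
            v[k] = _round(v[k], 4) if isinstance(v[k], float) else v[k]

    if community_table is not None and not community_table.empty:
        pooled = diversity(community_table, level="pooled")
        per_sec = diversity(community_table, level="per_section")
        dom = dominant_taxa(community_table)
        bc = adjacent_dissimilarity(community_table)
        report["community"] = {
            "pooled": {
                "richness": pooled.richness,
                "shannon": _round(pooled.shannon),
                "pielou": _round(pooled.pielou),
                "total_reads": pooled.n_reads,
            },
            "per_section_richness": {
                "mean": _round(float(per_sec["richness"].mean())),
                "sd": _round(float(per_sec["richness"].std(ddof=1))),
                "min": int(per_sec["richness"].min()),
                "max": int(per_sec["richness"].max()),
            },
            "per_section_pielou": {
                "min": _round(float(per_sec["pielou"].min())),
                "max": _round(float(per_sec["pielou"].max())),
            },
            "dominance": {
                "n_dominant": len(dom.taxa),
                "taxa": dom.taxa,
                "top3_share_pct": _round(float(dom.cumulative_top_pct[2]))
                if len(dom.taxa) >= 3
                else None,
                "dominant_share_pct": _round(float(dom.cumulative_top_pct[-1]))
                if len(dom.taxa)
                else None,
            },
            "adjacent_bray_curtis": {
                "mean": _round(bc.mean),
                "sd": _round(bc.sd),
                "min": _round(float(bc.records["bray_curtis"].min())),
                "max": _round(float(bc.records["bray_curtis"].max())),
                "n_pairs": bc.n_pairs,
            },
        }
        rel = relative_abundance(community_table)
        cors = {}
        aligned = section_table.set_index("section_id")
        for taxon in dom.taxa[:3]:
            ab = rel.loc[taxon].reindex(aligned.index)
            r_t, r2_t = abundance_covariate_correlation(
                ab.to_numpy(float), aligned[thickness_column].to_numpy(float)
            )
            r_c, r2_c = abundance_covariate_correlation(
                ab.to_numpy(float), aligned["tcc_cells_per_cm2"].to_numpy(float)
            )
            cors[taxon] = {
                "thickness_r2": _round(r2_t),
                "tcc_r2": _round(r2_c),
            }
        report["community"]["taxon_covariate_r2"] = cors

    return report
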