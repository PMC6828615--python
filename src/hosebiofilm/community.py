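"""Diversity and dominance analysis of the taxa x section count table.

The community table is a pandas DataFrame of non-negative integer read
counts with taxon labels (ZOTU/ASV ids or assigned names) as the index and
section ids (``top_001`` ... ``bottom_100``) as columns.  Sections lost to
failed amplification are simply absent columns; adjacency-aware statistics
reconstruct the gap structure from the section ids and never pair sections
across a gap (or across the top/bottom cut).

Conventions: Shannon H' uses the natural logarithm, so Pielou evenness
J' = H'/ln S lies in [0, 1]; adjacent-section Bray-Curtis is computed on
relative abundances by default (raw counts optional); the dominance
threshold (>= 1% of reads by default) applies to the pooled table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis

from .config import HALVES
from .synthetic import parse_section_id

__all__ = [
    "DiversitySummary",
    "DominanceSummary",
    "relative_abundance",
    "diversity",
    "bray_curtis",
    "adjacent_dissimilarity",
    "dominant_taxa",
    "abundance_covariate_correlation",
    "ordered_sections",
]


def _check_counts(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("empty community table")
    vals = table.to_numpy()
    if np.any(vals < 0):
        raise ValueError("counts must be non-negative")


def ordered_sections(table: pd.DataFrame) -> list[str]:
    """Section columns sorted canonically (top 1..K, then bottom 1..K)."""
    order = {h: i for i, h in enumerate(HALVES)}
    return sorted(table.columns, key=lambda c: (order[parse_section_id(c)[0]],
                                                parse_section_id(c)[1]))


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion table: every section column sums to 1.

    All-zero columns (no reads) are returned as NaN -- they behave as
    missing sections downstream.
    """
    _check_counts(table)
    sums = table.sum(axis=0).astype(float)
    sums[sums == 0] = np.nan
    return table / sums


@dataclass
class DiversitySummary:
    """Richness S, Shannon H' (natural log) and Pielou evenness J'."""

    richness: int
    shannon: float
    pielou: float
    n_reads: int


def _diversity_one(counts: np.ndarray, base: float | None = None) -> DiversitySummary:
    counts = counts[counts > 0]
    s = int(counts.size)
    if s == 0:
        return DiversitySummary(0, np.nan, np.nan, 0)
    h = float(stats.entropy(counts, base=base))  # normalizes internally
    log_s = np.log(s) if base is None else np.log(s) / np.log(base)
    j = 0.0 if s == 1 else float(h / log_s)
    return DiversitySummary(s, h, j, int(counts.sum()))


def diversity(
    table: pd.DataFrame, level: str = "pooled", base: float | None = None
) -> DiversitySummary | pd.DataFrame:
    """Alpha diversity of the count table.

    ``level='pooled'`` sums reads over all sections first and returns one
    :class:`DiversitySummary`; ``level='per_section'`` returns a DataFrame
    (rows = section ids) with columns richness/shannon/pielou/n_reads.
    ``base`` switches the Shannon logarithm (natural log by default; J' is
    base-invariant).  Empty sections come back as richness 0 with NaN
    indices (missing).
    """
    _check_counts(table)
    if level == "pooled":
        return _diversity_one(table.sum(axis=1).to_numpy(dtype=float), base)
    if level != "per_section":
        raise ValueError(f"unknown level {level!r}")
    rows = {
        sid: _diversity_one(table[sid].to_numpy(dtype=float), base)
        for sid in table.columns
    }
    return pd.DataFrame(
        {
            "richness": {k: v.richness for k, v in rows.items()},
            "shannon": {k: v.shannon for k, v in rows.items()},
            "pielou": {k: v.pielou for k, v in rows.items()},
            "n_reads": {k: v.n_reads for k, v in rows.items()},
        }
    )


def bray_curtis(p, q, use: str = "proportions") -> float:
    """Bray-Curtis dissimilarity between two sections.

    ``BC = 1 - 2 * sum(min(p_i, q_i)) / (sum(p) + sum(q))``; with
    ``use='proportions'`` (default) counts are normalized first so
    sequencing depth does not enter; ``use='counts'`` applies the formula to
    raw counts.  Returns NaN (flagged undefined) when both sections are
    empty.
    """
    if use not in ("proportions", "counts"):
        raise ValueError(f"unknown mode {use!r}")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("sections must share the same taxon indexing")
    if p.sum() == 0 and q.sum() == 0:
        return np.nan
    if use == "proportions":
        if p.sum() == 0 or q.sum() == 0:
            return np.nan
        p = p / p.sum()
        q = q / q.sum()
    return float(_braycurtis(p, q))


@dataclass
class DissimilaritySeries:
    """Adjacent-section Bray-Curtis records with their summary."""

    records: pd.DataFrame  # columns: section_a, section_b, bray_curtis
    mean: float
    sd: float
    n_pairs: int


def adjacent_dissimilarity(
    table: pd.DataFrame, use: str = "proportions"
) -> DissimilaritySeries:
    """Bray-Curtis between every pair of adjacent retained sections.

    Pairs are consecutive section indices within the same half; a missing
    section (absent column) breaks adjacency, so no pair spans a gap.
    """
    _check_counts(table)
    cols = ordered_sections(table)
    if len(cols) < 2:
        raise ValueError("need at least 2 non-missing sections")
    recs = []
    for ca, cb in zip(cols[:-1], cols[1:]):
        ha, ia = parse_section_id(ca)
        hb, ib = parse_section_id(cb)
        if ha == hb and ib == ia + 1:
            recs.append(
                (ca, cb, bray_curtis(table[ca].to_numpy(), table[cb].to_numpy(), use))
            )
    records = pd.DataFrame(recs, columns=["section_a", "section_b", "bray_curtis"])
    bc = records["bray_curtis"].dropna()
    return DissimilaritySeries(
        records=records,
        mean=float(bc.mean()) if len(bc) else np.nan,
        sd=float(bc.std(ddof=1)) if len(bc) > 1 else 0.0,
        n_pairs=int(len(records)),
    )


@dataclass
class DominanceSummary:
    """Taxa holding at least ``threshold`` of all pooled reads."""

    taxa: list[str]  # ordered by total reads (desc), ties by label
    share_pct: pd.Series  # overall relative abundance (%) per dominant taxon
    cumulative_top_pct: np.ndarray  # cumulative share of top 1..N dominants
    threshold_pct: float
    total_reads: int


def dominant_taxa(table: pd.DataFrame, threshold: float = 0.01) -> DominanceSummary:
    """Select dominant taxa at a pooled read-share threshold (default 1%)."""
    _check_counts(table)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = table.sum(axis=1)
    grand = float(totals.sum())
    if grand == 0:
        return DominanceSummary([], pd.Series(dtype=float), np.array([]), threshold * 100, 0)
    share = totals / grand
    ranked = share[totals > 0].sort_index().sort_values(ascending=False, kind="stable")
    dominant = ranked[ranked >= threshold]
    return DominanceSummary(
        taxa=list(dominant.index),
        share_pct=dominant * 100.0,
        cumulative_top_pct=np.cumsum(dominant.to_numpy()) * 100.0,
        threshold_pct=threshold * 100.0,
        total_reads=int(grand),
    )


def abundance_covariate_correlation(taxon_series, covariate_series) -> tuple[float, float]:
    """Pearson r (and R^2) between a taxon's relative abundance and a covariate.

    Inputs are aligned per-section series (NaN = missing); only sections
    present in both enter.  Returns ``(nan, nan)`` (flagged undefined) when
    either aligned series has zero variance.
    """
    x = np.asarray(taxon_series, dtype=float)
    y = np.asarray(covariate_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be aligned")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 aligned non-missing sections")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r
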