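"""Spatial-heterogeneity statistics for per-section series.

Operates on any per-section quantity (thickness, TCC, richness, relative
abundance of one taxon, ...) laid out in longitudinal order.  Missing
sections are NaN entries; they break adjacency, so no pair of adjacent
sections and no aggregation window may span a gap.

Statistics across scales:

* ``micro_scale_variation`` -- (max-min)/max within one section's column
  profile (um scale),
* ``adjacent_variation`` -- percent difference between consecutive
  cm-sections (the small-scale statistic),
* ``fold_range``, ``longitudinal_trend``, ``group_compare`` -- whole-hose
  (m-scale) summaries,
* ``representativeness_curve`` -- how fast aggregated multi-section samples
  approach the whole-system mean (sampling-strategy simulation),
* ``window_contrast`` -- mean +/- sd contrast between two section spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AdjacentVariation",
    "TrendSummary",
    "GroupComparison",
    "RepresentativenessCurve",
    "WindowContrast",
    "adjacent_variation",
    "micro_scale_variation",
    "fold_range",
    "longitudinal_trend",
    "group_compare",
    "representativeness_curve",
    "window_contrast",
]


def _clean(series) -> np.ndarray:
    return np.asarray(series, dtype=float)


@dataclass
class AdjacentVariation:
    """Percent variation between consecutive non-missing sections."""

    per_pair: np.ndarray
    mean: float
    sd: float
    n_pairs: int
    n_undefined: int = 0  # pairs whose mean is zero (excluded but counted)


def adjacent_variation(series, denominator: str = "pair_mean") -> AdjacentVariation:
    """Variation between adjacent sections, in percent.

    For each pair of consecutive non-missing sections the variation is
    ``|x_{i+1} - x_i| / m * 100`` with ``m`` the pair mean (symmetric
    default) or the first value (``denominator='first'``).  Pairs spanning a
    missing section are skipped; pairs with a zero denominator are excluded
    from the mean but counted in ``n_undefined``.
    """
    if denominator not in ("pair_mean", "first"):
        raise ValueError(f"unknown denominator {denominator!r}")
    x = _clean(series)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing sections")
    pair_ok = ok[:-1] & ok[1:]
    a, b = x[:-1][pair_ok], x[1:][pair_ok]
    denom = (a + b) / 2.0 if denominator == "pair_mean" else a
    defined = denom != 0
    per_pair = np.abs(b - a)[defined] / denom[defined] * 100.0
    return AdjacentVariation(
        per_pair=per_pair,
        mean=float(per_pair.mean()) if per_pair.size else np.nan,
        sd=float(per_pair.std(ddof=1)) if per_pair.size > 1 else 0.0,
        n_pairs=int(per_pair.size),
        n_undefined=int((~defined).sum()),
    )


def micro_scale_variation(profile) -> float:
    """Within-section variation (%): (max - min) / max over detected columns.

    ``profile`` is a per-column thickness profile (NaN = undetected).
    Returns NaN (undefined) when the maximum is zero.
    """
    x = _clean(profile)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least 2 detected columns")
    if x.max() == 0:
        return np.nan
    return float((x.max() - x.min()) / x.max() * 100.0)


def fold_range(series) -> float:
    """max/min of a strictly positive series (e.g., the 3-fold TCC range)."""
    x = _clean(series)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty series")
    if x.min() <= 0:
        raise ValueError("fold range requires strictly positive values")
    return float(x.max() / x.min())


@dataclass
class TrendSummary:
    """OLS summary of a longitudinal trend along the hose."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    percent_increase: float  # fitted end vs fitted start, % (NaN if undefined)
    ci95_slope: tuple[float, float]
    n: int


def longitudinal_trend(series, positions_cm) -> TrendSummary:
    """Ordinary least-squares fit of a per-section series against position.

    ``percent_increase`` compares the fitted values at the first and last
    positions: ``(fit(L) - fit(0)) / fit(0) * 100``; it is NaN (flagged)
    when the fitted start is <= 0.
    """
    y = _clean(series)
    x = _clean(positions_cm)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend")
    res = stats.linregress(x, y)
    fit0 = res.intercept + res.slope * x.min()
    fitL = res.intercept + res.slope * x.max()
    pct = (fitL - fit0) / fit0 * 100.0 if fit0 > 0 else np.nan
    tcrit = stats.t.ppf(0.975, x.size - 2)
    return TrendSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        percent_increase=float(pct),
        ci95_slope=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        n=int(x.size),
    )


@dataclass
class GroupComparison:
    """Welch two-sample t-test with group summaries."""

    t: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def group_compare(a, b) -> GroupComparison:
    """Welch t-test between two groups of sections (e.g., top vs bottom)."""
    a = _clean(a)
    b = _clean(b)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0  # degenerate: identical constants
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t=float(t),
        p=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )


@dataclass
class RepresentativenessCurve:
    """Mean |window mean - global mean| / global mean (%) per window size."""

    window_sizes: np.ndarray
    deviation_pct: np.ndarray
    n_windows: np.ndarray
    mode: str = "sliding"

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.window_sizes.tolist(), self.deviation_pct.tolist()))


def representativeness_curve(
    series, window_sizes, mode: str = "sliding"
) -> RepresentativenessCurve:
    """Simulate larger sample sizes by averaging k adjacent sections.

    For each window size k, every run of k adjacent non-missing sections
    (sliding by default, disjoint optional) is averaged and compared with the
    global mean over all non-missing sections; the curve reports the mean
    absolute relative deviation in percent.  Windows never span a gap.  At
    k = series length (complete series) the deviation is exactly 0.
    """
    if mode not in ("sliding", "disjoint"):
        raise ValueError(f"unknown mode {mode!r}")
    x = _clean(series)
    ok = ~np.isnan(x)
    gmean = x[ok].mean() if ok.any() else np.nan
    if not np.isfinite(gmean) or gmean == 0:
        raise ValueError("global mean is zero or undefined")
    ks = np.asarray(sorted(set(int(k) for k in window_sizes)))
    if np.any(ks < 1) or np.any(ks > x.size):
        raise ValueError("window sizes must lie in [1, series length]")
    dev = np.full(ks.size, np.nan)
    nw = np.zeros(ks.size, dtype=int)
    for j, k in enumerate(ks):
        starts = range(0, x.size - k + 1, 1 if mode == "sliding" else k)
        means = [
            x[i : i + k].mean() for i in starts if ok[i : i + k].all()
        ]
        if means:
            means = np.asarray(means)
            dev[j] = float(np.mean(np.abs(means - gmean) / abs(gmean)) * 100.0)
            nw[j] = len(means)
    return RepresentativenessCurve(
        window_sizes=ks, deviation_pct=dev, n_windows=nw, mode=mode
    )


@dataclass
class WindowContrast:
    """Mean +/- sd in two section spans and their difference (b - a)."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    difference: float


def window_contrast(series, range_a, range_b) -> WindowContrast:
    """Contrast two non-overlapping section spans of a per-section series.

    Ranges are (start, stop) half-open 0-based indices into the series.
    Missing sections are dropped within each range; a range left empty (or
    with a single value) after removal is rejected.
    """
    x = _clean(series)
    (a0, a1), (b0, b1) = range_a, range_b
    if not (0 <= a0 < a1 <= x.size and 0 <= b0 < b1 <= x.size):
        raise ValueError("ranges out of bounds")
    if max(a0, b0) < min(a1, b1):
        raise ValueError("ranges overlap")
    va = x[a0:a1]
    vb = x[b0:b1]
    va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
    if va.size < 2 or vb.size < 2:
        raise ValueError("each range needs at least 2 non-missing sections")
    return WindowContrast(
        mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)),
        n_a=int(va.size),
        mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)),
        n_b=int(vb.size),
        difference=float(vb.mean() - va.mean()),
    )
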