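# Methods

This note documents the models, parameter choices and numerical conventions
behind `hosebiofilm`, in the spirit of a simulator's model documentation:
what is simulated, what is measured, which knobs matter, and what the
synthetic data can and cannot tell you about real hoses.

## 1. The measurement setting being emulated

A 120 cm piece of flexible hose is cut into 20 × 6 cm pieces, bisected
longitudinally into *top* and *bottom* halves, imaged with OCT (B-scans of
2 mm length × 1 mm depth, 30 per piece ⇒ 1,200 per hose), then cut into
5 × 1.2 cm sections per piece (⇒ 200 "cm-sections" per hose).  Each section
yields a thickness mean (6 images), a TCC value (flow cytometry, cells/cm²)
and a ZOTU read-count vector (16S amplicon sequencing).  Sections are
indexed 1–100 per half from the upstream end; positions are section
midpoints in cm.  All layout arithmetic lives in `HoseLayout` and is
validated at construction.

## 2. Thickness field

Per half, the ground-truth field on a 1 mm grid over [0, 120] cm is

    T(x) = trend(x) · (1 + s·η(x)),   trend(x) = baseline + slope·x,

with η Gaussian white noise smoothed by a Gaussian kernel of
σ = `topo_wavelength_mm`/2 (the "hills and dunes" topography), clipped to
[0, `max_thickness_um`].  Noise is *proportional to the local trend level*
— thicker biofilm carries proportionally larger hills — which keeps the
relative small-scale variation stationary along a trending hose.

The scale factor `s` is calibrated per draw so that the **expected
adjacent-section variation statistic equals `smallscale_cv`**: with section
means M_j, E|M_{j+1}−M_j| / level = √(2/π)·sd(ΔM)/level, so the smoothed
noise is rescaled to sd(ΔM) = `smallscale_cv`·√(π/2)·level.  `smallscale_cv`
is therefore directly the targeted adjacent-variation level (0.12 ⇒ ≈12 %).

Parameter defaults (control-hose preset; all exposed):

| parameter | default | rationale |
|---|---|---|
| baseline (µm) | top 202.2, bottom 258.2 | half means 252/386 µm at mid-hose given the slopes |
| slope (µm/cm) | top 0.83, bottom 2.13 | reported longitudinal trends |
| smallscale_cv | top 0.12, bottom 0.24 | reported adjacent variation 11.7 %/23.9 % |
| topo_wavelength_mm | 6 | mm-scale protrusions; short enough that adjacent 1.2 cm section means are effectively independent, so per-section OLS confidence intervals are valid (≥90 % coverage over seeded replicates) |
| max_thickness_um | 850 | physical ceiling: the biofilm must stay inside the 1 mm OCT imaging depth (substratum at 90 % depth) |

Section means of the field are exact trapezoidal averages over each
1.2 cm span (section boundaries coincide with grid knots at the default
resolution), which makes the field-vs-image round trip well defined.

## 3. TCC

Per section, with z_T the standardized section-mean thickness of the whole
hose and z an independent standard normal draw:

    TCC = tcc_mean · (1 + tcc_cv·(ρ·z_T + √(1−ρ²)·z)),  clipped at 0,

so the sample Pearson r(TCC, thickness) → ρ (`tcc_thickness_corr`, default
0.4: "weak", between the two reported half-wise values) and the realized CV
→ `tcc_cv` (default 0.2, matching a mean of 2.4×10⁷ ± 0.5×10⁷ cells/cm²).
Standardizing across the whole hose (not per half) reproduces the reported
asymmetry: the thinner top half inherits slightly lower TCC.

## 4. Community table

Expected per-section proportions are assembled in four steps and then
sampled multinomially at `reads_per_section` (default 50,000):

1. **Base profile.**  Three named dominants (24.7 %, 23.4 %, 9.6 %); the
   remainder is a geometric rank-abundance tail (`geometric_ratio` 0.81
   over `n_geometric` 110 ranks) plus a uniform **rare floor**
   (`rare_mass` 4×10⁻⁴ spread over all leftover taxa, `n_taxa` 384 total).
   A pure geometric tail cannot satisfy per-section richness ~55–92 at
   5×10⁴ reads *and* pooled richness of several hundred simultaneously;
   the rare floor carries the pooled richness (each rare taxon is seen a
   few times per hose but rarely per section).  At these defaults the
   generator realizes top-10 dominance ≈ 89 %, pooled J′ ≈ 0.41,
   per-section richness ≈ 65 and pooled richness ≈ 340.
2. **Spatial wobble.**  Each taxon's abundance is multiplied by
   exp(σ·w − σ²/2) with w a per-taxon unit-variance field smoothed over
   `wobble_window_sections` (5) sections within each half
   (σ = `taxon_wobble_sd`, 0.55).  This supplies the spatial
   autocorrelation and drives adjacent-section Bray–Curtis to ≈ 0.15.
3. **Anti-correlated pair.**  The two leading dominants share one smooth
   field f with opposite signs, exp(±s·f) (strength 0.6), reproducing the
   reported negative correlation between them.
4. **Step changes.**  `(taxon, half, first, last, delta)` entries add
   `delta` to that taxon's expected proportion on those sections and
   rescale the others, so a window contrast recovers `delta` exactly in
   expectation (default: +0.081 for the third dominant on top sections
   81–91).

Whole sections are dropped with `missing_section_prob` (default 0.025,
emulating failed DNA amplification); dropped sections are absent columns,
never imputed, and all adjacency-aware statistics refuse to pair across the
resulting gaps.

## 5. B-scan rendering and thickness extraction

Rendering: 8-bit grayscale, row 0 at the probe (water ≈30, biofilm ≈120,
substratum ≈220 — arbitrary but fixed so tests are stable); the substratum
interface sits at 90 % of the imaging depth and the surface
`round(T/axial_pixel)` rows above it (axial 2 µm/px, lateral 4 µm/px).
Optional additive Gaussian speckle (`noise_sd`) and Poisson-distributed
floating-debris blobs (`artifact_rate`) whose bounding boxes are recorded —
the synthetic stand-in for structures an operator would mask by hand.

Extraction, per column (A-scan):

1. axial 5-px moving average, centred finite-difference gradient;
2. threshold = max(5 × background-gradient SD from the top 16 water rows,
   4.0), required over **2 consecutive rows** — a first-crossing search
   scans hundreds of water rows, so a lower single-row threshold
   false-triggers on speckle (a 3σ single-row rule fails in roughly a third
   of columns at speckle SD 8);
3. surface = first qualifying row; substratum = strongest gradient ≥3 rows
   deeper (coinciding with the surface when nothing qualifies, i.e. zero
   measurable biofilm);
4. both interfaces snap to the strongest raw single-pixel intensity step
   within ±3 rows, which makes noise-free step edges exact.

Thickness = (substratum − surface) × axial pixel.  Columns below the
4.4 µm axial detection limit are *censored* and count as limit/2 in the
image mean (configurable to `exclude`; the averaging of sub-limit regions
is a genuine free choice — limit/2 is the unbiased point estimate under a
uniform prior on [0, limit)).  Undetected columns are excluded; an image
with >50 % undetected columns is flagged and dropped from its section mean,
mirroring the manual-repair path of real OCT workflows (explicit per-range
overrides are available as `manual_overrides`).  Six image means average
into each 1.2 cm section, unweighted.

## 6. Statistics conventions

* Adjacent variation uses the symmetric pair mean as denominator (the
  first-value variant is an option); zero-denominator pairs are excluded
  but counted.
* µm-scale variation is (max−min)/max over a section's detected,
  uncensored columns.
* Trends are ordinary least squares; `percent_increase` compares fitted
  values at the first and last positions and is flagged undefined if the
  fitted start is ≤0.  (Note: a slope of 0.83 µm/cm over 120 cm is an
  absolute increase of ~100 µm; relative and absolute "percent increase"
  must not be conflated.)
* Group contrast is Welch's t; two zero-variance equal groups give p = 1 by
  convention.
* The representativeness curve uses sliding windows by default (maximal use
  of 200 sections); `disjoint` gives strictly independent windows.  Windows
  of non-missing adjacent sections only; at k = n (complete series) the
  deviation is exactly 0.
* Shannon H′ uses the natural log (J′ = H′/ln S; base exposed);
  J′ = 0 by convention at S = 1.  Dominance (≥1 % threshold) applies to the
  pooled table, ties broken lexicographically.  Adjacent Bray–Curtis uses
  relative abundances by default (`use="counts"` available) — sequencing
  depth is equal per section in the simulation but not in general.
* Volume: V_biofilm = T̄ ×10⁸ µm³/cm²; V_cells = TCC × 0.3 µm³ (mean single
  cell volume, configurable); hose totals default to the `unit` area model
  (1 cm² per section), which is the convention under which per-cm² results
  scale to whole-hose totals by ×200; the `geometric` half-shell model
  (1.2 cm × π × 0.4 cm ≈ 1.508 cm² per section) is provided.

## 7. Determinism

One RNG stream per artifact (field / TCC / community / images), split from
the master seed via `SeedSequence([seed, stream, ...])`; regenerating one
artifact never shifts another, every B-scan has its own substream, and a
config + seed determines all outputs bit-exactly (reports embed a config
hash).

## 8. What the synthetic data does *not* emulate — and limitations

* No read-level sequence simulation: no PCR/chimera/primer bias, no
  taxonomy assignment; the generator produces the downstream count table
  directly, with equal depth per retained section.
* Thickness noise is Gaussian and stationary (relative to trend); real
  biofilms show occasional sloughing events and heavier-tailed local jumps.
  Passing round-trip and recovery tests therefore demonstrates correctness
  of the *pipeline*, not that real hoses follow this field model.
* The OCT renderer uses flat substrates, a single axial intensity profile
  and additive speckle; real B-scans have curvature, attenuation with
  depth, and multiplicative speckle.  The detector's parameters are exposed
  (`DetectionConfig`) precisely because real images will need retuning.
* TCC and community are linked to thickness only through the configured
  correlation; no mechanistic growth model is implied.
* The real-hose preset inherits the printed overall mean (9.8 µm) even
  though the source's real-hose thickness summaries are mutually
  inconsistent; all of its values are plain parameters.
* Problem sizes in the test-suite and acceptance script (full 1,200-image
  round trips; 50–400 replicate hoses for recovery statistics) were chosen
  so Monte-Carlo error is small relative to the tolerances being checked
  while a complete run stays in the tens of seconds on one CPU.
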