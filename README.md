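# hosebiofilm

Spatial-heterogeneity analysis of sectioned drinking-water biofilms.

Biofilms in building plumbing (here: the inside of a flexible PVC-P shower
hose) are routinely sampled as a single swab or coupon, yet they are
heterogeneous from the µm to the m scale.  This package re-implements, as a
tested and reusable pipeline, a high-resolution sampling analysis in which a
120 cm hose is bisected longitudinally into *top* and *bottom* halves and
cut into 200 sections of 1.2 cm, each characterized by

* **structure** — biofilm thickness from OCT B-scans (2 mm × 1 mm,
  30 per 6 cm piece, 1,200 per hose), extracted by gray-scale gradient
  analysis of each depth profile;
* **numbers** — total cell concentrations (TCC, cells/cm²) from flow
  cytometry;
* **community** — a ZOTU/ASV read-count table (taxa × sections) from 16S
  rRNA amplicon sequencing.

Because the raw measurements of such studies are rarely deposited, the
package ships a first-class **synthetic hose generator** with known ground
truth that emulates the reported statistical structure (longitudinal trends,
hill-and-dune topography, weak TCC–thickness correlation, a three-taxon
dominated community with spatial autocorrelation, localized step changes,
and randomly missing sections), so every stage of the pipeline is testable
end to end.

## The statistics at its core

For a per-section series \(x_1,\dots,x_n\) (thickness, TCC, richness,
relative abundance, …) laid out along the hose:

* adjacent-section variation
  \(\;100\cdot|x_{i+1}-x_i| / \bar{x}_{i,i+1}\) — the small-scale
  heterogeneity statistic (missing sections break adjacency);
* µm-scale variation \((T_{max}-T_{min})/T_{max}\) within one section's
  OCT column profile;
* fold range \(\max x/\min x\), OLS longitudinal trends, Welch *t*
  top-vs-bottom contrasts, and window contrasts (mean ± sd of two
  11-section spans);
* the representativeness curve: for window size \(k\), the mean of
  \(|\bar{x}_{window} - \bar{x}|/\bar{x}\) over all runs of \(k\) adjacent
  sections — simulating what a single larger sample of length
  \(1.2k\) cm would have reported;
* community metrics: richness \(S\), Shannon \(H' = -\sum p_i\ln p_i\),
  Pielou evenness \(J' = H'/\ln S\), Bray–Curtis dissimilarity
  \(1 - 2\sum\min(p_i,q_i)/(\sum p_i + \sum q_i)\) between adjacent
  sections, dominant taxa at ≥ 1 % of pooled reads, taxa–covariate
  Pearson correlations;
* volume reconstruction: \(V_\mathrm{biofilm} = \bar T \times 10^8\)
  µm³/cm², \(V_\mathrm{cells} = \mathrm{TCC} \times 0.3\) µm³/cm², their
  ratio \(V_\mathrm{cells}{:}V_\mathrm{biofilm}\) in percent, and hose
  totals.

## Worked example

```python
import hosebiofilm as hb

cfg = hb.control_hose_config(seed=1)          # laboratory-grown hose preset
section_table, community, field = hb.simulate_hose(cfg)

top = section_table[section_table.half == "top"]
trend = hb.longitudinal_trend(top.true_thickness_um, top.position_cm)
av = hb.adjacent_variation(top.true_thickness_um)
print(f"top thickness: {top.true_thickness_um.mean():.0f} um, "
      f"slope {trend.slope:.2f} um/cm (R2 {trend.r_squared:.2f})")
print(f"adjacent-section variation: {av.mean:.1f} +/- {av.sd:.1f}% (n={av.n_pairs})")

dom = hb.dominant_taxa(community)
bc = hb.adjacent_dissimilarity(community)
pooled = hb.diversity(community, level="pooled")
print(f"richness S={pooled.richness}, evenness J'={pooled.pielou:.2f}")
print(f"{len(dom.taxa)} dominant taxa; top 3 hold {dom.cumulative_top_pct[2]:.1f}% of reads")
print(f"adjacent Bray-Curtis: {bc.mean:.2f} +/- {bc.sd:.2f} (n={bc.n_pairs})")
```

prints

```
top thickness: 255 um, slope 0.71 um/cm (R2 0.45)
adjacent-section variation: 12.1 +/- 8.3% (n=99)
richness S=340, evenness J'=0.41
14 dominant taxa; top 3 hold 57.5% of reads
adjacent Bray-Curtis: 0.15 +/- 0.06 (n=185)
```

Read: this simulated hose thickens by ~0.7 µm per cm of length (large-scale
trend), yet consecutive 1.2 cm sections already differ by ~12 % (small-scale
heterogeneity).  The community is low-diversity — three taxa carry 57 % of
all reads — while adjacent sections stay compositionally similar
(Bray–Curtis ≈ 0.15).  The 15 sections "lost to amplification" (the
`missing` flag) are visible in the reduced pair count (185 instead of 199).

The OCT side of the pipeline goes the other way — from images to numbers:

```python
img_cfg = hb.ImagingConfig(noise_sd=0.0)
half, piece, idx, image = next(iter(hb.render_hose(field, img_cfg, seed=1)))
profile = hb.measure_image(image, img_cfg)     # mask -> detect -> per-column T
print(profile.mean_um, hb.micro_scale_variation(profile.thickness_um))
```

A command-line front end wraps the same stages
(`hosebiofilm simulate | thickness | stats | community | volume | report`);
`hosebiofilm report --seed 123 --out report.json` produces the full
per-hose statistics report with config-hash provenance, byte-identical
across reruns.

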