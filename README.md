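# neuroquant

Quantitative tools for studying the **microglial barrier around amyloid
plaques** and its downstream readouts, as used in Alzheimer's-disease mouse
histology and the companion in-vitro and plasma assays:

- **Plaque quantification** — segmentation of ThioS/MOAB-2–stained deposits
  from calibrated multi-channel z-stacks, plaque counts and equivalent
  diameters, Iba1⁺ area fractions, and counts of microglial somata within a
  fixed physical radius (default 25 µm) of each plaque center.
- **Barrier coverage and dystrophic neurites** — per-plaque *microglial
  coverage*, defined as the fraction of the perimeter arc (in degrees)
  colocalized with Iba1; extension of covered/uncovered angular sectors to
  the limit of Lamp1⁺ dystrophic-neurite halos; Lamp1 area per degree by
  sector class; coverage–dystrophy correlation by plaque-size bin.
- **Sholl analysis** — neurite intersections with concentric circles at
  5 µm increments, from SWC morphologies (exact segment–sphere counting) or
  binary masks (rasterized circles), with area-under-curve summaries.
- **Phagocytosis scoring** — per-cell mean FITC-Aβ intensity and the
  proportion of Aβ⁺ (phagocytic) microglia from nuclei-seeded watershed
  segmentations or imported label images.
- **Plasma miRNA screen** — expression filtering (count ≥ 10 in > 50% of
  each group), TMM normalization, a negative-binomial conditional exact
  test with method-of-moments common dispersion, Benjamini–Hochberg FDR,
  DEM selection at |log2FC| > 1 and FDR < 0.05, a 95%-interval signature
  rule for individual case samples, PCA, and 2^−ΔΔCt relative expression.
- **Synthetic data with exact ground truth** — generators for all of the
  above (disk plaques with known angular coverage and halo densities,
  branched SWC trees, phagocytosis fields with a known positive fraction,
  negative-binomial count matrices with known DE labels), so every analysis
  stage can be validated against a ground truth it has never seen.

## The core statistic

For a plaque with centroid **c**, a ray is cast at each angular bin θ
(Δθ = 1°). The outermost plaque-mask crossing on the ray defines the
perimeter point p(θ); the bin is *covered* iff Iba1⁺ signal lies within
±1 µm of p(θ) along the ray. Coverage is

    C = (Δθ · #covered bins) / 360°,   C ∈ [0, 1],

with covered + uncovered degrees = 360 exactly. Lamp1⁺ pixels outside the
plaque are assigned to the angular bin of their angle from **c**, capped at
that bin's Lamp1 outer extent, and the per-degree dystrophy of each sector
class is its summed area divided by its total degrees.

## Worked example

```python
import neuroquant as nq

cfg = nq.SimConfig(field_size_um=(70, 70), seed=1)
spec = nq.PlaqueSpec(
    center_um=(35, 35), radius_um=7,
    covered_intervals_deg=[(0, 90), (180, 270)],   # true coverage 0.5
    lamp1_density_covered=0.05, lamp1_density_uncovered=0.25,
)
stack, truth = nq.simulate_histology_stack(cfg, [spec])

proj = nq.project_central_slices(stack, stack.n_slices // 2)
plaque = nq.segment_plaques(proj[cfg.channel_roles["plaque"]],
                            cfg.pixel_size_um)[0]
prof = nq.build_angular_profile(
    proj[cfg.channel_roles["iba1"]], proj[cfg.channel_roles["lamp1"]],
    plaque, cfg.pixel_size_um)
cov = nq.microglia_coverage(prof)
dys = nq.dystrophy_by_sector(
    proj[cfg.channel_roles["lamp1"]], prof, cov, plaque, cfg.pixel_size_um)
print(f"coverage {cov.coverage:.3f}  (truth {spec.true_coverage})")
print(f"lamp1 per degree: covered {dys.lamp1_per_deg_covered:.3f}, "
      f"uncovered {dys.lamp1_per_deg_uncovered:.3f} um^2/deg")
```

prints

```
coverage 0.500  (truth 0.5)
lamp1 per degree: covered 0.146, uncovered 0.668 um^2/deg
```

— the estimated coverage matches the generator's half-circle envelopment
exactly, and the dystrophic-neurite density in uncovered sectors is ~4.5×
the covered one, reflecting the generator's 0.25 vs 0.05 halo densities.

## Command line

```sh
neuroquant simulate --out run/ --seed 1 --n-plaques 4
neuroquant plaques  --image run/stack.tif --out run/
neuroquant coverage --image run/stack.tif --out run/
neuroquant sholl    --swc neuron.swc --out out/
neuroquant phago    --image field.tif --out out/
neuroquant mirna-dem --counts counts.tsv --samples samples.tsv --out out/
```

Every output table carries the tool version and a hash of the resolved
configuration; re-running a stage with the same config and seed reproduces
its tables byte-for-byte.

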