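# spacetrace

Cell-type-specific dynamic metabolism from MALDI mass spectrometry imaging
(MSI) combined with ¹³C isotope tracing.

## What it is for

High-resolution MALDI-MSI records a mass spectrum per tissue pixel, but a
single section is a metabolic snapshot.  Incubating tissue slices with
¹³C-labeled nutrients ([U-¹³C₆]glucose, [U-¹³C₅]glutamine,
[U-¹³C₁₈]linoleate) and imaging sections at several timepoints adds the
dynamic dimension — at the cost that every (tracer, timepoint) condition
lives on a different physical section.  `spacetrace` reunites them: since
phospholipid profiles are cell-type specific and stable over a 2-hour
incubation, pixels with matching lipid profiles across sections represent
the same cell type.  **Anchors** — scored mutual-nearest-neighbor pixel
pairs in a shared lipid projection — link a control section to each labeled
section, and the ¹³C-isotopologue intensities are imputed onto the control
pixels by anchor-weighted kNN averaging.  The result is one dataset in
which every pixel carries the complete labeling timecourse for every
tracer, on which the package computes:

- **fraction enrichment** of isotopologue M+i:
  f_i = x_i / Σ_j x_j over M+0..M+n, after natural-abundance correction
  (solving measured ≈ A·x by NNLS with
  A[i,j] = C(n−j, i−j) p^{i−j} (1−p)^{n−i}, p = 0.0107);
- **time-averaged enrichment**: trapezoid AUC of f(t) over the timecourse
  divided by total time;
- **carbon contribution** of a nutrient to a metabolite: Σ n·f_n / C over
  the tracer-attributable isotopologues;
- **cell typing** (Leiden on an SNN graph of lipid pseudo-counts, UMAP
  maps, 3-D-embedding RGB histology, immunofluorescence-based pixel
  selection) and **diffusion pseudotime** trajectories with
  pseudotime–enrichment correlations;
- a built-in **leave-one-factor-out validation**: withhold metabolites
  from one half of a bisected section, impute them from the other half and
  grade the imputed-versus-measured Spearman correlations
  (r > 0.8 very strong, 0.6–0.8 strong, 0.4–0.6 moderate);
- a **synthetic-tissue simulator** with known cell-type maps and
  mono-exponential labeling kinetics f(t) = P(1 − e^{−kt}), so the entire
  pipeline is testable at desk scale.

Inputs are peak-picked pixel × feature TSV matrices (or imzML), a feature
reference table, and optionally co-registered 8-bit stain rasters.  See
`docs/methods.md` for the full model description.

## Worked example

Simulate one labeled section (100×100 pixels, 6 cell types, 40 lipids,
4 metabolites with full isotopologue ladders, 10% noise), bisect it
vertically, withhold the metabolites from the left half and impute them
from the right half via lipid anchors:

```python
from spacetrace import synthetic_tissue as st
from spacetrace.validation import split_half, cross_validate

config = st.SimConfig(shape=(100, 100), n_types=6, n_lipids=40,
                      noise_cv=0.1, tracers={"glc13": (120.0,)})
control, labeled, truth = st.generate(config, seed=7)
section = labeled[0]                      # [U-13C6]glucose, 120 min

feats = st.feature_table(config)
lipids = list(feats.query("kind == 'lipid'")["feature_id"])
metabs = []                               # base peaks + labeled isotopologues
for name, cc, _ in config.metabolites:
    ns = sorted({0, max(1, cc // 2), cc})
    metabs += [name if n == 0 else f"{name}_M+{n}" for n in ns]

half_a, half_b = split_half(section, "vertical")
report = cross_validate(half_a, half_b, lipids, metabs,
                        features=feats, n_clusters=6, seed=7)
print(f"pixels: {report.n_pixels}, anchors: {report.n_anchors}, "
      f"clusters: {report.n_clusters}")
print(f"pixel-level mean r   = {report.pixel_mean_r:.3f} "
      f"({report.grades['pixel']})")
print(f"cluster-level mean r = {report.cluster_mean_r:.3f} "
      f"({report.grades['cluster']})")
print(f"enrichment ratio     = {report.enrichment_ratio_mean:.3f} "
      f"+/- {report.enrichment_ratio_sd:.3f}")
```

prints

```
pixels: 5000, anchors: 8540, clusters: 6
pixel-level mean r   = 0.899 (very_strong)
cluster-level mean r = 0.990 (very_strong)
enrichment ratio     = 0.997 +/- 0.006
```

Reading: 8,540 anchors link the 5,000 left-half pixels to the right half;
imputed metabolite intensities correlate with the withheld measurements at
r ≈ 0.90 pixel-by-pixel and r ≈ 0.99 on cell-type means, and the average
¹³C enrichment computed from imputed data is within ~0.3% of the directly
measured value — imputation preserves both spatial detail and the
downstream enrichment calculation.

## Command line

A thin CLI wraps the library:

```sh
spacetrace simulate --seed 7 --outdir data/          # synthetic dataset + truth
spacetrace cluster  --input data/control.tsv --resolution 1.0 --seed 7 --out clusters.tsv
spacetrace render   --input data/control.tsv --feature lip00 --clip-q 0.99 --out lip00.png
spacetrace validate --section data/glc13_t120.tsv --lipids data/features.tsv --out report.json
spacetrace pipeline --seed 7 --outdir run/           # full end-to-end run + manifest
```

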