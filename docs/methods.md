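# Methods

## The problem

MALDI mass spectrometry imaging (MSI) records one mass spectrum per tissue
pixel, resolving metabolites and (phospho)lipids at 5–20 µm pixel size —
close to single-cell resolution in kidney tissue.  Combining MSI with
¹³C-labeled nutrient tracing ([U-¹³C₆]glucose, [U-¹³C₅]glutamine,
[U-¹³C₁₈]linoleate) in cultured tissue slices turns the static metabolic
snapshot into a dynamic measurement: isotopologue intensities (M+n peaks at
base m/z + n·1.003355 Da) report how much of each metabolite pool has
turned over by each incubation timepoint.

The catch is that each (tracer, timepoint) condition requires its own tissue
section, so no single pixel ever carries the whole timecourse.  The core of
this package is the computational fix: phospholipid profiles are cell-type
specific and stable over a 2-hour incubation, so pixels with matching lipid
profiles across sections represent the same cell type and can share their
labeling measurements.  Every analysis stage downstream of peak picking is
implemented here; peak-picked pixel × feature matrices are the input.

## Pipeline and model choices

**Normalization and pseudo-counts.** Each pixel's spectrum is divided by
its total ion count (TIC) to remove per-pixel acquisition variation; rows
then sum to 1.  For clustering and anchoring, intensities are converted to
pseudo-counts by `floor(100 × value)`, making the data comparable to the
sparse count matrices single-cell tools are built for.  Variance
stabilization is `log1p` followed by per-feature z-scoring — a deliberate
simplification of regularized negative-binomial regression (SCTransform),
adequate for 0–100 pseudo-counts used purely as preprocessing.

**Cell typing.** PCA (30 components) on stabilized lipid counts, a
k-nearest-neighbor graph (k = 15) with shared-nearest-neighbor Jaccard
weights, and Leiden community detection.  One consequence of count
quantization deserves note: many pixels share identical small integer
vectors, which can shatter one biological type into several disconnected
graph islands, and Leiden can never merge communities the graph does not
connect.  `cluster()` exposes the pure Leiden contract; `cluster_k()`
targets an exact cluster count by running Leiden at the smallest resolution
yielding at least that many communities and then Ward-merging community
centroids in PCA space — the standard cluster-tree consolidation.  Use
`cluster_k` when the number of expected types is known (as in the
validation protocol).

**Anchor-based imputation.** To assemble the full timecourse on one
control section, anchors are found between the control (query) and each
labeled section (reference) on shared lipid features:

1. stabilize each dataset, fit PCA on the reference, project the query
   onto the reference basis ("pcaproject"), L2-normalize;
2. mutual nearest neighbors (k_anchor = 5) are candidate anchors;
3. each anchor is scored by the overlap of its two members'
   k_score = 30 neighborhoods among reference pixels, min–max scaled to
   [0, 1];
4. anchors are filtered by rank (reference member must be within
   k_filter = 200 reference neighbors of the query member in log1p,
   L2-normalized feature space) **and** by an absolute cosine-similarity
   floor (default 0.5) in that same space.  The similarity floor exists
   because mutual nearest neighbors always exist geometrically — even
   between datasets sharing no cell types — so a rank filter alone cannot
   fail when it should.

Transfer then imputes each reference feature onto every query pixel as a
convex combination over its k_weight = 50 nearest anchors (distance to the
anchors' query members in the shared projection), with Gaussian weights
`exp(−d²/σ²) · score`; σ defaults to the per-pixel mean anchor distance.
Raw TIC-normalized intensities are transferred (not fractions), so imputed
isotopologue sets stay internally consistent and enrichment is recomputed
downstream.  Two deterministic tie-breaks make self-transfer exact: exact
same-index duplicate rows are always included as anchors, and k_weight = 1
prefers a pixel's own self-pair among equidistant anchors.

**Natural-abundance correction.** With n carbons and natural ¹³C abundance
p = 0.0107, a true M+j state is observed as a binomial smear
`A[i,j] = C(n−j, i−j) p^(i−j) (1−p)^(n−i)`.  Correction solves
`measured ≈ A x` by non-negative least squares (an exact triangular solve
serves as the vectorized fast path; rows whose exact solution dips negative
under noise fall back to NNLS).  Only the metabolite's own carbons are
corrected — no ²H/¹⁵N/¹⁸O terms and no tracer-impurity correction, matching
uniformly labeled tracers of ≥ 98% purity.  Correction is applied per pixel,
after TIC normalization and before fraction enrichment.

**Enrichment dynamics.** Fraction enrichment of isotopologue M+i is its
corrected intensity over the summed M+0..M+n intensities of that metabolite
in that pixel (NaN when the total is 0).  A timecourse is summarized as the
trapezoid area under enrichment-versus-time divided by total time
("AUC normalized to total time"), computed per pixel and then averaged
within clusters (mean ± s.d., NaN pixels excluded).  Direct carbon
contribution of a nutrient to glutamate uses the fractional-contribution
convention `Σ n·f_n / C` over the tracer-attributable isotopologues
(glucose → M+2, M+3; glutamine → M+3, M+5; linoleate → M+2); the plain-sum
convention is available via an argument, and the isotopologue lists are
configurable.

**Trajectory.** Gradual transitions (healthy → maladaptively repaired
tubule) are ordered by diffusion pseudotime: an adaptive-bandwidth Gaussian
kernel on the kNN graph (k = 30 — denser than the clustering graph because
diffusion geometry on heavily tied quantized counts needs more edges),
diffusion-map coordinates scaled by λ/(1−λ), and pseudotime = diffusion
distance from the root centroid, shifted so the minimum is 0.  The root is
the user-named healthy cluster or pixel.  Spearman correlation (average
ranks, t-approximation p-values) links pseudotime to per-pixel enrichment.

**Validation protocol.** `cross_validate` withholds the metabolite features
of a query section (or half-section), imputes them from a reference via
lipid anchors, and reports Spearman correlations per metabolite feature at
the single-pixel level and on cluster means, graded as: r > 0.8 very
strong; 0.6 < r ≤ 0.8 strong; 0.4 < r ≤ 0.6 moderate (upper-exclusive
bins).  TIC normalization runs on each half's full feature set before the
withholding, so the query's lipid profile keeps its original scale.  The
enrichment-accuracy ratio is the mean over clusters and metabolites of
(imputed average enrichment) / (detected average enrichment), where average
enrichment is the per-cluster mean of labeled-over-total fraction
enrichment; being a ratio it is computed on as-transferred intensities
(natural-abundance correction cancels).  Correlations are computed over the
features an experiment would actually retain — unlabeled base peaks plus
isotopologues flagged by `detect_labeled_features` (labeled-section mean ≥
3× control mean); isotopologue channels carrying only the natural-abundance
smear are noise and are not "detected labeled peaks".

## The synthetic-tissue generator

The simulator emulates the tissue-slice labeling experiment so that every
stage has ground truth:

- **Layout**: seeded Voronoi blobs, 10 sites per cell type by default —
  many small scattered regions, like tubule cross-sections, so that any
  bisection of a section contains all types.  Each section draws its own
  layout (serial sections share composition, not geometry);
  `proportion_jitter` perturbs per-type region weights between replicates.
- **Profiles**: per-type lipid archetypes are lognormal
  (median 10, σ = 1 across 40 features by default); per-(type, metabolite)
  total abundance takes distinct multiplicative levels (factor 1.5 between
  adjacent levels, permuted independently per metabolite) — cell types
  differ severalfold in metabolite content, giving well-defined cluster
  ranks.
- **Kinetics**: mono-exponential labeling `f(t) = P(1 − e^{−kt})` with
  plateau P ~ U(0.15, 0.6) and rate k ~ U(0.01, 0.05) min⁻¹ per
  (type, metabolite, tracer) — the simplest monotone model for a 2-hour
  non-steady-state incubation.  At plateau the labeled fraction splits over
  a fully labeled isotopologue (70%) and a half-labeled one (30%),
  mimicking direct incorporation versus one-turn scrambling.
- **Isotope physics**: true isotopologue vectors are forward-convolved with
  the natural-abundance matrix, so a t = 0 section shows exactly the
  natural-abundance pattern and correction + enrichment recovers the
  configured `f(t)`·split to machine precision on noiseless data.
- **Noise**: mean-1 multiplicative lognormal per pixel × feature
  (CV 0.2 default) plus a per-pixel lognormal TIC gain (CV 0.1); emitted
  intensities are TIC-unnormalized.
- **Oracles**: `truth_enrichment` returns the expected AUC-normalized
  enrichment per (type, metabolite, isotopologue), either at the sampled
  timepoints (the correct oracle for a pipeline that measured those
  timepoints) or on a fine grid approximating the continuous average —
  the two differ by trapezoid discretization (~2% for typical kinetics),
  which is why exactness claims are made only at shared timepoints.

What the simulator does **not** emulate: mass spectra and peak shapes,
matrix-cluster interference, metabolite delocalization between neighboring
pixels, isomer ambiguity, section-to-section thickness or matrix-deposition
gradients, and spatially correlated noise.  Passing tests therefore show
the computational pipeline is correct and well-calibrated under realistic
abundance structure and noise levels — not that real-tissue performance
will match the synthetic numbers.

## Numerical choices and degenerate inputs

- Quantiles (hotspot clipping at q = 0.99) use linear interpolation between
  order statistics; clipping is monotone, and idempotent whenever
  q·(n−1) lands on an order statistic (true for typical image sizes).
- Zero-TIC pixels are an error listing offending coordinates (drop them
  first); all-zero isotopologue vectors correct to zero and yield NaN
  enrichment; empty clusters are omitted from summaries with a warning.
- PCA uses full SVD with a fixed seed; Leiden and UMAP receive explicit
  seeds; every provenance dict records the parameters and seed, and the
  pipeline manifest hashes every artifact so identical configs reproduce
  identical outputs.
- Degenerate embedding axes (max = min) map to RGB channel 0; disconnected
  pixels in trajectory analysis either raise (default) or become NaN.

## Problem sizes used in the shipped checks

The test suite exercises sections between 24×24 and 100×100 pixels; the
acceptance script re-enacts the bisected-section and cross-sample
validations on 100×100-pixel sections (6 types, 40 lipids, 4 metabolites
with full isotopologue ladders), averaging each statistic over metabolite
features and 5 repetitions, and the kinetics checks use 60×60 sections
across the 5-point timecourse.  These sizes reproduce the protocol's
behavior faithfully while keeping a full run in the order of a minute on
one CPU.

## Known limitations

- The anchor projection is reference-PCA ("pcaproject"); CCA-style joint
  projection is not implemented.
- Transfer's top-k anchor selection is order-dependent in the presence of
  exact distance ties (duplicated quantized profiles); results differ by
  at most one tied anchor's weight.
- Image co-registration (rotation/translation fitting) is caller-provided;
  `register_if` only block-resamples an already aligned raster.
- No batch correction beyond anchoring into a single control reference; no
  branch detection in trajectories; no steady-state flux modeling —
  enrichment dynamics are descriptive, not flux estimates.
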