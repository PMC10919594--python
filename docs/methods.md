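# Methods

## Problem and scope

`gliamorph` quantifies the shape of individual microglia — the resident
immune cells of the brain, whose silhouettes range from finely ramified
(surveillant) to compact and ameboid (activated) — and asks whether shape
alone separates cells sampled from different tissue regions of a rat
glioma model: contralateral control tissue (CL), the peritumoral brain
zone (PBZ, the radiologically normal 2 mm rim around the tumor border),
the tumor interface (INT) and the tumor core (TUM). The package implements
the measurement chain (binary mask → 16 descriptors) and the morphotype
statistics (feature selection, hierarchical clustering, discriminant
classification, permutation-tested PCA, PERMANOVA) as a reusable,
seed-reproducible pipeline.

## The 16 descriptors

Geometry is computed in pixel units and converted to micrometres at the
end (default pixel size 0.081 µm, a 100x oil objective). For one isolated,
border-free 8-connected mask:

- **NOB** — branches of the topological skeleton. Skeleton pixels are
  classified by 8-neighbor count (endpoint 1, slab 2, junction ≥ 3);
  adjacent junction pixels merge into junction nodes and NOB counts
  maximal slab paths between nodes.
- **FD** — box-counting fractal dimension of the contour: occupied-box
  counts at dyadic box sizes from 2 px to a quarter of the pattern extent,
  averaged over 4 uniformly spaced diagonal grid offsets; FD is the
  least-squares slope of log N versus log (1/ε). Smooth contours give
  FD ≈ 1 (a digital disk measures 0.95, a 512-px line 1.0 within 0.05);
  an order-7 Sierpinski raster measures within 0.1 of log 3/log 2.
- **LAC** — gliding-box lacunarity: at each box size and grid offset the
  per-box foreground density is computed over the mask's bounding box
  (boxes clipped at the region edge are normalized by the intersection
  area, so a filled rectangle scores exactly 0), λ = (σ/µ)² with the
  population σ, and LAC is the mean over sizes and offsets.
- **CA, CP** — foreground pixel count (area) and boundary pixel count
  (pixels with a 4-neighbor in background), scaled to µm²/µm.
- **CHA, CHP, DEN, CHSR, MSACH, CHC** — convex hull quantities. The hull
  is taken over pixel *corners* (each foreground pixel contributes its
  unit square), so CHA ≥ CA and DEN = CA/CHA ≤ 1 by construction. CHP is
  the hull polygon edge length; CHSR the ratio of the maximum pairwise
  vertex distance (MSACH) to the perpendicular projection extent;
  CHC = 4π·CHA/CHP².
- **R, CC** — roughness CP/CHP and cell circularity 4π·CA/CP².
- **TRMM, MR, DOB** — radii from the hull's area centroid to its
  vertices: max/min ratio, mean, and twice the minimum-enclosing-circle
  radius (Welzl's algorithm, deterministic shuffle, 1e-9 px containment
  slack).

Two conventions deserve emphasis because they are deliberately mixed, as
is common practice in this literature: CP counts boundary pixels while
CHP is a true polygon length. Consequently R can dip slightly below 1 for
compact digital shapes and CC of a digital disk is ≈ 1.24 rather than 1;
the analytic identity CC = 1 holds for the formula evaluated on a
mathematical circle's area and perimeter. The boundary-pixel count of a
digital disk grows as ≈ 5.7·r rather than 2π·r, which is exactly why
ramified cells in this descriptor system have such small CC values
(order 10⁻³).

## Preprocessing

Micrograph crops are reduced to one binary cell by: blue-channel
extraction (color input), a frequency-domain bandpass passing structure
between 3 and 40 px (difference of Gaussians with σ = cutoff/2), unsharp
masking (radius 2, amount 1), a 3×3 median despeckle, Otsu thresholding
(the cell is assumed dark on a lighter background and intensities are
inverted first), hole filling and largest-8-connected-component
isolation. Each filter can be disabled. The filters buy noise robustness
at the cost of a pixel or so of boundary localization: on a clean
two-level image only the plain-threshold path reproduces the source mask
exactly, while the full chain recovers noisy renders with Jaccard
overlap ≥ 0.8 in the calibrated noise range. The binarization rule and
unsharp parameters are configurable because the upstream literature does
not pin them down.

## Synthetic data

Because no raw micrographs ship with the package, two generators define
the test conditions.

**Silhouettes.** A filled soma disk plus recursively branching jittered
strokes, with four presets spanning the activation continuum (ramified →
hyper-ramified → reactive → ameboid, standing in for CL → PBZ → INT →
TUM). `tortuosity` is the SD of a branch's cumulative angular drift; side
branches arrive as a Poisson process (`branching_prob` per ~3 µm) and
recursion is capped at depth 3. Preset parameters (soma radius 2.8–5.2 µm,
primary branches 7 → 2, branch length 27 → 3.5 µm, width 0.55–1.3 µm)
were chosen so that the preset *means* reproduce the published regional
ordering of the ramification descriptors (NOB, CP, CHA, MSACH decreasing;
DEN, CC increasing) with the ramified preset in the control regime
(FD ≈ 1.35, DEN ≈ 0.14). Absolute NOB/LAC values are not matched to the
histology — skeleton branch counts depend strongly on stroke rasterization
— so tests assert orderings and regimes, not equality with printed means.

**Feature tables.** Cohorts are drawn directly from the published
per-region mean ± SD of each descriptor (80 cells per region), each
descriptor independent normal, clipped to its valid range (positive;
DEN, CC, CHC ≤ 1; CHSR, TRMM ≥ 1). Clipping rather than resampling is
used; at the published parameter values the clipped tail mass is < 1%
(checked for the worst case, tumor DEN). The printed statistics for the
two morphotype clusters found *within* an independent 200-cell
peritumoral sample (n = 69 and n = 131) parameterize the heterogeneity
analysis the same way. The tables carry no inter-descriptor correlation —
only marginal moments are published — so synthetic cohorts are easier to
separate than real cells along any single axis but lack the covariance
that makes real LDA accuracy as high as reported (94% on histology;
~0.8 on synthetic marginals). Passing tests therefore demonstrate that
the machinery recovers structure of the stated magnitude, not that it
reproduces the histology.

## Statistics

- **Standardization**: per-column z-scores with the n−1 SD.
- **MMI** (multimodality index): (m3² + 1)/(m4 + 3(n−1)²/((n−2)(n−3)))
  with bias-corrected sample skewness m3 and *excess* kurtosis m4. The
  excess convention is forced by value consistency: the classic uniform
  benchmark 5/9 ≈ 0.556 — and hence the 0.55 selection threshold — only
  emerges with excess kurtosis (uniform: 0 + (−1.2) + 3 → 1/1.8). A
  normal sample scores 1/3; columns with MMI > 0.55 are selected.
- **Kruskal–Wallis/Dunn**: tie-corrected H (scipy), Dunn z statistics on
  pooled ranks with Bonferroni-adjusted two-sided p.
- **Welch's t** with Welch–Satterthwaite df.
- **PERMANOVA**: Euclidean distances on z-scored features (negatives
  after z-scoring rule out Bray–Curtis), pseudo-F from the distance-based
  sum-of-squares decomposition, p = (#{F_perm ≥ F_obs} + 1)/(B + 1) with
  B = 999 by default — the floor p = 0.001 is the minimum achievable —
  and Bonferroni-corrected pairwise runs. The statistic matches
  scikit-bio's PERMANOVA to machine precision and the Monte-Carlo p
  matches exhaustive enumeration on tiny samples; null rejection at
  α = 0.05 calibrates to 0.02–0.08.
- **Normality checks** (KS against a normal with sample-estimated
  moments — conservative in the Lilliefors sense — and Shapiro–Wilk) are
  logged, not used for gating.

## Morphotype models

- **Clustering**: Ward's objective applied directly to the Manhattan
  distance matrix of z-scored cells via the Lance–Williams update (the
  classic recursion on supplied dissimilarities; Ward's variance
  derivation is Euclidean, and using city-block input is a deliberate,
  documented choice). The tree is cut into k = 4 branches; each branch is
  named by its modal region (ties to the larger cluster, then the fixed
  order CL, PBZ, INT, TUM); cells whose own region differs from their
  branch identity are "minority cells" and are excluded before
  classification. Input must be standardized (column SD within 1 ± 0.01)
  or the call fails loudly.
- **k-selection**: silhouette (same Manhattan metric) maximized over
  k = 2..8, Calinski–Harabasz reported for concordance; a best silhouette
  below 0.25 flags low confidence.
- **LDA**: Fisher discriminant on CA, DEN, CC (the two highest-MMI
  descriptors plus the low-correlation area term), stratified 70/30
  split, predictors standardized on training statistics; g−1 axes,
  per-axis proportion of trace, held-out accuracy. Wilks' Λ =
  det(W)/det(T) with Bartlett's χ² = −(N−1−(p+g)/2)·ln Λ on df = p(g−1);
  for p = 3, g = 4 this is df = 9. The split is stratified with a fixed
  default seed since the original randomization is unspecified.
- **Permutation PCA**: PCA on the correlation matrix of the 13
  descriptors not used by the LDA. The null permutes each column
  independently across rows; a PC is significant when its observed
  percent variance exceeds the null's 95th percentile at the same rank.
  The "index loading" of variable j on PC k is its squared unit loading
  times PC k's percent variance (the source tool's exact statistic is not
  published; this choice reproduces the reported magnitudes, e.g. ≈ 8 for
  the strongest of 13 variables on a 70% PC), tested against its own
  permutation null. Bootstrap resampling of cells (default 1000) gives
  percentile CIs for percent variance and never moves the point
  estimates. Type-I error calibrates to 0.02–0.10 on isotropic noise.

## Pipeline and reproducibility

`run_full` executes simulate/load → z-score → MMI screen → group tests →
PERMANOVA → cluster/cut/identify → minority exclusion → LDA + Wilks →
permutation PCA, persisting `features.csv`, `clusters.json`, `lda.json`,
`pca.json` and `report.json`. One top-level seed fans out into named
per-stage substreams (`stage_seed`), so adding a stage never shifts
another stage's randomness and fixed-seed runs are byte-identical.
Default problem sizes are the study's own (4 × 80 cells, 999 PERMANOVA
permutations, 1000 PCA permutations/bootstraps); the test suite uses 99
permutations and 10–20 replicate cohorts, sizes at which every
calibration already stabilizes.

## Known limitations

- Synthetic tables have no inter-descriptor correlation and silhouettes
  are stick-figure cells: neither emulates staining artifacts,
  overlapping cells, or 3-D structure collapsed to 2-D.
- Ward-on-Manhattan lacks Ward's variance interpretation; it is provided
  because it is the field's stated combination, not because it is
  optimal.
- The manual cell reconstruction step of the original workflow is
  replaced by largest-component selection; touching cells are not split.
- FD and LAC depend on the grid conventions (dyadic sizes, 4 offsets);
  values are bit-reproducible given the convention but not comparable
  across tools using other grids (FracLac-style defaults differ in
  unpublished details).
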