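# gliamorph

Single-cell microglia morphometry and morphotype discovery.

Microglia — the brain's resident immune cells — shift from finely
ramified, surveillant silhouettes to compact, ameboid ones as they
activate, and that shape continuum tracks pathology around brain tumors.
`gliamorph` measures 16 shape descriptors from a binary mask of one cell
and runs the multivariate statistics that turn per-cell descriptors into
morphotypes: multimodality-index feature selection, Ward/Manhattan
hierarchical clustering with branch identities, linear discriminant
classification with Wilks' test, permutation-tested PCA and PERMANOVA.
It is aimed at quantitative neuropathology workflows — for example
comparing microglia from a tumor core, its interface, the peritumoral
brain zone (PBZ) and contralateral control tissue.

## The descriptors

From one isolated 8-connected mask (pixel size in µm):

| group | descriptors |
|---|---|
| skeleton | NOB (branch count of the topological skeleton) |
| contour texture | FD (box-counting fractal dimension of the outline), LAC (gliding-box lacunarity, mean (σ/µ)² of box densities) |
| size | CA (area), CP (outline pixel count) |
| convex hull | CHA, CHP, DEN = CA/CHA, CHSR (major/minor hull axis), MSACH (max hull span), CHC = 4π·CHA/CHP² |
| shape ratios | R = CP/CHP, CC = 4π·CA/CP² |
| hull radii | TRMM (max/min centroid–vertex radius), MR (mean radius), DOB (bounding-circle diameter) |

The hull is taken over pixel corners, so DEN ≤ 1 always. CC evaluates to
exactly 1 for a mathematical circle's area/perimeter pair.

Because no raw micrographs are distributable, the package ships
generators for (a) microglia-like binary silhouettes across four
activation presets and (b) feature tables drawn from published
per-region descriptor means/SDs (80 cells per region), so the whole
pipeline runs and is tested without any download.

## Worked example

```python
import gliamorph as gm

# measure one synthetic ramified cell
mask = gm.generate_cell_mask("ramified", seed=1)
vec = gm.measure_cell(mask)
print(f"NOB={vec.NOB:.0f} FD={vec.FD:.2f} DEN={vec.DEN:.3f} CA={vec.CA:.1f} um^2")

# full cohort analysis on a published-statistics table
from gliamorph.pipeline import RunConfig, run_full
report = run_full(RunConfig(seed=3, out_dir="demo_run"))
print("clusters:", report["clustering"]["identity"])
print("LDA accuracy:", round(report["lda"]["accuracy"], 3),
      "df:", report["lda"]["df"])
print("significant PCs:", report["pca"]["significant_pcs"])
```

prints

```
NOB=265 FD=1.38 DEN=0.173 CA=373.1 um^2
clusters: {'2': 'CL', '4': 'TUM', '3': 'INT', '1': 'PBZ'}
LDA accuracy: 0.811 df: 9
significant PCs: [1]
```

The ramified cell sits in the control regime (low density, fractal
dimension near 1.4, hundreds of skeleton branches). On the synthetic
cohort the four-branch Ward/Manhattan cut recovers one branch per
region, the three-predictor LDA (CA, DEN, CC) classifies held-out cells
far above the 25% chance level with the expected 9 degrees of freedom,
and the permutation test retains a single dominant principal component —
as expected for tables built from independent marginals.

A CLI mirrors the library: `gliamorph simulate cells|table`, `measure`,
`stats`, `cluster`, `classify`, `pca`, `run-all` (see `--help`).

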