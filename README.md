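# phenoplate

High-content phenotyping of dissociated human induced pluripotent stem cells
(iPSCs) plated on an extracellular-matrix concentration gradient.  The
package is aimed at cell-phenotyping and screening groups who image 96-well
plates in four channels (DAPI, EdU/488, CellMask/647, brightfield) and want
an open, testable pipeline from raw field images to per-condition phenotypic
profiles.

## What it computes

For each field the pipeline segments nuclei from DAPI (robust-range
threshold at 5% of the 1st–99.9th percentile interval, then a
distance-transform watershed whose h-maxima depth is 0.40 x the component's
maximum interior distance, for an expected nucleus diameter of 18 µm) and
grows one cell per nucleus into the CellMask foreground by seeded watershed.
Objects then pass the selection cascade

```
Nuclei -> Nuclei 2 -> Cell unselected -> Cell
```

keeping nucleus area in [60, 600] µm², EdU median < 10,000, DAPI median in
[500, 10,000], brightfield median > 0, removing border objects, and finally
discarding cells of area >= 6000 µm² (which removes the rare oversized
feeder-cell contaminants).

Each retained cell carries nine phenotypic features — nucleus/cell area,
roundness `4πA/P²`, width-to-length, DAPI and EdU medians, and the *context
feature* `n_per_clump`: clumps are connected components of the distance-0
region-adjacency graph of cell masks, and each cell is tagged with its
clump's size (1 = single cell).

Per well the package aggregates transformed feature means and SDs (log10
for areas and intensities, square for the bounded ratios) over all cells and
over single cells, plus:

* **EdU⁺ fraction** — the area under the KDE of log10 EdU medians not
  explained by a Gaussian fitted to the main (EdU-negative) peak;
* **fraction of single cells** and the **inverse mean clump size** `p̂ =
  1/mean(clump sizes)`, the maximum-likelihood parameter of the geometric
  clump-size law observed on such plates (exponentially fewer clumps of
  bigger sizes);
* cell count.

Condition profiling standardises the well-level features, runs PCA (SVD,
deterministic signs), and summarises each condition's PC1/PC2 scores by the
bivariate-normal 68%-coverage ellipse (χ²₂ quantile).

A fully ground-truthed synthetic plate simulator (`phenoplate.synthetic`)
generates condition-dependent cell counts, geometric clump sizes placed in
mutual contact with inter-clump clearance, a two-population log-normal EdU
mixture, and rare feeder contaminants — so every stage is testable without
real data.  See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate an 18-well fibronectin plate (conditions Fn1/Fn5/Fn25, six
replicate wells each, nine fields per well) and profile it end to end:

```python
from phenoplate import synthetic
from phenoplate.pipeline import run_study
from phenoplate.plate_io import make_column_layout

layout = make_column_layout(("Fn1", "Fn5", "Fn25"), seed=0)
params = synthetic.default_params()
images = (img for img, _ in synthetic.iter_simulated_fields(layout, params, seed=0))
study = run_study(images, layout)

per_condition = study.summaries.groupby("condition")[
    ["cell_count", "edu_positive_fraction",
     "fraction_single", "inverse_mean_clump_size"]].mean().round(3)
print(per_condition.to_string())
print("rank by cell count:", " > ".join(study.report.rank_by_cell_count))
print("variance explained by PC1+PC2:",
      round(100 * study.pca.variance_fraction[:2].sum(), 1), "%")
```

prints (about 90 s on one CPU):

```
           cell_count  edu_positive_fraction  fraction_single  inverse_mean_clump_size
condition
Fn1           101.333                  0.244            0.547                    0.742
Fn25          321.000                  0.243            0.164                    0.392
Fn5           180.333                  0.210            0.316                    0.573
rank by cell count: Fn25 > Fn5 > Fn1
variance explained by PC1+PC2: 67.1 %
```

Reading the numbers: attached-cell counts rise with fibronectin
concentration (Fn25 > Fn5 > Fn1) while the EdU⁺ fractions stay comparable —
the count differences reflect adhesion/survival, not proliferation.  High
fibronectin also promotes clumping: the inverse mean clump size falls from
0.74 (mostly singles) to 0.39 (mean clump ≈ 2.6 cells) and the single-cell
fraction drops from 0.55 to 0.16 accordingly.  Two principal components carry about two
thirds of the between-well variance, and the Fn1 and Fn25 68% ellipses are
disjoint in that plane (`study.ellipses`).

The same pipeline runs from disk via the CLI:

```
phenoplate simulate --seed 0 --out plate/
phenoplate process --images plate/ --layout plate/layout.csv --out results/
```

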