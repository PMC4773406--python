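# Methods

`phenoplate` reimplements, as open algorithmic components, a high-content
phenotyping workflow for dissociated human iPSCs plated across a fibronectin
concentration gradient (conditions Fn1/Fn5/Fn25, i.e. 1/5/25 µg/ml coating)
in 96-well plates imaged at 10x in four channels: DAPI (nuclei), Alexa-488
(EdU incorporation), CellMask 647 (plasma membrane) and brightfield.  This
note records the model choices, the parameters that matter, and what the
synthetic validation does and does not demonstrate.

## Segmentation

The original analysis used a proprietary commercial pipeline whose nucleus
("M Method", 18 µm diameter, splitting coefficient 0.40, common threshold
0.05) and cytoplasm ("method A", threshold 0.05) detectors are unpublished.
We substitute open algorithms that honour the semantics of those documented
parameters; no bit-compatibility is claimed.

**Flatfield correction.** A smooth illumination surface is estimated from
each image by normalised Gaussian convolution at a scale of 1/8 of the image
extent (far above the cell diameter), evaluated on a strided grid and
bilinearly interpolated for speed.  The image is divided by the surface and
rescaled to preserve its mean.  A constant image is a fixed point; a
constant-zero image returns unchanged with a warning.

**Nuclei.** The DAPI channel is smoothed with a Gaussian of
`smoothing_sigma_um` (default 1.0 µm).  Foreground is everything above
`background + common_threshold x robust range`, where background is the 1st
intensity percentile and the robust range runs to the 99.9th percentile.
Two numerical guards matter here:

* the *upper percentile* is 99.9, not 99: at 10x magnification nuclei cover
  roughly 1% of a field, so a 99th-percentile "signal" estimate sits in the
  background and the threshold collapses into the noise;
* a *noise guard* (`median + 4 x 1.4826 x MAD` of the smoothed image) caps
  the threshold from below so a signal-free field — whose robust range is
  pure noise — yields zero objects instead of one giant component.

Touching nuclei are split by a watershed on the interior distance
transform.  Within each connected foreground component, maxima shallower
than `splitting_coefficient x (maximum interior distance)` are suppressed
(h-maxima); surviving seeds closer than `min_seed_separation_um` (default
5 µm) are merged.  Objects below 10% of the nominal nucleus area
(pi (18/2)^2 µm^2) are discarded as debris — safely below the 60 µm^2
population filter applied later.  The default smoothing scale is 1.0 µm
rather than diameter/8: a heavier blur widens the low-threshold halo around
each nucleus enough to bridge the gaps between nuclei of touching cells.

**Cells.** A seeded watershed grows each nucleus into the membrane-stain
foreground (same robust threshold construction with `cytoplasm_threshold`).
Cell labels equal their seed nucleus labels; nucleus pixels are forced into
the watershed mask, so every cell region contains its nucleus, and touching
cells partition shared foreground along the watershed line.  Nuclei with no
membrane foreground keep cell == nucleus and are flagged.

**Border objects.** Any label whose cell region touches an image edge is
removed (8-connectivity); survivors are relabelled consecutively and the
removal is recorded in the mask provenance.

## Features

Nine phenotypic features per retained cell: nucleus and cell area (pixel
count x pixel size^2), roundness (`4 pi A / P^2`, perimeter by weighted
boundary chain, clipped to (0, 1] because rasterisation can exceed the
isoperimetric bound), width-to-length (minor/major axis of the moment
ellipse), the DAPI and EdU median intensities, and the cells-per-clump
context feature.  Medians are measured on the nucleus region — DAPI and EdU
are nuclear signals and precede cytoplasm detection in the original
pipeline's order; the region choice is an explicit argument of
`measure_intensity`.  The brightfield median is carried as a QC column only.

## Object-filter cascade

`Nuclei -> Nuclei 2 -> Cell unselected -> Cell`, with thresholds: nucleus
area in [60, 600] µm^2, EdU median < 10,000, DAPI median in [500, 10,000],
brightfield median > 0, then border removal on the cell region, then cell
area < 6000 µm^2.  "Between" bounds are read as closed intervals and
"below"/"over" as strict inequalities (`strict_bounds=False` flips both).
The cell-area ceiling removes the rare oversized feeder-cell (mouse
embryonic fibroblast) contaminants.  Every removed row carries
machine-readable reasons, and stage counts are monotone non-increasing by
construction.

## Clump context

Cells in mutual contact form a clump; a single cell is a clump of size 1.
Because the seeded watershed separates touching cells by construction,
"distance 0" contact is mapped to adjacency of dilated-by-one regions: two
labels are adjacent when pixels come within a Chebyshev distance of 2.
Clumps are connected components of this region-adjacency graph, computed per
field (border cells are already gone and fields are non-contiguous
acquisitions, so clumps never span fields).  Each cell is tagged with its
clump's size — the context feature — and conservation (sum of clump sizes ==
retained cell count) is asserted per field.

## Well aggregation

Features are variance-stabilised before averaging: log10 for the
right-skewed positive quantities (areas, intensity medians), squaring for
the ratios bounded at 1 (roundness, width-to-length); the mapping is
configurable.  Means and standard deviations (SD missing, not zero, when
n = 1) are computed for all cells and separately for single cells.  Clumping
is summarised by the fraction of single cells and by the inverse mean clump
size — the maximum-likelihood parameter of a geometric law on {1, 2, ...},
reported with a chi-square goodness of fit (tail pooled beyond the last
expected count >= 5).

**EdU-positive fraction.** Per well, log10 EdU medians are density-estimated
by Gaussian KDE with Silverman bandwidth; the global density mode is taken
as the EdU-negative main peak.  A Gaussian is least-squares fitted to the
sub-mode side of the KDE curve (region up to one initial sigma above the
mode), initialised from the mirrored sub-mode spread of the data combined in
quadrature with the KDE bandwidth so the peak lives on the same smoothed
scale as the empirical density; its mass is capped at 1.  The positive
fraction is the integral of the density above the fitted peak mean that the
peak does not explain, after subtracting one pointwise KDE sampling standard
error (`sqrt(f / (2 sqrt(pi) n h))`), clipped to [0, 1].  Three numerical
choices deserve emphasis, each fixed after an explicit bias analysis:

* fitting the peak rather than reading the KDE maximum pointwise — the
  maximum is positively biased by about one sampling SE, which propagates
  to a spurious +5% positive fraction on a fully negative well;
* the fit region extends one sigma past the mode so a KDE wiggle cannot
  truncate the crest out of the window and collapse the fitted width;
* the sampling-noise floor and the above-the-peak restriction (EdU-positive
  cells are the brighter population) keep the positive-part residual from
  integrating pure noise.

With these, the estimator recovers true fractions 0/0.1/0.3/0.5 within 0.05
in >= 90% of replicates at 2000 cells per well, and unexposed control wells
read <= 0.05.  The estimator requires >= 30 values (otherwise missing, with
a warning) and is invariant under rescaling all intensities by a constant.

## Condition analysis

Well summaries are assembled into a standardised matrix (per-feature
transformed means and SDs over all cells, log10 cell count, EdU-positive
fraction, fraction single, inverse mean clump size; z-scored because the
features mix units).  Wells with any missing value are dropped listwise with
a logged count; zero-variance columns are dropped with a warning.  PCA is a
singular-value decomposition of the centred matrix; signs are fixed by
making the largest-magnitude loading of each component positive, and all
components are returned so variance fractions sum to 1.  Per condition, the
first-two-component scores are summarised by the bivariate-normal contour at
the chi-square(2) quantile of the requested coverage (0.68 by default, the
1-sigma-equivalent "68% of samples" ellipse); overlap between ellipses is
decided by dense boundary sampling plus centre containment.  A per-condition
report gives min/max/mean of cell count, EdU fraction, clumping statistics,
the cell-count rank order, and kernel-density tables for the nucleus
morphology features when object-level data is supplied.

## Synthetic plates

The simulator provides ground-truthed inputs with the statistical structure
the pipeline assumes; defaults define the study conditions and are not
tuning knobs.

* Geometry: 960 x 960 px fields at 0.65 µm/px (a typical 10x widefield
  scale; the pixel size is configurable because instruments vary), 9 fields
  per well, border wells unused, conditions randomised per column block.
* Counts: clumps per well are Poisson with mean
  `expected_attached_cells x p`, clump sizes i.i.d. geometric(p) on
  {1, 2, ...}, so expected total cells match the preset.  Presets: Fn1
  110 cells/well, p = 0.70; Fn5 200, p = 0.55; Fn25 320, p = 0.40 —
  attachment ordered with fibronectin concentration and clumping stronger at
  high concentration, with the EdU-positive fraction (0.30) shared across
  conditions.  Absolute counts are scaled to the simulated field area; the
  source study reports orderings, not per-field counts.
* Morphology: log-normal areas (nucleus median 150 µm^2, cell medians
  380/480/600 µm^2), beta-distributed width-to-length clipped to
  [0.35, 1], uniform orientation; nuclei are concentric, co-oriented and
  shrunk to fit within their cells.  These distributions are engineering
  choices — the source study publishes no quantitative morphology
  distributions.
* Placement: clump members sit on a jittered hexagonal spiral at 0.95 x the
  touching distance (mutual contact); clumps keep >= 8 px clearance via
  bounding-circle rejection sampling, so distance-0 clump detection has
  unambiguous truth.  Overpacked configurations raise a `PackingError`
  rather than silently violating clearance.
* Intensities: per-channel Gaussian backgrounds; DAPI and membrane signals
  log-normal around fixed scales; EdU intensity a log10-Gaussian mixture
  (negative 2.5 +/- 0.12, positive 3.6 +/- 0.15) — separable, and both
  medians below the 10,000 artefact ceiling so real positives survive the
  filter cascade.  Feeder contaminants (rate 0.1/well) render with
  ~8000 µm^2 cell area to exercise the cell-area filter while passing the
  nucleus filters.
* Determinism: everything is a pure function of (params, layout, seed);
  per-well and per-field seeds derive from the master seed through
  `numpy` seed sequences.

**What passing tests show — and do not show.** The simulator draws hard-edged
ellipses with additive Gaussian noise; it has no optical point-spread
function, no focus drift, no staining heterogeneity within nuclei, no
photobleaching, and its clumps are locally regular hexagonal packings rather
than the irregular aggregates of real iPSC colonies.  Recovery results
(nucleus recall/precision >= 0.9, exact clump partitions, EdU fraction
within 0.05) therefore validate the algorithmic correctness and the internal
consistency of the pipeline under its stated assumptions, not its accuracy
on real micrographs.  Conversely, headline numbers from the original study
(37% single cells over 41 replicate experiments; about two thirds of
variance in two components) are properties of unreleased real data; the
simulated plate reproduces their qualitative structure (mid-thirties single
-cell percentages, PC1+PC2 around two thirds, ordered cell counts,
non-overlapping extreme-condition ellipses) but no equality with those
figures is asserted anywhere.

## Problem sizes

Default validation runs use one 18-well plate (3 conditions x 6 wells,
9 fields each, ~3500-4000 retained cells) for the end-to-end checks, 2000
cells/well x 50 replicates for EdU estimator recovery, 1000 clumps x 100
replicates for geometric recovery, and 100 random label masks for the clump
oracle — sizes at which every statistical tolerance above is comfortably
resolvable on a single CPU.

## Known limitations

* The segmentation substitutes are parameter-compatible, not
  output-identical, with the commercial modules they replace; absolute
  morphology values (e.g. measured nucleus areas inflate by the threshold
  halo, ~30-40% at the default settings) are internally consistent but not
  instrument-calibrated.
* The EdU decomposition assumes the negative population is the global
  density mode and positives are brighter; it under-reports slightly
  (-0.02 to -0.07) for wells below ~300 cells.
* Clump detection is field-local; colonies spanning field borders are
  handled by border-object removal, not stitching.
* `compare_conditions` reports descriptive ranges only; the source workflow
  publishes no between-condition hypothesis tests and none are added.
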