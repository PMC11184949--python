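# Methods

## The uniformity battery

The object of study is the spatial evenness of crop growth inside a single
trial plot, observed as a per-pixel trait map (LAI, SPAD, plant height in
cm) or a per-pixel vegetation indicator (FVC). Continuous traits are
discretised into classes of width `w` — the *classification parameter* —
anchored at origin 0 in trait units, with half-open bins
`[k·w, (k+1)·w)`; a pixel's class is `floor((v − origin)/w)`. Only nonempty
classes are counted, so the abundance `S` is the number of occupied classes
and `P_i` the fraction of pixels in class `i`. Shannon entropy
`H' = −Σ P_i ln P_i` (natural log throughout), Pielou `J' = H'/ln S`,
Alatalo `E = (1/ΣP_i² − 1)/(e^{H'} − 1)`, and optionally Sheldon
`e^{H'}/S` and Heip `(e^{H'} − 1)/(S − 1)` are evaluated on the class
distribution; mean, sample variance (n−1 denominator), `CV = s/x̄`, and
optionally Lloyd's mean crowding `m* = x̄ + s²/x̄ − 1` and the clustering
index `I = s²/x̄ − 1` on the raw values.

Conventions that fix otherwise ambiguous cases:

- `S = 1` (all pixels in one class): `J'` and `E` are the indeterminate
  form 0/0 and are **defined as 0**, so perfectly uniform growth sits at
  the low end of the scale, consistent with the negative index–yield
  association the rest of the package works with. Heip's index instead
  raises, since no continuity argument selects a value.
- Undefined ratios (CV, `m*`, `I` at `x̄ = 0`; Pearson r of a constant
  series) are NaN markers, never silently dropped.
- Binning is translation-dependent through the origin; the origin is
  configurable and defaults to 0 so results are reproducible.
- LAI/SPAD/PH batteries are computed over vegetation pixels when a crop
  mask is supplied (the default in the pipeline); FVC always uses every
  ROI pixel, because the indicator itself is the trait.

Default classification parameters are LAI 0.5, SPAD 2, PH 2 cm. Six
statistics × four traits = 24 per plot-stage: 20 uniformity indices plus
the 4 trait means, labelled with the standard abbreviations (PH's Shannon
entropy is `PHH` to avoid clashing with the trait tag).

## Trait extraction

**NDVI / FVC.** NDVI = `(NIR − red)/(NIR + red)` per pixel (red 669 nm,
NIR 820 nm bands); pixels with zero band sum are invalidated. Vegetation is
segmented at the valley of the NDVI histogram: per growth stage, values are
histogrammed on [−1, 1] (bin 0.02 NDVI, configurable), smoothed with a
centred 5-bin moving average, and the minimum-count bin centre strictly
between the two highest peaks is the stage's valley; ties across a flat
valley resolve to the central bin, so a wide empty gap between modes yields
its midpoint. The working threshold is the arithmetic mean of per-stage
valleys. A unimodal histogram raises an error naming the stage rather than
guessing. FVC is the fraction of ROI pixels with NDVI **strictly above**
the threshold (ties are background); a pixel belongs to the ROI iff its
centre lies inside the polygon.

**Plant height.** The 97th percentile of ground-normalised point
elevations, under the linear-interpolation order-statistic convention
(`numpy.percentile` default): the 97th percentile of 0.00, 0.01, …, 1.00
is exactly 0.97. Clouds are assumed ground-normalised; soil segmentation
belongs to upstream photogrammetry tooling.

**LAI / SPAD regression.** A single-hidden-layer feed-forward network —
10 hidden neurons for LAI, 20 for SPAD, tanh hidden activation, linear
output — trained by stochastic-gradient backpropagation for 5,000
iterations at learning rate 0.005 after a seeded 2:1 train/test split.
References to "10/20 hidden layers" in this model family are read as
hidden *neurons* in one layer: a 10–20-layer plain-backprop network at
this learning rate would not train, and one hidden layer is the standard
BPNN idiom. Inputs and targets are standardised before training and
predictions de-standardised, making the learning rate scale-free. The
feature set is deliberately open (any raster stack); vegetation-index
recipes vary by sensor. Fit reports carry R²/RMSE for both splits; a
constant target is flagged degenerate rather than fitted.

## The synthetic field

The simulator emulates the statistical structure the pipeline assumes, on
the target trial geometry: 1.5 × 1.25 m plots at 3 cm GSD with 0.25 m row
spacing. Per trait, a plot surface is
`mean + correlated field + iid pixel noise`, clipped nonnegative; the
correlated field is white noise smoothed with a Gaussian kernel whose
bandwidth is the correlation length (periodic boundaries, exact kernel-norm
rescaling, so the marginal sd equals the configured field sd). Rows are
vegetated stripes of width `row_spacing/2` centred on row centres
(half-open in pixel-centre coordinates, so stripes cover half the plot up
to pixel quantisation); inter-row pixels are invalid for trait rasters and
are the soil class in spectral scenes. Spectral scenes draw per-pixel NDVI
around a soil mode (0.12) and vegetation mode (0.80) with sd 0.05 and
back-compute red/NIR at constant total reflectance 0.6, so per-pixel NDVI
is exact and the histogram is bimodal; the generator records the true
vegetation mask and its exact pixel fraction as true FVC, and warns when
the modes are closer than 4× the pixel noise sd. Point clouds draw
`z ~ Normal(PH mean, PH sd)` above a zero ground plane and record the
generating distribution's 97th percentile as truth (untruncated; the
sub-zero mass is negligible at the defaults). Yield and biomass are
`a·(trait mean) − b·(uniformity index) + Normal(0, σ)` per plot, with
defaults `(2.0, 5.0, 0.15)` and `(4.5, 9.0, 0.30)` chosen to place plots
in the realistic 4–7 Mg/ha yield and 9–14 Mg/ha biomass range; `b > 0`
plants the negative index–outcome association the analysis layer is meant
to recover.

Default trait levels are mid-season wheat values: LAI 3.2, SPAD 45,
PH 80 cm, with field sds 0.5 / 3 / 8 and correlation length 0.15 m. The
LAI mean is deliberately bin-centre aligned for the default 0.5 bin width:
a mean sitting exactly on a bin edge makes even a near-constant plot split
evenly into two classes (Pielou ≈ 1), which would invert the
heterogeneity→evenness ordering the index expresses. Every generator is a
pure function of (config, trait, plot, stage): identical inputs are
bit-identical regardless of call order.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: radiative transfer or realistic spectra, crop
phenology (stages are independent draws), lodging, mixed pixels at row
edges beyond simple averaging, measurement bias in any sensor, and any
genetic structure across plots. Quantitative within-plot autocorrelation of
real wheat is unknown here; the correlation length is a plausible
placeholder, not an estimate.

## Association layer

Correlations are Pearson (signed linear association is the quantity of
interest), with pairwise deletion and n reported; no multiple-testing
correction is applied by default, matching common practice for these
exploratory matrices (a Benjamini–Hochberg pass can be layered on the
output table if wanted). MLR is ordinary least squares on a seeded 7:3
train/validation split; validation metrics use the untouched 30% only, and
the split seed is recorded. Rank-deficient designs error with the collinear
columns named. Cultivar clustering is agglomerative with Ward linkage on
Euclidean distance over z-scored (yield, biomass) means, cut at k = 3 and
relabelled C1..Ck by descending mean yield; one-way ANOVA is the classical
F test, two-way (year × cultivar) is fitted without interaction by default
because one observation per cultivar-year leaves no degrees of freedom for
it.

The four frozen published regression models ship as a JSON data file and
are immutable: evaluation applies the printed coefficients to raw predictor
values (no standardisation — the printed equations are taken at face
value). Tests pin every coefficient digit-for-digit.

**Sensitivity sweeps.** The bin-width sweep recomputes the entropy indices
over the standard grids (LAI 0.25–7.5, SPAD 1–40, PH 1–50 cm) and
correlates each with outcomes; a width that swallows all values of every
plot gives S = 1, entropy 0 and an undefined (NaN) correlation — the
designed degenerate endpoint. The GSD sweep block-averages rasters by
integer factors (valid-pixel means; all-invalid blocks become invalid;
trailing partial blocks dropped), multiplying the GSD accordingly, e.g.
3 → 6 → 12 → 24 cm.

## Problem sizes and numerical choices

Simulation-backed checks run at 100 plots (42 × 50 px rasters) and, for
replicate-based claims, 20 seeded repetitions or 50 replicate plots —
sizes at which the planted effects are comfortably resolvable while the
whole suite stays fast. Sweep-trend assertions allow a 0.05 slack per
adjacent step (about one standard error of r at n = 100) on top of a strict
overall decrease. Index oracle agreement is asserted at 1e-10, OLS against
the normal equations at 1e-8, and the ANOVA null-rejection rate within
3 binomial standard errors of 0.05 over 1,000 replicates.

## Known limitations

- No photogrammetry: orthomosaicking, georeferencing, radiometric
  calibration and CRS handling are out of scope; coordinates are planar
  metres in a local plot frame, rasters are NPZ files.
- Distance-based uniformity indices (nearest-neighbour non-randomness,
  spacing-based uniform-distribution indices) need individual plant
  coordinates, which dense canopies do not provide; they are deliberately
  absent.
- The valley threshold assumes a genuinely bimodal NDVI scene; sparse or
  fully closed canopies need a manual threshold.
- Binning anchored at a fixed origin is translation-dependent: shifting all
  values by a fraction of the bin width can change S and the indices. This
  is inherent to the method; the bin-width sweep is the tool for judging
  robustness.
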