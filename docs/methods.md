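# Methods

`flatquant` measures Cre/lox reporter recombination efficiency on
flatmounted epithelial monolayers (the motivating tissue is the mouse
retinal pigment epithelium, imaged en face as a butterflied eyecup) and
compares treatment groups with a mixed-effects model. This note documents
the measurement model, the synthetic-data generator used to validate it,
the numerical choices, and the known limitations.

## The measurement model

Two efficiency statistics are computed per eye, and per anatomical region:

* **Percent area.** After preprocessing, the reporter channel is
  segmented at a threshold; with `A_Exp` the segmented pixel count and
  `A_Tot` the measurable tissue pixel count,

      A_Per = A_Exp / A_Tot × 100.

* **Percent nuclei** (for nuclear-localized reporter signal, as in fetal
  eyes). With `N_Nuc` detected DAPI nuclei and `N_Exp` of them
  reporter-positive,

      N_Per = N_Exp / N_Nuc × 100.

  In the alternative `independent_objects` counting mode, reporter-positive
  blobs are counted on their own; this can exceed the nucleus count, so
  `N_Per` can exceed 100%. Such values are reported with an `over_100`
  flag, never clamped — losing them would hide a real failure mode of
  object counting.

### Preprocessing

1. **Channel split.** Multi-plane TIFFs are split into `reporter`
   (tdTomato), `nuclei` (DAPI) and `junction` (ZO-1) roles. ZO-1 is carried
   for visualization only.
2. **QC gate.** An image whose *original* intensity spread
   `(max − min)/(2^16 − 1)` is below 5% of the dynamic range has no usable
   signal-to-noise and is excluded from analysis entirely (it contributes
   no rows to the study table; its exclusion is logged). The gate is
   evaluated on the reporter channel, before any rescaling, and depends
   only on the intensity extremes — it is invariant to pixel permutation.
3. **Background subtraction** (optional, default on for real images).
   Morphological opening with a disk of radius 1/20 of the smaller image
   dimension estimates the smooth background; the estimate is subtracted.
   An opening treats any bright region wider than the disk as background,
   so the radius must exceed the largest genuine foreground feature. For
   simulated images the pipeline is run with subtraction off: the
   generator adds no background haze, and large clusters of expressing
   cells would otherwise be eroded.
4. **Intensity rescale.** A linear stretch maps the 0.5th and 99.5th
   intensity percentiles onto [0, 65535] so that 99% of the signal fills
   the dynamic range; values outside are clipped (at most 1% of pixels).
   The stretch is interpreted symmetrically; coverage is configurable.
   Percentiles are taken at actual order statistics (lower/higher), which
   makes the operation exactly idempotent and order-preserving on
   non-clipped pixels.
5. **8-bit conversion.** The fixed linear map `v → floor(v/257)`. No
   re-stretching: contrast is already set.

### Measurable-area bookkeeping

The background mask is built with exact arithmetic: every pixel of the
(8-bit) image gains one intensity unit, saturating at 255 (wrapping would
mint spurious zeros), then all excluded regions — no tissue, bubbles,
damage — are set to 0. A pixel is background **iff** it is exactly 0
afterwards; there is no tolerance band. Hence

    A_Tot + (background pixels) = image area,   exactly.

Exclusions are machine-readable inputs (boolean/label rasters or pixel
polygons) rather than interactive ROIs; on synthetic data they come from
the generator's ground truth. Foreground pixels outside the mask are never
modified.

### Segmentation and nuclei

* The expression threshold is, by default, Otsu's threshold computed over
  the non-background pixels (dark but measurable tissue stays in the
  histogram), standing in for a manually validated threshold; a fixed
  8-bit value can be configured instead, and a 4-panel montage
  (raw | processed | area basis | segmentation overlay) is written for
  human validation. A pixel is expressing iff strictly above the
  threshold, so lowering the threshold never shrinks the segmentation.
* Nuclei: Otsu over tissue pixels, connected components, and a
  local-maximum-seeded watershed split applied only to components larger
  than 1.5× the median component area (a doublet criterion — splitting
  everything would shred well-separated nuclei). Components smaller than
  `min_area` (default 4 px) and nuclei overlapping the background mask by
  more than half are discarded. A nucleus is reporter-positive iff its
  *mean* reporter intensity exceeds the threshold (mean, not max, to
  resist hot pixels).

### Regional geometry

All regional geometry is anchored at the optic-nerve center (from
metadata, or the tissue centroid as a fallback):

* **Quadrants.** Dorsal/ventral and nasal/temporal are axis-aligned
  half-planes through the center. Which image side is nasal follows eye
  laterality (left/right eyes mirror); the fixed convention is nasal =
  image left for OD, image right for OS. Pixels exactly on an axis go to
  the nasal/dorsal side — an explicit, tested tie-break.
* **Central vs peripheral.** The tissue diameter is measured along each
  orthogonal axis line through the center (interior holes ignored — the
  *total* extent of the butterflied eyecup). The central region is the
  ellipse with half those diameters, boundary inclusive; the rest is
  periphery. On a solid ellipse this puts 25% of the total area in the
  center — equivalently a center:periphery ratio of 1:3; the package
  reports center/total. If the center pixel itself falls in an excluded
  hole (a bubble over the optic nerve) the geometry is still defined, as
  holes are gaps in measurability, not anatomy.

The same threshold is shared by all regions of an eye, so regional
`A_Exp`/`A_Tot` decompose the whole-eye values exactly within each
partition family. A region with no measurable pixels yields a measurement
marked missing; the statistics stage accepts unbalanced data. Users can
supply their own region masks to mimic manual cropping.

## Statistics

Percent values are correlated within mouse (two eyes) and within eye
(regional repeated measures), and eyes go missing via the QC gate, so
group comparisons use a linear mixed-effects model fit by REML
(statsmodels `MixedLM`):

    percent ~ group,  random intercept per mouse
                      (+ variance component for eye-within-mouse when the
                         data carry several rows per eye)

With a single row per eye the eye component is confounded with the
residual and is omitted — not a simplification but an identifiability
fact. Variance components at the zero boundary can defeat BFGS, so the
fit falls back through gradient-free optimizers before declaring
non-convergence.

All pairwise group contrasts are tested simultaneously with a single-step
max-|T| adjustment (the Tukey-style post-test for fitted models): each
adjusted p is `P(max_j |T_j| ≥ |t_i|)` under the estimated contrast
correlation. The reference distribution is multivariate **t** with
between-mouse degrees of freedom (mice − groups), because treatment group
varies between mice; the asymptotic normal reference is available as an
option but is measurably liberal in small samples (family-wise error 7.1%
instead of ~5% at 10 mice/group in the package's own null calibration).
The rank-deficient contrast correlation (k groups give k−1 free
contrasts) is handled by evaluating the max-|T| distribution on its
reduced-rank square root with a deterministic scrambled-Sobol
quasi-Monte-Carlo sample (2^14 points; p-value resolution ~10^-4, ample
at the 0.05 level). Significance is α = 0.05 on adjusted p-values; stars
follow ≤0.05 / ≤0.01 / ≤0.001.

Residual normality is checked with a one-sample Kolmogorov–Smirnov test
against a normal with the sample mean and SD. Because the parameters are
estimated from the same residuals the p-value is conservative; the result
carries a `params_estimated` flag saying so.

## The synthetic flatmount generator

Every downstream stage is validated by parameter recovery on simulated
eyes, because no real images ship with the package. One simulated eye is:

* a **silhouette** — an ellipse (semi-axes 0.45× the image dimensions) or
  a butterflied variant with four 24°-wide wedge cuts along the diagonals
  (the orthogonal axes through the optic nerve stay intact, as in a real
  butterflied eyecup, and wedges start at 20% of the radius);
* a **cell mosaic** — `n_cells` seed points drawn uniformly over tissue
  pixels, tissue tiled by nearest-seed (Voronoi) assignment; the nucleus
  of each cell sits at its cell's centroid, which spaces nuclei
  near-regularly like a real monolayer;
* **expression flags** — each cell expresses with probability
  `expressing_fraction_central` if its centroid lies in the central
  ellipse, else `expressing_fraction_peripheral`; the two probabilities
  are independent so a central>peripheral gradient can be simulated;
* **rendering** — DAPI as one Gaussian blob per cell (σ = cell
  diameter/6); the reporter over whole expressing cells (cytoplasmic) or
  their nucleus blobs only (nuclear); ZO-1 as the cell-border skeleton;
  artifact discs alternately saturated and zero-signal; multiplicative
  vignetting; Poisson shot noise (gain in photons per intensity unit; 0
  selects the infinite-photon, noise-free limit) plus Gaussian read
  noise; clipping and 16-bit quantization. No signal is rendered outside
  tissue ∪ artifacts.

Defaults are one set of realistic study conditions, fixed once: 512×512
px, 600 cells, central/peripheral expressing fractions 0.65/0.53 (the
regional gradient reported for adult eyes), cytoplasmic reporter, two
artifacts, vignette strength 0.2, shot-noise gain 0.01 (≈7% noise at the
signal amplitude of 20000), read noise SD 100. All randomness flows
through one seeded generator; identical spec + seed is bit-identical.

The study-table generator draws hierarchical per-eye percent values
(group mean + mouse deviate + eye deviate, truncated to [0, 100]) with
independent eye dropout, and is used for the type-I-error and
effect-recovery calibration of the statistics stage (3 null groups, 10
mice/group, mouse SD 5, eye SD 3, 10% missing eyes, 1000 replicates).

### What the generator does not emulate

Point-spread optics, chromatic aberration, melanin pigment, real artifact
morphology (bubbles are stylized discs), irregular cell-size gradients,
and 3-D tissue. Passing recovery tests therefore shows the *arithmetic
and segmentation logic* are sound under a fair camera model — not that
thresholds transfer to any particular microscope. The montage exists
precisely because real images still need human threshold validation.

### Problem sizes used in the test suite

Recovery tests run on 320×320 px eyes with 250 cells (7 seeds per
condition; mean |A_Per/100 − truth| ≤ 0.05 against ground-truth pixel
counts, mean |N_Per/100 − truth| ≤ 0.03 on nuclear renders); the quadrant
homogeneity check uses 6000 cells so binomial sampling noise sits under
the 4-point band; geometry checks use a 2000×1400 px ellipse. These sizes
were chosen as the smallest at which the checked property is not
dominated by sampling noise.

## Known limitations

* On cytoplasmic renders, `N_Per` overestimates slightly: nuclei of
  non-expressing cells adjacent to expressing neighbours pick up reporter
  signal over part of their pixel set. Counting-based validation uses
  nuclear-localized renders, matching the statistic's intended use.
* Nucleus recall is bounded by merging of abutting blobs (~95% at the
  default density on measurable tissue); the ratio statistic `N_Per` is
  nearly unbiased because merging affects numerator and denominator
  alike.
* The KS normality p-value ignores parameter estimation (by design,
  flagged); a Lilliefors correction would reject more often.
* Degrees of freedom for contrasts use the between-mouse count; a
  Satterthwaite approximation is not implemented.
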