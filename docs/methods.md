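# Methods

This note documents the models, algorithms and parameter choices behind
each stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying procedures left room.

## Microglia morphometry

**Dynamic FWHM thresholding.** A single Gaussian is fitted by nonlinear
least squares to a 256-bin intensity histogram; the accepted band is
`[peak − FWHM/2, peak + FWHM/2]` (FWHM = 2.3548 σ), clipped to the
observed range. When the fit fails, the half-max crossings of the
smoothed raw histogram are used. A constant image raises a
degenerate-histogram error rather than returning an arbitrary band.

**Stain-mode selection.** On bright-field DAB images the dominant
histogram mode is the light background, so a band around the fitted peak
would select background, not cells. `stain_threshold` therefore fits the
dominant (background) Gaussian first, suppresses its ±1.5 FWHM
neighbourhood, fits up to two further Gaussians to the residual mass,
and picks the most-stained mode — lowest mean for the blue channel
(stain is dark), highest for saturation (stain is saturated). With
distinct body and process staining this selects the densely stained cell
bodies, which is what the body-segmentation step targets. A cell-free
image yields no stain mode and an empty mask, a valid result.

**Cell-body segmentation.** Pixels inside *either* the blue band or the
saturation band (HSV S channel) are selected; the saturation definition
is a choice, as the original color model is unnamed. The band mask is
porous under pixel noise (an FWHM band captures ~76% of a Gaussian
mode), so the mask is morphologically closed (disc radius 2, on an
edge-replicated pad so border contact is preserved) and hole-filled
before filtering. Regions under `area_min_px` (default 2000 px, tied to
full-resolution 60× acquisition and exposed as a parameter) or touching
the image border are removed; survivors are eroded by a disc of radius
2 px (the erosion amount is unspecified upstream; radius 2 is the
package default and configurable).

**Process segmentation.** Saturation channel only: Gaussian blur
(σ = 3 px default), squaring, convolution with a 3×3 Laplacian
(configurable), keep responses ≥ 0.8 × max ("within 20% of maximum"
read as a fraction of the maximum response), the same small-object and
border filters, outline extraction, subtraction of body pixels, dilation
(disc radius 2) and union with the body mask. The step's sensitivity
depends on the relative contrast of processes vs bodies; on fixtures
where processes are fainter than somata it mostly adds soma outlines and
ridge fragments, which is sufficient for the area:perimeter index.

**Hydraulic radius.** Area is the pixel count; the perimeter estimator
defaults to the total marching-squares contour length, which stays
within ~5% of the continuous value for discs (−4.9% on r = 50 px),
axis-aligned squares (+0.3%) and 1-px strips (−0.2%) alike. The Crofton
4-direction estimator (near-exact on discs but ~6% biased on axis-
aligned squares) and the weighted boundary-pixel count (~2× high on thin
strips) remain selectable; no single scikit-image estimator is accurate
across both compact and thin shapes, which decided the default. The
index is scale-covariant (up-sampling k× multiplies it by ≈ k).

**Cell selection.** Automated mode proxies the manual criteria (in
focus, completely segmented, fully contained): no border contact, area
bounds, optional solidity bound. Replay mode applies a recorded
choice mapping so a curation session is exactly reproducible.

**Density and summaries.** Density is centroids-in-polygon (shapely,
boundary-inclusive) divided by polygon area in mm². Group summaries
average per animal first, then report mean ± SEM over animals; a
single-animal group reports SEM as missing rather than zero.

## Transfer classification

Per z-slice, the marker channel (TH = red, Iba-1 = green by default;
the channel map is configurable because different experiments put the
syn signal in different channels) is mean-filtered with a 31-px square
kernel — about one expected soma diameter at the default 0.5 µm/px — and
thresholded to flood the soma interior. Marker and syn channels get
individual thresholds; the composite is the AND of the three masks, and
a cell is positive when some z-slice contains ≥ `min_punctum_px` = 4
contiguous composite pixels (single-pixel positives would be noise-
dominated; the knob is exposed). Positivity is OR-ed across slices,
matching orthogonal-view inspection of reconstructed cells.

Automatic thresholds are Otsu with a background floor of
mean + 3 sd: Otsu alone bisects the noise distribution of a signal-free
channel and would select roughly half its voxels, destroying specificity
on negative cells; the floor leaves channels with real signal untouched.
Fixed thresholds can be supplied instead.

In multi-cell stacks, adjacent somata can merge under the large
averaging filter; the footprint of the soma mask is instance-split by
watershed on its distance transform, seeded at peaks at least half a
kernel width apart. Percent positive is computed per animal
(100 · n⁺/n) and summarized per group as mean ± SEM.

## Bulk RNA-seq

* **CPM / log2CPM**: counts / (library size × TMM factor) × 10⁶; log2CPM
  uses a library-size-adjusted prior count (default 2), i.e. sample *j*
  adds `p_j = 2 · N_j / mean(N)` and computes
  `log2((x + p_j)/(N_j + 2 p_j) · 10⁶)`, following the convention of the
  standard tooling. FPKM divides CPM by gene length in kb.
* **Expression filters**: keep genes with CPM > 0.1 in ≥ 3 samples
  (raw CPM); then, after normalization, keep genes whose group-mean
  log2CPM exceeds 0 in the LPS *or* IL-4 group. PBS samples are carried
  through normalization but excluded from the contrast.
* **TMM**: reference sample = the one whose upper quartile of scaled
  counts is closest to the mean upper quartile; per sample, M-values are
  doubly trimmed (30% on M, 5% on A) and combined by inverse-variance
  weights from the asymptotic binomial variance; factors are rescaled to
  geometric mean 1. The implementation reproduces the reference
  implementation's factors to ≤ 5 × 10⁻⁶ on a frozen fixture and
  recovers planted composition shifts within 2% when ≤ 30% of genes are
  asymmetrically DE — the estimator's stated domain.
* **Moderated DE (LPS − IL-4; positive = up in LPS)**: log2CPM response
  with prior count 0.5; an unweighted per-gene fit supplies residual
  standard deviations whose square roots are lowess-smoothed (span 0.5)
  against average log2 count; observation weights are the inverse
  fourth power of the interpolated trend; weighted least squares per
  gene; residual variances are shrunk by empirical Bayes toward an
  abundance-dependent (lowess) prior, with the prior df estimated by
  moment matching of log variances (trigamma inversion). On a frozen
  fixture the log2FC agree with the reference precision-weighted
  pipeline to < 5 × 10⁻⁴ and the FDR < 0.05 sets are identical; on null
  simulations the type-I error at p < 0.05 is ~0.05.
* **BH adjustment** delegates to statsmodels' step-up implementation
  behind `bh_adjust` and is verified exhaustively against the brute-
  force definition in the tests.
* **MDS**: the distance between two samples is the root-mean-square of
  the top-500 largest absolute log2 differences per pair (leading
  log-fold-change); classical Torgerson scaling embeds the matrix.
* **Clustering** is scipy UPGMA on Euclidean distances; **enrichment**
  is the one-sided hypergeometric tail against a user-supplied
  background with BH across categories (no live database access: gene
  sets come from GMT files).

## Stereology

`N̂ = ΣQ⁻ · interval · (grid area / frame area) · (thickness /
dissector height)`. Nominal cut thickness (30 µm) stands in for measured
mounted thickness, which is unavailable off-microscope; it is a
parameter. Presets carry the two published designs (graft: interval 6,
70×70 µm frame, 150×150 µm grid; nigral: interval 8, 100×100, 200×200;
both 12 µm dissector, 2 µm guards). The Gundersen–Jensen CE uses the
noise term ΣQ⁻ plus the systematic-sampling variance from lag-0/1/2
products, with smoothness class m = 1 (denominator 240) or m = 0
(denominator 12) selectable, since which was used upstream is unstated.
A simulation of the full scheme (random section phase, random grid
offset, random dissector depth) on a uniform point population confirms
unbiasedness within 2% over 500 resamplings.

## Synthetic data

The generators are pure functions of their configs (seed included) and
every simulated object has exactly one truth record.

* **Confocal stacks** default to the acquisition geometry being
  emulated: 1024×1024 frames, 80 slices at 0.2 µm (a 16 µm stack),
  12-bit channels. The nominal in-plane pixel size is exposed explicitly
  (default 0.5 µm/px, chosen so a ~15 µm soma spans ~30 px, matching the
  default soma filter) because the acquisition metadata being emulated
  states it ambiguously. Somata are spheres with DAPI nuclei; positive
  cells (exactly `round(n_cells · frac_positive)`, chosen without
  replacement) receive puncta strictly inside the soma. Rendering order:
  ideal intensities → Gaussian PSF (z σ scaled by z-step/pixel-size) →
  scaled Poisson shot noise → additive Gaussian read noise (sd 30 at
  12-bit scale) → clip/quantize. Not emulated: stitching, bleaching,
  spectral crosstalk, aberrations — the downstream operators are not
  sensitive to them.
* **DAB sections**: amoeboid cells are discs (radius 28–40 px),
  ramified cells a small soma (12–18 px) with 4–7 radial branches
  (length 40–90 px, width 5 px). Branches are stained at 60% strength
  between soma color (120, 80, 40) and background (235, 230, 225),
  reflecting that thin processes take up less chromogen — this is also
  what gives the body/process segmentation distinct targets. Truth area
  and perimeter are measured on each cell's noise-free binary render
  with the package's default perimeter estimator. Additive RGB noise
  (sd 4) is applied last.
* **Counts**: baseline abundances are log-normal on the log2CPM scale
  (mean 4, sd 2), normalized to proportions once *before* the DE shift,
  so the planted LPS/IL-4 group-mean ratio of a DE gene is exactly
  2^lfc; the shift itself then perturbs realized library sums, giving
  the compositional asymmetry TMM exists to correct. Counts are
  gamma-Poisson with dispersion 0.1 by default (dispersion 0 reduces to
  Poisson); group sizes default to 4 PBS / 5 LPS / 8 IL-4; 70% of DE
  genes go up in LPS.

**What passing tests show — and do not.** The simulators contain
isolated, well-separated, spherical/ideal cells and clean two-mode
stains; real tissue has overlapping arbors, uneven staining, debris and
out-of-focus structure. Recovery results on these fixtures validate the
*implementations* (mask logic, estimators, calibration), not the
field performance of the measurements on real sections.

**Problem sizes.** The image-based tests and the acceptance script use
down-scaled fixtures — 256×256 frames, 16 z-slices, 10 cells per stack
(100 cells per condition across 10 stacks, 5 seeds), 512-768 px
sections, 1000–3000-gene matrices — chosen as the smallest sizes at
which every estimator operates in its intended regime; all analysis
parameters that scale with acquisition (the 2000-px area cutoff, soma
filter width) are exposed and documented above.

## Known limitations

* The morphometry process step inherits the upstream chain's contrast
  assumptions; heavily textured backgrounds would need the blur and
  response-fraction knobs retuned.
* The transfer classifier assigns one call per watershed-split soma;
  overlapping cells in z are not separated (per-slice 2-D processing
  with cross-slice OR, as designed).
* Statistical inference on percent-positive readouts (mixed-effects
  count regression) is intentionally out of scope and left to external
  statistics software; the package stops at per-animal/group summaries.
* Gene-set enrichment runs only on user-supplied collections; there is
  no live STRING/GO/GSEA retrieval.
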