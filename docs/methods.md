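# Methods

This note documents the models behind each module, the defaults and
why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer should know about.

## Stain separation

Brightfield absorbance follows Beer–Lambert: for 8-bit intensity I and
white level W, OD = −log10((I + ε)/W) per channel, with ε = 1 intensity
unit guarding the logarithm. The guard bounds the maximum
representable OD at −log10(1/255) ≈ 2.41, which matches what 8-bit
quantization can distinguish anyway; it also means a perfectly white
pixel maps to exactly 0 after clipping. The round trip RGB → OD → RGB
is exact to ±1 gray level on [1, 254].

Unmixing solves od = c·M per pixel, where the rows of M are the unit
absorption vectors of hematoxylin (0.650, 0.704, 0.286) and DAB
(0.268, 0.570, 0.776) — the Ruifrok–Johnston presets used by FIJI's
colour-deconvolution plugin — and a residual completed as their
normalized cross product. Slides from other scanners or stain lots can
supply a recalibrated 3×3 matrix as CSV. Negative concentrations are
unmixing noise; they are clipped to 0 for counting but retained
unclipped in `StainChannels.raw` so that deconvolve→recompose is the
identity to 1e−6 (the clipped maps alone cannot round-trip).

## Ki-67 pipeline

**Background subtraction.** The rolling-ball background is the
grayscale opening of the channel by a ball-shaped structuring
function. scikit-image's `rolling_ball` computes only the apex
envelope (a single erosion-like pass), which deviates from the true
opening near sharp peaks, and its exact algorithm needs ~17 s per
1024² channel at radius 50; we therefore implement the opening
directly (scipy grey erosion + dilation with the half-ball height
profile) and, for radii above 10 px, adopt FIJI's large-radius
strategy: block-minimum downscale (factor 2/4/8 for radius
>10/>30/>100), open at the reduced radius, bilinear-upsample the
background and cap it at the signal. Flat images and additive offsets
are removed exactly in both paths; measured background error against
the exact opening is ~0.003 OD mean on drift + nuclei scenes. The
radius unit is pixels ("radius of 50" in the FIJI convention);
`Ki67Config` exposes it.

**Contrast normalization** is a linear percentile stretch (defaults:
0.35% saturated pixels, FIJI's Enhance Contrast default) applied per
stain channel so both channels reach similar maxima before
thresholding.

**Segmentation.** Both positive and negative nuclei must be
segmented; neither channel alone contains all of them, so the
threshold runs on the pixelwise maximum of the two normalized
channels, with Otsu's threshold and 8-connected labeling. Touching
nuclei are deliberately not split: clumps fall to the >130 µm² filter,
consistent with a size-filtered particle analysis. Positivity is
decided on the *raw* unmixed concentrations (not the normalized maps):
a particle is positive when its mean DAB concentration exceeds its
mean hematoxylin concentration. This argmax rule is parameter-free; a
fixed DAB cutoff would need per-batch tuning.

**Size filter.** Areas are pixel counts × pixel_size_um². The bounds
are strict (< 13 µm² and > 130 µm² excluded; equality kept), reading
the published bounds literally. Whether the original scripts filtered
in µm² or px² at scanner resolution is unknowable; calibration is
explicit everywhere (default 0.25 µm/px, a typical 20× scan).

**ROI masks.** A tumor-region mask crops to its bounding box and
blanks non-mask pixels, making a rectangular mask exactly equivalent
to pre-cropping (verified by test). An empty mask yields a flagged
missing result, as does a field with no surviving nuclei (LI is NaN,
never 0, when the denominator is empty).

## OPN area fraction

The four classes (background outside tissue, background in tissue,
OPN-positive, OPN-negative) follow the trained-segmentation workflow:
a random forest (100 trees, fixed seed, single-threaded for
reproducibility) over per-pixel features — raw RGB plus, per channel
and per scale σ ∈ {1, 2, 4, 8} px, Gaussian-smoothed intensity,
gradient magnitude and Laplacian of Gaussian (3 + 9·|scales| = 39
features). The original feature set and scales were never published;
this reconstruction spans sprinkle-to-structure sizes at 20× and is
documented as a reconstruction. Prediction ties break toward the
lower class id (sklearn's first-argmax). The two background classes
stay distinct through segmentation and are merged only in the area
denominator: fraction = 100·A₃/(A₃+A₄), making the result invariant
to how much empty slide the field of view contains. A field with no
tissue pixels returns NaN with a warning.

Classifiers serialize with joblib and enforce their training feature
layout by name at prediction time (reordering is allowed, mismatch is
an error).

## Scoring

OPN IHC score = intensity × percent, no rounding; range [0, 300].
Allred = proportion score + intensity score with consistency enforced
(percent > 0 ⇔ intensity ≥ 1), so the totals are exactly {0, 2–8}.
The published proportion bins share their edges (1–10, 10–33, 33–67,
67–100); we use left-closed/right-open bins with the last closed at
100. The membership of exactly 1/10/33/67% is not decidable from the
published description; the edges are an argument for users who prefer
the other convention. `estimate_intensity` is a quantitative surrogate
for the visual 0–3 intensity: it bins the mean DAB OD of the positive
area at cutoffs 0.15/0.35/0.60 (weak/moderate/strong in OD terms for
typical DAB staining) and floors the score at 1 whenever any positive
area exists, preserving the Allred consistency rule.

## Grading

The rule engine is total and monotone (more mitoses or more atypical
features never lower the grade). A mitotic count of exactly 20/10 HPF
sits between the published grade-II band (4–19) and "above 20"; we
assign grade III at ≥ 20, the human WHO-2016 convention. Mitotic
counts are interpreted per 10 HPF throughout. Benign subtype labels
are metadata and never influence the grade; chordoid/clear-cell
subtype-driven grade II is out of scope (no such rule details in the
cohorts this package serves).

## Statistics

Spearman's rs is the Pearson correlation of tie-averaged ranks with
the two-sided t approximation (n − 2 df), via scipy. Kruskal–Wallis is
tie-corrected with a χ² p-value (k − 1 df), via scipy. Dunn's z for
groups i, j is (R̄ᵢ − R̄ⱼ)/√[(N(N+1)/12 − ΣT(t³−t)/(12(N−1)))·(1/nᵢ+1/nⱼ)]
with two-sided normal p-values and Bonferroni multiplier k(k−1)/2
capped at 1 — hand-implemented (no installed package provides it) and
tested against an independent naive implementation to 1e−10. Two-sided
p-values follow the dunnTest default. Correlations are declined below
n = 3 and flagged "low number"; missing values drop pairwise for
correlations and per measure for group tests. α = 0.05 two-sided
throughout. The familywise type-I error of the full KW→Dunn chain,
measured on 1000 null replicates with cohort-like group sizes, is
0.035 (KW alone: 0.048).

## Synthetic data

The Ki-67 generator places non-overlapping ellipses (lognormal areas,
median 45 µm², σ_log 0.35, clipped to [16, 120] µm² so the central
mass sits inside the 13–130 µm² analysis window), paints each with
hematoxylin (peak OD 0.8) or DAB (peak OD 0.9) ±15% jitter, smooths
edges (σ 0.6 px), adds smooth neutral drift (0.06 OD) and Gaussian
sensor noise (σ 2 gray levels), and renders through the same
Beer–Lambert mixing the analysis inverts. The positive count is
round(n·fraction) (banker's rounding); recorded truth is the realized
tally. Artifacts — DAB specks of 1–8 µm² and clumps of 150–300 µm² —
are placed in free space so they exercise the size filter. Default
field: 1024² px at 0.5 µm/px (a 0.26 mm² field holding ≥ 500 nuclei at
realistic density while keeping a 30-slide recovery sweep near one
minute); the pixel size is a SlideSpec field, not a constant.

The OPN generator carves a noisy-ellipse tissue section into gaps,
positive and negative tissue by thresholding smooth Gaussian random
fields at quantiles, so the realized positive fraction matches the
request to rasterization accuracy; intensity levels 1/2/3 map to DAB
OD 0.25/0.45/0.70. Scribbles are sampled from the 2-px-eroded truth
regions, the way a human avoids class boundaries.

The cohort generator draws Ki-67 LI lognormal (median 6.1, σ_log 0.9 —
mean ≈ 9, matching published feline meningioma cohorts), OPN percent
as normal(51, 20) clipped to [0, 100], intensity with weak/moderate/
strong prevalence 7/14/32 of 53, sex categories 19/7/27/0 of 53, and
computes the score columns through the scoring module itself, so every
score invariant holds by construction. Optional structure: per-subtype
log-shifts of LI and a Gaussian-copula rank correlation between LI and
OPN percent.

What the generators do **not** emulate: chromatin texture, nucleolar
substructure, overlapping/touching nuclei (real clusters are handled
only via the size filter), stain-vector drift between batches (a
SlideSpec switch can perturb the matrix), uneven section thickness,
and scanner color profiles. A green recovery test therefore
establishes that the measurement chain is unbiased under correct
optics and calibrated stain vectors — not that it is robust to badly
calibrated stains or heavy nuclear overlap.

## Known limitations

- Whole-slide pyramid formats are out of scope; the unit of work is a
  field of view or pre-exported region.
- No watershed splitting of touching nuclei; dense fields will push
  genuine nuclei into the >130 µm² exclusion.
- The OPN classifier is not designed to transfer across stain batches;
  retrain per batch from fresh scribbles.
- Mitotic figures, brain invasion and subtype are inputs, never
  computed from images.
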