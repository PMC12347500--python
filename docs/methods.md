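# Methods

This note documents the models and procedures implemented in
`tvclahe`, the choices made where the underlying protocol leaves room,
and what the synthetic phantom study does and does not demonstrate.

## The enhancement problem

Periapical radiographs of mandibular incisors often fail to show the
root canal system clearly: canals are thin (roughly 0.2–1 mm), only a
few gray levels darker than the surrounding dentin, and superimposed
on textured trabecular bone and slow illumination gradients.  Missed
canals are a leading cause of endodontic failure, and CBCT — the 3-D
gold standard — is not always available.  Contrast enhancement of the
2-D radiograph is the low-cost alternative this package implements and
evaluates.

## Enhancement algorithms

All algorithms operate on 8-bit images (256 gray levels); 16-bit DICOM
input is reduced by an observed min–max rescale (`to_8bit`), the only
reduction that requires no window/level metadata.  A single rounding
rule (half up) is used everywhere so outputs are bit-reproducible.

**Histogram equalization (HE).** Global remapping
`m(v) = round((cdf(v) − cdf_min) / (N − cdf_min) · 255)` so that the
darkest occupied level maps to 0 and the cumulative histogram becomes
approximately linear.

**CLAHE.** The image is padded (edge-replicate) to a multiple of the
tile grid (default 8×8).  Per tile, the 256-bin histogram is clipped
at `β = max(1, round(clip · tile_pixels / 256))`; the clipped excess is
redistributed uniformly in a single pass, `floor(E/256)` per bin plus
one extra count to the first `E mod 256` bins, which conserves the
count exactly and is deterministic.  The per-tile mapping is
`round(cdf_t(v)/tile_pixels · 255)` (no cdf-origin shift, hence the
small documented offset against HE in the degenerate one-tile,
no-clipping configuration).  Output pixels bilinearly blend the four
nearest tile-center mappings; border strips clamp to the available
tiles.  The stand-alone default clip limit is 2.0.

**Gaussian-background division.** The image is divided by its own
Gaussian blur (σ = 50 px, reflect boundary, blur floored at 5 gray
levels), suppressing large-scale trends while retaining local
structure.  The ratio image has no intrinsic range, so it is min–max
rescaled onto [0, 255]; a constant ratio maps to mid-gray 128.  Min–max
was chosen because it is parameter-free; the alternative (fixed
gain around ratio 1) would introduce two new unconstrained constants.

**TV denoising (Chambolle).** The ROF model
`min_u TV(u) + (1/2λ)‖u − f‖²` with λ = 0.1 on [0, 1]-scaled
intensities, solved by Chambolle's dual projection
`p ← (p + τ∇(div p − f/λ)) / (1 + τ|∇(div p − f/λ)|)` with the
classical step τ = 0.25, stopping when the largest dual change falls
below 2·10⁻⁴ or after 200 iterations.  Forward-difference gradient
with zero last row/column and its exact adjoint divergence.  The
implementation is cross-checked in the test suite against an
independent solver (scikit-image) to within one gray level.

**TV-CLAHE.** The four-stage composition
CLAHE(1.5, 8×8) → background division → TV denoise (0.1) →
CLAHE(1.5, 8×8).  Both CLAHE stages use the same parameters.

**G-CLAHE (reconstruction).** GEI = global HE of the input; starting
from the input, CLAHE is applied repeatedly with clip `1.0 + 0.5k` at
round k, and the iteration stops the first time SSIM to the GEI
decreases, returning the previous iterate (hard cap 20 rounds).  The
source algorithm's exact schedule and similarity measure are not fully
specified in the material this package works from; the clip schedule,
SSIM choice and cap are this package's own reconstruction and should
be read as a faithful sketch, not a reference implementation.

**CLAHE-POA (reconstruction).** A pelican-style population search
(population 10, 20 iterations, clip bounds 0.5–8.0, seeded) over the
CLAHE clip limit.  Objective: `−PSNR_n − SSIM + MSE_n` of the enhanced
image against the input, PSNR and MSE min–max normalized over the
current population, equal weights.  Exploration moves a candidate
toward a better random candidate (or away from a worse one);
exploitation perturbs within a radius shrinking as
`0.2·(1 − t/T)·range`; moves are accepted greedily.  The composite
weights and hyper-parameters are not published in the source material;
equal weights after normalization is the neutral choice.

## Image-quality metrics

PSNR (`10·log₁₀(MAX²/MSE)`, MAX = 255), SNR (`10·log₁₀(μ²/σ²)` over
the whole image), Shannon entropy and order-2 Rényi entropy of the
256-bin normalized histogram (bits), and SSIM.  SSIM is computed from
whole-image statistics — one global window — with
C1 = (0.01·255)², C2 = (0.03·255)²; a 7×7 mean-pooled windowed variant
is available behind a flag but the global form is canonical here.
Population (N-denominator) variances are used in every metric.  A zero
MSE or zero σ yields +infinity, serialized as `inf` in CSV and ordered
above any finite value; a zero-mean noisy image yields −infinity for
SNR, which the printed formula admits.

**Canal CNR.** `|μ_ring − μ_canal| / σ_ring`, the ring being the
ground-truth canal mask dilated by a 5 px disk minus the mask.  CNR is
the objective surrogate for observer-rated canal visibility on
phantoms; it requires a ground-truth mask and therefore exists only in
the synthetic study.

## The phantom generator

Each phantom is built deterministically from a seed: a bone background
(low-frequency Gaussian random field, correlation length ≈ min(h,w)/9,
amplitude 10 gray levels, plus a random linear gradient of ±15), a
bright soft-edged tooth (+40 gray levels, crown wide, apex narrow),
one or two canal centerlines following a Vertucci configuration drawn
from the incisor mix (I/II/III/IV = 70/15/10/5%), rasterized at the
canal width and subtracted at the canal contrast (default Δ = 8),
then acquisition blur (σ = 3 px) and additive Gaussian detector noise
(σ = 6), clamped to [0, 255].  Vertucci II merges at mid-root, III
splits and rejoins, IV stays separate — schematic geometry, not
anatomy.

**Canvas scale.** The default canvas is 600×800 px: the 1200×1600
detector geometry at half scale (0.036 mm/px), with the canal default
12 px ≈ 0.43 mm.  The scale is dictated by the TV stage: a
fixed-weight ROF denoiser erases any ridge or valley shallower than
roughly `2λ/width` of the intensity range, so a canal must keep
approximately the width-to-weight ratio it has on the clinical
detector (~17–55 px) for the pipeline to operate in the same regime.
Measurements with this implementation show the erosion directly: a
3 px line loses ~17 gray levels of depth at λ = 0.1, a 12 px line ~4.
At quarter scale (300×400, 3–6 px canals) the same pipeline removes
the canal entirely, regardless of implementation quality, and the
enhancement comparison degenerates.  Half scale is therefore the
largest downscale that still tests what the method does clinically;
it keeps the full 20-seed battery under about a minute on one CPU.

**What the phantoms do not model.** Overlapping anatomy ("anatomical
noise"), scatter, detector nonlinearity, pulp-chamber detail,
calcification, patient positioning.  Passing the phantom battery shows
the pipeline's contrast/denoising behavior in the intended geometry;
it does not certify clinical detection rates.

## The rating simulator and statistics harness

Ordinal 1–5 visibility ratings are simulated from a latent-variable
model: method effect + image random effect (N(0, 0.5), shared across
methods and raters, giving the paired structure) + rater bias +
independent N(0, noise) per cell, discretized at thresholds
{1.5, 2.5, 3.5, 4.5}.

The harness mirrors the evaluation protocol: Shapiro–Wilk as a
normality gate (delegated to scipy; any p < 0.05 flags the family
non-normal), paired Wilcoxon signed-rank (zero differences dropped,
mid-ranks for ties, statistic `min(W+, W−)`; exact two-sided p by full
enumeration of sign patterns via dynamic programming up to n = 25,
normal approximation with tie and continuity corrections beyond),
Bonferroni over the whole method × metric family, the Friedman test
with the standard tie-correction divisor and the asymptotic χ²(k−1)
reference, and ICC(2,k) — two-way random effects, absolute agreement,
average measure — with a 95% CI from the F-based single-rater interval
transformed by the Spearman–Brown relation.  ICC and Friedman are
cross-checked in the tests against independent implementations
(pingouin, scipy) and brute-force sums-of-squares/enumeration oracles.

## Numerical conventions and degenerate inputs

Round half up everywhere; population variances; constant images pass
through HE/CLAHE/TV unchanged (CLAHE maps them to a possibly different
but still constant level); constant ratio → 128; all-zero paired
differences and zero-variance rating matrices raise degenerate-input
errors rather than returning NaN.  All stochastic components (phantom
generation, rating simulation, the POA search) consume a single
explicit integer seed and are bit-reproducible.

## Known limitations

* G-CLAHE and CLAHE-POA are best-effort reconstructions from prose
  descriptions; their outputs should not be compared numerically
  against the original authors' code.
* The fractional-derivative enhancer (KCFDO) that sometimes appears in
  comparative studies is not implementable from the material this
  package is based on and is out of scope.
* SNR in dB of a typical radiograph is small (≈ 2) because the global
  standard deviation is of the same order as the mean; the metric is
  reported as defined, but it measures global brightness uniformity
  more than noise.
* The benchmark report reproduces the *structure* of a clinical
  comparison table; its numbers on phantoms are not comparable to
  numbers computed on patient images.
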