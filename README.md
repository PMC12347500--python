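# tvclahe

Contrast enhancement of periapical dental radiographs for root-canal
visibility, built around **TV-CLAHE**: contrast-limited adaptive
histogram equalization combined with total-variation denoising.

Thin, low-contrast root canals are easy to miss on 2-D periapical
radiographs, and missed canals are a major cause of endodontic
failure.  This package provides, for imaging researchers and
image-analysis practitioners:

* the TV-CLAHE pipeline and baseline enhancers (HE, CLAHE, G-CLAHE,
  CLAHE-POA), implemented from first principles;
* five image-quality metrics (PSNR, SNR, Shannon and order-2 Rényi
  entropy, SSIM) plus a canal contrast-to-noise ratio (CNR);
* a synthetic periapical phantom generator with ground-truth canal
  masks (Vertucci type I–IV geometries), so every stage is testable
  without patient data;
* an observer-statistics harness (Shapiro–Wilk gate, exact Wilcoxon
  signed-rank, Bonferroni, Friedman, ICC(2,k)) and a benchmark-report
  builder;
* a `tvclahe` command-line interface over all of the above.

## The method

TV-CLAHE enhances a radiograph in four deterministic stages:

1. **CLAHE** (clip limit 1.5, 8×8 tile grid) — local contrast.  Each
   tile's 256-bin histogram is clipped at
   β = max(1, round(clip·tile_pixels/256)) with uniform excess
   redistribution; tile mappings m_t(v) = round(cdf_t(v)/tile_pixels·255)
   are blended bilinearly.
2. **Background division** — the image is divided by its Gaussian blur
   (σ = 50 px, floored at 5), removing large-scale intensity trends.
3. **TV denoising** — Chambolle's dual projection for the ROF model
   min_u TV(u) + (1/2λ)‖u−f‖², λ = 0.1, removing the noise the first
   stage amplified while preserving canal edges.
4. **CLAHE** again with the same parameters.

Enhancement quality is scored with PSNR = 10·log₁₀(MAX²/MSE),
SNR = 10·log₁₀(μ²/σ²), H = −Σ p(i)·log₂ p(i),
H₂ = −log₂ Σ p(i)², the global SSIM index, and on phantoms the canal
CNR = |μ_ring − μ_canal| / σ_ring against the ground-truth mask.

## Worked example

```python
from tvclahe import (PhantomParams, generate_phantom, tv_clahe, clahe,
                     canal_cnr, compute_report)

ph = generate_phantom(PhantomParams(seed=42))   # 600x800 phantom + mask
enhanced = tv_clahe(ph.image)

print(canal_cnr(ph.image, ph.canal_mask))                    # 0.310
print(canal_cnr(clahe(ph.image, 2.0, (8, 8)), ph.canal_mask))  # 0.635
print(canal_cnr(enhanced, ph.canal_mask))                    # 1.004
```

The canal of this phantom (a Vertucci type I single canal, 8 gray
levels deep under noise of σ = 6) has CNR 0.31 in the raw image —
barely above the detection threshold.  Plain CLAHE raises it to 0.64;
TV-CLAHE reaches 1.00, because the denoising stage removes the noise
that CLAHE amplifies while the canal edges survive.  The five quality
metrics of the enhanced image against the original:

```python
rep = compute_report("phantom42", "tv-clahe", ph.image, enhanced)
# PSNR=17.60 dB  SNR=12.56 dB  H=6.92 bits  H2=6.57 bits  SSIM=0.40
```

Low PSNR/SSIM with increased entropy is the expected signature of an
aggressive local-contrast method: it trades fidelity to the original
pixels for visibility of structure.

The same run from the shell:

```sh
tvclahe phantom --n 1 --out phantoms --seed 42
tvclahe enhance phantoms/phantom_000.png enhanced.png --method tv-clahe
tvclahe benchmark phantoms --methods he,clahe,tv-clahe --out bench
```

`bench/metrics.csv` holds one row per image × method with the five
metrics; `bench/report.csv` adds mean (SD) summaries, paired Wilcoxon
tests against the originals and Bonferroni-corrected significance
flags.

## Layout

```
src/tvclahe/
  imagio.py    GrayImage container; PNG/TIFF/DICOM I/O; 16->8 bit
  enhance.py   HE, CLAHE, background division, Chambolle TV, TV-CLAHE,
               G-CLAHE, CLAHE-POA
  metrics.py   PSNR, SNR, entropies, SSIM, canal CNR
  phantom.py   phantom generator and ordinal rating simulator
  stats.py     Wilcoxon, Bonferroni, Friedman, ICC(2,k), report builder
  cli.py       enhance / phantom / benchmark subcommands
docs/methods.md   model documentation and design rationale
```
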