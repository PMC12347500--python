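"""Image-quality metrics.

Five whole-image metrics used to compare enhancement methods —
PSNR, SNR, Shannon entropy, order-2 Renyi entropy and SSIM — plus the
canal contrast-to-noise ratio (CNR), an objective surrogate for
observer-rated root-canal visibility on phantoms with known masks.

Conventions, applied uniformly: population (N-denominator) variances
and covariances; entropies over the 256-bin normalized histogram in
bits; a zero MSE or zero standard deviation yields +infinity
(serialized as ``inf`` in CSV reports and ordered above any finite
value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imagio import GrayImage

__all__ = [
    "MetricReport",
    "psnr",
    "snr",
    "shannon_entropy",
    "renyi_entropy",
    "ssim",
    "canal_cnr",
    "compute_report",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("psnr", "snr", "shannon_entropy", "renyi_entropy", "ssim")


@dataclass(frozen=True)
class MetricReport:
    """Per-image, per-method values of the five quality metrics."""

    image_id: str
    method: str
    psnr: float
    snr: float
    shannon_entropy: float
    renyi_entropy: float
    ssim: float


def _check_pair(x: GrayImage, y: GrayImage) -> None:
    if x.pixels.shape != y.pixels.shape:
        raise ValueError(
            f"image dimensions differ: {x.pixels.shape} vs {y.pixels.shape}")
    if x.bit_depth != y.bit_depth:
        raise ValueError(f"bit depths differ: {x.bit_depth} vs {y.bit_depth}")


def psnr(ref: GrayImage, test: GrayImage) -> float:
    """Peak signal-to-noise ratio, 10 log10(MAX^2 / MSE), in dB.

    MAX is the maximum representable intensity (255 for 8-bit);
    identical images give +infinity.
    """
    _check_pair(ref, test)
    mse = float(np.mean((ref.astype_float() - test.astype_float()) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(ref.max_value ** 2 / mse)


def snr(img: GrayImage) -> float:
    """Global signal-to-noise ratio, 10 log10(mu^2 / sigma^2), in dB.

    sigma is the population standard deviation of the whole image; a
    constant image gives +infinity.
    """
    a = img.astype_float()
    mu = a.mean()
    var = a.var()  # population
    if var == 0.0:
        return float("inf")
    if mu == 0.0:
        return float("-inf")
    return 10.0 * np.log10(mu * mu / var)


def _histogram_probs(img: GrayImage) -> np.ndarray:
    if img.bit_depth != 8:
        raise ValueError("entropy metrics are defined on 8-bit images")
    counts = np.bincount(img.pixels.ravel(), minlength=256)
    return counts / counts.sum()


def shannon_entropy(img: GrayImage) -> float:
    """Shannon entropy of the 256-bin histogram, in bits (0 log 0 := 0)."""
    p = _histogram_probs(img)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def renyi_entropy(img: GrayImage, alpha: float = 2.0) -> float:
    """Renyi entropy of order alpha, (1/(1-alpha)) log2 sum p_i^alpha.

    Order 2 (the default) emphasizes the dominant intensities; alpha
    must be positive and different from 1 (use
    :func:`shannon_entropy` for the alpha -> 1 limit).
    """
    if alpha <= 0 or alpha == 1.0:
        raise ValueError("alpha must be > 0 and != 1; use shannon_entropy for alpha=1")
    p = _histogram_probs(img)
    nz = p[p > 0]
    return float(np.log2((nz ** alpha).sum()) / (1.0 - alpha))


def ssim(x: GrayImage, y: GrayImage, windowed: bool = False) -> float:
    """Structural similarity index from whole-image statistics.

    The global (single-window) form
    ``(2 mux muy + C1)(2 sxy + C2) / ((mux^2 + muy^2 + C1)(sx^2 + sy^2 + C2))``
    with C1 = (0.01*255)^2, C2 = (0.03*255)^2 and population
    (co)variances.  ``windowed=True`` instead averages the same
    expression over 7x7 uniform local windows (mean-pooled), the
    sliding-window convention; the global form is the canonical one
    here.
    """
    _check_pair(x, y)
    c1 = (0.01 * 255.0) ** 2
    c2 = (0.03 * 255.0) ** 2
    ax = x.astype_float()
    ay = y.astype_float()
    if not windowed:
        mux, muy = ax.mean(), ay.mean()
        vx, vy = ax.var(), ay.var()
        cov = ((ax - mux) * (ay - muy)).mean()
        num = (2 * mux * muy + c1) * (2 * cov + c2)
        den = (mux * mux + muy * muy + c1) * (vx + vy + c2)
        return float(num / den)
    size = 7
    mux = ndimage.uniform_filter(ax, size)
    muy = ndimage.uniform_filter(ay, size)
    vx = ndimage.uniform_filter(ax * ax, size) - mux * mux
    vy = ndimage.uniform_filter(ay * ay, size) - muy * muy
    cov = ndimage.uniform_filter(ax * ay, size) - mux * muy
    num = (2 * mux * muy + c1) * (2 * cov + c2)
    den = (mux * mux + muy * muy + c1) * (vx + vy + c2)
    return float((num / den).mean())


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def canal_cnr(img: GrayImage, canal_mask: np.ndarray, ring_radius: int = 5) -> float:
    """Contrast-to-noise ratio of a canal against its surrounding ring.

    ``CNR = |mean(ring) - mean(canal)| / std(ring)`` where the ring is
    the mask dilated by a disk of ``ring_radius`` pixels minus the mask
    itself (population std; a noiseless ring gives +infinity).
    """
    mask = np.asarray(canal_mask, dtype=bool)
    if mask.shape != img.pixels.shape:
        raise ValueError("mask dimensions must match the image")
    if not mask.any():
        raise ValueError("canal mask is empty")
    ring = ndimage.binary_dilation(mask, structure=_disk(ring_radius)) & ~mask
    if not ring.any():
        raise ValueError("background ring is empty")
    a = img.astype_float()
    mu_canal = a[mask].mean()
    ring_vals = a[ring]
    sigma_ring = ring_vals.std()  # population
    contrast = abs(ring_vals.mean() - mu_canal)
    if sigma_ring == 0.0:
        return float("inf")
    return float(contrast / sigma_ring)


def compute_report(image_id: str, method: str, ref: GrayImage,
                   test: GrayImage) -> MetricReport:
    """All five metrics of ``test`` relative to the reference image."""
    return MetricReport(
        image_id=image_id,
        method=method,
        psnr=psnr(ref, test),
        snr=snr(test),
        shannon_entropy=shannon_entropy(test),
        renyi_entropy=renyi_entropy(test, 2.0),
        ssim=ssim(ref, test),
    )
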