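"""Contrast-enhancement algorithms for periapical radiographs.

Implements, from first principles:

* global histogram equalization (HE),
* contrast-limited adaptive histogram equalization (CLAHE) with
  clip-and-redistribute histograms and bilinear blending of tile
  mappings,
* Gaussian-background division normalization,
* Chambolle's dual-projection solver for total-variation (ROF)
  denoising,
* the composed TV-CLAHE pipeline
  (CLAHE -> background normalization -> TV denoise -> CLAHE),
* G-CLAHE, an iterative local enhancement stopped when similarity to
  the globally equalized image starts to fall, and
* CLAHE-POA, a pelican-style population search over the CLAHE clip
  limit driven by a PSNR/SSIM/MSE composite objective.

All operations take and return 8-bit :class:`~tvclahe.imagio.GrayImage`
instances of identical dimensions and are bit-reproducible (stochastic
search is seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imagio import GrayImage, round_half_up
from . import metrics as _metrics

__all__ = [
    "EnhanceParams",
    "hist_equalize",
    "clahe",
    "clip_redistribute",
    "gaussian_background_normalize",
    "tv_denoise_chambolle",
    "tv_clahe",
    "g_clahe",
    "clahe_poa",
    "METHODS",
    "apply_method",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Tunables of the enhancement pipeline.

    Defaults reproduce the reference protocol: stand-alone CLAHE uses
    clip limit 2.0 on an 8x8 tile grid; the TV-CLAHE stages use clip
    1.5 with the same grid, background normalization with a Gaussian
    of sigma = 50 px floored at 5 gray levels, and Chambolle TV
    denoising with fidelity weight 0.1.
    """

    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    tv_clip: float = 1.5
    norm_sigma: float = 50.0
    norm_floor: float = 5.0
    tv_weight: float = 0.1
    tv_max_iter: int = 200
    tv_tol: float = 2e-4
    poa_clip_bounds: tuple[float, float] = (0.5, 8.0)
    poa_pop: int = 10
    poa_iters: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0 or self.tv_clip <= 0:
            raise ValueError("clip limits must be positive")
        r, c = self.clahe_tiles
        if r < 1 or c < 1:
            raise ValueError("tile grid must be positive")
        if self.norm_sigma <= 0 or self.norm_floor <= 0:
            raise ValueError("norm_sigma and norm_floor must be positive")
        if self.tv_weight <= 0:
            raise ValueError("tv_weight must be positive")
        lo, hi = self.poa_clip_bounds
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("poa_clip_bounds must satisfy 0 < low <= high")


def _require_8bit(img: GrayImage) -> np.ndarray:
    if img.bit_depth != 8:
        raise ValueError("enhancement operates on 8-bit images; apply to_8bit first")
    return img.pixels


def hist_equalize(img: GrayImage) -> GrayImage:
    """Global histogram equalization over the 256-level histogram.

    The mapping is ``m(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255)``
    where ``cdf_min`` is the smallest nonzero cumulative count, so the
    darkest occupied level maps to 0 and the brightest to 255.
    Constant images are returned unchanged.
    """
    a = _require_8bit(img)
    hist = np.bincount(a.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = a.size
    cdf_min = int(cdf[np.flatnonzero(hist)[0]])
    if cdf_min == n:  # constant image
        return GrayImage(a.copy(), 8)
    lut = round_half_up((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return GrayImage(lut[a], 8)


def clip_redistribute(hist: np.ndarray, beta: int) -> np.ndarray:
    """Clip histogram counts at ``beta`` and redistribute the excess.

    The total excess E is spread uniformly, floor(E / nbins) to every
    bin plus one extra count to each of the first ``E mod nbins`` bins
    (ascending order).  A single pass; the total count is conserved
    exactly.
    """
    hist = np.asarray(hist, dtype=np.int64)
    clipped = np.minimum(hist, beta)
    excess = int(hist.sum() - clipped.sum())
    nbins = hist.size
    base, rem = divmod(excess, nbins)
    out = clipped + base
    out[:rem] += 1
    return out


def clahe(img: GrayImage, clip: float = 2.0,
          tiles: tuple[int, int] = (8, 8)) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is padded (edge-replicate) so its dimensions divide
    evenly into the tile grid.  Each tile's 256-bin histogram is
    clipped at ``beta = max(1, round(clip * tile_pixels / 256))`` with
    uniform excess redistribution, its cumulative mapping
    ``m_t(v) = round(cdf_t(v) / tile_pixels * 255)`` computed, and each
    output pixel is the bilinear blend of the four nearest tile-center
    mappings (border strips clamp to the available tiles).
    """
    a = _require_8bit(img)
    rows, cols = int(tiles[0]), int(tiles[1])
    if rows < 1 or cols < 1:
        raise ValueError("tile grid must be positive")
    h, w = a.shape
    if rows > h or cols > w:
        raise ValueError(f"tile grid {rows}x{cols} larger than image {h}x{w}")
    if clip <= 0:
        raise ValueError("clip must be positive")

    th = -(-h // rows)  # ceil division
    tw = -(-w // cols)
    hp, wp = th * rows, tw * cols
    ap = np.pad(a, ((0, hp - h), (0, wp - w)), mode="edge")

    tile_pixels = th * tw
    beta = max(1, int(round_half_up(clip * tile_pixels / 256.0)))

    luts = np.empty((rows, cols, 256), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = ap[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256)
            hist = clip_redistribute(hist, beta)
            cdf = np.cumsum(hist)
            luts[i, j] = round_half_up(cdf / tile_pixels * 255.0)

    # tile-center coordinates in padded-pixel space; clamp outside strips
    gy = np.clip((np.arange(hp) + 0.5) / th - 0.5, 0.0, rows - 1.0)
    gx = np.clip((np.arange(wp) + 0.5) / tw - 0.5, 0.0, cols - 1.0)
    i0 = np.floor(gy).astype(np.intp)
    j0 = np.floor(gx).astype(np.intp)
    i1 = np.minimum(i0 + 1, rows - 1)
    j1 = np.minimum(j0 + 1, cols - 1)
    fy = (gy - i0)[:, None]
    fx = (gx - j0)[None, :]

    rr0 = i0[:, None]
    rr1 = i1[:, None]
    cc0 = j0[None, :]
    cc1 = j1[None, :]
    v = ap
    out = ((1 - fy) * (1 - fx) * luts[rr0, cc0, v]
           + (1 - fy) * fx * luts[rr0, cc1, v]
           + fy * (1 - fx) * luts[rr1, cc0, v]
           + fy * fx * luts[rr1, cc1, v])
    out = np.clip(round_half_up(out), 0, 255).astype(np.uint8)
    return GrayImage(out[:h, :w], 8)


def gaussian_background_normalize(img: GrayImage, sigma: float = 50.0,
                                  floor: float = 5.0) -> GrayImage:
    """Divide out the large-scale background trend.

    The image is divided by its Gaussian blur (reflect boundary, the
    blur clamped below at ``floor`` to avoid division blow-up); the
    ratio, which has no intrinsic gray range, is min--max rescaled onto
    [0, 255].  A constant ratio maps to mid-gray 128.
    """
    if sigma <= 0 or floor <= 0:
        raise ValueError("sigma and floor must be positive")
    a = _require_8bit(img).astype(np.float64)
    bg = ndimage.gaussian_filter(a, sigma=sigma, mode="reflect")
    bg = np.maximum(bg, floor)
    ratio = a / bg
    lo, hi = ratio.min(), ratio.max()
    if hi - lo < 1e-12:
        return GrayImage(np.full(a.shape, 128, dtype=np.uint8), 8)
    out = round_half_up((ratio - lo) / (hi - lo) * 255.0)
    return GrayImage(out.astype(np.uint8), 8)


def _gradient(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy = np.zeros_like(u)
    gx = np.zeros_like(u)
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    return gy, gx


def _divergence(py: np.ndarray, px: np.ndarray) -> np.ndarray:
    d = np.empty_like(py)
    d[0, :] = py[0, :]
    d[1:, :] = py[1:, :] - py[:-1, :]
    d[:, 0] += px[:, 0]
    d[:, 1:] += px[:, 1:] - px[:, :-1]
    return d


def tv_denoise_chambolle(img: GrayImage, weight: float = 0.1,
                         max_iter: int = 200, tol: float = 2e-4) -> GrayImage:
    """Total-variation denoising by Chambolle's dual projection.

    Solves the ROF model ``min_u TV(u) + (1 / 2 lambda) ||u - f||^2``
    with ``lambda = weight`` on intensities scaled to [0, 1].  The dual
    variable p is iterated as
    ``p <- (p + tau grad(div p - f/lambda)) / (1 + tau |grad(div p - f/lambda)|)``
    (equivalently ``grad = -grad(u)/lambda`` with ``u = f - lambda div p``)
    using the classical step ``tau = 0.25``, until the largest change
    in p falls below ``tol`` or ``max_iter`` is reached.  The result is
    clipped back to [0, 255] and rounded.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    f = _require_8bit(img).astype(np.float64) / 255.0
    py = np.zeros_like(f)
    px = np.zeros_like(f)
    tau = 0.25
    c = tau / weight
    u = f
    for _ in range(int(max_iter)):
        u = f - weight * _divergence(py, px)
        gy, gx = _gradient(u)
        norm = np.sqrt(gy * gy + gx * gx)
        denom = 1.0 + c * norm
        py_new = (py - c * gy) / denom
        px_new = (px - c * gx) / denom
        change = max(np.abs(py_new - py).max(), np.abs(px_new - px).max())
        py, px = py_new, px_new
        if change < tol:
            break
    u = f - weight * _divergence(py, px)
    out = np.clip(round_half_up(u * 255.0), 0, 255).astype(np.uint8)
    return GrayImage(out, 8)


def tv_clahe(img: GrayImage, params: EnhanceParams | None = None) -> GrayImage:
    """The four-stage TV-CLAHE pipeline.

    1. CLAHE (clip 1.5, 8x8 tiles) for initial local contrast;
    2. division by the Gaussian-blurred image (sigma 50, floor 5) to
       suppress large-scale intensity trends;
    3. Chambolle TV denoising (weight 0.1) to remove the noise the
       first stage amplified while keeping canal edges;
    4. a final CLAHE pass with the same parameters to restore local
       contrast after denoising.
    """
    p = params or EnhanceParams()
    out = clahe(img, p.tv_clip, p.clahe_tiles)
    out = gaussian_background_normalize(out, p.norm_sigma, p.norm_floor)
    out = tv_denoise_chambolle(out, p.tv_weight, p.tv_max_iter, p.tv_tol)
    out = clahe(out, p.tv_clip, p.clahe_tiles)
    return out


def g_clahe(img: GrayImage, params: EnhanceParams | None = None,
            max_rounds: int = 20) -> GrayImage:
    """Iterative local enhancement guided by the global equalization.

    Repeatedly applies CLAHE with a growing clip limit
    (``1.0 + 0.5 k`` at round k) and tracks the SSIM between the
    locally enhanced image (LEI) and the globally equalized image
    (GEI); iteration stops at the first round whose similarity falls
    below its predecessor's, and the predecessor is returned.  The
    returned iterate thus carries the running-maximum similarity over
    the visited sequence.  Deterministic.
    """
    p = params or EnhanceParams()
    gei = hist_equalize(img)
    lei = GrayImage(_require_8bit(img).copy(), 8)
    best_sim = _metrics.ssim(lei, gei)
    for k in range(max_rounds):
        nxt = clahe(lei, 1.0 + 0.5 * k, p.clahe_tiles)
        sim = _metrics.ssim(nxt, gei)
        if sim < best_sim:
            return lei
        lei, best_sim = nxt, sim
    return lei


def _poa_objective(img: GrayImage, outs: list[GrayImage]) -> np.ndarray:
    """Composite objective -PSNR_n - SSIM + MSE_n over a population.

    PSNR and MSE (of each candidate's CLAHE output against the input)
    are min--max normalized across the population; SSIM is already on
    [-1, 1].  Non-finite PSNR (identical output) is treated as the
    population's best finite value.
    """
    ref = img.astype_float()
    mse = np.array([np.mean((ref - o.astype_float()) ** 2) for o in outs])
    with np.errstate(divide="ignore"):
        psnr = 10.0 * np.log10(255.0 ** 2 / np.where(mse > 0, mse, np.nan))
    finite = np.isfinite(psnr)
    psnr = np.where(finite, psnr, np.nanmax(psnr[finite]) if finite.any() else 0.0)
    ssim_vals = np.array([_metrics.ssim(o, img) for o in outs])

    def mmnorm(v: np.ndarray) -> np.ndarray:
        rng = v.max() - v.min()
        if rng <= 0:
            return np.full_like(v, 0.5)
        return (v - v.min()) / rng

    return -mmnorm(psnr) - ssim_vals + mmnorm(mse)


def clahe_poa(img: GrayImage, params: EnhanceParams | None = None
              ) -> tuple[GrayImage, float]:
    """CLAHE with the clip limit tuned by a pelican-style search.

    A population of clip candidates inside ``poa_clip_bounds`` evolves
    through an exploration phase (each candidate moves toward a
    randomly chosen better candidate, or away from a worse one) and an
    exploitation phase (perturbation within a radius shrinking as
    ``0.2 * (1 - iter / n_iters) * range``), each move accepted only if
    it improves the composite PSNR/SSIM/MSE objective.  Seeded and
    deterministic.  Returns the enhanced image at the best clip of the
    final population together with that clip.
    """
    p = params or EnhanceParams()
    lo, hi = p.poa_clip_bounds
    rng = np.random.default_rng(p.seed)
    span = hi - lo

    cache: dict[float, GrayImage] = {}

    def enhanced(clip: float) -> GrayImage:
        key = round(float(clip), 6)
        if key not in cache:
            cache[key] = clahe(img, max(key, 1e-6), p.clahe_tiles)
        return cache[key]

    pop = lo + span * rng.random(p.poa_pop) if span > 0 else np.full(p.poa_pop, lo)

    def scores(clips: np.ndarray) -> np.ndarray:
        return _poa_objective(img, [enhanced(c) for c in clips])

    for it in range(p.poa_iters):
        f = scores(pop)
        # exploration: move toward a better random candidate / away from worse
        prey_idx = rng.integers(0, p.poa_pop, size=p.poa_pop)
        r = rng.random(p.poa_pop)
        intensity = rng.integers(1, 3, size=p.poa_pop)  # I in {1, 2}
        prey = pop[prey_idx]
        better = f[prey_idx] < f
        cand = np.where(better,
                        pop + r * (prey - intensity * pop),
                        pop + r * (pop - prey))
        cand = np.clip(cand, lo, hi)
        both = np.concatenate([pop, cand])
        fb = scores(both)
        accept = fb[p.poa_pop:] < fb[:p.poa_pop]
        pop = np.where(accept, cand, pop)

        # exploitation: shrinking local perturbation
        radius = 0.2 * (1.0 - it / max(p.poa_iters, 1)) * span
        cand = np.clip(pop + radius * (2.0 * rng.random(p.poa_pop) - 1.0), lo, hi)
        both = np.concatenate([pop, cand])
        fb = scores(both)
        accept = fb[p.poa_pop:] < fb[:p.poa_pop]
        pop = np.where(accept, cand, pop)

    final_scores = scores(pop)
    best = float(pop[int(np.argmin(final_scores))])
    return enhanced(best), best


METHODS = ("he", "clahe", "clahe-poa", "g-clahe", "tv-clahe")


def apply_method(img: GrayImage, method: str,
                 params: EnhanceParams | None = None) -> GrayImage:
    """Dispatch an enhancement method by its short name."""
    p = params or EnhanceParams()
    method = method.lower()
    if method == "he":
        return hist_equalize(img)
    if method == "clahe":
        return clahe(img, p.clahe_clip, p.clahe_tiles)
    if method == "clahe-poa":
        return clahe_poa(img, p)[0]
    if method == "g-clahe":
        return g_clahe(img, p)
    if method == "tv-clahe":
        return tv_clahe(img, p)
    raise ValueError(f"unknown method {method!r}; supported: {', '.join(METHODS)}")
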