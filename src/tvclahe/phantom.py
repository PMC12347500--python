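"""Synthetic periapical-radiograph phantoms with ground-truth masks.

A phantom emulates the geometry of an intraoral periapical radiograph
of a mandibular incisor: a textured bone background with a slow
illumination gradient, a bright elongated tooth, and one or two dark,
thin, low-contrast root canals whose configuration follows the
Vertucci classification (Type I single canal 70%, II merging 15%,
III split-rejoin 10%, IV two separate 5%, the reported incisor mix).
The canal centerlines are returned as a binary ground-truth mask so
contrast-to-noise can be measured objectively, standing in for the
observer visibility ratings collected on patient images.

The default canvas is 600x800 px, the 1200x1600 px detector geometry
at half scale (0.036 mm/px).  Half scale is the largest downscale at
which the enhancement pipeline stays in its clinical operating
regime: the TV-denoising stage runs at a fixed fidelity weight, so it
erases any structure shallower than roughly 2*weight/width of the
intensity range, and a typical 0.43 mm incisor canal must remain
about 12 px wide to survive it the way it does on the clinical
detector.  (At quarter scale a canal is 3-6 px wide and the same TV
stage removes it entirely, regardless of implementation.)

A companion latent-variable simulator produces ordinal 1-5 observer
ratings (subjects x raters) for exercising the statistics harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .imagio import GrayImage, round_half_up
from .stats import RatingMatrix

__all__ = [
    "PhantomParams",
    "Phantom",
    "generate_phantom",
    "draw_vertucci_type",
    "simulate_ratings",
    "VERTUCCI_TYPES",
]

VERTUCCI_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one phantom.

    ``canal_contrast`` is the gray-level decrement of the canal against
    the surrounding dentin before blur and noise; at the default 8
    levels against noise sigma 6 the canal is genuinely low-contrast,
    as on the clinical images that motivated enhancement.
    """

    height: int = 600
    width: int = 800
    vertucci_mix: tuple[float, float, float, float] = (0.70, 0.15, 0.10, 0.05)
    canal_width: float = 12.0
    canal_contrast: float = 8.0
    blur_sigma: float = 3.0
    noise_sigma: float = 6.0
    background_texture_amp: float = 10.0
    tooth_brightness: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom must be at least 32x32 pixels")
        if abs(sum(self.vertucci_mix) - 1.0) > 1e-9:
            raise ValueError("vertucci_mix must sum to 1")
        if self.canal_contrast < 0:
            raise ValueError("canal_contrast must be non-negative")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.canal_width <= 0:
            raise ValueError("canal_width must be positive")


@dataclass(frozen=True)
class Phantom:
    image: GrayImage
    canal_mask: np.ndarray
    params: PhantomParams
    vertucci_type: str

    def save(self, stem) -> None:
        """Write image, mask and a JSON sidecar of the parameters."""
        from . import imagio

        stem = str(stem)
        imagio.write_image(self.image, stem + ".png")
        imagio.write_image(
            GrayImage(self.canal_mask.astype(np.uint8) * 255, 8),
            stem + "_mask.png")
        sidecar = asdict(self.params)
        sidecar["vertucci_type"] = self.vertucci_type
        with open(stem + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def draw_vertucci_type(rng: np.random.Generator,
                       mix: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)) -> str:
    """Draw a canal configuration label from the incisor-type mix."""
    return VERTUCCI_TYPES[int(rng.choice(len(VERTUCCI_TYPES), p=mix))]


def _smooth_offset(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """A gentle random lateral wobble for a canal centerline."""
    phase = rng.uniform(0, 2 * np.pi)
    cycles = rng.uniform(0.5, 1.5)
    amp = amplitude * rng.uniform(0.3, 1.0)
    t = np.linspace(0.0, 1.0, n)
    return amp * np.sin(2 * np.pi * cycles * t + phase)


def _canal_centerlines(rng: np.random.Generator, p: PhantomParams,
                       vtype: str, cx: np.ndarray,
                       y0: int, y1: int) -> list[np.ndarray]:
    """Per-row x positions of each canal from chamber (y0) to apex (y1).

    Returns arrays of length y1 - y0 (NaN where a branch is absent).
    Geometry is schematic: Type II merges at mid-root, Type III splits
    and rejoins between one- and two-thirds of the root, Type IV stays
    separate.
    """
    n = y1 - y0
    t = np.linspace(0.0, 1.0, n)
    base = cx[y0:y1] + _smooth_offset(rng, n, p.width * 0.02)
    sep = p.width * rng.uniform(0.025, 0.04)  # half-separation of branches
    if vtype == "I":
        return [base]
    if vtype == "II":  # two canals merge into one at mid-root
        merge = 0.55
        spread = np.clip(1.0 - t / merge, 0.0, 1.0)
        return [base - sep * spread, base + sep * spread]
    if vtype == "III":  # canal splits and rejoins
        lobe = np.clip(np.sin(np.pi * np.clip((t - 0.33) / 0.37, 0.0, 1.0)), 0, 1)
        return [base - sep * lobe, base + sep * lobe]
    if vtype == "IV":  # two separate canals to two foramina
        return [base - sep, base + sep]
    raise ValueError(f"unknown Vertucci type {vtype!r}")


def generate_phantom(params: PhantomParams | None = None) -> Phantom:
    """Generate one phantom radiograph with its canal mask.

    Construction order: textured background with a linear gradient,
    bright soft-edged tooth, canal paths subtracted at
    ``canal_contrast``, Gaussian blur, additive Gaussian noise, clamp
    to [0, 255].  Deterministic for a fixed seed.
    """
    p = params or PhantomParams()
    rng = np.random.default_rng(p.seed)
    h, w = p.height, p.width

    # 1. bone background: low-frequency field + linear gradient
    corr = max(min(h, w) / 9.0, 8.0)  # ~33 px at the default scale
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), corr,
                                    mode="reflect")
    fr = field.std()
    if fr > 0:
        field = field / fr * p.background_texture_amp
    gdir = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    grad = (np.cos(gdir) * (xx - w / 2) / w + np.sin(gdir) * (yy - h / 2) / h)
    img = 110.0 + field + 15.0 * grad

    # 2. bright tooth: vertically elongated, tapering toward the apex
    cx0 = w / 2 + rng.uniform(-0.05, 0.05) * w
    tilt = rng.uniform(-0.05, 0.05)
    cx = cx0 + tilt * (np.arange(h) - h / 2)  # per-row tooth axis
    y_top, y_apex = int(0.06 * h), int(0.94 * h)
    half_w = np.full(h, np.nan)
    span = np.arange(y_top, y_apex)
    frac = (span - y_top) / max(y_apex - y_top - 1, 1)
    half_w[span] = w * (0.16 - 0.10 * frac)  # crown wide, apex narrow
    dist = np.abs(xx - cx[:, None]) / np.where(np.isnan(half_w), 1.0, half_w)[:, None]
    inside = ~np.isnan(half_w)[:, None] & (dist < 1.0)
    soft = np.clip((1.0 - dist) / 0.15, 0.0, 1.0) * inside
    # soften the crown and apex ends as well
    end_taper = np.ones(h)
    end_taper[span] = np.minimum(1.0, np.minimum(
        (span - y_top + 1) / (0.08 * h), (y_apex - span) / (0.08 * h)))
    soft *= np.clip(end_taper, 0.0, 1.0)[:, None]
    img += p.tooth_brightness * soft

    # 3. canal path(s) with ground-truth mask
    vtype = draw_vertucci_type(rng, p.vertucci_mix)
    y0, y1 = int(0.22 * h), int(0.90 * h)
    centerlines = _canal_centerlines(rng, p, vtype, cx, y0, y1)
    mask = np.zeros((h, w), dtype=bool)
    half = p.canal_width / 2.0
    cols = np.arange(w)
    for line in centerlines:
        for i, x_c in enumerate(line):
            if np.isnan(x_c):
                continue
            row = y0 + i
            sel = np.abs(cols - x_c) <= half
            mask[row, sel] = True
    mask &= soft > 0.5  # canals live inside the tooth
    img -= p.canal_contrast * mask

    # 4-5. acquisition blur and detector noise
    if p.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma, mode="reflect")
    noise = rng.standard_normal((h, w)) * p.noise_sigma
    img = np.clip(round_half_up(img + noise), 0, 255).astype(np.uint8)
    return Phantom(GrayImage(img, 8), mask, p, vtype)


def simulate_ratings(n_images: int, methods: list[str],
                     rater_bias: np.ndarray, method_effects: np.ndarray,
                     noise_sd: float, seed: int,
                     image_sd: float = 0.5) -> dict[str, RatingMatrix]:
    """Simulate ordinal 1-5 visibility ratings per method.

    Latent score for image i, rater r under method m:
    ``method_effect[m] + image_effect[i] + rater_bias[r] + noise``,
    with the image effect N(0, image_sd) shared across methods and
    raters (paired structure) and noise N(0, noise_sd) independent per
    cell.  Latent values are discretized at thresholds
    {1.5, 2.5, 3.5, 4.5} onto the 1 (Same) ... 5 (Excellent) scale.
    Deterministic per seed.
    """
    rater_bias = np.asarray(rater_bias, dtype=float)
    method_effects = np.asarray(method_effects, dtype=float)
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if rater_bias.size < 2:
        raise ValueError("need at least 2 raters")
    if method_effects.size != len(methods):
        raise ValueError("method_effects must match methods")
    rng = np.random.default_rng(seed)
    img_eff = rng.standard_normal(n_images) * image_sd
    thresholds = np.array([1.5, 2.5, 3.5, 4.5])
    out: dict[str, RatingMatrix] = {}
    for m, name in enumerate(methods):
        noise = rng.standard_normal((n_images, rater_bias.size)) * noise_sd
        latent = (method_effects[m] + img_eff[:, None]
                  + rater_bias[None, :] + noise)
        scores = 1 + (latent[..., None] >= thresholds).sum(axis=-1)
        out[name] = RatingMatrix(scores.astype(float),
                                 tuple(f"img{i}" for i in range(n_images)),
                                 tuple(f"rater{j}" for j in range(rater_bias.size)))
    return out
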