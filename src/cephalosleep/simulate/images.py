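"""Synthetic mottled mantle textures and warped image pairs.

``gen_pattern_image_pair`` produces a texture of dark elliptical blobs on a
bright noisy background (image A), a smoothly deformed copy (image B) and
the control-point displacements defining the deformation, for exercising
the moving-least-squares alignment and threshold-overlap scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from ..imagewarp import ControlPointSet, mls_warp, mls_jacobian_min

__all__ = ["PatternImageConfig", "gen_mantle_texture", "gen_pattern_image_pair"]


@dataclass
class PatternImageConfig:
    size: tuple = (256, 256)        # (height, width)
    n_blobs: int = 25
    blob_radius_px: tuple = (3.0, 6.0)
    blob_intensity: tuple = (30, 65)     # dark blob grey levels
    background: float = 225.0
    noise_sd: float = 6.0
    noise_smooth_px: float = 1.2
    #: control-point grid (rows, cols) spanning the image with a margin
    warp_grid: tuple = (4, 4)
    #: SD of each control point's displacement components, pixels
    warp_magnitude_px: float = 8.0
    #: render image B with fresh noise instead of warping A's noise field;
    #: with False, B is exactly the warped image A
    independent_noise: bool = False
    seed: int = 0


def gen_mantle_texture(cfg: PatternImageConfig, seed: int | None = None,
                       noise_seed: int | None = None) -> np.ndarray:
    """One synthetic mantle texture (8-bit grey).

    ``seed`` controls the blob layout, ``noise_seed`` the additive noise, so
    the same macroscopic pattern can be re-rendered with fresh noise.
    """
    layout_rng = np.random.default_rng(cfg.seed if seed is None else seed)
    noise_rng = np.random.default_rng(
        layout_rng.integers(2**31) if noise_seed is None else noise_seed
    )
    h, w = cfg.size
    img = np.full((h, w), cfg.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_blobs):
        cx = layout_rng.uniform(0.1 * w, 0.9 * w)
        cy = layout_rng.uniform(0.1 * h, 0.9 * h)
        rx = layout_rng.uniform(*cfg.blob_radius_px)
        ry = layout_rng.uniform(*cfg.blob_radius_px)
        ang = layout_rng.uniform(0, np.pi)
        level = layout_rng.uniform(*cfg.blob_intensity)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        img[inside] = np.minimum(img[inside], level)
    img = gaussian_filter(img, 0.8)  # soften blob edges
    noise = noise_rng.normal(0, cfg.noise_sd, (h, w))
    if cfg.noise_smooth_px > 0:
        noise = gaussian_filter(noise, cfg.noise_smooth_px)
        sd = noise.std()
        if sd > 0:
            noise *= cfg.noise_sd / sd
    return np.clip(np.rint(img + noise), 0, 255).astype(np.uint8)


def _control_grid(cfg: PatternImageConfig, rng: np.random.Generator) -> ControlPointSet:
    h, w = cfg.size
    rows, cols = cfg.warp_grid
    margin = 0.08
    ys = np.linspace(margin * h, (1 - margin) * h, rows)
    xs = np.linspace(margin * w, (1 - margin) * w, cols)
    gx, gy = np.meshgrid(xs, ys)
    src = np.column_stack([gx.ravel(), gy.ravel()])
    dst = src + rng.normal(0, cfg.warp_magnitude_px, src.shape)
    return ControlPointSet(src, dst)


def gen_pattern_image_pair(
    cfg: PatternImageConfig,
) -> tuple[np.ndarray, np.ndarray, ControlPointSet]:
    """Texture, smoothly warped copy, and the generating control points.

    Image B is image A deformed by the similarity-MLS warp defined by the
    control-point displacements; the warp is checked for fold-over (negative
    Jacobian determinant) and rejected with an error if found.  Away from
    borders the warp is intensity-preserving, so the two histograms agree
    closely.
    """
    rng = np.random.default_rng(cfg.seed)
    cps = _control_grid(cfg, rng)
    h, w = cfg.size
    if not np.allclose(cps.src, cps.dst):
        jmin = mls_jacobian_min(cps, (w, h))
        if jmin <= 0:
            raise ValueError(
                f"warp magnitude causes fold-over (min Jacobian {jmin:.3f})"
            )
    if cfg.independent_noise:
        clean_cfg = replace(cfg, noise_sd=0.0)
        clean = gen_mantle_texture(clean_cfg, seed=cfg.seed)
        noise_a = rng.normal(0, 1, (h, w))
        noise_b = rng.normal(0, 1, (h, w))
        if cfg.noise_smooth_px > 0:
            noise_a = gaussian_filter(noise_a, cfg.noise_smooth_px)
            noise_b = gaussian_filter(noise_b, cfg.noise_smooth_px)
            noise_a *= cfg.noise_sd / noise_a.std()
            noise_b *= cfg.noise_sd / noise_b.std()
        image_a = np.clip(np.rint(clean + noise_a), 0, 255).astype(np.uint8)
        image_b = np.clip(np.rint(mls_warp(clean, cps).astype(float) + noise_b),
                          0, 255).astype(np.uint8)
    else:
        image_a = gen_mantle_texture(cfg, seed=cfg.seed)
        image_b = mls_warp(image_a, cps)
    return image_a, image_b, cps
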