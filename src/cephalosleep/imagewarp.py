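"""Mantle-image alignment and control-point moving-least-squares warping.

Alignment is a two-stage procedure: a global similarity transform computed
from second-moment ellipse fits of the mantle masks, then (for detailed
pattern comparison) a non-linear similarity-variant moving-least-squares
(MLS) deformation interpolating manually selected corresponding points.
Pattern match between two aligned images is scored as the intersection-
over-union of their inverted, thresholded dark-pattern masks.

The similarity-MLS map is computed in closed form via complex arithmetic:
a 2-D similarity transform is multiplication by a complex number plus a
translation, so the weighted least-squares similarity at each pixel is a
weighted complex linear regression.  The map interpolates control points
exactly and reproduces any global similarity transform exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ControlPointSet",
    "mls_map",
    "mls_warp",
    "mls_jacobian_min",
    "fit_mask_ellipse",
    "align_mantle",
    "threshold_match",
    "BACKGROUND_GREY",
]

BACKGROUND_GREY = 127


@dataclass
class ControlPointSet:
    """Paired 2-D control points in (x, y) pixel coordinates."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self):
        self.src = np.atleast_2d(np.asarray(self.src, dtype=float))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src and dst must be matching (n, 2) arrays")
        if self.src.shape[0] < 3:
            raise ValueError("need at least three control point pairs")
        d = np.linalg.norm(self.src[:, None] - self.src[None, :], axis=2)
        if np.any(d[np.triu_indices(len(self.src), 1)] == 0):
            raise ValueError("duplicate source control points")

    def collinear(self, tol: float = 1e-9) -> bool:
        p = self.src - self.src.mean(axis=0)
        return np.linalg.svd(p, compute_uv=False)[1] <= tol * max(1.0, np.abs(p).max())

    def swapped(self) -> "ControlPointSet":
        return ControlPointSet(self.dst.copy(), self.src.copy())


def mls_map(points_xy: np.ndarray, src: np.ndarray, dst: np.ndarray,
            alpha: float = 2.0) -> np.ndarray:
    """Evaluate the similarity-MLS deformation taking src -> dst at points.

    For each evaluation point v, a similarity transform is fit by weighted
    least squares with inverse-distance weights ``w_i = |v - src_i|^(-2*alpha)``
    and applied to v.  Vectorised over all points.
    """
    v = np.atleast_2d(np.asarray(points_xy, dtype=float))
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    zp = src[:, 0] + 1j * src[:, 1]
    zq = dst[:, 0] + 1j * dst[:, 1]
    zv = v[:, 0] + 1j * v[:, 1]

    d2 = np.abs(zv[:, None] - zp[None, :]) ** 2          # (N, K)
    w = 1.0 / (d2 ** alpha + 1e-12)
    wsum = w.sum(axis=1)
    pstar = (w @ zp) / wsum
    qstar = (w @ zq) / wsum
    zhat = zp[None, :] - pstar[:, None]                  # centred src
    yhat = zq[None, :] - qstar[:, None]                  # centred dst
    mu = (w * np.abs(zhat) ** 2).sum(axis=1)
    a = (w * np.conj(zhat) * yhat).sum(axis=1) / np.where(mu > 0, mu, 1.0)
    out = a * (zv - pstar) + qstar
    return np.column_stack([out.real, out.imag])


def mls_jacobian_min(cps: ControlPointSet, extent_xy: tuple[int, int],
                     step: int = 8, alpha: float = 2.0) -> float:
    """Minimum Jacobian determinant of the forward MLS map on a coarse grid.

    Negative values indicate local fold-over of the deformation.
    """
    w, h = extent_xy
    xs = np.arange(0, w, step, dtype=float)
    ys = np.arange(0, h, step, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    eps = 0.5
    fx1 = mls_map(pts + [eps, 0], cps.src, cps.dst, alpha)
    fx0 = mls_map(pts - [eps, 0], cps.src, cps.dst, alpha)
    fy1 = mls_map(pts + [0, eps], cps.src, cps.dst, alpha)
    fy0 = mls_map(pts - [0, eps], cps.src, cps.dst, alpha)
    dfdx = (fx1 - fx0) / (2 * eps)
    dfdy = (fy1 - fy0) / (2 * eps)
    det = dfdx[:, 0] * dfdy[:, 1] - dfdx[:, 1] * dfdy[:, 0]
    return float(det.min())


def mls_warp(image: np.ndarray, cps: ControlPointSet, alpha: float = 2.0,
             cval: float = BACKGROUND_GREY) -> np.ndarray:
    """Warp an image by the similarity-MLS deformation src -> dst.

    Backward mapping: the output pixel at ``dst`` samples the input at
    ``src`` (bilinear).  The deformation interpolates control points exactly
    and reduces to the global transform when all pairs are related by one
    similarity.
    """
    if cps.collinear():
        raise ValueError("control points are collinear")
    img = np.asarray(image)
    grey = img if img.ndim == 2 else None
    h, w = img.shape[:2]
    gx, gy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    # backward map interpolates dst -> src
    src_pos = mls_map(pts, cps.dst, cps.src, alpha)
    coords = np.array([src_pos[:, 1].reshape(h, w), src_pos[:, 0].reshape(h, w)])

    def _sample(channel):
        return map_coordinates(channel.astype(float), coords, order=1,
                               mode="constant", cval=cval)

    if img.ndim == 2:
        out = _sample(img)
    else:
        out = np.stack([_sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), np.iinfo(img.dtype).min, np.iinfo(img.dtype).max)
    return out.astype(img.dtype)


# --------------------------------------------------------------------------- #
# mantle alignment

class EllipseFit(NamedTuple):
    centroid_xy: tuple[float, float]
    orientation: float       # angle of the major axis from the +x axis, radians
    major: float             # major axis length, pixels
    minor: float
    area: float


def fit_mask_ellipse(mask: np.ndarray, min_area: int = 100) -> EllipseFit:
    """Second-moment ellipse fit of a binary foreground mask."""
    from skimage.measure import regionprops

    m = np.asarray(mask).astype(np.uint8)
    if m.sum() < min_area:
        raise ValueError(f"degenerate mask (area {int(m.sum())} < {min_area} px)")
    props = regionprops(m)[0]
    cy, cx = props.centroid
    # regionprops orientation is the angle between the row axis and the major
    # axis; convert to the angle from +x (column) axis
    theta = np.pi / 2 - props.orientation
    return EllipseFit((cx, cy), theta, props.axis_major_length,
                      props.axis_minor_length, props.area)


class MantleAlignment(NamedTuple):
    image: np.ndarray
    rotation_rad: float
    scale: float
    ellipse: EllipseFit
    reference_ellipse: EllipseFit


def align_mantle(
    image: np.ndarray,
    mask: np.ndarray,
    reference_mask: np.ndarray,
    flip_180: bool = False,
    downsample: float = 0.2,
    target_size: tuple[int, int] | None = None,
    cval: float = BACKGROUND_GREY,
) -> MantleAlignment:
    """Align a mantle image onto a reference by ellipse fit + similarity map.

    The similarity transform (rotation, isotropic scale, translation) maps
    the image mask's ellipse centre and major axis onto the reference's.
    The 180-degree major-axis ambiguity is resolved by ``flip_180``
    (anterior/posterior direction is determined manually and passed in).
    The output is cropped to the reference mask's bounding box, downsampled
    (default 20%, or resized to ``target_size`` as (height, width)), with the
    background painted uniform grey.
    """
    from skimage.transform import SimilarityTransform, warp, rescale, resize

    e_img = fit_mask_ellipse(mask)
    e_ref = fit_mask_ellipse(reference_mask)
    rot = e_ref.orientation - e_img.orientation
    if flip_180:
        rot += np.pi
    scale = e_ref.major / e_img.major
    # forward: v_ref = s R (v_img - c_img) + c_ref
    T = (SimilarityTransform(translation=-np.array(e_img.centroid_xy))
         + SimilarityTransform(rotation=rot, scale=scale)
         + SimilarityTransform(translation=np.array(e_ref.centroid_xy)))
    img = np.asarray(image, dtype=float)
    aligned = warp(img, T.inverse, output_shape=reference_mask.shape,
                   order=1, cval=cval, preserve_range=True)
    warped_mask = warp(np.asarray(mask, dtype=float), T.inverse,
                       output_shape=reference_mask.shape, order=0, cval=0)
    aligned[warped_mask < 0.5] = cval

    rows = np.flatnonzero(reference_mask.any(axis=1))
    cols = np.flatnonzero(reference_mask.any(axis=0))
    crop = aligned[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if target_size is not None:
        out = resize(crop, target_size, order=1, preserve_range=True,
                     anti_aliasing=True)
    else:
        out = rescale(crop, downsample, order=1, preserve_range=True,
                      anti_aliasing=True)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    # report rotation wrapped to (-pi, pi]
    rot_w = (rot + np.pi) % (2 * np.pi) - np.pi
    return MantleAlignment(out, float(rot_w), float(scale), e_img, e_ref)


# --------------------------------------------------------------------------- #
# threshold overlap

class ThresholdMatch(NamedTuple):
    mask_a: np.ndarray
    mask_b: np.ndarray
    iou: float
    threshold: int


def threshold_match(image_a: np.ndarray, image_b: np.ndarray,
                    thresh: int | None = None) -> ThresholdMatch:
    """Dark-pattern overlap score between two aligned images.

    Both images are grey-scaled, inverted and binarised at an 8-bit
    threshold (dark pattern regions map to 1); the score is the
    intersection-over-union of the two masks.  The default threshold is
    Otsu's value on the pooled inverted pixels, clipped to the 180-230
    range used for image-specific thresholds.
    """
    a = _to_grey(image_a)
    b = _to_grey(image_b)
    if a.shape != b.shape:
        raise ValueError("images must share dimensions")
    inv_a, inv_b = 255 - a, 255 - b
    if thresh is None:
        from skimage.filters import threshold_otsu

        thresh = int(np.clip(threshold_otsu(np.concatenate([inv_a.ravel(),
                                                            inv_b.ravel()])), 180, 230))
    if not 0 <= thresh <= 255:
        raise ValueError("threshold must be an 8-bit level")
    mask_a = inv_a >= thresh
    mask_b = inv_b >= thresh
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        raise ValueError("both masks empty at this threshold; score undefined")
    iou = np.logical_and(mask_a, mask_b).sum() / union
    return ThresholdMatch(mask_a, mask_b, float(iou), int(thresh))


def _to_grey(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
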