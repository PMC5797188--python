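"""Intensity and geometry conditioning applied before registration."""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .model import Grid, VolumetricImage
from .transforms import CompositeTransform, LinearTransform, resample

__all__ = [
    "histogram_match",
    "robust_rescale",
    "coarse_brain_mask",
    "threshold_brain_mask",
    "signed_distance_transform",
    "orient_dorsal_ventral",
    "z_flip_candidates",
    "NoNeuropilSignalError",
]


class NoNeuropilSignalError(RuntimeError):
    """Raised when an image has no usable foreground (no neuropil signal)."""


def histogram_match(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    n_levels: int = 256,
    n_match_points: int = 7,
) -> VolumetricImage:
    """Monotone percentile-landmark intensity matching of moving onto fixed.

    A piecewise-linear map is fitted through ``n_match_points`` interior
    percentile landmarks plus the 1st/99th percentile ends, so the matched
    image's percentiles agree with the fixed image's at the match points.
    """
    mov = moving.data.astype(np.float64)
    fix = fixed.data.astype(np.float64)
    if np.ptp(mov) == 0 or np.ptp(fix) == 0:
        warnings.warn("constant image in histogram_match; returning input unchanged")
        return moving.copy()
    qs = np.concatenate(([1.0], np.linspace(10.0, 90.0, n_match_points), [99.0]))
    src = np.percentile(mov, qs)
    dst = np.percentile(fix, qs)
    # collapse ties so np.interp sees strictly increasing abscissae
    keep = np.concatenate(([True], np.diff(src) > 0))
    src, dst = src[keep], dst[keep]
    matched = np.interp(mov, src, dst)
    # linear extension beyond the end landmarks
    lo_slope = (dst[1] - dst[0]) / (src[1] - src[0]) if len(src) > 1 else 1.0
    hi_slope = (dst[-1] - dst[-2]) / (src[-1] - src[-2]) if len(src) > 1 else 1.0
    matched = np.where(mov < src[0], dst[0] + (mov - src[0]) * lo_slope, matched)
    matched = np.where(mov > src[-1], dst[-1] + (mov - src[-1]) * hi_slope, matched)
    if np.issubdtype(moving.data.dtype, np.integer):
        info = np.iinfo(moving.data.dtype)
        matched = np.clip(np.rint(matched), info.min, info.max).astype(moving.data.dtype)
    return moving.copy(data=matched)


def robust_rescale(
    img: VolumetricImage, p_low: float = 1.0, p_high: float = 99.8
) -> VolumetricImage:
    """Clip to [p_low, p_high] percentiles and scale to [0, 1] (float).

    The upper percentile excludes saturated block artifacts in the
    background without flattening bright neuropil.
    """
    data = img.data.astype(np.float64)
    lo, hi = np.percentile(data, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image in robust_rescale; returning zeros")
        return img.copy(data=np.zeros_like(data))
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return img.copy(data=out)


def _ball_structure(radius_um: float, spacing: Tuple[float, float, float]) -> np.ndarray:
    r = np.maximum(np.floor(radius_um / np.asarray(spacing)).astype(int), 0)
    axes = [np.arange(-n, n + 1) * s for n, s in zip(r, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return gx**2 + gy**2 + gz**2 <= radius_um**2


def coarse_brain_mask(
    img: VolumetricImage,
    opening_radius_um: float = 4.0,
    threshold: Optional[float] = None,
) -> VolumetricImage:
    """Coarse binary brain mask: Otsu on a half-resolution volume, morphological
    opening with a 4 μm ball, largest connected component, back at full size."""
    data = img.data.astype(np.float32)
    half = ndimage.zoom(data, (0.5, 0.5, 1.0), order=1)
    if np.ptp(half) == 0:
        raise NoNeuropilSignalError("no neuropil signal: constant image")
    thr = threshold_otsu(half) if threshold is None else threshold
    binary = half > thr
    if not binary.any():
        raise NoNeuropilSignalError("no neuropil signal: empty foreground")
    half_spacing = (img.spacing[0] * 2, img.spacing[1] * 2, img.spacing[2])
    opened = ndimage.binary_opening(binary, structure=_ball_structure(opening_radius_um, half_spacing))
    if not opened.any():
        raise NoNeuropilSignalError("no neuropil signal: foreground removed by opening")
    labels, n = ndimage.label(opened)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        opened = labels == (1 + int(np.argmax(sizes)))
    opened = ndimage.binary_fill_holes(opened)
    zoom = tuple(f / h for f, h in zip(img.shape, opened.shape))
    full = ndimage.zoom(opened.astype(np.uint8), zoom, order=0, grid_mode=False)
    # zoom with order=0 can be off by one voxel in size; pad/trim to match
    full = _fit_shape(full, img.shape) > 0
    # the opened region only excludes artifacts; the mask boundary itself
    # comes from the full-resolution threshold inside a slightly dilated
    # version of that region
    region = ndimage.binary_dilation(full, iterations=2)
    refined = (data > thr) & region
    if refined.any():
        labels, n = ndimage.label(refined)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            refined = labels == (1 + int(np.argmax(sizes)))
        full = ndimage.binary_fill_holes(refined)
    return img.copy(data=full.astype(np.uint8), channel_label="mask")


def threshold_brain_mask(img: VolumetricImage, threshold: Optional[float] = None) -> VolumetricImage:
    """Precise mask by simple intensity thresholding (for clean/fused images)."""
    data = img.data.astype(np.float32)
    if np.ptp(data) == 0:
        raise NoNeuropilSignalError("no neuropil signal: constant image")
    thr = threshold_otsu(data) if threshold is None else threshold
    binary = data > thr
    if not binary.any():
        raise NoNeuropilSignalError("no neuropil signal: empty foreground")
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    binary = ndimage.binary_fill_holes(binary)
    return img.copy(data=binary.astype(np.uint8), channel_label="mask")


def _fit_shape(arr: np.ndarray, shape: Tuple[int, int, int]) -> np.ndarray:
    slices = tuple(slice(0, min(a, s)) for a, s in zip(arr.shape, shape))
    out = np.zeros(shape, dtype=arr.dtype)
    out[slices] = arr[slices]
    for axis in range(3):
        if arr.shape[axis] < shape[axis]:  # replicate last slice when short
            idx = [slice(None)] * 3
            src = [slice(None)] * 3
            idx[axis] = slice(arr.shape[axis], shape[axis])
            src[axis] = slice(arr.shape[axis] - 1, arr.shape[axis])
            out[tuple(idx)] = out[tuple(src)]
    return out


def signed_distance_transform(mask: VolumetricImage) -> VolumetricImage:
    """Anisotropy-aware Euclidean distance (μm) to the mask surface.

    Sign convention fixed repo-wide: negative inside the mask, positive
    outside.  Distances are measured between voxel centers.
    """
    binary = mask.data > 0
    if not binary.any() or binary.all():
        raise ValueError("signed distance transform requires a proper binary mask")
    sampling = mask.spacing
    d_out = ndimage.distance_transform_edt(~binary, sampling=sampling)
    d_in = ndimage.distance_transform_edt(binary, sampling=sampling)
    return mask.copy(data=(d_out - d_in).astype(np.float32), channel_label="other")


def orient_dorsal_ventral(
    img: VolumetricImage, template_grid: Grid
) -> Tuple[VolumetricImage, LinearTransform]:
    """Translate the intensity center of mass to the template's geometric
    center, flipping the dorsal-ventral (y) axis first when the mass sits in
    the bottom half of the image.

    Returns the image resampled onto the template grid together with the
    transform (template space → subject space, resampling convention).
    """
    data = img.data.astype(np.float64)
    total = data.sum()
    if total <= 0:
        raise NoNeuropilSignalError("no neuropil signal: zero-mass image")
    com_idx = ndimage.center_of_mass(data)
    com = img.index_to_physical(np.asarray(com_idx))
    img_center = img.grid.center
    transforms = []
    # bottom half = larger y; a small dead zone keeps the rule idempotent
    # when the mass already sits at the center
    flipped = com[1] > img_center[1] + 0.02 * img.grid.extent[1]
    if flipped:
        transforms.append(LinearTransform.flip(axis=1, center=img_center))
        com = transforms[-1].apply(com)
    shift = com - template_grid.center  # template point -> subject point
    transforms.append(LinearTransform.from_translation(shift))
    # members apply right-to-left: translate into the (possibly flipped)
    # frame first, then mirror back into original subject space
    t = CompositeTransform(transforms) if len(transforms) > 1 else transforms[0]
    aligned = resample(img, t, template_grid, interp="linear")
    return aligned, t


def z_flip_candidates(img: VolumetricImage):
    """The two z-orientation hypotheses: identity and a flip about the
    physical center of the z-extent.  Returns ``[(img, identity), (flipped,
    flip_transform)]``."""
    center = img.grid.center
    identity = LinearTransform.identity()
    flip = LinearTransform.flip(axis=2, center=center)
    flipped = img.copy(data=img.data[:, :, ::-1].copy())
    return [(img, identity), (flipped, flip)]
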