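"""Similarity measures driving the registrations and the QA indicators."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import VolumetricImage

__all__ = [
    "MetricValue",
    "ncc",
    "mattes_mi",
    "local_ncc",
    "regional_mi",
    "sphere_voxel_indices",
]


@dataclass(frozen=True)
class MetricValue:
    name: str  # NCC | MMI | point_distance
    value: float
    n_samples: int
    domain: str = "full"  # full | masked | subregion

    def __post_init__(self) -> None:
        if self.name == "NCC" and not (-1.0 - 1e-9 <= self.value <= 1.0 + 1e-9):
            raise ValueError(f"NCC value {self.value} outside [-1, 1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")


def ncc(fixed_samples, moving_samples) -> float:
    """Pearson normalized cross correlation of two equally long sample lists."""
    f = np.asarray(fixed_samples, dtype=np.float64).ravel()
    m = np.asarray(moving_samples, dtype=np.float64).ravel()
    if f.size != m.size or f.size < 2:
        raise ValueError("ncc requires two equally long sample lists (n >= 2)")
    f = f - f.mean()
    m = m - m.mean()
    denom = np.sqrt((f @ f) * (m @ m))
    if denom == 0:
        warnings.warn("constant input to ncc; returning 0")
        return 0.0
    return float(np.clip((f @ m) / denom, -1.0, 1.0))


def mattes_mi(fixed_samples, moving_samples, n_bins: int = 32) -> float:
    """Mutual information (nats) from the joint intensity histogram.

    Samples are linearly binned over each channel's observed range.  A
    degenerate (constant) channel carries no information and yields 0.
    """
    f = np.asarray(fixed_samples, dtype=np.float64).ravel()
    m = np.asarray(moving_samples, dtype=np.float64).ravel()
    if f.size != m.size:
        raise ValueError("sample lists must have equal length")
    if f.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {f.size}")
    if np.ptp(f) == 0 or np.ptp(m) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(f, m, bins=n_bins)
    p = joint / joint.sum()
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    nz = p > 0
    mi = np.sum(p[nz] * (np.log(p[nz]) - np.log(pf[:, None] * pm[None, :])[nz]))
    return float(max(mi, 0.0))


def _mask_bbox(mask: np.ndarray):
    idx = np.nonzero(mask)
    return [(int(a.min()), int(a.max())) for a in idx]


def local_ncc(
    fixed: VolumetricImage,
    moving_warped: VolumetricImage,
    mask: VolumetricImage,
    subregion_edge: float = 20.0,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 10,
) -> float:
    """NCC over one random cubic subregion (``subregion_edge`` μm) of the mask.

    The subregion center is drawn uniformly from mask voxels; if the drawn
    cube contains fewer than 2 mask voxels a new cube is drawn, falling back
    to the full mask after ``max_tries`` attempts.
    """
    rng = np.random.default_rng() if rng is None else rng
    mask_arr = mask.data > 0
    if not mask_arr.any():
        raise ValueError("local_ncc requires a non-empty mask")
    flat = np.flatnonzero(mask_arr)
    half = np.maximum(
        np.rint(0.5 * subregion_edge / np.asarray(fixed.spacing)).astype(int), 1
    )
    for _ in range(max_tries):
        center = np.unravel_index(rng.choice(flat), mask_arr.shape)
        sl = tuple(
            slice(max(c - h, 0), min(c + h + 1, n))
            for c, h, n in zip(center, half, mask_arr.shape)
        )
        sub_mask = mask_arr[sl]
        if sub_mask.sum() >= 2:
            f = fixed.data[sl][sub_mask]
            m = moving_warped.data[sl][sub_mask]
            if np.ptp(f) > 0 and np.ptp(m) > 0:
                return ncc(f, m)
    return ncc(fixed.data[mask_arr], moving_warped.data[mask_arr])


def sphere_voxel_indices(img: VolumetricImage, center, radius: float) -> tuple:
    """Index tuple of voxels whose physical center lies within ``radius`` μm
    of ``center``; restricted to a bounding box for efficiency."""
    center = np.asarray(center, dtype=float)
    lo = img.physical_to_index(center - radius)
    hi = img.physical_to_index(center + radius)
    lo = np.maximum(np.floor(lo).astype(int), 0)
    hi = np.minimum(np.ceil(hi).astype(int) + 1, img.shape)
    if np.any(lo >= hi):
        return (np.array([], dtype=int),) * 3
    axes = [
        img.origin[a] + np.arange(lo[a], hi[a]) * img.spacing[a] for a in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    inside = (
        (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        <= radius**2
    )
    ii, jj, kk = np.nonzero(inside)
    return (ii + lo[0], jj + lo[1], kk + lo[2])


def regional_mi(
    fixed: VolumetricImage,
    moving_warped: VolumetricImage,
    center,
    radius: float,
    n_bins: int = 32,
    min_voxels: int = 50,
) -> float:
    """Mutual information over a spherical region (μm) of both images."""
    if fixed.grid != moving_warped.grid:
        raise ValueError("regional_mi requires images on one grid")
    idx = sphere_voxel_indices(fixed, center, radius)
    n = idx[0].size
    if n < min_voxels:
        raise ValueError(
            f"sphere of radius {radius} μm covers only {n} voxels "
            f"(< {min_voxels}); too small for this grid"
        )
    return mattes_mi(fixed.data[idx], moving_warped.data[idx], n_bins=n_bins)
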