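"""Masked B-spline free-form registration.

The deformation is a cubic B-spline on an isotropic physical grid (finest
level 12 μm).  The total fixed→moving map is ``init(x + u(x))`` with ``u``
the spline displacement; optimization runs adaptive stochastic gradient
descent on randomly drawn intensity samples with an analytic NCC gradient.

Two sampling modes mirror the two registration scenarios: template
generation samples the full image domain (after histogram matching),
subject-to-template always samples inside the template brain mask, either
globally or from one random 20 μm cubic subregion per iteration.

``register_multimetric`` adds a corresponding-point Euclidean distance term
whose weight is rescaled at every level so the two metric *gradients* (not
the metric values) keep a caller-chosen ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .metrics import MetricValue, ncc
from .model import Grid, LandmarkSet, VolumetricImage
from .global_registration import _downsample, _pyramid_factors, flatten_linear
from .transforms import (
    BSplineTransform,
    CompositeTransform,
    DisplacementField,
    LinearTransform,
    Transform,
)

__all__ = [
    "DeformableConfig",
    "MultiMetricConfig",
    "register_bspline",
    "register_multimetric",
    "jacobian_determinant",
]


@dataclass
class DeformableConfig:
    grid_spacing: float = 12.0
    levels: int = 5
    metric: str = "global_random_NCC"  # or masked_local_NCC
    subregion_edge: float = 20.0
    iterations_per_level: int = 300
    samples_per_iteration: int = 2048
    seed: int = 0
    step0_um: float = 0.8     # first-iteration control-point step
    asgd_alpha: float = 0.602

    def __post_init__(self) -> None:
        if self.metric not in ("global_random_NCC", "masked_local_NCC"):
            raise ValueError(f"unknown metric mode {self.metric!r}")

    def validate_against(self, fixed: VolumetricImage) -> None:
        if self.grid_spacing <= max(fixed.spacing):
            raise ValueError(
                f"grid_spacing {self.grid_spacing} must exceed the largest voxel "
                f"spacing {max(fixed.spacing)}"
            )
        voxel_diag = float(np.linalg.norm(fixed.spacing))
        if self.subregion_edge <= voxel_diag:
            raise ValueError(
                f"subregion_edge {self.subregion_edge} must exceed the voxel "
                f"diagonal {voxel_diag:.2f}"
            )

    def grid_pyramid(self) -> List[float]:
        return [
            self.grid_spacing * 2 ** max(self.levels - 2 - l, 0)
            for l in range(self.levels)
        ]


@dataclass
class MultiMetricConfig:
    template_landmarks: LandmarkSet
    subject_landmarks: LandmarkSet
    relative_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.template_landmarks.labels != self.subject_landmarks.labels:
            raise ValueError(
                "landmark labels must match 1:1 between template and subject sets: "
                f"{self.template_landmarks.labels} vs {self.subject_landmarks.labels}"
            )
        if len(self.template_landmarks) not in (2, 6, 8):
            raise ValueError(
                "guide landmarks come in sets of 2 (VNC), 6 (thoracic) or 8 (both); "
                f"got {len(self.template_landmarks)}"
            )


# ---------------------------------------------------------------------------
# cubic B-spline sampling machinery
# ---------------------------------------------------------------------------

def _cubic_basis(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline weights for fractional offsets t in [0, 1)."""
    t2 = t * t
    t3 = t2 * t
    return np.stack(
        [
            (1 - 3 * t + 3 * t2 - t3) / 6.0,
            (4 - 6 * t2 + 3 * t3) / 6.0,
            (1 + 3 * t + 3 * t2 - 3 * t3) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


_OFFSETS = np.stack(
    np.meshgrid(np.arange(4), np.arange(4), np.arange(4), indexing="ij"), -1
).reshape(64, 3)


def _spline_support(transform: BSplineTransform, pts: np.ndarray):
    """Flat coefficient indices (N, 64) and tensor weights (N, 64) for pts."""
    g = (pts - transform.grid_origin) / transform.grid_spacing
    base = np.floor(g).astype(int) - 1
    frac = g - np.floor(g)
    shape = transform.coefficients.shape[:3]
    if np.any(base < 0) or np.any(base + 3 >= np.asarray(shape)):
        raise ValueError("sample points leave the B-spline support")
    wx = _cubic_basis(frac[:, 0])
    wy = _cubic_basis(frac[:, 1])
    wz = _cubic_basis(frac[:, 2])
    w = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]).reshape(-1, 64)
    idx = (
        (base[:, 0, None] + _OFFSETS[None, :, 0]) * (shape[1] * shape[2])
        + (base[:, 1, None] + _OFFSETS[None, :, 1]) * shape[2]
        + (base[:, 2, None] + _OFFSETS[None, :, 2])
    )
    return idx, w


def _displacement_from_support(coeffs_flat: np.ndarray, idx, w) -> np.ndarray:
    return np.einsum("nk,nkc->nc", w, coeffs_flat[idx])


def _scatter_gradient(shape, idx, w, per_sample_grad: np.ndarray) -> np.ndarray:
    g = np.zeros((int(np.prod(shape[:3])), 3))
    np.add.at(g, idx.ravel(), (w[:, :, None] * per_sample_grad[:, None, :]).reshape(-1, 3))
    return g


def _refine_coefficients(
    prev: BSplineTransform, target: BSplineTransform
) -> np.ndarray:
    """Coefficients of ``target``'s grid reproducing ``prev``'s displacement
    at the new control nodes (cubic interpolation condition)."""
    shape = target.coefficients.shape[:3]
    axes = [
        target.grid_origin[a] + np.arange(shape[a]) * target.grid_spacing
        for a in range(3)
    ]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = prev.displacement(nodes).reshape(*shape, 3)
    coeffs = np.empty_like(values)
    for c in range(3):
        coeffs[..., c] = ndimage.spline_filter(values[..., c], order=3, mode="mirror")
    return coeffs


# ---------------------------------------------------------------------------
# sample draws
# ---------------------------------------------------------------------------

def _level_mask(mask: Optional[VolumetricImage], img: VolumetricImage) -> Optional[np.ndarray]:
    if mask is None:
        return None
    src = np.rint(
        mask.grid.physical_to_index(img.grid.physical_points().reshape(-1, 3))
    ).astype(int)
    src = np.clip(src, 0, np.asarray(mask.shape) - 1)
    return (mask.data[tuple(src.T)] > 0).reshape(img.shape)


def _draw_samples(
    img: VolumetricImage,
    mode: str,
    mask: Optional[np.ndarray],
    n: int,
    subregion_edge: float,
    rng: np.random.Generator,
    mask_flat: Optional[np.ndarray],
):
    shape = np.asarray(img.shape)
    if mode == "global_random_NCC":
        if mask is None:
            idx = np.column_stack([rng.integers(0, s, size=n) for s in shape])
        else:
            choice = rng.choice(mask_flat, size=min(n, mask_flat.size))
            idx = np.column_stack(np.unravel_index(choice, img.shape))
        return idx
    # masked_local_NCC: all mask voxels of one random cube per iteration
    half = np.maximum(np.rint(0.5 * subregion_edge / np.asarray(img.spacing)).astype(int), 1)
    for _ in range(10):
        center = np.unravel_index(rng.choice(mask_flat), img.shape)
        sl = tuple(
            slice(max(c - h, 0), min(c + h + 1, s))
            for c, h, s in zip(center, half, shape)
        )
        sub = mask[sl]
        if sub.sum() >= 8:
            ii, jj, kk = np.nonzero(sub)
            idx = np.column_stack([ii + sl[0].start, jj + sl[1].start, kk + sl[2].start])
            if idx.shape[0] > n:
                idx = idx[rng.choice(idx.shape[0], n, replace=False)]
            return idx
    choice = rng.choice(mask_flat, size=min(n, mask_flat.size))
    return np.column_stack(np.unravel_index(choice, img.shape))


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------

def _ncc_and_sample_grad(f: np.ndarray, m: np.ndarray):
    fc = f - f.mean()
    mc = m - m.mean()
    b = mc @ mc
    c = fc @ fc
    if b <= 0 or c <= 0:
        return 0.0, np.zeros_like(m)
    a = fc @ mc
    denom = np.sqrt(b * c)
    value = a / denom
    grad = fc / denom - (a / (np.sqrt(c) * b**1.5)) * mc
    return float(value), grad


def register_bspline(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    init: Transform,
    cfg: DeformableConfig,
    mask: Optional[VolumetricImage] = None,
    _mm: Optional[MultiMetricConfig] = None,
) -> Tuple[BSplineTransform, MetricValue]:
    """Estimate the B-spline deformation refining ``init`` (fixed→moving).

    Returns the spline on the finest (``cfg.grid_spacing``) grid and the
    final full-resolution NCC of the warped moving image against the fixed
    image (masked when a mask is given).  The metric history per level is
    attached to the returned transform as ``metric_history``.
    """
    if init is None:
        raise ValueError("register_bspline requires an initial transform")
    cfg.validate_against(fixed)
    if cfg.metric == "masked_local_NCC" and mask is None:
        raise ValueError("masked_local_NCC requires a mask")
    init_lin = flatten_linear(init)
    J = init_lin.matrix
    rng = np.random.default_rng(cfg.seed)

    factors = _pyramid_factors(cfg.levels, fixed.shape)
    grid_pyramid = cfg.grid_pyramid()
    transform: Optional[BSplineTransform] = None
    history: List[List[float]] = []

    for li, (f, gsp) in enumerate(zip(factors, grid_pyramid)):
        fx = _downsample(fixed, f)
        mv = _downsample(moving, f)
        new_t = BSplineTransform.domain_covering(fixed.grid, gsp)
        if transform is not None:
            if (
                transform.grid_spacing == new_t.grid_spacing
                and transform.coefficients.shape == new_t.coefficients.shape
            ):
                new_t = transform
            else:
                new_t = BSplineTransform(
                    new_t.grid_origin, new_t.grid_spacing,
                    _refine_coefficients(transform, new_t),
                )
        transform = new_t
        coeffs_flat = transform.coefficients.reshape(-1, 3)

        grad_vols = np.gradient(mv.data.astype(np.float32), *mv.spacing)
        mask_lvl = _level_mask(mask, fx)
        mask_flat = None if mask_lvl is None else np.flatnonzero(mask_lvl)
        if mask_flat is not None and mask_flat.size == 0:
            raise ValueError("mask is empty at pyramid level")

        lam = None
        gain = None
        A = max(0.1 * cfg.iterations_per_level, 5.0)
        level_history: List[float] = []
        for it in range(cfg.iterations_per_level):
            idx = _draw_samples(
                fx, cfg.metric, mask_lvl, cfg.samples_per_iteration,
                cfg.subregion_edge, rng, mask_flat,
            )
            pts = fx.index_to_physical(idx)
            sup_idx, sup_w = _spline_support(transform, pts)
            u = _displacement_from_support(coeffs_flat, sup_idx, sup_w)
            y = init_lin.apply(pts + u)
            ycoord = mv.grid.physical_to_index(y).T
            m = ndimage.map_coordinates(
                mv.data.astype(np.float32), ycoord, order=1, mode="constant", cval=0.0
            )
            fvals = fx.data[tuple(idx.T)].astype(np.float64)
            value, dm = _ncc_and_sample_grad(fvals, m)
            if np.isnan(value):
                raise FloatingPointError(
                    f"NaN metric at level {li} iteration {it}; diagnostics: "
                    f"max|u|={np.abs(u).max():.3g}, samples={len(m)}"
                )
            level_history.append(value)
            gm = np.stack(
                [
                    ndimage.map_coordinates(gv, ycoord, order=1, mode="constant", cval=0.0)
                    for gv in grad_vols
                ],
                axis=-1,
            )
            per_sample = -dm[:, None] * (gm @ J)  # minimize -NCC
            grad = _scatter_gradient(transform.coefficients.shape, sup_idx, sup_w, per_sample)

            if _mm is not None and _mm.relative_weight > 0:
                pgrad, _ = _point_term(transform, coeffs_flat, init_lin, _mm)
                if lam is None:
                    gn, pn = np.abs(grad).max(), np.abs(pgrad).max()
                    lam = 0.0 if pn == 0 else _mm.relative_weight * (gn + 1e-12) / pn
                grad = grad + lam * pgrad

            if gain is None:
                g0 = np.abs(grad).max()
                # a vanishing first gradient means the images already agree at
                # this level (the metric gradient scales with misalignment);
                # calibrating the gain on numerical noise would blow up
                gain = 0.0 if g0 < 1e-7 else cfg.step0_um * (A + 1) ** cfg.asgd_alpha / g0
            step = gain / (A + it + 1) ** cfg.asgd_alpha
            peak = step * np.abs(grad).max()
            if peak > 2.0 * cfg.step0_um:  # trust region per iteration
                step *= 2.0 * cfg.step0_um / peak
            coeffs_flat -= step * grad

        history.append(level_history)

    transform.metric_history = history  # type: ignore[attr-defined]
    final = _final_metric(fixed, moving, transform, init_lin, mask)
    return transform, final


def _point_term(
    transform: BSplineTransform,
    coeffs_flat: np.ndarray,
    init_lin: LinearTransform,
    mm: MultiMetricConfig,
):
    """Gradient and value of the mean corresponding-point distance."""
    p = mm.template_landmarks.coords
    q = mm.subject_landmarks.coords
    sup_idx, sup_w = _spline_support(transform, p)
    u = _displacement_from_support(coeffs_flat, sup_idx, sup_w)
    y = init_lin.apply(p + u)
    diff = y - q
    dist = np.linalg.norm(diff, axis=1)
    value = float(dist.mean())
    unit = diff / np.maximum(dist, 1e-9)[:, None]
    per_point = (unit @ init_lin.matrix) / len(p)
    grad = _scatter_gradient(transform.coefficients.shape, sup_idx, sup_w, per_point)
    return grad, value


def _final_metric(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    transform: BSplineTransform,
    init_lin: LinearTransform,
    mask: Optional[VolumetricImage],
    max_samples: int = 50000,
) -> MetricValue:
    if mask is not None:
        idx = np.argwhere(mask.data > 0)
        domain = "masked"
    else:
        idx = np.indices(fixed.shape).reshape(3, -1).T
        domain = "full"
    if idx.shape[0] > max_samples:
        idx = idx[:: int(np.ceil(idx.shape[0] / max_samples))]
    pts = fixed.index_to_physical(idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y = init_lin.apply(pts + transform.displacement(pts))
    m = ndimage.map_coordinates(
        moving.data.astype(np.float32), moving.grid.physical_to_index(y).T,
        order=1, mode="constant", cval=0.0,
    )
    f = fixed.data[tuple(idx.T)].astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = ncc(f, m)
    return MetricValue("NCC", value, n_samples=len(f), domain=domain)


def register_multimetric(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    init: Transform,
    cfg: DeformableConfig,
    mm: MultiMetricConfig,
    mask: Optional[VolumetricImage] = None,
) -> Tuple[BSplineTransform, MetricValue]:
    """Landmark-guided deformable registration.

    The cost couples the NCC term with the mean Euclidean distance between
    the template guide landmarks (mapped through the current transform) and
    their manual annotations in the subject; the distance term's weight is
    set per level from the ratio of the two gradient magnitudes so that
    ``relative_weight`` balances gradients, not metric values.  With
    ``relative_weight == 0`` the result equals :func:`register_bspline` for
    the same seed.
    """
    return register_bspline(fixed, moving, init, cfg, mask=mask, _mm=mm)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(I + ∇u) of a displacement field, voxelwise (central differences)."""
    u = field.vectors
    sp = field.grid.spacing
    F = np.zeros((*u.shape[:3], 3, 3))
    for c in range(3):
        gx, gy, gz = np.gradient(u[..., c], *sp)
        F[..., c, 0] = gx
        F[..., c, 1] = gy
        F[..., c, 2] = gz
    F += np.eye(3)
    return np.linalg.det(F)
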