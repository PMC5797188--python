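"""Linear alignment stages: multiresolution similarity/affine registration,
SDT feature registration with rotation multi-start, the 0.4-threshold
path-selection rule, and the six-stage subject-to-template global pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, optimize

from .metrics import MetricValue, mattes_mi, ncc
from .model import Grid, VolumetricImage
from .preprocess import (
    coarse_brain_mask,
    orient_dorsal_ventral,
    robust_rescale,
    signed_distance_transform,
    threshold_brain_mask,
    z_flip_candidates,
)
from .transforms import CompositeTransform, LinearTransform, resample

__all__ = [
    "GlobalRegistrationResult",
    "RegistrationDivergenceError",
    "register_linear",
    "register_sdt",
    "select_global_path",
    "run_global_pipeline",
    "compose_linear",
    "SIMILARITY_ACCEPT_THRESHOLD",
]

SIMILARITY_ACCEPT_THRESHOLD = 0.4


class RegistrationDivergenceError(RuntimeError):
    pass


@dataclass
class GlobalRegistrationResult:
    transform: CompositeTransform
    stage_scores: Dict[str, MetricValue] = field(default_factory=dict)
    selected_path: str = "sdt"  # sdt | intensity
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if self.warning is not None and "registration failure" not in self.warning:
            raise ValueError("warning, when present, must be a registration failure warning")

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "stage_scores": {
                k: {"name": v.name, "value": v.value, "n_samples": v.n_samples,
                    "domain": v.domain}
                for k, v in self.stage_scores.items()
            },
            "selected_path": self.selected_path,
            "warning": self.warning,
        }


# ---------------------------------------------------------------------------
# composition helpers
# ---------------------------------------------------------------------------

def _matrix_kind(matrix: np.ndarray) -> str:
    if np.allclose(matrix, np.eye(3), atol=1e-12):
        return "translation"
    det = np.linalg.det(matrix)
    if det > 0:
        scale = det ** (1.0 / 3.0)
        R = matrix / scale
        if np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            return "similarity"
    return "affine"


def compose_linear(outer: LinearTransform, inner: LinearTransform) -> LinearTransform:
    """Single linear transform equal to ``outer ∘ inner`` (inner acts first)."""
    # outer(inner(x)) = Mo (Mi (x - ci) + ci + ti - co) + co + to
    m = outer.matrix @ inner.matrix
    c = inner.center
    t = (
        outer.matrix @ (inner.center + inner.translation - outer.center)
        + outer.center
        + outer.translation
        - inner.center
    )
    return LinearTransform(kind=_matrix_kind(m), matrix=m, translation=t, center=c)


def flatten_linear(t) -> LinearTransform:
    if isinstance(t, LinearTransform):
        return t
    if isinstance(t, CompositeTransform):
        members = [flatten_linear(m) for m in t.transforms]
        out = members[-1]
        for m in reversed(members[:-1]):
            out = compose_linear(m, out)
        return out
    raise TypeError(f"cannot flatten {type(t).__name__} into a linear transform")


# ---------------------------------------------------------------------------
# parameterizations (dimensionless Powell parameters -> transform)
# ---------------------------------------------------------------------------

_ROT_UNIT = 0.1     # rad
_LOGS_UNIT = 0.05
_TRANS_UNIT = 2.0   # μm
_MAT_UNIT = 0.05


def _build_transform(kind: str, params: np.ndarray, center: np.ndarray) -> LinearTransform:
    if kind == "translation":
        return LinearTransform.from_translation(params * _TRANS_UNIT)
    if kind == "similarity":
        rz, logs, tx, ty, tz = params
        return LinearTransform.similarity(
            scale=float(np.exp(logs * _LOGS_UNIT)),
            angles=(0.0, 0.0, rz * _ROT_UNIT),
            translation=np.array([tx, ty, tz]) * _TRANS_UNIT,
            center=center,
        )
    if kind == "affine":
        m = np.eye(3) + params[:9].reshape(3, 3) * _MAT_UNIT
        return LinearTransform(
            kind="affine", matrix=m, translation=params[9:] * _TRANS_UNIT, center=center
        )
    raise ValueError(f"unknown transform kind {kind!r}")


_N_PARAMS = {"translation": 3, "similarity": 5, "affine": 12}

# capture window (in dimensionless parameter units) at the coarsest level,
# halved at every finer level: the optimizer is deliberately local, large
# rotations are the SDT stage's job
_WINDOW0 = {
    "translation": np.full(3, 5.0),                       # ±10 μm
    "similarity": np.array([3.0, 3.0, 5.0, 5.0, 5.0]),    # ±17°, ±16%, ±10 μm
    "affine": np.concatenate([np.full(9, 4.0), np.full(3, 5.0)]),
}


# ---------------------------------------------------------------------------
# multiresolution machinery
# ---------------------------------------------------------------------------

def _pyramid_factors(levels: int, shape, min_inplane: int = 8, min_z: int = 4):
    out = []
    for level in range(levels):
        f = 2 ** (levels - 1 - level)
        fx = min(f, max(shape[0] // min_inplane, 1))
        fy = min(f, max(shape[1] // min_inplane, 1))
        fz = min(f, max(shape[2] // min_z, 1))
        out.append((fx, fy, fz))
    return out


def _downsample(img: VolumetricImage, factors) -> VolumetricImage:
    if all(f == 1 for f in factors):
        return img.copy(data=img.data.astype(np.float32))
    sigma = [f / 2.0 if f > 1 else 0.0 for f in factors]
    sm = ndimage.gaussian_filter(img.data.astype(np.float32), sigma=sigma)
    zoom = [1.0 / f for f in factors]
    data = ndimage.zoom(sm, zoom, order=1)
    spacing = tuple(s * f for s, f in zip(img.spacing, factors))
    return VolumetricImage(data, spacing, img.origin, img.channel_label)


def _sample_points(img: VolumetricImage, mask: Optional[np.ndarray], max_samples: int):
    if mask is not None:
        idx = np.argwhere(mask)
    else:
        shape = img.shape
        idx = np.indices(shape).reshape(3, -1).T
    if idx.shape[0] > max_samples:
        stride = int(np.ceil(idx.shape[0] / max_samples))
        idx = idx[::stride]
    pts = img.index_to_physical(idx)
    values = img.data[tuple(idx.T)].astype(np.float64)
    return pts, values


def _metric_fn(name: str):
    if name == "NCC":
        return lambda f, m: ncc(f, m)
    if name == "MMI":
        return lambda f, m: mattes_mi(f, m, n_bins=32)
    raise ValueError(f"metric must be NCC or MMI, got {name!r}")


def _evaluate(metric, fixed_vals, moving_img, pts, transform) -> float:
    mapped = transform.apply(pts)
    idx = moving_img.grid.physical_to_index(mapped).T
    m = ndimage.map_coordinates(
        moving_img.data.astype(np.float32), idx, order=1, mode="constant", cval=0.0
    )
    if np.ptp(m) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return metric(fixed_vals, m)


def register_linear(
    fixed: VolumetricImage,
    moving: VolumetricImage,
    kind: str = "similarity",
    metric: str = "NCC",
    init: Optional[LinearTransform] = None,
    levels: int = 5,
    fixed_mask: Optional[VolumetricImage] = None,
    max_samples: int = 8000,
    maxiter: int = 6,
    multistart_angles: Sequence[float] = (0.0,),
) -> Tuple[LinearTransform, MetricValue]:
    """Optimize a linear fixed→moving transform over a multiresolution pyramid.

    The returned transform includes ``init`` (it is the full fixed→moving
    map).  ``multistart_angles`` (radians, in-plane) seeds several starts at
    the coarsest level; the best is refined.  Raises
    :class:`RegistrationDivergenceError` if the metric worsens over three
    consecutive levels.
    """
    if kind not in _N_PARAMS:
        raise ValueError(f"kind must be one of {sorted(_N_PARAMS)}")
    init_t = LinearTransform.identity() if init is None else flatten_linear(init)
    metric_fn = _metric_fn(metric)
    center = fixed.grid.center
    factors = _pyramid_factors(levels, fixed.shape)
    mask_arr = None if fixed_mask is None else fixed_mask.data > 0

    params = np.zeros(_N_PARAMS[kind])
    level_scores: List[float] = []
    worse_streak = 0
    for li, f in enumerate(factors):
        fx_img = _downsample(fixed, f)
        mv_img = _downsample(moving, f)
        level_mask = None
        if mask_arr is not None:
            level_mask = mask_arr[:: f[0], :: f[1], :: f[2]]
            level_mask = _fit_mask(level_mask, fx_img.shape)
        pts, fvals = _sample_points(fx_img, level_mask, max_samples)
        if np.ptp(fvals) == 0:
            continue

        def objective(p):
            t_new = _build_transform(kind, p, center)
            return -_evaluate(metric_fn, fvals, mv_img, pts, compose_linear(init_t, t_new))

        if li == 0 and len(multistart_angles) > 1 and kind == "similarity":
            best_val, best_p = np.inf, params
            for ang in multistart_angles:
                p0 = params.copy()
                p0[0] = ang / _ROT_UNIT
                val = objective(p0)
                if val < best_val:
                    best_val, best_p = val, p0
            params = best_p
        start_score = -objective(params)
        # geometric window decay keeps the optimizer local: large rotations
        # are the SDT stage's job
        window = _WINDOW0[kind] * 0.5**li
        res = optimize.minimize(
            objective, params, method="Powell",
            bounds=optimize.Bounds(params - window, params + window),
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-6},
        )
        params = res.x
        score = -res.fun
        # divergence: optimization leaves the metric worse than its own
        # initialization (same samples) on 3 consecutive levels
        if score < start_score - 1e-9:
            worse_streak += 1
            if worse_streak >= 3:
                raise RegistrationDivergenceError(
                    f"metric worsened over 3 consecutive levels: {level_scores + [score]}"
                )
        else:
            worse_streak = 0
        level_scores.append(score)

    total = compose_linear(init_t, _build_transform(kind, params, center))
    final = MetricValue(metric, float(level_scores[-1]), n_samples=len(fvals),
                        domain="masked" if mask_arr is not None else "full")
    return total, final


def _fit_mask(mask: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(mask.shape, shape))
    out[sl] = mask[sl]
    return out


def register_sdt(
    fixed_mask_sdt: VolumetricImage,
    moving_mask_sdt: VolumetricImage,
    init: Optional[LinearTransform] = None,
    levels: int = 4,
    max_samples: int = 8000,
) -> Tuple[LinearTransform, MetricValue]:
    """Similarity registration of two signed-distance images with the MMI
    metric; multi-start over in-plane angles gives robustness to rotations
    up to ±90°."""
    angles = np.deg2rad(np.arange(-90, 91, 30))
    return register_linear(
        fixed_mask_sdt,
        moving_mask_sdt,
        kind="similarity",
        metric="MMI",
        init=init,
        levels=levels,
        max_samples=max_samples,
        multistart_angles=angles,
    )


def select_global_path(
    sdt_result: Tuple[LinearTransform, float],
    run_intensity: Callable[[], Tuple[LinearTransform, float]],
    threshold: float = SIMILARITY_ACCEPT_THRESHOLD,
) -> GlobalRegistrationResult:
    """The fallback rule: keep the SDT path when its similarity passes the
    threshold; otherwise run the intensity path and keep it if it passes;
    otherwise keep whichever scored higher and attach a failure warning.

    Both candidate scores are NCC on the NP channel so they live on one
    commensurable scale.
    """
    sdt_t, sdt_score = sdt_result
    if sdt_score >= threshold:
        return GlobalRegistrationResult(
            transform=CompositeTransform([sdt_t]),
            stage_scores={"sdt": MetricValue("NCC", sdt_score, 1)},
            selected_path="sdt",
        )
    int_t, int_score = run_intensity()
    scores = {
        "sdt": MetricValue("NCC", sdt_score, 1),
        "intensity": MetricValue("NCC", int_score, 1),
    }
    if int_score >= threshold:
        return GlobalRegistrationResult(
            transform=CompositeTransform([int_t]), stage_scores=scores,
            selected_path="intensity",
        )
    if int_score > sdt_score:
        chosen, path = int_t, "intensity"
    else:
        chosen, path = sdt_t, "sdt"
    return GlobalRegistrationResult(
        transform=CompositeTransform([chosen]), stage_scores=scores,
        selected_path=path,
        warning=f"registration failure warning: no method passed the {threshold} threshold",
    )


# ---------------------------------------------------------------------------
# the six-stage subject-to-template global pipeline
# ---------------------------------------------------------------------------

def _masked_ncc(fixed: VolumetricImage, warped: VolumetricImage,
                mask: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ncc(fixed.data[mask], warped.data[mask])


def run_global_pipeline(template, scan, levels: int = 4,
                        max_samples: int = 8000) -> GlobalRegistrationResult:
    """Stages: dorsal-ventral alignment → z-flip candidates → SDT similarity
    (with 0.4-threshold intensity fallback) → NP similarity refinement →
    composition.  ``template`` is a :class:`~larvreg.template.TemplatePackage`.

    Both z-flip branches run through all stages; the branch with the higher
    final masked NCC wins.
    """
    tpl_np = robust_rescale(template.np_template)
    tpl_mask = template.brain_mask
    tpl_sdt = signed_distance_transform(tpl_mask)
    tpl_mask_arr = tpl_mask.data > 0

    sub_np = robust_rescale(scan.channels["NP"])
    aligned, t_orient = orient_dorsal_ventral(sub_np, tpl_np.grid)

    best = None
    stage_scores: Dict[str, MetricValue] = {}
    for name, (cand_img, t_flip) in zip(
        ("unflipped", "zflipped"), z_flip_candidates(aligned)
    ):
        sub_mask = coarse_brain_mask(cand_img)
        sub_sdt = signed_distance_transform(sub_mask)
        sdt_t, _ = register_sdt(tpl_sdt, sub_sdt, levels=levels,
                                max_samples=max_samples)
        sdt_ncc = _masked_ncc(tpl_np, resample(cand_img, sdt_t, tpl_np.grid),
                              tpl_mask_arr)

        def run_intensity(img=cand_img):
            t, _ = register_linear(tpl_np, img, kind="similarity", metric="NCC",
                                   levels=levels, fixed_mask=tpl_mask,
                                   max_samples=max_samples)
            score = _masked_ncc(tpl_np, resample(img, t, tpl_np.grid), tpl_mask_arr)
            return t, score

        selection = select_global_path((sdt_t, sdt_ncc), run_intensity)
        t_coarse = flatten_linear(selection.transform)
        t_refined, _ = register_linear(
            tpl_np, cand_img, kind="similarity", metric="NCC", init=t_coarse,
            levels=levels, fixed_mask=tpl_mask, max_samples=max_samples,
        )
        final_ncc = _masked_ncc(
            tpl_np, resample(cand_img, t_refined, tpl_np.grid), tpl_mask_arr
        )
        stage_scores[f"zflip:{name}"] = MetricValue(
            "NCC", final_ncc, int(tpl_mask_arr.sum()), domain="masked"
        )
        branch = {
            "name": name, "t_flip": t_flip, "t_refined": t_refined,
            "selection": selection, "score": final_ncc,
        }
        if best is None or final_ncc > best["score"]:
            best = branch

    selection = best["selection"]
    stage_scores.update(
        {f"select:{k}": v for k, v in selection.stage_scores.items()}
    )
    total = CompositeTransform([t_orient, best["t_flip"], best["t_refined"]])
    return GlobalRegistrationResult(
        transform=total,
        stage_scores=stage_scores,
        selected_path=selection.selected_path,
        warning=selection.warning,
    )
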