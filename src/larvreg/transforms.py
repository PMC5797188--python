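"""Spatial transforms: linear maps, cubic B-spline free-form deformations,
dense displacement fields, composition, resampling and field averaging.

Direction convention (fixed repo-wide): every transform maps *fixed-image*
points into *moving-image* space, so warping the moving image onto the
fixed grid is a single :func:`resample` call.  Composites apply their
members right-to-left (the last list element acts first on the point).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .model import Grid, VolumetricImage
from . import io as _io

__all__ = [
    "LinearTransform",
    "BSplineTransform",
    "DisplacementField",
    "CompositeTransform",
    "Transform",
    "apply_transform",
    "resample",
    "to_displacement_field",
    "mean_displacement_field",
    "save_transform",
    "load_transform",
]


def _as_points(p) -> Tuple[np.ndarray, bool]:
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    return np.atleast_2d(pts), single


def _euler_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class LinearTransform:
    """y = M (x - c) + c + t with x, y, c, t in μm."""

    kind: str = "affine"  # translation | similarity | affine
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.kind not in ("translation", "similarity", "affine"):
            raise ValueError(f"unknown linear transform kind {self.kind!r}")
        if self.kind == "translation" and not np.allclose(self.matrix, np.eye(3)):
            raise ValueError("translation transform must have identity matrix")
        if self.kind == "similarity":
            s = np.linalg.det(self.matrix)
            if s <= 0:
                raise ValueError("similarity transform requires det > 0")
            scale = s ** (1.0 / 3.0)
            R = self.matrix / scale
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                raise ValueError("similarity matrix is not (uniform scale)·(rotation)")

    # --- constructors -----------------------------------------------------------
    @classmethod
    def identity(cls) -> "LinearTransform":
        return cls(kind="translation")

    @classmethod
    def from_translation(cls, t) -> "LinearTransform":
        return cls(kind="translation", translation=np.asarray(t, dtype=float))

    @classmethod
    def similarity(cls, scale=1.0, angles=(0.0, 0.0, 0.0), translation=(0, 0, 0),
                   center=(0, 0, 0)) -> "LinearTransform":
        return cls(
            kind="similarity",
            matrix=float(scale) * _euler_xyz(*angles),
            translation=translation,
            center=center,
        )

    @classmethod
    def flip(cls, axis: int, center) -> "LinearTransform":
        m = np.eye(3)
        m[axis, axis] = -1.0
        return cls(kind="affine", matrix=m, center=np.asarray(center, dtype=float))

    # --- behaviour --------------------------------------------------------------
    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        out = (pts - self.center) @ self.matrix.T + self.center + self.translation
        return out[0] if single else out

    @property
    def jacobian(self) -> np.ndarray:
        return self.matrix

    def inverse(self) -> "LinearTransform":
        inv = np.linalg.inv(self.matrix)
        # y = M(x-c)+c+t  =>  x = M^-1 (y - c - t) + c
        return LinearTransform(
            kind=self.kind if self.kind != "translation" else "translation",
            matrix=inv,
            translation=-inv @ self.translation,
            center=self.center,
        )

    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
        }


class BSplineTransform:
    """Cubic B-spline free-form deformation on a regular isotropic μm grid.

    ``coefficients`` has shape ``(nx, ny, nz, 3)``; control point ``(i,j,k)``
    sits at ``grid_origin + (i,j,k) * grid_spacing``.  Points outside the
    spline support are extrapolated by the identity (zero displacement).
    """

    def __init__(
        self,
        grid_origin,
        grid_spacing: float,
        coefficients: np.ndarray,
        order: int = 3,
    ) -> None:
        self.grid_origin = np.asarray(grid_origin, dtype=float).reshape(3)
        self.grid_spacing = float(grid_spacing)
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.order = int(order)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")

    @classmethod
    def domain_covering(
        cls, grid: Grid, grid_spacing: float, order: int = 3
    ) -> "BSplineTransform":
        """Zero transform whose control grid covers ``grid`` plus spline support."""
        margin = (order + 1) // 2 + 1
        lo = np.asarray(grid.origin, dtype=float)
        extent = np.asarray(grid.extent, dtype=float)
        n = np.ceil(extent / grid_spacing).astype(int) + 1 + 2 * margin
        origin = lo - margin * grid_spacing
        return cls(origin, grid_spacing, np.zeros((*n, 3)), order=order)

    def _grid_coords(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.grid_origin) / self.grid_spacing

    def displacement(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        g = self._grid_coords(pts).T  # (3, N)
        shape = np.asarray(self.coefficients.shape[:3])
        inside = np.all((g.T >= 1.0) & (g.T <= shape - 2.0), axis=1)
        if not np.all(inside):
            warnings.warn(
                "points outside B-spline support extrapolated by identity",
                stacklevel=2,
            )
        out = np.empty((pts.shape[0], 3))
        for axis in range(3):
            out[:, axis] = ndimage.map_coordinates(
                self.coefficients[..., axis], g, order=self.order,
                prefilter=False, mode="constant", cval=0.0,
            )
        return out[0] if single else out

    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        out = pts + self.displacement(pts)
        return out[0] if single else out

    def max_displacement(self) -> float:
        """Upper bound via control-point magnitudes (B-spline convex hull)."""
        return float(np.max(np.linalg.norm(self.coefficients, axis=-1), initial=0.0))

    def to_dict(self) -> dict:
        return {
            "type": "bspline",
            "grid_origin": self.grid_origin.tolist(),
            "grid_spacing": self.grid_spacing,
            "order": self.order,
            "shape": list(self.coefficients.shape[:3]),
            "coefficients": self.coefficients.tolist(),
        }


class DisplacementField:
    """Dense displacement vectors (μm) sampled on a reference grid."""

    def __init__(self, vectors: np.ndarray, grid: Grid) -> None:
        self.vectors = np.asarray(vectors, dtype=float)
        self.grid = grid
        if self.vectors.shape != (*grid.shape, 3):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match grid "
                f"{grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: Grid) -> "DisplacementField":
        return cls(np.zeros((*grid.shape, 3)), grid)

    def displacement(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        idx = self.grid.physical_to_index(pts).T
        out = np.empty((pts.shape[0], 3))
        for axis in range(3):
            out[:, axis] = ndimage.map_coordinates(
                self.vectors[..., axis], idx, order=1, mode="nearest"
            )
        return out[0] if single else out

    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        out = pts + self.displacement(pts)
        return out[0] if single else out

    def invert(self, max_iter: int = 30, tol: float = 0.1) -> "DisplacementField":
        """Approximate inverse on the same grid by fixed-point iteration.

        Stops when the max residual ``|u(x + v(x)) + v(x)|`` drops below
        ``tol`` μm (default 0.1 μm, well below voxel size) or after
        ``max_iter`` sweeps.
        """
        pts = self.grid.physical_points().reshape(-1, 3)
        v = np.zeros_like(pts)
        for _ in range(max_iter):
            u_at = self.displacement(pts + v)
            residual = v + u_at
            v = -u_at
            if np.max(np.linalg.norm(residual, axis=1)) < tol:
                break
        return DisplacementField(v.reshape(*self.grid.shape, 3), self.grid)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def save(self, path) -> None:
        _io._write_metaimage(self.vectors, self.grid.spacing, self.grid.origin, Path(path))

    @classmethod
    def load(cls, path) -> "DisplacementField":
        data, spacing, origin = _io._read_metaimage(Path(path))
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(f"{path}: not a 3-component displacement field")
        return cls(data, Grid(data.shape[:3], spacing, origin))


class CompositeTransform:
    """Ordered transform chain; ``apply`` runs members right-to-left."""

    def __init__(self, transforms: Sequence) -> None:
        self.transforms: List = list(transforms)
        if not self.transforms:
            raise ValueError("composite transform needs at least one member")

    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        for t in reversed(self.transforms):
            pts = np.atleast_2d(t.apply(pts))
        return pts[0] if single else pts

    def linear_jacobian(self) -> np.ndarray:
        """Product of the Jacobians of the linear members (others as identity)."""
        j = np.eye(3)
        for t in self.transforms:
            if isinstance(t, LinearTransform):
                j = j @ t.matrix
            elif isinstance(t, CompositeTransform):
                j = j @ t.linear_jacobian()
        return j

    def to_dict(self) -> dict:
        return {"type": "composite", "transforms": [t.to_dict() for t in self.transforms]}


Transform = Union[LinearTransform, BSplineTransform, DisplacementField, CompositeTransform]


def apply_transform(t: Transform, points) -> np.ndarray:
    """Map fixed-space point(s) (μm) into moving-image space."""
    pts = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return t.apply(pts)


_INTERP_ORDER = {"linear": 1, "cubic": 3, "nearest": 0}


def _check_not_degenerate(t: Transform) -> None:
    # reflections (flips) are legitimate pipeline members; only a collapsed
    # (non-invertible) matrix is degenerate
    if isinstance(t, LinearTransform):
        if abs(np.linalg.det(t.matrix)) < 1e-12:
            raise ValueError("degenerate linear transform (det ~ 0)")
    elif isinstance(t, CompositeTransform):
        for m in t.transforms:
            _check_not_degenerate(m)


def resample(
    moving: VolumetricImage,
    t: Transform,
    reference: Union[Grid, VolumetricImage],
    interp: str = "linear",
) -> VolumetricImage:
    """Warp ``moving`` onto the ``reference`` grid through fixed→moving map ``t``.

    Out-of-domain voxels get intensity 0.  Nearest interpolation keeps masks
    binary and 8-bit data exact for integer-voxel shifts.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"interp must be one of {sorted(_INTERP_ORDER)}")
    _check_not_degenerate(t)
    grid = reference.grid if isinstance(reference, VolumetricImage) else reference
    pts = grid.physical_points().reshape(-1, 3)
    mapped = apply_transform(t, pts)
    idx = moving.grid.physical_to_index(mapped).T
    order = _INTERP_ORDER[interp]
    data = ndimage.map_coordinates(
        moving.data.astype(np.float32 if order > 0 else moving.data.dtype),
        idx, order=order, mode="constant", cval=0.0,
    ).reshape(grid.shape)
    if order == 0:
        data = data.astype(moving.data.dtype)
    return VolumetricImage(
        data=data, spacing=grid.spacing, origin=grid.origin,
        channel_label=moving.channel_label,
    )


def to_displacement_field(t: Transform, reference: Union[Grid, VolumetricImage]) -> DisplacementField:
    """Densify any transform: vectors[v] = t(x_v) − x_v on the reference grid."""
    grid = reference.grid if isinstance(reference, VolumetricImage) else reference
    pts = grid.physical_points().reshape(-1, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = apply_transform(t, pts) - pts
    return DisplacementField(vec.reshape(*grid.shape, 3), grid)


def mean_displacement_field(
    fields: Sequence[DisplacementField], include_identity: bool = True
) -> DisplacementField:
    """Pointwise arithmetic mean of fields sharing one reference grid.

    With ``include_identity`` a zero field joins the average (a scan's own
    deformation to itself), biasing the mean space toward each subject
    equally.
    """
    if not fields:
        raise ValueError("mean_displacement_field needs at least one field")
    grid = fields[0].grid
    for f in fields[1:]:
        if f.grid != grid:
            raise ValueError("all fields must share one reference grid")
    total = np.zeros_like(fields[0].vectors)
    for f in fields:
        total += f.vectors
    n = len(fields) + (1 if include_identity else 0)
    return DisplacementField(total / n, grid)


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

def save_transform(t: Transform, path) -> None:
    if isinstance(t, DisplacementField):
        t.save(path)
        return
    Path(path).write_text(json.dumps(t.to_dict(), indent=2))


def _from_dict(d: dict) -> Transform:
    if d["type"] == "linear":
        return LinearTransform(
            kind=d["kind"], matrix=np.array(d["matrix"]),
            translation=np.array(d["translation"]), center=np.array(d["center"]),
        )
    if d["type"] == "bspline":
        return BSplineTransform(
            np.array(d["grid_origin"]), d["grid_spacing"],
            np.array(d["coefficients"]).reshape(*d["shape"], 3), order=d["order"],
        )
    if d["type"] == "composite":
        return CompositeTransform([_from_dict(m) for m in d["transforms"]])
    raise ValueError(f"unknown transform type {d['type']!r}")


def load_transform(path) -> Transform:
    path = Path(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        return DisplacementField.load(path)
    return _from_dict(json.loads(path.read_text()))
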