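"""Core domain types shared by every stage of the pipeline.

Conventions fixed repo-wide:

* Image arrays are indexed ``data[i, j, k]`` where axis 0 is x (fast
  in-plane axis), axis 1 is y (slow in-plane axis) and axis 2 is z
  (slice axis).
* Voxel indices are 0-based.  The physical position (in micrometres) of
  voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``, i.e. the
  origin sits at the *center* of voxel ``(0, 0, 0)``.
* All geometry (landmarks, transforms, metric radii, grid spacings) is
  expressed in physical micrometres; voxel anisotropy is never ignored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CHANNEL_LABELS",
    "Grid",
    "VolumetricImage",
    "BrainScan",
    "LandmarkSet",
    "QAReport",
]

CHANNEL_LABELS = ("NP", "NT", "GE", "mask", "other")


@dataclass(frozen=True)
class Grid:
    """Sampling geometry of a 3D scalar grid (shape + spacing + origin)."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # --- coordinate conversions -------------------------------------------------
    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Convert (continuous) voxel indices, shape (..., 3), to μm points."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Convert μm points, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical size (μm) spanned by the voxel centers along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid (μm)."""
        return np.asarray(self.origin) + 0.5 * np.asarray(self.extent)

    def physical_points(self) -> np.ndarray:
        """All voxel-center positions as an array of shape ``shape + (3,)``."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        idx = self.physical_to_index(pts)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx <= shape - 1), axis=-1)


@dataclass
class VolumetricImage:
    """A 3D scalar image on a physical grid; the unit of all registration."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_label: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"image data must have exactly 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(
                f"channel_label must be one of {CHANNEL_LABELS}, got {self.channel_label!r}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return self.grid.index_to_physical(idx)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        return self.grid.physical_to_index(pts)

    def copy(self, data: Optional[np.ndarray] = None, **kwargs) -> "VolumetricImage":
        out = replace(self)
        out.data = self.data.copy() if data is None else np.asarray(data)
        for k, v in kwargs.items():
            setattr(out, k, v)
        out.__post_init__()
        return out

    def astype(self, dtype) -> "VolumetricImage":
        return self.copy(data=self.data.astype(dtype))


@dataclass
class BrainScan:
    """One imaged CNS: a set of co-registered channels sharing a grid."""

    scan_id: str
    channels: Dict[str, VolumetricImage]

    def __post_init__(self) -> None:
        if "NP" not in self.channels:
            raise ValueError(f"scan {self.scan_id!r}: NP channel is required")
        ref = self.channels["NP"].grid
        for label, img in self.channels.items():
            if img.grid != ref:
                raise ValueError(
                    f"scan {self.scan_id!r}: channel {label!r} grid {img.grid} "
                    f"differs from NP grid {ref}"
                )

    @property
    def np(self) -> VolumetricImage:
        return self.channels["NP"]

    @property
    def grid(self) -> Grid:
        return self.channels["NP"].grid

    def __contains__(self, label: str) -> bool:
        return label in self.channels


class LandmarkSet:
    """Named 3D points in physical μm, order-preserving, unique labels."""

    def __init__(
        self,
        labels: Sequence[str],
        coords: np.ndarray,
        frame_id: str = "",
    ) -> None:
        self.labels: List[str] = [str(l) for l in labels]
        self.coords = np.atleast_2d(np.asarray(coords, dtype=float))
        if len(self.labels) == 0:
            self.coords = self.coords.reshape(0, 3)
        self.frame_id = frame_id
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate landmark labels: {dupes}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[Tuple[str, np.ndarray]]:
        return zip(self.labels, self.coords)

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.coords[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def subset(self, labels: Sequence[str]) -> "LandmarkSet":
        coords = np.array([self[l] for l in labels], dtype=float).reshape(len(labels), 3)
        return LandmarkSet(list(labels), coords, frame_id=self.frame_id)

    def with_coords(self, coords: np.ndarray, frame_id: Optional[str] = None) -> "LandmarkSet":
        return LandmarkSet(
            self.labels, coords, frame_id=self.frame_id if frame_id is None else frame_id
        )

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {l: c for l, c in self}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LandmarkSet)
            and self.labels == other.labels
            and np.array_equal(self.coords, other.coords)
        )

    def __repr__(self) -> str:
        return f"LandmarkSet({len(self)} points, frame_id={self.frame_id!r})"


@dataclass
class QAReport:
    """Per-scan registration confidence (percent) and the accept/flag call.

    Invariants: ``ti == m_score * s_score / 100`` within float tolerance and
    ``decision == "flagged"`` exactly when ``min(vi, ti) < threshold``.
    """

    scan_id: str
    vi: float
    ti: float
    m_score: float
    s_score: float
    decision: str
    threshold: float = 50.0

    def __post_init__(self) -> None:
        for name in ("vi", "ti"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if not math.isclose(self.ti, self.m_score * self.s_score / 100.0, abs_tol=1e-6):
            raise ValueError(
                f"ti={self.ti} inconsistent with m*s/100="
                f"{self.m_score * self.s_score / 100.0}"
            )
        expected = "flagged" if min(self.vi, self.ti) < self.threshold else "accepted"
        if self.decision not in ("accepted", "flagged"):
            raise ValueError(f"decision must be accepted|flagged, got {self.decision!r}")
        if self.decision != expected:
            raise ValueError(
                f"decision {self.decision!r} inconsistent with vi={self.vi}, "
                f"ti={self.ti}, threshold={self.threshold}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "scan_id": self.scan_id,
                "vi": self.vi,
                "ti": self.ti,
                "m_score": self.m_score,
                "s_score": self.s_score,
                "decision": self.decision,
                "threshold": self.threshold,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "QAReport":
        return cls(**json.loads(text))
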