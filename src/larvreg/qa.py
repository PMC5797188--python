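"""Automatic detection of local registration failures.

Two local confidence indicators, both in percent:

* VI — regional mutual information between template and registered scan in
  10 μm spheres at the two terminal cord anchor points, normalized by the
  calibration cohort's maximum (the best-registered terminal scores 100%).
* TI — product M·S/100 at the six thoracic nerve anchors, where M is
  regional MI in 15 μm spheres (percent of calibration max) and S is a
  strain-based confidence from the 95th percentile of the normalized
  Eulerian strain magnitude in 35 μm spheres (zero excess strain over the
  calibration cohort maps to 100%, decreasing linearly to 0 at ``s_cap``
  robust units above it).

A scan is flagged for manual correction when either indicator falls below
the 50% threshold (strictly; exactly 50 is accepted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .metrics import regional_mi, sphere_voxel_indices
from .model import LandmarkSet, QAReport, VolumetricImage
from .transforms import DisplacementField

__all__ = [
    "StrainSample",
    "eulerian_strain_magnitude",
    "vi_indicator",
    "ti_indicator",
    "qa_decide",
    "assess_scan",
    "QA_THRESHOLD",
    "VI_RADIUS",
    "TI_MI_RADIUS",
    "TI_STRAIN_RADIUS",
]

QA_THRESHOLD = 50.0
VI_RADIUS = 10.0
TI_MI_RADIUS = 15.0
TI_STRAIN_RADIUS = 35.0
_SINGULAR_CAP = 10.0


@dataclass
class StrainSample:
    anchor_label: str
    magnitudes: np.ndarray
    p95: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(self.magnitudes < 0):
            raise ValueError("strain magnitudes must be >= 0")
        expected = float(np.percentile(self.magnitudes, 95))
        if not np.isclose(self.p95, expected):
            raise ValueError(f"p95 {self.p95} != 95th percentile {expected}")

    @classmethod
    def from_magnitudes(cls, anchor_label: str, magnitudes) -> "StrainSample":
        mags = np.asarray(magnitudes, dtype=float)
        return cls(anchor_label, mags, float(np.percentile(mags, 95)))


def eulerian_strain_magnitude(
    field: DisplacementField,
    at: Optional[np.ndarray] = None,
    singular_cap: float = _SINGULAR_CAP,
) -> np.ndarray:
    """Frobenius norm of the Eulerian (Almansi) strain e = ½(I − (F Fᵀ)⁻¹)
    with F = I + ∇u from central differences in physical μm.

    Returns the full volume, or values at the given physical points (nearest
    grid node).  Voxels with a (near-)singular F get ``singular_cap``.
    """
    u = field.vectors
    sp = field.grid.spacing
    F = np.empty((*u.shape[:3], 3, 3))
    for c in range(3):
        gx, gy, gz = np.gradient(u[..., c], *sp)
        F[..., c, 0] = gx
        F[..., c, 1] = gy
        F[..., c, 2] = gz
    F += np.eye(3)
    det = np.linalg.det(F)
    singular = np.abs(det) <= 1e-6
    if singular.any():
        warnings.warn(
            f"{int(singular.sum())} voxels with singular deformation gradient; "
            "strain capped"
        )
        F[singular] = np.eye(3)  # placeholder; overwritten with the cap below
    b_inv = np.linalg.inv(F @ np.swapaxes(F, -1, -2))
    e = 0.5 * (np.eye(3) - b_inv)
    mag = np.linalg.norm(e, axis=(-2, -1))
    mag[singular] = singular_cap
    if at is None:
        return mag
    idx = np.rint(field.grid.physical_to_index(np.atleast_2d(at))).astype(int)
    idx = np.clip(idx, 0, np.asarray(field.grid.shape) - 1)
    return mag[tuple(idx.T)]


def vi_indicator(
    template: VolumetricImage,
    registered_np: VolumetricImage,
    anchors: LandmarkSet,
    calibration: Dict,
    radius: float = VI_RADIUS,
) -> float:
    """Terminal-cord confidence: worst anchor's regional MI as a percent of
    the calibration maximum, clipped to [0, 100]."""
    if len(anchors) != 2:
        raise ValueError(f"vi_indicator expects 2 anchors, got {len(anchors)}")
    vi_max = calibration["vi_max"]
    scores = []
    for label, point in anchors:
        mi = regional_mi(template, registered_np, point, radius)
        scores.append(100.0 * mi / max(vi_max[label], 1e-12))
    return float(np.clip(min(scores), 0.0, 100.0))


def ti_indicator(
    template: VolumetricImage,
    registered_np: VolumetricImage,
    field: DisplacementField,
    anchors: LandmarkSet,
    calibration: Dict,
    mi_radius: float = TI_MI_RADIUS,
    strain_radius: float = TI_STRAIN_RADIUS,
) -> Tuple[float, float, float]:
    """Thoracic-nerve confidence: per anchor TI_a = M_a·S_a/100; the scan's
    TI is the minimum over the six anchors (one failed nerve must flag the
    scan).  Returns (M, S, TI) of the worst anchor."""
    if len(anchors) != 6:
        raise ValueError(f"ti_indicator expects 6 anchors, got {len(anchors)}")
    mi_max = calibration["ti_mi_max"]
    median = calibration["strain_median"]
    mad = calibration["strain_mad"]
    z_ref = calibration["strain_p95_ref"]
    s_cap = calibration["s_cap"]
    mag = eulerian_strain_magnitude(field)

    worst = None
    for label, point in anchors:
        mi = regional_mi(template, registered_np, point, mi_radius)
        m_score = float(np.clip(100.0 * mi / max(mi_max[label], 1e-12), 0.0, 100.0))
        idx = sphere_voxel_indices(template, point, strain_radius)
        sample = StrainSample.from_magnitudes(label, mag[idx])
        z95 = (sample.p95 - median) / mad
        s_score = float(np.clip(100.0 * (1.0 - np.clip(z95 - z_ref, 0.0, s_cap) / s_cap),
                                0.0, 100.0))
        ti = m_score * s_score / 100.0
        if worst is None or ti < worst[2]:
            worst = (m_score, s_score, ti)
    return worst


def qa_decide(
    vi: float,
    ti: float,
    m_score: Optional[float] = None,
    s_score: Optional[float] = None,
    threshold: float = QA_THRESHOLD,
    scan_id: str = "",
) -> QAReport:
    """Flag iff VI or TI falls strictly below the threshold."""
    if m_score is None or s_score is None:
        m_score, s_score = ti, 100.0
    decision = "flagged" if min(vi, ti) < threshold else "accepted"
    return QAReport(
        scan_id=scan_id, vi=vi, ti=ti, m_score=m_score, s_score=s_score,
        decision=decision, threshold=threshold,
    )


def assess_scan(
    template_pkg,
    registered_np: VolumetricImage,
    field: DisplacementField,
    scan_id: str = "",
    threshold: float = QA_THRESHOLD,
) -> QAReport:
    """Score one registered scan against a template package."""
    vi = vi_indicator(
        template_pkg.np_template, registered_np, template_pkg.vnc_anchors,
        template_pkg.qa_calibration,
    )
    m, s, ti = ti_indicator(
        template_pkg.np_template, registered_np, field,
        template_pkg.thoracic_anchors, template_pkg.qa_calibration,
    )
    return qa_decide(vi, ti, m, s, threshold=threshold, scan_id=scan_id)
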