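"""Landmark registration error (LRE) statistics and cohort aggregation.

Reporting conventions: per-scan LREs are averaged per registration first;
cohort statistics are then the mean ± sample standard deviation and the
median of those per-scan means, and the mean of the per-scan maxima.
Report rounding is one decimal μm, half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import LandmarkSet
from .transforms import Transform, apply_transform

__all__ = [
    "LREResult",
    "landmark_registration_error",
    "aggregate_scans",
    "intra_rater_stats",
    "qa_confusion",
    "round_report",
    "load_intra_rater_table",
    "load_cohort_lre_table",
]


def _data_path(name: str):
    from importlib.resources import files

    return files("larvreg").joinpath("data", name)


def load_intra_rater_table() -> pd.DataFrame:
    """The 30-landmark × 4-scan intra-rater deviation table (μm), landmarks
    as index."""
    with _data_path("intra_rater_deviations.csv").open() as fh:
        return pd.read_csv(fh, index_col="landmark")


def load_cohort_lre_table() -> pd.DataFrame:
    """Per-scan LRE statistics (μm) of a 25-scan cohort under fully automatic
    and semi-automatic registration; ``corrected`` marks the scans whose
    partially failed registrations were corrected with guide landmarks."""
    with _data_path("cohort_lre.csv").open() as fh:
        return pd.read_csv(fh, index_col="scan")


def round_report(value: float, decimals: int = 1) -> float:
    """Half-up rounding as printed in the report tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LREResult:
    scan_id: str
    per_landmark: Dict[str, float]
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        errors = np.array(list(self.per_landmark.values()), dtype=float)
        if errors.size == 0:
            raise ValueError(f"scan {self.scan_id!r}: no landmark errors")
        if np.any(errors < 0):
            raise ValueError("landmark errors must be >= 0")
        self.mean = float(errors.mean())
        self.sd = float(errors.std(ddof=1)) if errors.size > 1 else 0.0
        self.median = float(np.median(errors))
        self.max = float(errors.max())

    @classmethod
    def from_stats(cls, scan_id: str, mean: float, sd: float, median: float,
                   maximum: float) -> "LREResult":
        """Carrier for published per-scan statistics without per-landmark data."""
        out = cls.__new__(cls)
        out.scan_id = scan_id
        out.per_landmark = {}
        out.mean, out.sd, out.median, out.max = (
            float(mean), float(sd), float(median), float(maximum)
        )
        return out


def landmark_registration_error(
    reference: LandmarkSet,
    subject_landmarks: LandmarkSet,
    transform: Transform,
    scan_id: str = "",
) -> LREResult:
    """Euclidean distance (μm), per label, between the transformed reference
    landmark (template space mapped into subject space) and the annotated
    subject position.  Labels present in only one set are excluded with a
    warning, never silently dropped."""
    common = [l for l in reference.labels if l in subject_landmarks]
    missing = sorted(
        set(reference.labels).symmetric_difference(subject_landmarks.labels)
    )
    if missing:
        warnings.warn(f"landmarks excluded (present in one set only): {missing}")
    if not common:
        raise ValueError("no common landmark labels between the two sets")
    ref_pts = reference.subset(common).coords
    sub_pts = subject_landmarks.subset(common).coords
    mapped = np.atleast_2d(apply_transform(transform, ref_pts))
    errors = np.linalg.norm(mapped - sub_pts, axis=1)
    return LREResult(
        scan_id=scan_id or subject_landmarks.frame_id,
        per_landmark=dict(zip(common, errors.tolist())),
    )


def aggregate_scans(results: Sequence[LREResult]) -> Dict[str, float]:
    """Cohort statistics: LREs are averaged per registration, then the
    median, mean and sample standard deviation of those means are computed;
    the maximum is the mean over each registration's largest error."""
    if not results:
        raise ValueError("aggregate_scans needs at least one result")
    means = np.array([r.mean for r in results])
    maxima = np.array([r.max for r in results])
    return {
        "n": len(results),
        "mean": float(means.mean()),
        "sd": float(means.std(ddof=1)) if means.size > 1 else 0.0,
        "median": float(np.median(means)),
        "max": float(maxima.mean()),
    }


def intra_rater_stats(deviations: pd.DataFrame) -> Dict[str, object]:
    """Statistics of a landmarks × scans table of annotation deviations (μm):
    the grand mean/sd over all entries, each landmark's maximum over scans,
    the mean/sd of those maxima, and the overall maximum."""
    table = deviations.to_numpy(dtype=float)
    if table.ndim != 2 or table.size == 0:
        raise ValueError("deviations must be a non-empty 2D table")
    per_landmark_max = table.max(axis=1)
    return {
        "grand_mean": float(table.mean()),
        "grand_sd": float(table.std(ddof=1)),
        "per_scan_mean": table.mean(axis=0),
        "per_landmark_max": per_landmark_max,
        "mean_of_maxima": float(per_landmark_max.mean()),
        "sd_of_maxima": float(per_landmark_max.std(ddof=1)),
        "overall_max": float(table.max()),
    }


_QA_LABELS = ("accepted", "rejected")


def qa_confusion(
    expert: Mapping[str, str], predicted: Mapping[str, str]
) -> pd.DataFrame:
    """2×2 confusion matrix (expert rows, predicted columns) with row/column
    sums, over the scan ids present in both maps."""
    ids = sorted(set(expert) & set(predicted))
    if not ids:
        raise ValueError("no common scan ids between expert and predicted maps")
    counts = np.zeros((2, 2), dtype=int)
    for sid in ids:
        e, p = expert[sid], predicted[sid]
        if e not in _QA_LABELS or p not in _QA_LABELS:
            raise ValueError(f"labels must be accepted|rejected, got {e!r}/{p!r}")
        counts[_QA_LABELS.index(e), _QA_LABELS.index(p)] += 1
    df = pd.DataFrame(
        counts,
        index=[f"expert_{l}" for l in _QA_LABELS],
        columns=[f"predicted_{l}" for l in _QA_LABELS],
    )
    df["sum"] = df.sum(axis=1)
    df.loc["sum"] = df.sum(axis=0)
    return df
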