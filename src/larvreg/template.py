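"""Population-based template construction.

All pairwise deformations are estimated with the four-stage pipeline
(histogram matching, two z-flip affine candidates, candidate selection by
final similarity, deformable refinement).  Every scan is then carried into
the population average space by the mean of its deformations to all other
scans, warped there, and fused voxelwise (mean or, to suppress background
blur from nerve strings, median).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .deformable import DeformableConfig, register_bspline
from .global_registration import register_linear, flatten_linear
from .metrics import regional_mi
from .model import BrainScan, Grid, LandmarkSet, VolumetricImage
from .phantom import QA_ANCHOR_LABELS, THORACIC_ANCHOR_LABELS, VNC_ANCHOR_LABELS
from .preprocess import histogram_match, robust_rescale, threshold_brain_mask, z_flip_candidates
from .qa import eulerian_strain_magnitude
from .metrics import sphere_voxel_indices
from .transforms import (
    CompositeTransform,
    DisplacementField,
    LinearTransform,
    mean_displacement_field,
    resample,
    to_displacement_field,
)
from . import io as _io

__all__ = [
    "TemplatePackage",
    "PairwiseRegistrationError",
    "pairwise_register_all",
    "build_average_space",
    "fuse",
    "propagate_channel",
    "build_template",
    "register_template_pair",
]

TI_MI_RADIUS = 15.0
VI_MI_RADIUS = 10.0
STRAIN_RADIUS = 35.0


class PairwiseRegistrationError(RuntimeError):
    def __init__(self, fixed_id: str, moving_id: str, cause: Exception) -> None:
        super().__init__(f"pairwise registration {moving_id!r} -> {fixed_id!r} failed: {cause}")
        self.fixed_id = fixed_id
        self.moving_id = moving_id


@dataclass
class TemplatePackage:
    np_template: VolumetricImage
    brain_mask: VolumetricImage
    qa_anchors: LandmarkSet  # 2 VNC terminal + 6 thoracic points, template space
    qa_calibration: Dict
    fusion: str
    nt_template: Optional[VolumetricImage] = None
    provenance: Dict = field(default_factory=dict)
    gold_landmarks: Optional[LandmarkSet] = None  # full schema, template space

    def __post_init__(self) -> None:
        if len(self.qa_anchors) != 8:
            raise ValueError(f"qa_anchors must hold exactly 8 points, got {len(self.qa_anchors)}")
        missing = [l for l in QA_ANCHOR_LABELS if l not in self.qa_anchors]
        if missing:
            raise ValueError(f"qa_anchors missing labels: {missing}")
        if not (self.brain_mask.data > 0).any():
            raise ValueError("brain mask is empty")

    @property
    def vnc_anchors(self) -> LandmarkSet:
        return self.qa_anchors.subset(list(VNC_ANCHOR_LABELS))

    @property
    def thoracic_anchors(self) -> LandmarkSet:
        return self.qa_anchors.subset(list(THORACIC_ANCHOR_LABELS))

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        _io.write_stack(self.np_template.astype(np.float32), d / "np_template.mha")
        if self.nt_template is not None:
            _io.write_stack(self.nt_template.astype(np.float32), d / "nt_template.mha")
        _io.write_stack(self.brain_mask.astype(np.uint8), d / "brain_mask.mha")
        _io.write_landmarks(self.qa_anchors, d / "qa_anchors.csv")
        if self.gold_landmarks is not None:
            _io.write_landmarks(self.gold_landmarks, d / "gold_landmarks.csv")
        (d / "qa_calibration.json").write_text(json.dumps(self.qa_calibration, indent=2))
        (d / "provenance.json").write_text(
            json.dumps({"fusion": self.fusion, **self.provenance}, indent=2)
        )

    @classmethod
    def load(cls, directory) -> "TemplatePackage":
        d = Path(directory)
        np_t = _io.read_stack(d / "np_template.mha", channel_label="NP")
        nt_path = d / "nt_template.mha"
        nt_t = _io.read_stack(nt_path, channel_label="NT") if nt_path.exists() else None
        mask = _io.read_stack(d / "brain_mask.mha", channel_label="mask")
        anchors = _io.read_landmarks(d / "qa_anchors.csv", frame_id="template")
        calib = json.loads((d / "qa_calibration.json").read_text())
        prov = json.loads((d / "provenance.json").read_text())
        fusion = prov.pop("fusion", "median")
        gold_path = d / "gold_landmarks.csv"
        gold = _io.read_landmarks(gold_path, frame_id="template") if gold_path.exists() else None
        return cls(
            np_template=np_t, nt_template=nt_t, brain_mask=mask,
            qa_anchors=anchors, qa_calibration=calib, fusion=fusion, provenance=prov,
            gold_landmarks=gold,
        )


# ---------------------------------------------------------------------------
# pairwise registration (template-generation variant, 4 stages)
# ---------------------------------------------------------------------------

def register_template_pair(
    fixed: BrainScan,
    moving: BrainScan,
    cfg: Optional[DeformableConfig] = None,
    linear_levels: int = 3,
) -> CompositeTransform:
    """Histogram match → two z-flip affine candidates → select by final NCC →
    deformable refinement.  Returns the fixed→moving composite."""
    cfg = cfg or DeformableConfig(metric="global_random_NCC")
    fx = robust_rescale(fixed.channels["NP"])
    mv = robust_rescale(moving.channels["NP"])
    mv = histogram_match(mv, fx)

    candidates = []
    for _, t_flip in z_flip_candidates(mv):
        t, score = register_linear(
            fx, mv, kind="affine", metric="NCC", init=t_flip, levels=linear_levels
        )
        candidates.append((score.value, t))
    affine = max(candidates, key=lambda c: c[0])[1]

    bspline, _ = register_bspline(fx, mv, init=affine, cfg=cfg)
    return CompositeTransform([affine, bspline])


def pairwise_register_all(
    scans: Sequence[BrainScan],
    cfg: Optional[DeformableConfig] = None,
    linear_levels: int = 3,
) -> Dict[Tuple[int, int], DisplacementField]:
    """All N·(N−1) pairwise deformations T_ij (fixed i, moving j), densified
    on each fixed scan's grid; the diagonal holds zero fields."""
    if len(scans) < 3:
        raise ValueError(f"template construction needs at least 3 scans, got {len(scans)}")
    fields: Dict[Tuple[int, int], DisplacementField] = {}
    for i, fixed in enumerate(scans):
        fields[(i, i)] = DisplacementField.zero(fixed.grid)
        for j, moving in enumerate(scans):
            if i == j:
                continue
            try:
                t = register_template_pair(fixed, moving, cfg=cfg, linear_levels=linear_levels)
            except Exception as exc:  # re-raise with the pair named
                raise PairwiseRegistrationError(fixed.scan_id, moving.scan_id, exc) from exc
            fields[(i, j)] = to_displacement_field(t, fixed.grid)
    return fields


def build_average_space(
    fields: Dict[Tuple[int, int], DisplacementField],
    include_identity: bool = True,
) -> List[DisplacementField]:
    """Mean deformation T_i of every scan to all others (its map into the
    population average space)."""
    n = int(max(i for i, _ in fields) + 1)
    out = []
    for i in range(n):
        others = [fields[(i, j)] for j in range(n) if j != i]
        out.append(mean_displacement_field(others, include_identity=include_identity))
    return out


def fuse(warped: Sequence[VolumetricImage], method: str = "median") -> VolumetricImage:
    """Voxelwise fusion.  Even-count medians take the lower middle value so
    8-bit levels survive without fractional intensities."""
    if method not in ("mean", "median"):
        raise ValueError(f"fusion method must be mean|median, got {method!r}")
    grid = warped[0].grid
    for img in warped[1:]:
        if img.grid != grid:
            raise ValueError("fusion requires a common grid")
    stack = np.stack([img.data for img in warped], axis=0)
    if method == "mean":
        data = stack.mean(axis=0)
    else:
        data = np.sort(stack, axis=0)[(len(warped) - 1) // 2]
    return warped[0].copy(data=data)


def propagate_channel(
    scan: BrainScan, channel: str, transform_chain, reference: Grid,
    interp: str = "linear",
) -> VolumetricImage:
    """Resample a non-NP channel with the NP-derived transform chain (the
    channel itself is never re-registered)."""
    if channel not in scan.channels:
        raise KeyError(f"scan {scan.scan_id!r} has no channel {channel!r}")
    return resample(scan.channels[channel], transform_chain, reference, interp=interp)


# ---------------------------------------------------------------------------
# full template construction
# ---------------------------------------------------------------------------

def build_template(
    scans: Sequence[BrainScan],
    landmarks: Sequence[LandmarkSet],
    fusion: str = "median",
    cfg: Optional[DeformableConfig] = None,
    linear_levels: int = 3,
    include_identity: bool = True,
    s_cap: float = 500.0,
    calibrate_by_registration: bool = True,
) -> TemplatePackage:
    """Run the full population-based construction.

    ``landmarks`` supplies, per scan, at least the 8 QA anchor labels in
    that scan's space; anchors are carried into the average space and
    averaged over the cohort.  The QA calibration (max regional MI per
    anchor; pooled strain median/MAD) is frozen into the package so single
    new scans can be scored later without re-observing a cohort.

    With ``calibrate_by_registration`` (default) the calibration statistics
    come from full subject-to-template registrations of the cohort scans —
    the best *registered* scan defines the 100% mark, matching how new
    scans will be scored.  Otherwise the construction warps themselves are
    used (cheaper, but they are nearly self-similar and set an
    unrealistically high bar).
    """
    if len(landmarks) != len(scans):
        raise ValueError("one landmark set per scan is required")
    fields = pairwise_register_all(scans, cfg=cfg, linear_levels=linear_levels)
    mean_fields = build_average_space(fields, include_identity=include_identity)
    ref_grid = scans[0].grid

    inverse_fields = [t.invert() for t in mean_fields]  # template→subject maps
    warped_np, warped_nt = [], []
    for scan, inv in zip(scans, inverse_fields):
        warped_np.append(resample(scan.channels["NP"], inv, ref_grid))
        if "NT" in scan.channels:
            warped_nt.append(propagate_channel(scan, "NT", inv, ref_grid))

    np_template = fuse(warped_np, fusion)
    np_template.channel_label = "NP"
    nt_template = None
    if len(warped_nt) == len(scans):
        nt_template = fuse(warped_nt, fusion)
        nt_template.channel_label = "NT"
    brain_mask = threshold_brain_mask(np_template)

    anchor_stack = []
    for lms, t_i in zip(landmarks, mean_fields):
        subject_anchors = lms.subset(list(QA_ANCHOR_LABELS))
        anchor_stack.append(t_i.apply(subject_anchors.coords))
    qa_anchors = LandmarkSet(
        list(QA_ANCHOR_LABELS), np.mean(anchor_stack, axis=0), frame_id="template"
    )

    # template-space gold standard: every label shared by the whole cohort,
    # carried through each scan's mean deformation and averaged
    common = [l for l in landmarks[0].labels if all(l in lms for lms in landmarks)]
    gold = None
    if common:
        stacks = [
            t_i.apply(lms.subset(common).coords)
            for lms, t_i in zip(landmarks, mean_fields)
        ]
        gold = LandmarkSet(common, np.mean(stacks, axis=0), frame_id="template")

    calibration = _calibrate_qa(
        np_template, warped_np, inverse_fields, qa_anchors, s_cap=s_cap
    )
    pkg = TemplatePackage(
        np_template=np_template,
        nt_template=nt_template,
        brain_mask=brain_mask,
        qa_anchors=qa_anchors,
        qa_calibration=calibration,
        fusion=fusion,
        provenance={
            "scan_ids": [s.scan_id for s in scans],
            "n_pairwise_fields": len(fields),
            "include_identity": include_identity,
        },
        gold_landmarks=gold,
    )
    if calibrate_by_registration:
        _recalibrate_by_registration(pkg, scans, cfg, s_cap)
    return pkg


def _recalibrate_by_registration(
    pkg: TemplatePackage,
    scans: Sequence[BrainScan],
    cfg: Optional[DeformableConfig],
    s_cap: float,
) -> None:
    """Replace the calibration with statistics from real subject-to-template
    registrations of the cohort scans."""
    import dataclasses

    from .config import PipelineConfig
    from .workflow import register_scan  # local import: workflow imports this module

    pcfg = PipelineConfig()
    if cfg is not None:
        pcfg.deformable = dataclasses.replace(cfg, metric="masked_local_NCC")
    warped, fields_reg = [], []
    for scan in scans:
        outcome = register_scan(pkg, scan, pcfg)
        warped.append(outcome.warped_channels["NP"])
        fields_reg.append(outcome.field)
    pkg.qa_calibration = _calibrate_qa(
        pkg.np_template, warped, fields_reg, pkg.qa_anchors, s_cap=s_cap
    )


def _calibrate_qa(
    template_np: VolumetricImage,
    warped_np: Sequence[VolumetricImage],
    registration_fields: Sequence[DisplacementField],
    qa_anchors: LandmarkSet,
    s_cap: float,
) -> Dict:
    """Freeze the cohort statistics the VI/TI indicators normalize against."""
    vi_max = {}
    for label in VNC_ANCHOR_LABELS:
        center = qa_anchors[label]
        scores = [
            regional_mi(template_np, w, center, VI_MI_RADIUS) for w in warped_np
        ]
        vi_max[label] = float(max(scores))
    ti_mi_max = {}
    for label in THORACIC_ANCHOR_LABELS:
        center = qa_anchors[label]
        scores = [
            regional_mi(template_np, w, center, TI_MI_RADIUS) for w in warped_np
        ]
        ti_mi_max[label] = float(max(scores))

    pooled: List[np.ndarray] = []
    per_scan_sphere: List[List[np.ndarray]] = []
    for fld in registration_fields:
        mag = eulerian_strain_magnitude(fld)
        spheres = []
        for label in THORACIC_ANCHOR_LABELS:
            idx = sphere_voxel_indices(template_np, qa_anchors[label], STRAIN_RADIUS)
            spheres.append(mag[idx])
            pooled.append(mag[idx])
        per_scan_sphere.append(spheres)
    pooled_arr = np.concatenate(pooled)
    median = float(np.median(pooled_arr))
    mad = float(np.median(np.abs(pooled_arr - median)))
    if mad == 0:
        q75, q25 = np.percentile(pooled_arr, [75, 25])
        mad = float(q75 - q25) or 1.0

    # largest per-anchor p95 of the z-scored strain seen in the (clean)
    # calibration cohort: zero excess over this maps to S = 100
    z_p95 = [
        float(np.percentile((s - median) / mad, 95))
        for spheres in per_scan_sphere
        for s in spheres
    ]
    return {
        "vi_max": vi_max,
        "ti_mi_max": ti_mi_max,
        "strain_median": median,
        "strain_mad": mad,
        "strain_p95_ref": float(max(z_p95)),
        "s_cap": float(s_cap),
    }
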