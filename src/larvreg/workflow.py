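"""End-to-end orchestration of subject-to-template registration, quality
assessment and landmark-guided correction (the engine behind the CLI)."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .config import PipelineConfig
from .deformable import MultiMetricConfig, register_bspline, register_multimetric
from .global_registration import GlobalRegistrationResult, flatten_linear, run_global_pipeline
from .model import BrainScan, LandmarkSet, QAReport, VolumetricImage
from .phantom import QA_ANCHOR_LABELS, THORACIC_ANCHOR_LABELS, VNC_ANCHOR_LABELS
from .preprocess import robust_rescale
from .qa import assess_scan
from .template import TemplatePackage, propagate_channel
from .transforms import CompositeTransform, resample, to_displacement_field

__all__ = ["RegistrationOutcome", "register_scan", "correct_scan", "write_outcome"]


@dataclass
class RegistrationOutcome:
    scan_id: str
    transform: CompositeTransform      # template space -> subject space
    global_result: GlobalRegistrationResult
    warped_channels: Dict[str, VolumetricImage]
    qa_report: QAReport
    field: object                      # dense template->subject displacement
    corrected: bool = False


def register_scan(
    pkg: TemplatePackage,
    scan: BrainScan,
    cfg: Optional[PipelineConfig] = None,
) -> RegistrationOutcome:
    """Global pipeline → masked deformable → channel warping → QA."""
    cfg = cfg or PipelineConfig()
    global_result = run_global_pipeline(
        pkg, scan, levels=cfg.global_.levels, max_samples=cfg.global_.max_samples
    )
    return _deform_and_assess(pkg, scan, cfg, global_result, mm=None)


def correct_scan(
    pkg: TemplatePackage,
    scan: BrainScan,
    guide_landmarks: LandmarkSet,
    cfg: Optional[PipelineConfig] = None,
    global_result: Optional[GlobalRegistrationResult] = None,
) -> RegistrationOutcome:
    """Semi-automatic correction with 2 (VNC), 6 (thoracic) or 8 manually
    annotated guide landmarks in subject space; the matching template
    anchors ship in the template package."""
    cfg = cfg or PipelineConfig()
    _validate_guide_labels(guide_landmarks)
    template_guides = pkg.qa_anchors.subset(guide_landmarks.labels)
    mm = MultiMetricConfig(
        template_landmarks=template_guides,
        subject_landmarks=guide_landmarks,
        relative_weight=cfg.correction.relative_weight,
    )
    if global_result is None:
        global_result = run_global_pipeline(
            pkg, scan, levels=cfg.global_.levels, max_samples=cfg.global_.max_samples
        )
    out = _deform_and_assess(pkg, scan, cfg, global_result, mm=mm)
    out.corrected = True
    return out


def _validate_guide_labels(guides: LandmarkSet) -> None:
    unknown = [l for l in guides.labels if l not in QA_ANCHOR_LABELS]
    if unknown:
        raise ValueError(
            f"unrecognized guide landmark labels {unknown}; accepted labels: "
            f"{list(QA_ANCHOR_LABELS)}"
        )
    n = len(guides)
    label_set = set(guides.labels)
    valid = (
        label_set == set(VNC_ANCHOR_LABELS)
        or label_set == set(THORACIC_ANCHOR_LABELS)
        or label_set == set(QA_ANCHOR_LABELS)
    )
    if not valid:
        raise ValueError(
            f"guide landmarks must be the 2 VNC terminal points, the 6 thoracic "
            f"points, or all 8; got {n}: {sorted(label_set)}"
        )


def _deform_and_assess(
    pkg: TemplatePackage,
    scan: BrainScan,
    cfg: PipelineConfig,
    global_result: GlobalRegistrationResult,
    mm: Optional[MultiMetricConfig],
) -> RegistrationOutcome:
    fixed = robust_rescale(pkg.np_template)
    moving = robust_rescale(scan.channels["NP"])
    init = flatten_linear(global_result.transform)
    if mm is None:
        bspline, _ = register_bspline(
            fixed, moving, init=init, cfg=cfg.deformable, mask=pkg.brain_mask
        )
    else:
        bspline, _ = register_multimetric(
            fixed, moving, init=init, cfg=cfg.deformable, mm=mm, mask=pkg.brain_mask
        )
    total = CompositeTransform([init, bspline])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fld = to_displacement_field(total, pkg.np_template.grid)
        warped = {
            label: resample(scan.channels[label], total, pkg.np_template.grid)
            for label in scan.channels
        }
    qa = assess_scan(pkg, warped["NP"], fld, scan_id=scan.scan_id,
                     threshold=cfg.qa.threshold)
    return RegistrationOutcome(
        scan_id=scan.scan_id,
        transform=total,
        global_result=global_result,
        warped_channels=warped,
        qa_report=qa,
        field=fld,
    )


def write_outcome(
    outcome: RegistrationOutcome,
    out_dir,
    cfg: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Persist warped channels, the transform, the QA report and a run
    manifest (config hash, seeds, version) for reproducibility."""
    from . import io as _io
    from .transforms import save_transform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, img in outcome.warped_channels.items():
        _io.write_stack(img, out / f"registered_{label}.mha")
    save_transform(outcome.transform, out / "transform.json")
    outcome.field.save(out / "displacement_field.mha")
    (out / "qa_report.json").write_text(outcome.qa_report.to_json())
    cfg = cfg or PipelineConfig()
    manifest = {
        "scan_id": outcome.scan_id,
        "larvreg_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": seed if seed is not None else cfg.deformable.seed,
        "selected_path": outcome.global_result.selected_path,
        "warning": outcome.global_result.warning,
        "corrected": outcome.corrected,
        "decision": outcome.qa_report.decision,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
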