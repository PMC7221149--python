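"""End-to-end per-case analysis: register, resample, delineate, overlap.

The clinical order is preserved: the recurrence CT is rigidly registered to
the baseline CT (centres-of-mass initialisation, Mattes mutual
information), the transform is applied to the recurrence PET, the 3-class
segmentation on baseline PET yields VT and V1, the 2-class segmentation on
the resampled recurrence PET yields V2, and the four overlap indices are
computed on the baseline PET grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .flab import FlabOptions, SegmentationResult, flab_segment, roi_seed, select_roi
from .imageio import Image3D
from .overlap import OverlapResult, SuvStats, overlap_metrics, suv_stats
from .phantom import Study
from .registration import (
    RegistrationOptions,
    RigidTransform,
    apply_transform,
    center_of_mass_transform,
    compose,
    register_rigid_mi,
)


@dataclass
class PipelineOptions:
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    flab: FlabOptions = field(default_factory=FlabOptions)
    roi_suv_threshold: float = 2.5
    roi_dilate_voxels: int = 2
    exclude_box: tuple | None = None  # bladder exclusion, baseline-grid indices
    manual_correction: RigidTransform | None = None
    skip_registration: bool = False  # for pre-aligned inputs


@dataclass
class CaseReport:
    transform: RigidTransform
    registration_report: dict
    seg_baseline: SegmentationResult
    seg_recurrence: SegmentationResult
    pet2_resampled: Image3D
    overlap: OverlapResult
    suv_vt: SuvStats
    suv_v1: SuvStats
    suv_v2: SuvStats


def run_case(
    baseline: Study,
    recurrence: Study,
    options: PipelineOptions | None = None,
    case_id: str | None = None,
) -> CaseReport:
    opts = options or PipelineOptions()

    if opts.skip_registration:
        transform = RigidTransform()
        reg_report = {"skipped": True, "success": True}
    else:
        init = center_of_mass_transform(baseline.ct, recurrence.ct)
        transform, reg_report = register_rigid_mi(
            baseline.ct, recurrence.ct, init=init, opts=opts.registration
        )
    if opts.manual_correction is not None:
        transform = compose(opts.manual_correction, transform)

    pet2_res = apply_transform(
        recurrence.pet, transform, baseline.pet, interpolation="linear"
    )

    roi1 = select_roi(
        baseline.pet,
        "auto",
        suv_threshold=opts.roi_suv_threshold,
        dilate_voxels=opts.roi_dilate_voxels,
        exclude_box=opts.exclude_box,
    )
    seed1 = roi_seed(baseline.pet, roi1, exclude_box=opts.exclude_box)
    seg1 = flab_segment(baseline.pet, roi1, K=3, opts=opts.flab, seed_point=seed1)
    roi2 = select_roi(
        pet2_res,
        "auto",
        suv_threshold=opts.roi_suv_threshold,
        dilate_voxels=opts.roi_dilate_voxels,
        exclude_box=opts.exclude_box,
    )
    seed2 = roi_seed(pet2_res, roi2, exclude_box=opts.exclude_box)
    seg2 = flab_segment(pet2_res, roi2, K=2, opts=opts.flab, seed_point=seed2)

    ov = overlap_metrics(seg1.v1_mask, seg2.v2_mask, case_id=case_id)
    return CaseReport(
        transform=transform,
        registration_report=reg_report,
        seg_baseline=seg1,
        seg_recurrence=seg2,
        pet2_resampled=pet2_res,
        overlap=ov,
        suv_vt=suv_stats(baseline.pet, seg1.vt_mask),
        suv_v1=suv_stats(baseline.pet, seg1.v1_mask),
        suv_v2=suv_stats(pet2_res, seg2.v2_mask),
    )


def report_to_dict(report: CaseReport) -> dict:
    d = report.overlap.rounded()
    d["registration"] = {
        k: v for k, v in report.registration_report.items() if not isinstance(v, list)
    }
    d["transform"] = report.transform.to_dict()
    for name, s in (("vt", report.suv_vt), ("v1", report.suv_v1), ("v2", report.suv_v2)):
        d[f"suv_{name}"] = dataclasses.asdict(s)
    d["flab_baseline"] = {
        "class_means": report.seg_baseline.model.class_means.tolist(),
        "class_sds": report.seg_baseline.model.class_sds.tolist(),
        "iterations": report.seg_baseline.model.iterations,
        "converged": report.seg_baseline.model.converged,
    }
    d["flab_recurrence"] = {
        "class_means": report.seg_recurrence.model.class_means.tolist(),
        "class_sds": report.seg_recurrence.model.class_sds.tolist(),
        "iterations": report.seg_recurrence.model.iterations,
        "converged": report.seg_recurrence.model.converged,
    }
    return d
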