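"""Rigid recurrence-to-baseline alignment.

Registration is driven on the CT pair (Mattes mutual information,
multi-resolution) and the resulting transform is then applied to the
corresponding PET, mirroring the clinical workflow in which anatomy carries
the alignment and the functional image is resampled through it.

Transform convention
--------------------
:class:`RigidTransform` stores intrinsic Z-Y-X Euler angles in degrees, a
translation in mm and a rotation centre in mm.  As a point map it sends
*baseline-space* (fixed) physical points to the corresponding
*recurrence-space* (moving) points — exactly the map a resampler needs to
pull the recurrence image onto the baseline grid.  Registering a moved
recurrence study therefore recovers the misalignment that was applied to it.
Manual corrections are modelled as an extra transform composed with the
automatic result (the interactive step of the clinical procedure is not
reproducible; a transform file is).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imageio import Image3D, from_sitk, to_sitk

CONVENTION = "intrinsic-ZYX-degrees"


def _rotation_matrix_zyx(angles_deg: np.ndarray) -> np.ndarray:
    """R = Rz @ Ry @ Rx for angles (rx, ry, rz) in degrees."""
    rx, ry, rz = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_zyx_from_matrix(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_rotation_matrix_zyx`; returns degrees."""
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-9:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock; fold everything into rx
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return np.rad2deg(np.array([rx, ry, rz]))


@dataclass
class RigidTransform:
    """6-parameter rigid map: p -> R (p - c) + c + t."""

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        for name, vec in (
            ("rotation_deg", self.rotation_deg),
            ("translation_mm", self.translation_mm),
            ("center_mm", self.center_mm),
        ):
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{name} must be finite, got {vec}")
        if self.convention != CONVENTION:
            raise ValueError(f"unsupported convention {self.convention!r}")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return _rotation_matrix_zyx(self.rotation_deg)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of the point map."""
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center_mm + self.translation_mm - R @ self.center_mm
        return m

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, center_mm: np.ndarray | None = None
    ) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        R = matrix[:3, :3]
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("matrix is not a proper rotation (det != +1)")
        c = np.zeros(3) if center_mm is None else np.asarray(center_mm, dtype=float)
        t = matrix[:3, 3] - c + R @ c
        return cls(rotation_deg=_euler_zyx_from_matrix(R), translation_mm=t, center_mm=c)

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        R = self.rotation_matrix
        return (pts - self.center_mm) @ R.T + self.center_mm + self.translation_mm

    def inverse(self) -> "RigidTransform":
        inv = np.linalg.inv(self.matrix)
        return RigidTransform.from_matrix(inv, center_mm=self.center_mm)

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "center_mm": self.center_mm.tolist(),
            "convention": self.convention,
            "matrix": self.matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        if "rotation_deg" in d:
            return cls(
                rotation_deg=d["rotation_deg"],
                translation_mm=d["translation_mm"],
                center_mm=d.get("center_mm", (0, 0, 0)),
                convention=d.get("convention", CONVENTION),
            )
        return cls.from_matrix(np.asarray(d["matrix"]), center_mm=d.get("center_mm"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_sitk(self):
        import SimpleITK as sitk

        t = sitk.Euler3DTransform()
        t.SetComputeZYX(True)
        t.SetCenter([float(v) for v in self.center_mm])
        rx, ry, rz = np.deg2rad(self.rotation_deg)
        t.SetRotation(float(rx), float(ry), float(rz))
        t.SetTranslation([float(v) for v in self.translation_mm])
        return t


def compose(correction: RigidTransform, base: RigidTransform) -> RigidTransform:
    """Return correction∘base (apply ``base`` first, then ``correction``)."""
    return RigidTransform.from_matrix(
        correction.matrix @ base.matrix, center_mm=base.center_mm
    )


def center_of_mass_transform(fixed: Image3D, moving: Image3D) -> RigidTransform:
    """Pure translation aligning the intensity centres of mass.

    Intensities are shifted to be non-negative first (CT volumes carry
    negative HU), so the centroid is a proper weighted mean.
    """

    def _com(img: Image3D) -> np.ndarray:
        w = img.values.astype(float) - float(img.values.min())
        total = w.sum()
        if total <= 0:
            raise ValueError("image has zero intensity mass after HU shift")
        idx = np.indices(img.shape, dtype=float).reshape(3, -1).T
        com_idx = (w.reshape(-1, 1) * idx).sum(axis=0) / total
        return img.index_to_world(com_idx)[0]

    com_f = _com(fixed)
    com_m = _com(moving)
    return RigidTransform(
        translation_mm=com_m - com_f,
        center_mm=com_f,
    )


@dataclass
class RegistrationOptions:
    """Settings for the MI rigid registration.

    Defaults are conventional for pelvic CT-CT alignment: 50 histogram
    bins, three resolution levels (shrink 4/2/1) with 2/1/0 mm smoothing,
    regular metric sampling for determinism, regular-step gradient descent.
    """

    histogram_bins: int = 50
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas_mm: tuple[float, ...] = (2.0, 1.0, 0.0)
    sampling_fraction: float = 0.25
    learning_rate: float = 1.0
    min_step: float = 1e-4
    max_iterations: int = 250
    relaxation_factor: float = 0.6
    sampling_seed: int = 20210


def register_rigid_mi(
    fixed_ct: Image3D,
    moving_ct: Image3D,
    init: RigidTransform | None = None,
    opts: RegistrationOptions | None = None,
) -> tuple[RigidTransform, dict]:
    """6-DOF Mattes-MI registration of the moving CT onto the fixed CT.

    Returns the refined transform and a convergence report.  If the final
    metric is worse than the initial one the optimiser is considered
    diverged: the initial transform is returned with ``success=False``.
    """
    import SimpleITK as sitk

    opts = opts or RegistrationOptions()
    if init is None:
        init = center_of_mass_transform(fixed_ct, moving_ct)

    f = to_sitk(fixed_ct)
    m = to_sitk(moving_ct)

    def _method() -> "sitk.ImageRegistrationMethod":
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(
            numberOfHistogramBins=opts.histogram_bins
        )
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(opts.sampling_fraction, opts.sampling_seed)
        reg.SetInterpolator(sitk.sitkLinear)
        return reg

    probe = _method()
    probe.SetInitialTransform(init.to_sitk(), inPlace=False)
    initial_metric = float(probe.MetricEvaluate(f, m))

    reg = _method()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=opts.learning_rate,
        minStep=opts.min_step,
        numberOfIterations=opts.max_iterations,
        relaxationFactor=opts.relaxation_factor,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(opts.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(opts.smoothing_sigmas_mm))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    working = init.to_sitk()
    reg.SetInitialTransform(working, inPlace=True)

    iterations: list[int] = []
    reg.AddCommand(
        sitk.sitkMultiResolutionIterationEvent,
        lambda: iterations.append(reg.GetOptimizerIteration()),
    )
    reg.Execute(f, m)
    final_metric = float(reg.GetMetricValue())

    euler = sitk.Euler3DTransform(working)
    euler.SetComputeZYX(True)
    angles = np.rad2deg([euler.GetAngleX(), euler.GetAngleY(), euler.GetAngleZ()])
    result = RigidTransform(
        rotation_deg=angles,
        translation_mm=np.asarray(euler.GetTranslation()),
        center_mm=np.asarray(euler.GetCenter()),
    )

    success = final_metric <= initial_metric
    report = {
        "initial_metric": initial_metric,
        "final_metric": final_metric,
        "iterations_total": int(reg.GetOptimizerIteration()),
        "iterations_per_level_start": iterations,
        "stop_condition": reg.GetOptimizerStopConditionDescription(),
        "success": bool(success),
    }
    if not success:
        return init, report
    return result, report


def apply_transform(
    img: Image3D,
    t: RigidTransform,
    reference: Image3D,
    interpolation: str = "linear",
    default_value: float | None = None,
) -> Image3D:
    """Resample ``img`` onto ``reference``'s grid through ``t``.

    Binary masks must use nearest-neighbour interpolation (linear would
    manufacture fractional labels).  Out-of-field voxels are filled with
    -1000 for HU images and 0 otherwise, unless overridden.
    """
    import SimpleITK as sitk

    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    from .imageio import _is_binary_mask

    is_mask = _is_binary_mask(img.values)
    if is_mask and interpolation == "linear":
        raise ValueError("binary masks must be resampled with nearest interpolation")
    if default_value is None:
        default_value = -1000.0 if img.units == "HU" else 0.0
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        to_sitk(img), to_sitk(reference), t.to_sitk(), interp, float(default_value)
    )
    res = from_sitk(out, units=img.units)
    if is_mask:
        res = res.copy_with(values=(res.values > 0.5).astype(np.uint8))
    return res


def registration_error(
    truth: RigidTransform,
    estimate: RigidTransform,
    roi_mask: Image3D,
) -> float:
    """Target registration error: mean displacement discrepancy (mm) between
    the true and estimated maps over the ROI voxel centres."""
    mask = np.asarray(roi_mask.values) > 0
    if not mask.any():
        raise ValueError("ROI mask is empty")
    idx = np.argwhere(mask)
    pts = roi_mask.index_to_world(idx)
    return float(
        np.linalg.norm(truth.apply_points(pts) - estimate.apply_points(pts), axis=1).mean()
    )
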