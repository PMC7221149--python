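"""3-D image container, NIfTI-1 I/O and SUV conversion.

All images in this package are carried as :class:`Image3D`: a scalar voxel
array plus its grid geometry (per-axis spacing in mm, world origin in mm and
a 3x3 orthonormal direction matrix) and a unit tag.  World coordinates are
defined by the NIfTI affine ``world = direction @ diag(spacing) @ index +
origin`` with 0-based voxel indices; every inter-image comparison in the
pipeline happens after resampling to the baseline PET grid.

Units are carried in a small JSON sidecar next to each NIfTI file because
NIfTI-1 itself has no standard slot for SUV/HU tagging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

VALID_UNITS = ("SUV", "HU", "Bq_per_mL", "none")


@dataclass
class Image3D:
    """A 3-D scalar volume with voxel-grid geometry and a unit tag."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    units: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Image3D requires a 3-D array, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("Image3D requires a non-empty array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal within 1e-6")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("image values must be finite")

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) world coordinates in mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ (self.direction @ np.diag(self.spacing_mm)).T + np.asarray(
            self.origin_mm
        )

    def same_grid(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "Image3D":
        return Image3D(
            values=values,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            direction=self.direction.copy(),
            units=self.units if units is None else units,
        )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _is_binary_mask(values: np.ndarray) -> bool:
    if values.dtype == bool:
        return True
    uniq = np.unique(values)
    return uniq.size <= 2 and np.all(np.isin(uniq, (0, 1)))


def write_image(img: Image3D, path: str | Path, overwrite: bool = False) -> None:
    """Write an :class:`Image3D` to NIfTI-1 plus a JSON units sidecar.

    Binary masks (values in {0,1}) are stored as unsigned 8-bit; everything
    else as float32.  Refuses to clobber an existing file unless
    ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if _is_binary_mask(img.values):
        data = img.values.astype(np.uint8)
    else:
        data = img.values.astype(np.float32)
    nifti = nib.Nifti1Image(data, img.affine)
    nifti.header.set_zooms(img.spacing_mm)
    nib.save(nifti, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"units": img.units}, indent=2))


def read_image(path: str | Path, units: str | None = None) -> Image3D:
    """Read a 3-D NIfTI-1 image; units come from the sidecar unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    nifti = nib.load(str(path))
    data = np.asanyarray(nifti.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    aff = np.asarray(nifti.affine, dtype=float)
    linear = aff[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate affine (zero-length axis)")
    direction = linear / spacing
    if units is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            units = json.loads(sidecar.read_text()).get("units", "none")
        else:
            units = "none"
    return Image3D(
        values=np.ascontiguousarray(data),
        spacing_mm=tuple(spacing),
        origin_mm=tuple(aff[:3, 3]),
        direction=direction,
        units=units,
    )


def activity_to_suv(
    img: Image3D,
    weight_kg: float,
    injected_mbq: float,
    minutes_post_injection: float,
    half_life_min: float = 109.77,
) -> Image3D:
    """Convert a tracer-concentration image (Bq/mL) to body-weight SUV.

    SUV = concentration [Bq/mL] x body weight [g] / decay-corrected dose
    [Bq], with the injected dose decayed to scan time as
    ``dose x 2^(-t / half_life)``.  The default half-life is that of F-18.
    """
    if img.units != "Bq_per_mL":
        raise ValueError(f"expected a Bq_per_mL image, got units={img.units!r}")
    if weight_kg <= 0 or injected_mbq <= 0 or half_life_min <= 0:
        raise ValueError("weight, injected dose and half-life must be positive")
    if minutes_post_injection < 0:
        raise ValueError("minutes_post_injection must be non-negative")
    decayed_dose_bq = injected_mbq * 1e6 * 2.0 ** (-minutes_post_injection / half_life_min)
    suv = img.values.astype(float) * (weight_kg * 1000.0) / decayed_dose_bq
    return img.copy_with(values=suv, units="SUV")


# -- SimpleITK bridge (used by the registration module) ------------------

def to_sitk(img: Image3D):
    """Convert to a SimpleITK image (float32), preserving grid geometry."""
    import SimpleITK as sitk

    arr = np.transpose(np.asarray(img.values, dtype=np.float32), (2, 1, 0))
    out = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    out.SetSpacing([float(s) for s in img.spacing_mm])
    out.SetOrigin([float(o) for o in img.origin_mm])
    out.SetDirection([float(v) for v in img.direction.ravel()])
    return out


def from_sitk(sitk_img, units: str = "none") -> Image3D:
    import SimpleITK as sitk

    arr = np.transpose(sitk.GetArrayFromImage(sitk_img), (2, 1, 0))
    return Image3D(
        values=np.ascontiguousarray(arr),
        spacing_mm=tuple(sitk_img.GetSpacing()),
        origin_mm=tuple(sitk_img.GetOrigin()),
        direction=np.asarray(sitk_img.GetDirection(), dtype=float).reshape(3, 3),
        units=units,
    )
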