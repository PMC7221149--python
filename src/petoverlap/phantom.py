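"""Seeded generator of paired baseline/recurrence PET/CT pelvic studies.

Each generated case emulates the imaging situation of a cervical tumor
followed from baseline to local recurrence:

* a CT-grid anatomy (body, pelvic bones, bladder, air-filled rectum and a
  soft-tissue tumor bed) whose bladder filling differs between the two time
  points — the classic failure mode of automatic pelvic registration;
* a baseline PET with a heterogeneous tumor: whole metabolic volume VT with
  an interior high-uptake sub-volume V1 (the candidate boost target);
* a recurrence PET with a single recurrent uptake V2 planted so that the
  *true* overlap against V1 hits requested X = |V1∩V2|/|V1| and
  Y = |V1∩V2|/|V2| targets to within ±0.02;
* a known rigid misalignment applied to the recurrence study, so that
  registration accuracy can be scored against ground truth.

PET formation is simplified to an ideal piecewise-constant uptake map
convolved with an isotropic Gaussian point-spread function and corrupted by
intensity-dependent Gaussian noise; there is no sinogram-level simulation.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imageio import Image3D
from .registration import RigidTransform, apply_transform

# CT label codes and the HU value assigned to each
LABELS = {
    "exterior": 0,
    "soft_tissue": 1,
    "bone": 2,
    "bladder": 3,
    "rectum_air": 4,
    "tumor": 5,
}
HU_BY_LABEL = {0: -1000.0, 1: 40.0, 2: 700.0, 3: 10.0, 4: -900.0, 5: 45.0}


@dataclass
class PhantomParams:
    """Generator settings; defaults are calibrated to the study cohort
    (mean VT 41.9 cc, V1 fraction 0.43, V2 15.1 cc, SUVmax ~19.5)."""

    pet_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ct_spacing_mm: tuple[float, float, float] = (1.2, 1.2, 3.0)
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    suv_background: float = 1.0
    suv_tumor_low: float = 6.0
    suv_tumor_high: float = 19.5
    suv_bladder: float = 30.0
    class_sd: tuple[float, float, float] = (0.15, 0.35, 0.35)
    psf_fwhm_mm: float = 6.0
    vt_target_cc: float = 41.9
    v1_fraction: float = 0.43
    v2_target_cc: float = 15.1
    overlap_target_x: float = 0.70
    overlap_target_y: float | None = None  # None -> implied by X and volumes
    misalign_translation_mm: tuple[float, float, float] = (5.0, 3.0, -4.0)
    misalign_rotation_deg: tuple[float, float, float] = (3.0, 0.0, 2.0)
    bladder_fill_delta: float = 0.3
    ct_noise_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.suv_background < self.suv_tumor_low < self.suv_tumor_high):
            raise ValueError("SUV levels must be ordered background < tumor_low < tumor_high")
        if not 0 < self.v1_fraction < 1:
            raise ValueError("v1_fraction must lie in (0, 1)")
        if not 0 <= self.overlap_target_x <= 1:
            raise ValueError("overlap_target_x must lie in [0, 1]")
        if self.overlap_target_y is not None and not 0 <= self.overlap_target_y <= 1:
            raise ValueError("overlap_target_y must lie in [0, 1]")
        if min(self.pet_spacing_mm) <= 0 or min(self.ct_spacing_mm) <= 0:
            raise ValueError("voxel spacings must be strictly positive")
        if self.vt_target_cc <= 0 or self.v2_target_cc <= 0:
            raise ValueError("target volumes must be strictly positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if min(self.grid_shape) < 16:
            raise ValueError("degenerate grid: every axis needs at least 16 voxels")


@dataclass
class Study:
    """One time point: a PET (SUV) and a CT (HU) volume."""

    pet: Image3D
    ct: Image3D


@dataclass
class Ellipsoid:
    center_mm: np.ndarray
    radii_mm: np.ndarray

    def quad(self, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        x, y, z = coords
        c, r = self.center_mm, self.radii_mm
        return (
            ((x - c[0]) / r[0]) ** 2
            + ((y - c[1]) / r[1]) ** 2
            + ((z - c[2]) / r[2]) ** 2
        )

    def contains(self, coords) -> np.ndarray:
        return self.quad(coords) <= 1.0


@dataclass
class Organs:
    """Analytic pelvic geometry, evaluated lazily on any voxel grid."""

    body: Ellipsoid
    bladder: Ellipsoid  # baseline size; scaled per time point
    bones: list[Ellipsoid]
    rectum_center_mm: np.ndarray
    rectum_radius_mm: float
    rectum_half_len_mm: float
    tumor_parts: list[Ellipsoid]
    tumor_level: float  # union-field threshold defining VT in mm space

    def tumor_field(self, coords) -> np.ndarray:
        g = self.tumor_parts[0].quad(coords)
        for e in self.tumor_parts[1:]:
            np.minimum(g, e.quad(coords), out=g)
        return g

    def rectum_mask(self, coords) -> np.ndarray:
        x, y, z = coords
        c = self.rectum_center_mm
        radial = ((x - c[0]) / self.rectum_radius_mm) ** 2 + (
            (y - c[1]) / self.rectum_radius_mm
        ) ** 2
        return (radial <= 1.0) & (np.abs(z - c[2]) <= self.rectum_half_len_mm)


@dataclass
class PhantomTruth:
    """Ground truth of one generated case, all masks on the baseline PET grid."""

    vt_mask: Image3D
    v1_mask: Image3D
    v2_mask: Image3D
    true_transform: RigidTransform
    true_class_means: tuple[float, float, float]
    true_class_sds: tuple[float, float, float]
    achieved_x: float
    achieved_y: float
    achieved_dice: float
    achieved_of: float
    bladder_mask: Image3D | None = None
    body_mask: Image3D | None = None
    organs: Organs | None = None

    def bladder_exclusion_box(self, margin_voxels: int = 1):
        """Index box around the (baseline) bladder, for ROI exclusion."""
        mask = self.bladder_mask.values > 0
        idx = np.argwhere(mask)
        lo = np.maximum(idx.min(axis=0) - margin_voxels, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + margin_voxels, mask.shape)
        return tuple(lo), tuple(hi)


# ----------------------------------------------------------------------
# grids

def _centered_grid(shape, spacing) -> tuple[tuple, tuple]:
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return origin


def pet_grid_coords(params: PhantomParams):
    shape, spacing = params.grid_shape, params.pet_spacing_mm
    origin = _centered_grid(shape, spacing)
    axes = [
        origin[i] + spacing[i] * np.arange(shape[i], dtype=float) for i in range(3)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def ct_grid_shape(params: PhantomParams) -> tuple[int, int, int]:
    fov = [n * s for n, s in zip(params.grid_shape, params.pet_spacing_mm)]
    return tuple(int(round(f / s)) for f, s in zip(fov, params.ct_spacing_mm))


def ct_grid_coords(params: PhantomParams):
    shape = ct_grid_shape(params)
    spacing = params.ct_spacing_mm
    origin = _centered_grid(shape, spacing)
    axes = [
        origin[i] + spacing[i] * np.arange(shape[i], dtype=float) for i in range(3)
    ]
    return shape, np.meshgrid(*axes, indexing="ij", sparse=True)


def _blank_pet_image(params: PhantomParams, values, units="SUV") -> Image3D:
    return Image3D(
        values=values,
        spacing_mm=params.pet_spacing_mm,
        origin_mm=_centered_grid(params.grid_shape, params.pet_spacing_mm),
        units=units,
    )


# ----------------------------------------------------------------------
# organ sampling

def sample_organs(params: PhantomParams, rng: np.random.Generator) -> Organs:
    """Draw the seeded anatomy: jittered organ positions/sizes and the tumor
    as a union of 2-4 overlapping ellipsoids scaled to hit vt_target_cc."""
    fov = np.array([n * s for n, s in zip(params.grid_shape, params.pet_spacing_mm)])
    body = Ellipsoid(
        center_mm=np.zeros(3),
        radii_mm=np.array([0.46, 0.44, 0.49]) * fov * rng.uniform(0.97, 1.0, 3),
    )

    # tumor: union of ellipsoids around the grid centre
    r0 = (3.0 * params.vt_target_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    n_parts = int(rng.integers(2, 5))
    parts = []
    for _ in range(n_parts):
        offset = rng.uniform(-0.35, 0.35, 3) * r0
        radii = r0 * rng.uniform(0.75, 1.1, 3)
        parts.append(Ellipsoid(center_mm=offset, radii_mm=radii))

    coords = pet_grid_coords(params)
    g = parts[0].quad(coords)
    for e in parts[1:]:
        g = np.minimum(g, e.quad(coords))
    n_vt = max(int(round(params.vt_target_cc / _voxvol_cc(params))), 8)
    flat = np.sort(g.ravel())
    if n_vt >= flat.size:
        raise ValueError("vt_target_cc does not fit in the PET grid")
    level = float(flat[n_vt - 1])
    r_t = max(np.linalg.norm(e.center_mm) + e.radii_mm.max() for e in parts)
    r_t *= max(np.sqrt(level), 1.0)

    # bladder anterior to the tumor, sized to fit inside the body outline
    gap = 10.0
    limit = 0.92 * body.radii_mm[1]
    ay = min(26.0, max(12.0, (limit - r_t - gap) / 2.0))
    bladder = Ellipsoid(
        center_mm=np.array([rng.uniform(-5, 5), -(r_t + gap + ay), rng.uniform(-5, 5)]),
        radii_mm=np.array([ay * 1.2, ay, ay * 1.2]) * rng.uniform(0.95, 1.05, 3),
    )

    rr = min(14.0, max(8.0, (limit - r_t - gap) / 2.0))
    rectum_center = np.array([rng.uniform(-4, 4), r_t + gap + rr, 0.0])

    bones = [
        Ellipsoid(
            center_mm=np.array([sign * 0.33 * fov[0], 5.0, 0.0]),
            radii_mm=np.array([0.09 * fov[0], 0.09 * fov[1], 0.3 * fov[2]]),
        )
        for sign in (-1.0, 1.0)
    ]
    return Organs(
        body=body,
        bladder=bladder,
        bones=bones,
        rectum_center_mm=rectum_center,
        rectum_radius_mm=rr,
        rectum_half_len_mm=0.35 * fov[2],
        tumor_parts=parts,
        tumor_level=level,
    )


def _voxvol_cc(params: PhantomParams) -> float:
    return float(np.prod(params.pet_spacing_mm)) / 1000.0


def _scaled_bladder(organs: Organs, fill_scale: float) -> Ellipsoid:
    return Ellipsoid(
        center_mm=organs.bladder.center_mm,
        radii_mm=organs.bladder.radii_mm * fill_scale ** (1.0 / 3.0),
    )


# ----------------------------------------------------------------------
# anatomy and PET synthesis

def build_anatomy(
    params: PhantomParams,
    seed: int,
    bladder_scale: float = 1.0,
    organs: Organs | None = None,
) -> tuple[Image3D, Image3D, Organs]:
    """Build the CT-grid labelled anatomy and its HU rendering.

    Returns ``(labels, hu, organs)``.  ``bladder_scale`` multiplies the
    bladder *volume* (filling state); everything else is shared between
    time points.
    """
    if min(params.grid_shape) < 16:
        raise ValueError("degenerate grid: every axis needs at least 16 voxels")
    if organs is None:
        organs = sample_organs(params, np.random.default_rng(seed))
    shape, coords = ct_grid_coords(params)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[organs.body.contains(coords)] = LABELS["soft_tissue"]
    for bone in organs.bones:
        labels[bone.contains(coords)] = LABELS["bone"]
    labels[_scaled_bladder(organs, bladder_scale).contains(coords)] = LABELS["bladder"]
    labels[organs.rectum_mask(coords)] = LABELS["rectum_air"]
    labels[organs.tumor_field(coords) <= organs.tumor_level] = LABELS["tumor"]

    hu = np.empty(shape, dtype=np.float32)
    for code, value in HU_BY_LABEL.items():
        hu[labels == code] = value
    origin = _centered_grid(shape, params.ct_spacing_mm)
    labels_img = Image3D(labels, params.ct_spacing_mm, origin, units="none")
    hu_img = Image3D(hu, params.ct_spacing_mm, origin, units="HU")
    return labels_img, hu_img, organs


def ideal_uptake(
    organs: Organs,
    truth_masks: dict[str, np.ndarray],
    params: PhantomParams,
    timepoint: str = "baseline",
    bladder_scale: float = 1.0,
) -> tuple[Image3D, Image3D]:
    """Piecewise-constant uptake map plus the per-voxel noise-class SD map.

    ``truth_masks`` holds ``vt``/``v1`` (baseline) or ``v2`` (recurrence)
    boolean arrays on the PET grid."""
    coords = pet_grid_coords(params)
    body = organs.body.contains(coords)
    bladder = _scaled_bladder(organs, bladder_scale).contains(coords)

    ideal = np.where(body, params.suv_background, 0.0)
    sd_class = np.zeros(params.grid_shape, dtype=float)
    sd_class[body] = params.class_sd[0]
    if timepoint == "baseline":
        vt = np.asarray(truth_masks["vt"], bool)
        v1 = np.asarray(truth_masks["v1"], bool)
        ideal[vt] = params.suv_tumor_low
        ideal[v1] = params.suv_tumor_high
        sd_class[vt] = params.class_sd[1]
        sd_class[v1] = params.class_sd[2]
    elif timepoint == "recurrence":
        v2 = np.asarray(truth_masks["v2"], bool)
        ideal[v2] = params.suv_tumor_high
        sd_class[v2] = params.class_sd[2]
    else:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    ideal[bladder] = params.suv_bladder
    sd_class[bladder] = params.class_sd[0]
    return (
        _blank_pet_image(params, ideal),
        _blank_pet_image(params, sd_class, units="none"),
    )


def degrade_pet(
    ideal: Image3D,
    sd_class: Image3D,
    params: PhantomParams,
    seed: int,
    noise_scale: float = 1.0,
) -> Image3D:
    """Apply the acquisition model: isotropic Gaussian PSF, then zero-mean
    Gaussian noise with SD = class SD x sqrt(local blurred uptake /
    background uptake), clipped at zero.  A PSF FWHM of exactly 0 disables
    blurring (the noise-free, blur-free limit reproduces the ideal map)."""
    if params.psf_fwhm_mm < 0:
        raise ValueError("PSF FWHM must be non-negative")
    if params.psf_fwhm_mm > 0:
        sigma_vox = [
            params.psf_fwhm_mm / 2.354820045 / s for s in ideal.spacing_mm
        ]
        blurred = ndimage.gaussian_filter(np.asarray(ideal.values, float), sigma=sigma_vox)
    else:
        blurred = np.asarray(ideal.values, float)
    sd = (
        noise_scale
        * np.asarray(sd_class.values, float)
        * np.sqrt(np.maximum(blurred, 0.0) / params.suv_background)
    )
    rng = np.random.default_rng(seed)
    noisy = blurred + rng.normal(0.0, 1.0, blurred.shape) * sd
    return ideal.copy_with(np.maximum(noisy, 0.0).astype(np.float32), units="SUV")


def synthesize_pet(
    organs: Organs,
    truth_masks: dict[str, np.ndarray],
    params: PhantomParams,
    seed: int,
    timepoint: str = "baseline",
    bladder_scale: float = 1.0,
    noise_scale: float = 1.0,
) -> Image3D:
    """Form a PET (SUV) image: piecewise-constant uptake -> Gaussian PSF ->
    intensity-dependent Gaussian noise -> clip at zero."""
    ideal, sd_class = ideal_uptake(organs, truth_masks, params, timepoint, bladder_scale)
    return degrade_pet(ideal, sd_class, params, seed, noise_scale)


# ----------------------------------------------------------------------
# tumor masks and recurrence planting

def tumor_truth_masks(
    params: PhantomParams, organs: Organs, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """VT and its interior high-uptake sub-volume V1 on the PET grid.

    V1 is the ``v1_fraction`` of VT voxels nearest an interior anchor, so it
    is a compact blob strictly inside VT (as a voxel set)."""
    coords = pet_grid_coords(params)
    g = organs.tumor_field(coords)
    vt = g <= organs.tumor_level
    n_vt = int(vt.sum())
    if n_vt == 0:
        raise ValueError("empty tumor mask; vt_target_cc too small for the grid")
    vox = np.argwhere(vt)
    world = vox * np.asarray(params.pet_spacing_mm) + np.asarray(
        _centered_grid(params.grid_shape, params.pet_spacing_mm)
    )
    centroid = world.mean(axis=0)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    proj = (world - centroid) @ u
    anchor = centroid + u * 0.5 * proj.max()
    n_v1 = max(int(round(params.v1_fraction * n_vt)), 1)
    order = np.argsort(np.linalg.norm(world - anchor, axis=1), kind="stable")
    v1 = np.zeros_like(vt)
    sel = vox[order[:n_v1]]
    v1[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return vt, v1


def plant_recurrence(
    v1: np.ndarray,
    params: PhantomParams,
    organs: Organs,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Place the recurrence volume V2 so the true overlap hits the targets.

    V2 is assembled from the requested voxel counts directly: the
    intersection part is the ``round(X*|V1|)`` voxels of V1 nearest a
    boundary anchor, the remainder the nearest admissible voxels outside V1
    (inside the body, away from bladder and rectum).  Achieved X and Y are
    exact up to rounding; an inconsistent (X, Y, v2_target_cc) request is
    rejected.
    """
    v1 = np.asarray(v1, bool)
    n_v1 = int(v1.sum())
    if n_v1 == 0:
        raise ValueError("v1 mask is empty")
    voxvol = _voxvol_cc(params)
    n_v2 = max(int(round(params.v2_target_cc / voxvol)), 1)
    x_t, y_t = params.overlap_target_x, params.overlap_target_y

    n_int = int(round(x_t * n_v1))
    if n_int > n_v2:
        if y_t is None:
            raise ValueError(
                f"infeasible overlap request: X*|V1| = {n_int} voxels exceeds "
                f"|V2| = {n_v2} voxels (raise v2_target_cc or lower X)"
            )
    if y_t is not None:
        if abs(n_int / n_v2 - y_t) > 0.02:
            alt = int(round(y_t * n_v2))
            if alt <= n_v1 and abs(alt / n_v1 - x_t) <= 0.02:
                n_int = alt
            else:
                raise ValueError(
                    "infeasible overlap request: targets X="
                    f"{x_t}, Y={y_t} are inconsistent with |V1|={n_v1} and "
                    f"|V2|={n_v2} voxels (Y must be close to X*|V1|/|V2|)"
                )
    n_int = min(n_int, n_v1, n_v2)

    spacing = np.asarray(params.pet_spacing_mm)
    origin = np.asarray(_centered_grid(params.grid_shape, params.pet_spacing_mm))
    vox_v1 = np.argwhere(v1)
    world_v1 = vox_v1 * spacing + origin
    c1 = world_v1.mean(axis=0)
    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    boundary_reach = ((world_v1 - c1) @ w).max()
    anchor = c1 + w * boundary_reach
    if n_int == 0:
        # disjoint but adjacent: V2 grows against a one-voxel clearance
        # shell around V1, the regime where spurious overlap estimates arise
        anchor = anchor + w * float(max(spacing))

    v2 = np.zeros_like(v1)
    if n_int > 0:
        order = np.argsort(np.linalg.norm(world_v1 - anchor, axis=1), kind="stable")
        sel = vox_v1[order[:n_int]]
        v2[sel[:, 0], sel[:, 1], sel[:, 2]] = True

    n_out = n_v2 - n_int
    if n_out > 0:
        coords = pet_grid_coords(params)
        allowed = organs.body.contains(coords)
        allowed &= ~_scaled_bladder(organs, 1.0 + abs(params.bladder_fill_delta)).contains(
            coords
        )
        allowed &= ~organs.rectum_mask(coords)
        if n_int == 0:
            allowed &= ~ndimage.binary_dilation(v1, iterations=1)
        else:
            allowed &= ~v1
        vox_out = np.argwhere(allowed)
        if vox_out.shape[0] < n_out:
            raise ValueError("v2_target_cc does not fit in the admissible region")
        world_out = vox_out * spacing + origin
        order = np.argsort(np.linalg.norm(world_out - anchor, axis=1), kind="stable")
        sel = vox_out[order[:n_out]]
        v2[sel[:, 0], sel[:, 1], sel[:, 2]] = True

    inter = int((v1 & v2).sum())
    ach = {
        "x": inter / n_v1,
        "y": inter / n_v2,
        "dice": 2.0 * inter / (n_v1 + n_v2),
        "of": inter / min(n_v1, n_v2),
    }
    if abs(ach["x"] - x_t) > 0.02:
        raise ValueError(
            f"achieved X={ach['x']:.3f} misses target {x_t:.3f} by more than 0.02"
        )
    if y_t is not None and abs(ach["y"] - y_t) > 0.02:
        raise ValueError(
            f"achieved Y={ach['y']:.3f} misses target {y_t:.3f} by more than 0.02"
        )
    return v2, ach


def misalign(study: Study, true_transform: RigidTransform) -> Study:
    """Resample a recurrence study through the inverse of ``true_transform``
    so that registering it back to baseline should recover the transform."""
    inv = true_transform.inverse()
    return Study(
        pet=apply_transform(study.pet, inv, study.pet, interpolation="linear"),
        ct=apply_transform(study.ct, inv, study.ct, interpolation="linear"),
    )


# ----------------------------------------------------------------------
# case and cohort generation

def generate_case(
    params: PhantomParams, seed: int | None = None
) -> tuple[Study, Study, PhantomTruth]:
    """Generate one paired baseline/recurrence study with full ground truth."""
    master = np.random.default_rng(params.seed if seed is None else seed)
    s_organ, s_plant, s_pet1, s_pet2, s_ct1, s_ct2 = (
        int(v) for v in master.integers(0, 2**31 - 1, size=6)
    )

    rng_organ = np.random.default_rng(s_organ)
    organs = sample_organs(params, rng_organ)
    vt, v1 = tumor_truth_masks(params, organs, rng_organ)
    v2, ach = plant_recurrence(v1, params, organs, np.random.default_rng(s_plant))

    fill_scale = 1.0 + params.bladder_fill_delta
    _, hu1, _ = build_anatomy(params, 0, bladder_scale=1.0, organs=organs)
    _, hu2, _ = build_anatomy(params, 0, bladder_scale=fill_scale, organs=organs)

    def _ct_with_noise(hu: Image3D, s: int) -> Image3D:
        rng = np.random.default_rng(s)
        noisy = hu.values + rng.normal(0, params.ct_noise_hu, hu.shape).astype(
            np.float32
        )
        return hu.copy_with(values=noisy)

    pet1 = synthesize_pet(organs, {"vt": vt, "v1": v1}, params, s_pet1, "baseline")
    baseline = Study(pet=pet1, ct=_ct_with_noise(hu1, s_ct1))

    # The patient is repositioned *before* acquisition, so the misalignment
    # is applied to the ideal recurrence content and the PSF/noise are
    # applied afterwards, in the (misaligned) scanner frame.
    ideal2, sd2 = ideal_uptake(
        organs, {"v2": v2}, params, "recurrence", bladder_scale=fill_scale
    )
    true_t = RigidTransform(
        rotation_deg=params.misalign_rotation_deg,
        translation_mm=params.misalign_translation_mm,
        center_mm=(0.0, 0.0, 0.0),
    )
    moved_ideal = misalign(Study(pet=ideal2, ct=hu2), true_t)
    moved_sd2 = apply_transform(sd2, true_t.inverse(), sd2, interpolation="nearest")
    moved = Study(
        pet=degrade_pet(moved_ideal.pet, moved_sd2, params, s_pet2),
        ct=_ct_with_noise(moved_ideal.ct, s_ct2),
    )

    coords = pet_grid_coords(params)
    bladder_pet = _scaled_bladder(organs, 1.0).contains(coords)
    body_pet = organs.body.contains(coords)

    def _mask_img(m):
        return _blank_pet_image(params, m.astype(np.uint8), units="none")

    truth = PhantomTruth(
        vt_mask=_mask_img(vt),
        v1_mask=_mask_img(v1),
        v2_mask=_mask_img(v2),
        true_transform=true_t,
        true_class_means=(
            params.suv_background,
            params.suv_tumor_low,
            params.suv_tumor_high,
        ),
        true_class_sds=tuple(
            params.class_sd[i]
            * float(
                np.sqrt(
                    (params.suv_background, params.suv_tumor_low, params.suv_tumor_high)[i]
                    / params.suv_background
                )
            )
            for i in range(3)
        ),
        achieved_x=ach["x"],
        achieved_y=ach["y"],
        achieved_dice=ach["dice"],
        achieved_of=ach["of"],
        bladder_mask=_mask_img(bladder_pet),
        body_mask=_mask_img(body_pet),
        organs=organs,
    )
    assert not (v1 & ~vt).any(), "ground-truth V1 escaped VT"
    assert vt.any() and v1.any() and v2.any(), "empty ground-truth mask"
    return baseline, moved, truth


@dataclass
class CohortParams:
    """Per-case parameter distributions for a synthetic patient cohort.

    Volumes are log-normal with moments matched to the cohort statistics
    (positive support, heavy right tail); the V2>V1 subgroup is allocated
    deterministically at ``round(v2_gt_v1_fraction * n)`` cases so the
    subgroup size is reproducible.
    """

    base: PhantomParams = field(default_factory=PhantomParams)
    vt_mean_cc: float = 41.9
    vt_sd_cc: float = 31.6
    v1_fraction_mean: float = 0.43
    v1_fraction_sd: float = 0.08
    v2_mean_cc: float = 15.1
    v2_sd_cc: float = 13.5
    v2_gt_v1_fraction: float = 1.0 / 3.0
    x_range: tuple[float, float] = (0.55, 0.9)
    suvmax_mean: float = 19.5
    suvmax_sd: float = 7.4
    max_translation_mm: float = 8.0
    max_rotation_deg: float = 5.0
    bladder_fill_range: tuple[float, float] = (0.0, 0.5)


def _lognormal(rng, mean, sd, lo, hi) -> float:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), lo, hi))


def generate_cohort(
    n: int, cohort_params: CohortParams | None = None, seed: int = 0
) -> tuple[list[PhantomParams], dict]:
    """Draw per-case phantom parameters for an ``n``-patient cohort.

    Returns the list of per-case :class:`PhantomParams` (each carrying its
    own sub-seed) and a manifest recording every draw, including which cases
    are planted with V2 > V1.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    cp = cohort_params or CohortParams()
    rng = np.random.default_rng(seed)

    n_flag = int(round(cp.v2_gt_v1_fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[:n_flag] = True
    rng.shuffle(flags)

    cases: list[PhantomParams] = []
    records = []
    for i in range(n):
        vt = _lognormal(rng, cp.vt_mean_cc, cp.vt_sd_cc, 8.0, 120.0)
        v1f = float(np.clip(rng.normal(cp.v1_fraction_mean, cp.v1_fraction_sd), 0.25, 0.65))
        v1cc = v1f * vt
        if flags[i]:
            v2 = v1cc * rng.uniform(1.1, 1.8)
        else:
            v2 = _lognormal(rng, cp.v2_mean_cc, cp.v2_sd_cc, 2.0, 0.95 * v1cc)
        x = rng.uniform(*cp.x_range)
        x = min(x, 0.95 * v2 / v1cc) if v2 < v1cc else x
        suv_high = float(
            np.clip(rng.normal(cp.suvmax_mean, cp.suvmax_sd), cp.base.suv_tumor_low + 4.0, 45.0)
        )
        case = dataclasses.replace(
            cp.base,
            vt_target_cc=vt,
            v1_fraction=v1f,
            v2_target_cc=v2,
            overlap_target_x=x,
            overlap_target_y=None,
            suv_tumor_high=suv_high,
            misalign_translation_mm=tuple(
                rng.uniform(-cp.max_translation_mm, cp.max_translation_mm, 3)
            ),
            misalign_rotation_deg=tuple(
                rng.uniform(-cp.max_rotation_deg, cp.max_rotation_deg, 3)
            ),
            bladder_fill_delta=float(rng.uniform(*cp.bladder_fill_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(case)
        records.append(
            {
                "case_id": f"case_{i:03d}",
                "seed": case.seed,
                "v2_gt_v1_planted": bool(flags[i]),
                "params": _params_to_jsonable(case),
            }
        )
    manifest = {"n": n, "seed": seed, "cases": records}
    return cases, manifest


def _params_to_jsonable(p: PhantomParams) -> dict:
    d = dataclasses.asdict(p)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_case(
    out_dir: str | Path,
    baseline: Study,
    recurrence: Study,
    truth: PhantomTruth,
    overwrite: bool = False,
) -> None:
    """Write a case as NIfTI images + masks, transform and truth JSON."""
    from .imageio import write_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(baseline.pet, out / "pet1.nii.gz", overwrite=overwrite)
    write_image(baseline.ct, out / "ct1.nii.gz", overwrite=overwrite)
    write_image(recurrence.pet, out / "pet2.nii.gz", overwrite=overwrite)
    write_image(recurrence.ct, out / "ct2.nii.gz", overwrite=overwrite)
    for name in ("vt_mask", "v1_mask", "v2_mask"):
        write_image(getattr(truth, name), out / f"{name}.nii.gz", overwrite=overwrite)
    truth.true_transform.save(out / "true_transform.json")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "true_class_means": list(truth.true_class_means),
                "true_class_sds": list(truth.true_class_sds),
                "achieved_x": truth.achieved_x,
                "achieved_y": truth.achieved_y,
                "achieved_dice": truth.achieved_dice,
                "achieved_of": truth.achieved_of,
            },
            indent=2,
        )
    )
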