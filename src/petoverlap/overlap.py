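"""Spatial overlap quantification between the baseline high-uptake
sub-volume V1 and the recurrence volume V2.

Four indices, all on [0, 1] and computed by voxel-count set arithmetic on
the baseline PET grid:

    Dice = 2|V1∩V2| / (|V1|+|V2|)       OF = |V1∩V2| / min(|V1|,|V2|)
    X    = |V1∩V2| / |V1|               Y  = |V1∩V2| / |V2|

Identities: OF = max(X, Y) and Dice is the harmonic mean of X and Y.
Values are banded into concordance categories after rounding to two
decimals (the banding grid is itself two-decimal, so rounding closes the
gap between e.g. 0.20 and 0.21).  Cases where the recurrence volume exceeds
the baseline sub-volume (V2 > V1) are flagged: there the overlap analysis
loses its meaning — V2 can swallow V1 entirely and the boost-volume logic
inverts — so cohort summaries are reported with and without them.

Jaccard is deliberately omitted: it ranks cases identically to Dice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageio import Image3D

CONCORDANCE_BANDS = (
    (0.20, "very low"),
    (0.40, "low"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)

METRICS = ("dice", "of", "x", "y")


def classify_concordance(value: float) -> str:
    """Concordance band of an overlap index, after 2-decimal rounding."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"overlap index must lie in [0, 1], got {value}")
    r = round(float(value), 2)
    for upper, name in CONCORDANCE_BANDS:
        if r <= upper + 1e-12:
            return name
    raise AssertionError("unreachable")


@dataclass
class OverlapResult:
    """Volumes, the four overlap indices, their bands and the V2>V1 flag."""

    vol_v1_cc: float
    vol_v2_cc: float
    vol_intersection_cc: float
    dice: float
    of: float
    x: float
    y: float
    band_per_metric: dict[str, str]
    v2_gt_v1: bool
    case_id: str | None = None

    def rounded(self) -> dict:
        """Reporting view: indices to 2 decimals, volumes to 0.1 cc."""
        return {
            "case_id": self.case_id,
            "vol_v1_cc": round(self.vol_v1_cc, 1),
            "vol_v2_cc": round(self.vol_v2_cc, 1),
            "vol_intersection_cc": round(self.vol_intersection_cc, 1),
            "dice": round(self.dice, 2),
            "of": round(self.of, 2),
            "x": round(self.x, 2),
            "y": round(self.y, 2),
            "v2_gt_v1": self.v2_gt_v1,
            **{f"band_{m}": b for m, b in self.band_per_metric.items()},
        }


@dataclass
class SuvStats:
    suv_max: float
    suv_mean: float
    tlg_g: float


def _mask_array(mask, other=None) -> tuple[np.ndarray, float]:
    """Accept Image3D or ndarray; return boolean array + voxel volume (cc)."""
    if isinstance(mask, Image3D):
        return np.asarray(mask.values) > 0, mask.voxel_volume_cc
    return np.asarray(mask) > 0, float("nan")


def overlap_metrics(
    v1_mask,
    v2_mask,
    spacing_mm: tuple[float, float, float] | None = None,
    case_id: str | None = None,
) -> OverlapResult:
    """Compute the four overlap indices between two binary masks.

    Masks may be :class:`Image3D` (grids must match) or raw arrays with an
    explicit ``spacing_mm``.  Both masks must be non-empty — the overlap
    fraction is undefined otherwise.
    """
    if isinstance(v1_mask, Image3D) and isinstance(v2_mask, Image3D):
        if not v1_mask.same_grid(v2_mask):
            raise ValueError("masks live on different grids; resample first")
        spacing_mm = v1_mask.spacing_mm
        a = np.asarray(v1_mask.values) > 0
        b = np.asarray(v2_mask.values) > 0
    else:
        if spacing_mm is None:
            raise ValueError("spacing_mm is required for raw-array masks")
        a = np.asarray(v1_mask) > 0
        b = np.asarray(v2_mask) > 0
        if a.shape != b.shape:
            raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("overlap indices are undefined for an empty mask")
    ni = int((a & b).sum())
    voxvol = float(np.prod(spacing_mm)) / 1000.0
    x = ni / na
    y = ni / nb
    dice = 2.0 * ni / (na + nb)
    of = ni / min(na, nb)
    return OverlapResult(
        vol_v1_cc=na * voxvol,
        vol_v2_cc=nb * voxvol,
        vol_intersection_cc=ni * voxvol,
        dice=dice,
        of=of,
        x=x,
        y=y,
        band_per_metric={m: classify_concordance(v) for m, v in
                         zip(METRICS, (dice, of, x, y))},
        v2_gt_v1=nb > na,
        case_id=case_id,
    )


def suv_stats(img: Image3D, mask) -> SuvStats:
    """SUVmax, SUVmean and total lesion glycolysis over a masked volume.

    TLG = SUVmean x volume(cc), reported in grams (SUV is dimensionless and
    tissue density is taken as 1 g/mL)."""
    if img.units != "SUV":
        raise ValueError(f"suv_stats expects an SUV image, got {img.units!r}")
    m, _ = _mask_array(mask)
    if isinstance(mask, Image3D) and not img.same_grid(mask):
        raise ValueError("image and mask live on different grids")
    if m.shape != img.shape:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("empty mask")
    vals = img.values[m]
    vol_cc = int(m.sum()) * img.voxel_volume_cc
    mean = float(vals.mean())
    return SuvStats(suv_max=float(vals.max()), suv_mean=mean, tlg_g=mean * vol_cc)


# ----------------------------------------------------------------------
# cohort summaries

def results_table(results: list[OverlapResult]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        d = dataclasses.asdict(r)
        bands = d.pop("band_per_metric")
        d.update({f"band_{m}": b for m, b in bands.items()})
        if d.get("case_id") is None:
            d["case_id"] = f"case_{i:03d}"
        rows.append(d)
    return pd.DataFrame(rows)


def summarize_cohort(
    results: list[OverlapResult], exclude_v2_gt_v1: bool = False
) -> pd.DataFrame:
    """Per-metric median/min/max/mean/SD over a cohort.

    With ``exclude_v2_gt_v1`` the flagged cases are removed before
    summarising (the restricted analysis where overlap stays meaningful)."""
    if not results:
        raise ValueError("no results to summarize")
    use = [r for r in results if not (exclude_v2_gt_v1 and r.v2_gt_v1)]
    if not use:
        raise ValueError("no cases left after excluding V2>V1")
    rows = []
    for m in METRICS:
        vals = np.sort([getattr(r, m) for r in use])  # order-invariant stats
        rows.append(
            {
                "metric": m,
                "n": len(use),
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(use) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def cohort_summaries(results: list[OverlapResult]) -> dict[str, pd.DataFrame]:
    """The three subgroup views: all cases, V2<=V1 only, V2>V1 only."""
    out = {"all": summarize_cohort(results, exclude_v2_gt_v1=False)}
    kept = [r for r in results if not r.v2_gt_v1]
    flagged = [r for r in results if r.v2_gt_v1]
    if kept:
        out["v2_le_v1"] = summarize_cohort(kept)
    if flagged:
        out["v2_gt_v1"] = summarize_cohort(flagged)
    return out


# ----------------------------------------------------------------------
# threshold-bias experiment

DEFAULT_STRATA = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))


def bias_experiment(
    cohort_params=None,
    methods: tuple[str, ...] = ("oracle", "flab", "threshold:40/40", "threshold:70/40"),
    seed: int = 0,
    strata: tuple[float, ...] = DEFAULT_STRATA,
    cases_per_stratum: int = 4,
) -> pd.DataFrame:
    """Quantify delineation-induced overlap bias across true-overlap strata.

    For each true Dice level a phantom pair is generated with X = Y = Dice
    (so |V2| = |V1|) and *no* misalignment, isolating segmentation bias from
    registration error.  Each method delineates V1 and V2 and the
    estimated-minus-true error of every index is recorded.  ``oracle`` uses
    the ground-truth masks (a zero-bias sanity row); ``flab`` the 3-class /
    2-class fuzzy Bayesian pipeline; ``threshold:P1/P2`` fixed %SUVmax
    thresholds for V1 and V2 respectively.

    Returns a tidy table: one row per (method, stratum) with mean signed and
    mean absolute error per index.
    """
    from . import phantom as ph
    from .flab import flab_segment, roi_seed, select_roi, threshold_segment

    for m in methods:
        if m not in ("oracle", "flab") and not m.startswith("threshold:"):
            raise ValueError(f"unknown method {m!r}")

    cp = cohort_params or ph.CohortParams()
    rng = np.random.default_rng(seed)
    records = []
    for d in strata:
        for rep in range(cases_per_stratum):
            base = cp.base
            vt_cc = base.vt_target_cc
            v1_cc = base.v1_fraction * vt_cc
            params = dataclasses.replace(
                base,
                overlap_target_x=float(d),
                overlap_target_y=float(d),
                v2_target_cc=v1_cc,  # |V2| = |V1| so X = Y = Dice
                misalign_translation_mm=(0.0, 0.0, 0.0),
                misalign_rotation_deg=(0.0, 0.0, 0.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            baseline, recurrence, truth = ph.generate_case(params)
            true_ov = overlap_metrics(truth.v1_mask, truth.v2_mask)
            excl = truth.bladder_exclusion_box()
            for method in methods:
                v1_est, v2_est = _delineate(
                    method, baseline.pet, recurrence.pet, truth, excl,
                    flab_segment, select_roi, threshold_segment, roi_seed,
                )
                est = overlap_metrics(v1_est, v2_est)
                rec = {"method": method, "true_dice": float(d), "rep": rep}
                for m in METRICS:
                    rec[f"err_{m}"] = getattr(est, m) - getattr(true_ov, m)
                records.append(rec)
    raw = pd.DataFrame(records)
    agg = raw.groupby(["method", "true_dice"], as_index=False).agg(
        **{
            **{f"mean_signed_err_{m}": (f"err_{m}", "mean") for m in METRICS},
            **{f"mean_abs_err_{m}": (f"err_{m}", lambda s: s.abs().mean()) for m in METRICS},
            "n": ("rep", "size"),
        }
    )
    return agg


def _delineate(method, pet1, pet2, truth, excl, flab_segment, select_roi,
               threshold_segment, roi_seed):
    if method == "oracle":
        return truth.v1_mask, truth.v2_mask
    roi1 = select_roi(pet1, "auto", exclude_box=excl)
    roi2 = select_roi(pet2, "auto", exclude_box=excl)
    seed1 = roi_seed(pet1, roi1, exclude_box=excl)
    seed2 = roi_seed(pet2, roi2, exclude_box=excl)
    if method == "flab":
        seg1 = flab_segment(pet1, roi1, K=3, seed_point=seed1)
        seg2 = flab_segment(pet2, roi2, K=2, seed_point=seed2)
        return seg1.v1_mask, seg2.v2_mask
    pcts = method.split(":", 1)[1]
    p1, p2 = (float(v) for v in pcts.split("/"))
    return (threshold_segment(pet1, roi1, p1, seed_point=seed1),
            threshold_segment(pet2, roi2, p2, seed_point=seed2))
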