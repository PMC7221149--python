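"""Fuzzy locally adaptive Bayesian (FLAB-style) PET tumor delineation.

The observation model inside a tumor-bearing box ROI is a finite mixture of
K hard tissue classes (K=3 on baseline PET: background, lower-uptake tumor,
high-uptake sub-volume; K=2 on recurrence PET: background, tumor) augmented
with *fuzzy* transition labels between each adjacent class pair.  A fuzzy
label at level eps in (0,1) models a partial-volume voxel as

    y ~ Normal((1-eps)*mu_k + eps*mu_{k+1},  (1-eps)^2 sigma_k^2 + eps^2 sigma_{k+1}^2)

The *locally adaptive* prior blends each voxel's neighbourhood posterior
mass (3x3x3 mean) with the global label frequencies, so spatially coherent
regions reinforce themselves while isolated noise voxels are suppressed.

Estimation is a deterministic EM-style iteration (posterior -> moment
update -> prior re-estimation), with a deterministic quantile
initialisation; identical inputs always produce identical labels.  The
3-class run simultaneously yields the whole tumor volume VT and the
high-uptake sub-volume V1; the 2-class run yields the recurrence volume V2.
A fixed %SUVmax threshold comparator is included because it is the
historical alternative whose overlap bias this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .imageio import Image3D

FUZZY_LEVELS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class BoxROI:
    """Half-open index box ``[lo, hi)`` on an image grid."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(h - l < 3 for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"ROI must span at least 3 voxels per axis, got {self}")
        if any(l < 0 for l in self.lo):
            raise ValueError("ROI lower corner must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains_mask(self, mask: np.ndarray) -> bool:
        outside = np.asarray(mask, bool).copy()
        outside[self.slices] = False
        return not outside.any()


@dataclass
class FlabModel:
    """Fitted mixture: hard class parameters plus the fuzzy label grid."""

    n_classes: int
    fuzzy_levels: tuple[float, ...]
    class_means: np.ndarray
    class_sds: np.ndarray
    labels: list[tuple[int, float]]  # (lower class k, eps); eps=0 -> hard k
    iterations: int
    final_rel_change: float
    converged: bool

    def __post_init__(self):
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.class_sds = np.asarray(self.class_sds, dtype=float)
        if not np.all(np.diff(self.class_means) > 0):
            raise ValueError(f"class means must be strictly ascending: {self.class_means}")
        if np.any(self.class_sds <= 0):
            raise ValueError("class SDs must be positive")


@dataclass
class SegmentationResult:
    """Labels on the full grid plus the derived binary masks."""

    label_volume: np.ndarray  # int label index per voxel; -1 outside ROI
    model: FlabModel
    roi: BoxROI
    responsibilities: np.ndarray | None = None  # ROI-box (..., K) class posteriors
    vt_mask: Image3D | None = None
    v1_mask: Image3D | None = None
    v2_mask: Image3D | None = None
    warning: str | None = None


@dataclass
class FlabOptions:
    fuzzy_levels: tuple[float, ...] = FUZZY_LEVELS
    max_iter: int = 100
    tol: float = 1e-3
    lambda_global: float = 0.1
    min_class_voxels: int = 10
    fuzzy_cut: float = 0.5  # fuzzy voxels at eps >= cut join the upper mask


def _label_set(K: int, fuzzy_levels) -> list[tuple[int, float]]:
    labels: list[tuple[int, float]] = []
    for k in range(K - 1):
        labels.append((k, 0.0))
        labels.extend((k, eps) for eps in fuzzy_levels)
    labels.append((K - 1, 0.0))
    return labels


def _label_weights(labels: list[tuple[int, float]], K: int) -> np.ndarray:
    """L x K matrix: fuzzy label (k, eps) weighs (1-eps) on k and eps on k+1."""
    A = np.zeros((len(labels), K))
    for l, (k, eps) in enumerate(labels):
        if eps == 0.0:
            A[l, k] = 1.0
        else:
            A[l, k] = 1.0 - eps
            A[l, k + 1] = eps
    return A


def label_density(
    y: np.ndarray | float, label: tuple[int, float], model: FlabModel
) -> np.ndarray | float:
    """Gaussian density of observation(s) ``y`` under one (possibly fuzzy)
    label of a fitted model."""
    k, eps = label
    mu, sd = model.class_means, model.class_sds
    if eps == 0.0:
        m, v = mu[k], sd[k] ** 2
    else:
        m = (1.0 - eps) * mu[k] + eps * mu[k + 1]
        v = (1.0 - eps) ** 2 * sd[k] ** 2 + eps**2 * sd[k + 1] ** 2
    y = np.asarray(y, dtype=float)
    out = np.exp(-0.5 * (y - m) ** 2 / v) / np.sqrt(2.0 * np.pi * v)
    return out if out.ndim else float(out)


def init_params(intensities: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quantile initialisation of the class means/SDs."""
    y = np.asarray(intensities, dtype=float).ravel()
    if y.size < 10 * K:
        raise ValueError(f"need at least {10 * K} voxels to initialise {K} classes")
    spread = float(y.std())
    if spread <= 1e-12 * max(1.0, abs(float(y.mean()))):
        raise ValueError("constant ROI intensities: segmentation is degenerate")
    q = {2: (25, 75), 3: (25, 60, 95)}[K]
    means = np.percentile(y, q).astype(float)
    # quantile ties (heavily skewed ROIs) are nudged apart to keep ordering strict
    for i in range(1, K):
        if means[i] <= means[i - 1]:
            means[i] = means[i - 1] + 1e-3 * max(spread, 1e-6)
    sds = np.full(K, spread / K)
    return means, sds


def estimate_local_priors(
    posteriors: np.ndarray, lambda_global: float = 0.1
) -> np.ndarray:
    """Locally adaptive prior field.

    ``posteriors`` has shape (..., L) over a box grid; the prior for each
    voxel/label blends the mean posterior over the voxel's 3x3x3
    neighbourhood with the global label frequencies, then renormalises.
    """
    post = np.asarray(posteriors, dtype=float)
    global_freq = post.reshape(-1, post.shape[-1]).mean(axis=0)
    local = np.empty_like(post)
    for l in range(post.shape[-1]):
        local[..., l] = ndimage.uniform_filter(post[..., l], size=3, mode="nearest")
    prior = (1.0 - lambda_global) * local + lambda_global * global_freq
    prior /= prior.sum(axis=-1, keepdims=True)
    return prior


def select_roi(
    img: Image3D,
    mode: str = "auto",
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
    suv_threshold: float = 2.5,
    dilate_voxels: int = 2,
    exclude_box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
) -> BoxROI:
    """Select the tumor-bearing box ROI.

    ``auto`` takes the bounding box of the largest connected component with
    SUV above ``suv_threshold`` (ignoring anything inside ``exclude_box``,
    e.g. a hot bladder), dilated by ``dilate_voxels``.  ``user`` validates a
    supplied box.
    """
    if img.units != "SUV":
        raise ValueError(f"ROI selection expects an SUV image, got {img.units!r}")
    if mode == "user":
        if box is None:
            raise ValueError("mode='user' requires a box")
        return BoxROI(tuple(box[0]), tuple(box[1]))
    if mode != "auto":
        raise ValueError(f"unknown ROI mode {mode!r}")
    hot = img.values > suv_threshold
    if exclude_box is not None:
        excl = BoxROI(tuple(exclude_box[0]), tuple(exclude_box[1]))
        hot[excl.slices] = False
    cc, n = ndimage.label(hot)
    if n == 0:
        raise ValueError(f"no uptake above threshold {suv_threshold}")
    counts = np.bincount(cc.ravel())[1:]
    largest = int(np.argmax(counts)) + 1
    idx = np.argwhere(cc == largest)
    lo = np.maximum(idx.min(axis=0) - dilate_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + dilate_voxels, img.shape)
    return BoxROI(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


def _mixture_loglik(y, mu, sd, labels, K, sd_floor) -> float:
    """Mean log-likelihood under the fitted mixture with uniform weights;
    used only to rank deterministic warm starts."""
    A = _label_weights(labels, K)
    m_l = A @ mu
    v_l = np.maximum((A**2) @ (sd**2), sd_floor**2)
    logpdf = -0.5 * ((y[..., None] - m_l) ** 2 / v_l + np.log(2.0 * np.pi * v_l))
    return float(np.mean(logsumexp(logpdf - np.log(len(labels)), axis=-1)))


def _em_loop(y, mu, sd, labels, K, opts, sd_floor, max_iter):
    """Posterior / parameter / prior iteration over a given label set.

    Means are re-estimated by solving the normal equations of the fuzzy
    observation model (each label's mean is its eps-blend of the class
    means), so a fuzzy label contributes weight (1-eps) to its lower class
    and eps to its upper class without dragging the class means toward the
    middle of the partial-volume ramp.  Solutions are clipped to the
    observed intensity range as a numerical safeguard.
    """
    A = _label_weights(labels, K)
    L = len(labels)
    prior = np.full(y.shape + (L,), 1.0 / L)
    y_lo, y_hi = float(y.min()), float(y.max())
    post = prior
    rel_change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        m_l = A @ mu  # label means: (1-eps) mu_k + eps mu_{k+1}
        v_l = np.maximum((A**2) @ (sd**2), sd_floor**2)
        logpdf = -0.5 * (
            (y[..., None] - m_l) ** 2 / v_l + np.log(2.0 * np.pi * v_l)
        )
        logpost = np.log(np.maximum(prior, 1e-300)) + logpdf
        logpost -= logsumexp(logpost, axis=-1, keepdims=True)
        post = np.exp(logpost)

        r = post @ A  # (..., K): per-class responsibility
        w = r.reshape(-1, K).sum(axis=0)
        if np.any(w < opts.min_class_voxels):
            raise ValueError(
                f"class collapsed (posterior weight {w.min():.1f} voxels < "
                f"{opts.min_class_voxels}); reduce K"
            )
        n_l = post.reshape(-1, L).sum(axis=0)
        S = A.T @ (n_l[:, None] * A) + 1e-9 * np.eye(K)
        b = A.T @ (post.reshape(-1, L).T @ y.ravel())
        mu_new = np.clip(np.linalg.solve(S, b), y_lo, y_hi)
        # keep the class ordering identity stable under noisy updates
        mu_new = np.maximum.accumulate(mu_new)
        for k in range(1, K):
            if mu_new[k] <= mu_new[k - 1]:
                mu_new[k] = mu_new[k - 1] + sd_floor
        m_new = A @ mu_new
        resid2 = ((y[..., None] - m_new) ** 2 * post).reshape(-1, L).sum(axis=0)
        var_new = (A.T @ resid2) / w
        sd_new = np.maximum(np.sqrt(var_new), sd_floor)

        rel_change = float(
            np.max(np.abs(mu_new - mu) / np.maximum(np.abs(mu), 1e-12))
        )
        mu, sd = mu_new, sd_new
        prior = estimate_local_priors(post, opts.lambda_global)
        if rel_change < opts.tol:
            break
    return mu, sd, prior, post, it, rel_change


def roi_seed(
    img: Image3D,
    roi: BoxROI,
    exclude_box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
) -> tuple[int, int, int]:
    """The ROI seed: the SUVmax voxel of the ROI, optionally ignoring an
    exclusion box (so a hot bladder grazing the ROI cannot claim it)."""
    vals = np.full(img.shape, -np.inf)
    vals[roi.slices] = img.values[roi.slices]
    if exclude_box is not None:
        excl = BoxROI(tuple(exclude_box[0]), tuple(exclude_box[1]))
        vals[excl.slices] = -np.inf
    if not np.isfinite(vals).any():
        raise ValueError("ROI is entirely excluded")
    return tuple(int(v) for v in np.unravel_index(int(np.argmax(vals)), img.shape))


def flab_segment(
    img: Image3D,
    roi: BoxROI,
    K: int,
    opts: FlabOptions | None = None,
    seed_point: tuple[int, int, int] | None = None,
) -> SegmentationResult:
    """Run the fuzzy Bayesian segmentation inside ``roi``.

    Iterates posterior computation (label density x locally adaptive
    prior), posterior-weighted moment re-estimation of the class
    means/SDs — each fuzzy label contributing weight (1-eps) to its lower
    class and eps to its upper class — and prior re-estimation, until the
    maximum relative change of the class means drops below ``opts.tol``.
    """
    if K not in (2, 3):
        raise ValueError("K must be 2 or 3")
    opts = opts or FlabOptions()
    y = np.asarray(img.values[roi.slices], dtype=float)
    mu, sd = init_params(y, K)
    scale = max(1.0, float(np.abs(mu).max()))
    sd_floor = 1e-6 * scale
    sd = np.maximum(sd, sd_floor)

    # warm start: plain hard-class EM locates the class plateaus before the
    # fuzzy transition labels are introduced, so partial-volume ramps cannot
    # capture plateau voxels while the parameters are still far off.  Two
    # deterministic initialisations are tried (the quantile init can place
    # the middle class on the background when the tumor fills little of the
    # ROI box); the higher-likelihood fit wins.
    candidates = [(mu, sd)]
    if K == 3:
        lo, hi = np.percentile(y, [25, 95])
        alt = np.array([lo, (lo + hi) / 2.0, hi])
        for i in range(1, K):
            if alt[i] <= alt[i - 1]:
                alt[i] = alt[i - 1] + 1e-3 * scale
        candidates.append((alt, sd.copy()))
    hard_labels = _label_set(K, ())
    best = None
    for mu0, sd0 in candidates:
        try:
            fit = _em_loop(
                y, mu0.copy(), np.maximum(sd0, sd_floor), hard_labels, K, opts,
                sd_floor, max_iter=opts.max_iter
            )
        except ValueError:
            continue
        ll = _mixture_loglik(y, fit[0], fit[1], hard_labels, K, sd_floor)
        if best is None or ll > best[0]:
            best = (ll, fit)
    if best is None:
        raise ValueError("class collapsed under every initialisation; reduce K")
    mu, sd, _, _, it_warm, _ = best[1]

    labels = _label_set(K, opts.fuzzy_levels)
    mu, sd, prior, post, it, rel_change = _em_loop(
        y, mu, sd, labels, K, opts, sd_floor, max_iter=opts.max_iter
    )
    converged = rel_change < opts.tol

    # final labelling under the converged parameters
    A = _label_weights(labels, K)
    m_l = A @ mu
    v_l = np.maximum((A**2) @ (sd**2), sd_floor**2)
    logpdf = -0.5 * ((y[..., None] - m_l) ** 2 / v_l + np.log(2.0 * np.pi * v_l))
    logpost = np.log(np.maximum(prior, 1e-300)) + logpdf
    hard = np.argmax(logpost, axis=-1)
    logpost_n = logpost - logsumexp(logpost, axis=-1, keepdims=True)
    responsibilities = np.exp(logpost_n) @ A  # expected class membership

    model = FlabModel(
        n_classes=K,
        fuzzy_levels=tuple(opts.fuzzy_levels),
        class_means=mu,
        class_sds=sd,
        labels=labels,
        iterations=it_warm + it,
        final_rel_change=rel_change,
        converged=converged,
    )
    label_volume = np.full(img.shape, -1, dtype=np.int16)
    label_volume[roi.slices] = hard
    result = SegmentationResult(
        label_volume=label_volume,
        model=model,
        roi=roi,
        responsibilities=responsibilities,
        warning=None if converged else f"not converged after {opts.max_iter} iterations",
    )
    return masks_from_segmentation(
        result, img, K, fuzzy_cut=opts.fuzzy_cut, seed_point=seed_point
    )


def _component_containing(mask: np.ndarray, seed_idx: tuple[int, int, int]) -> np.ndarray:
    cc, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("segmentation produced an empty mask")
    seed_label = cc[seed_idx]
    if seed_label == 0:  # seed fell outside; keep the largest component
        counts = np.bincount(cc.ravel())[1:]
        seed_label = int(np.argmax(counts)) + 1
    return cc == seed_label


def masks_from_segmentation(
    seg: SegmentationResult,
    img: Image3D,
    K: int,
    fuzzy_cut: float = 0.5,
    seed_point: tuple[int, int, int] | None = None,
) -> SegmentationResult:
    """Derive the binary masks from the segmentation.

    Membership follows the fuzzy labelling at the eps >= cut rule: K=3
    gathers both tumor classes plus fuzzy voxels whose tumor-side level
    reaches the cut into VT, and the top class plus high-side fuzzy voxels
    into V1; K=2 analogously for V2.  When per-voxel class posteriors are
    available the rule is evaluated on the posterior-expected membership
    (fuzzy level blends included), which places the boundary at the true
    half-membership surface instead of snapping to the discrete fuzzy
    levels.  Only the connected component containing the ROI seed (the
    SUVmax voxel of the ROI) is retained.
    """
    labels = seg.model.labels
    lab = seg.label_volume
    in_roi = lab >= 0
    K_resp = seg.responsibilities

    def member(pred) -> np.ndarray:
        sel = np.array([pred(k, eps) for (k, eps) in labels])
        out = np.zeros(lab.shape, dtype=bool)
        out[in_roi] = sel[lab[in_roi]]
        return out

    def member_resp(class_slice) -> np.ndarray:
        """Expected membership of the given class range >= fuzzy_cut."""
        out = np.zeros(lab.shape, dtype=bool)
        out[seg.roi.slices] = K_resp[..., class_slice].sum(axis=-1) >= fuzzy_cut
        return out

    if seed_point is not None:
        seed_idx = tuple(seed_point)
    else:
        seed_idx = roi_seed(img, seg.roi)

    def as_img(mask: np.ndarray) -> Image3D:
        return Image3D(
            mask.astype(np.uint8),
            img.spacing_mm,
            img.origin_mm,
            img.direction.copy(),
            units="none",
        )

    if K == 3:
        if K_resp is not None:
            vt = member_resp(slice(1, 3))
            v1 = member_resp(slice(2, 3))
        else:
            vt = member(lambda k, eps: (k >= 1) or (k == 0 and eps >= fuzzy_cut))
            v1 = member(lambda k, eps: (k == 2) or (k == 1 and eps >= fuzzy_cut))
        vt = _component_containing(vt, seed_idx)
        v1 &= vt
        if not v1.any():
            raise ValueError("segmentation produced an empty V1 mask")
        v1 = _component_containing(v1, seed_idx)
        seg.vt_mask = as_img(vt)
        seg.v1_mask = as_img(v1)
    else:
        if K_resp is not None:
            v2 = member_resp(slice(1, 2))
        else:
            v2 = member(lambda k, eps: (k == 1) or (k == 0 and eps >= fuzzy_cut))
        v2 = _component_containing(v2, seed_idx)
        seg.v2_mask = as_img(v2)
    return seg


def threshold_segment(
    img: Image3D,
    roi: BoxROI,
    pct_of_suvmax: float,
    seed_point: tuple[int, int, int] | None = None,
) -> Image3D:
    """Fixed %SUVmax threshold comparator: voxels in the ROI at or above
    pct/100 of the ROI SUVmax.  By default the largest connected component
    is retained; with ``seed_point`` the component containing the seed (and
    the seed's value defines SUVmax, shielding the threshold from hot
    structures grazing the ROI box)."""
    if not 0 < pct_of_suvmax < 100:
        raise ValueError("pct_of_suvmax must lie strictly between 0 and 100")
    y = img.values[roi.slices]
    suvmax = float(img.values[seed_point]) if seed_point is not None else float(y.max())
    level = (pct_of_suvmax / 100.0) * suvmax
    mask = np.zeros(img.shape, dtype=bool)
    mask[roi.slices] = y >= level
    if not mask.any():
        raise ValueError("threshold produced an empty mask")
    if seed_point is not None:
        mask = _component_containing(mask, tuple(seed_point))
    else:
        cc, n = ndimage.label(mask)
        counts = np.bincount(cc.ravel())[1:]
        mask = cc == (int(np.argmax(counts)) + 1)
    return Image3D(
        mask.astype(np.uint8),
        img.spacing_mm,
        img.origin_mm,
        img.direction.copy(),
        units="none",
    )
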