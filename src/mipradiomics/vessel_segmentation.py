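"""Peritumoral vessel segmentation on MIP images.

The stage chain mirrors the clinical procedure: segment the breast, restrict
to the tumor-side (lateral) half, enhance curvilinear structures with a
multiscale Hessian eigenvalue (Frangi-type) filter, binarize and clean the
response (close small gaps, fill holes, drop tiny components), intersect with
the lateral breast mask, and finally enforce tumor/vessel disjointness by
erasing the intersection from the tumor ROI.

Algorithmic segmentations are scored against a reference mask at the level of
skeleton *segments* (skeleton pieces between branch points): a reference
segment found by the prediction is "correct", one not found is "missed", and
a predicted segment with no reference support is "incorrect".  Correct and
missed rates are complementary by construction; the incorrect rate is
normalized by the predicted segment count, which is why it is not the
complement of the correct rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects, skeletonize

from .errors import ContractError, SegmentationError
from .imaging_io import BinaryMask, MaskRole, MIPImage

logger = logging.getLogger(__name__)

__all__ = [
    "VesselnessParams",
    "VesselnessMap",
    "VesselCleanConfig",
    "DetectionMetrics",
    "segment_breast",
    "lateral_breast_mask",
    "hessian_vesselness",
    "binarize_and_clean",
    "remove_tumor_overlap",
    "detection_metrics",
]


@dataclass
class VesselnessParams:
    """Multiscale Hessian filter constants.

    ``beta`` controls sensitivity to the ridge-anisotropy ratio R_B = l1/l2;
    ``c`` controls sensitivity to second-order structureness S = ||H||_F.
    ``c = None`` uses the image-adaptive default: half the maximum Frobenius
    norm of the (scale-normalized) Hessian, per scale.
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    beta: float = 0.5
    c: float | None = None

    def __post_init__(self):
        scales = tuple(float(s) for s in self.scales)
        if len(scales) == 0:
            raise ContractError("at least one scale is required")
        if any(s <= 0 for s in scales):
            raise ContractError("scales must be strictly positive")
        if any(b >= a for a, b in zip(scales[1:], scales[:-1])):
            raise ContractError("scales must be strictly increasing")
        self.scales = scales
        if self.beta <= 0 or (self.c is not None and self.c <= 0):
            raise ContractError("beta and c must be positive")


@dataclass
class VesselnessMap:
    values: np.ndarray          # in [0, 1]
    scales_used: tuple[float, ...]
    best_scale: np.ndarray      # argmax sigma per pixel

    def __post_init__(self):
        if self.values.shape != self.best_scale.shape:
            raise ContractError("values and best_scale must share the raster")


@dataclass
class VesselCleanConfig:
    threshold: float | None = None  # None -> Otsu over in-mask nonzero response
    min_size: int = 20
    closing_radius: int = 1
    max_hole_size: int = 64         # only holes smaller than this are filled
    match_radius: float = 2.0       # used by detection_metrics default


@dataclass
class DetectionMetrics:
    correct_rate: float
    incorrect_rate: float
    missed_rate: float
    n_gt_segments: int
    n_pred_segments: int

    def __post_init__(self):
        for r in (self.correct_rate, self.incorrect_rate, self.missed_rate):
            if not 0.0 <= r <= 100.0:
                raise ContractError("rates must be percentages in [0, 100]")
        if abs(self.correct_rate + self.missed_rate - 100.0) > 1e-9:
            raise ContractError("correct_rate + missed_rate must equal 100")


# ---------------------------------------------------------------------------
# breast / lateral masks
# ---------------------------------------------------------------------------

def segment_breast(mip: MIPImage) -> BinaryMask:
    """Otsu threshold on a median-smoothed MIP, closed and hole-filled."""
    px = mip.pixels
    if np.ptp(px) == 0:
        raise SegmentationError("constant image: cannot segment breast")
    smoothed = ndimage.median_filter(px, size=5)
    if np.ptp(smoothed) == 0:
        raise SegmentationError("image is constant after smoothing")
    fg = smoothed > threshold_otsu(smoothed)
    if fg.all():
        logger.warning("breast threshold selected the whole frame; applying border policy")
        fg = np.zeros_like(fg)
        fg[1:-1, 1:-1] = True
        return BinaryMask(fg, role=MaskRole.BREAST, case_id=mip.case_id)
    if not fg.any():
        raise SegmentationError("breast threshold produced an empty mask")
    fg = closing(fg, disk(5))
    fg = ndimage.binary_fill_holes(fg)
    labeled, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
        fg = labeled == (1 + int(np.argmax(sizes)))
    return BinaryMask(fg, role=MaskRole.BREAST, case_id=mip.case_id)


def lateral_breast_mask(breast: BinaryMask, tumor: BinaryMask) -> BinaryMask:
    """Breast restricted to the image half containing the tumor centroid."""
    if tumor.is_empty:
        raise ContractError("tumor mask is empty")
    if breast.shape != tumor.shape:
        raise ContractError("breast and tumor masks must share the raster")
    w = breast.shape[1]
    centroid_col = float(np.mean(np.nonzero(tumor.pixels)[1]))
    cols = np.arange(w)
    if centroid_col == w / 2:
        logger.warning("tumor centroid exactly on midline; assigning left half")
        keep = cols < w / 2
    elif centroid_col < w / 2:
        keep = cols < w / 2
    else:
        keep = cols >= w / 2
    out = breast.pixels & keep[np.newaxis, :]
    return BinaryMask(out, role=MaskRole.LATERAL_BREAST, case_id=breast.case_id)


# ---------------------------------------------------------------------------
# Hessian vesselness
# ---------------------------------------------------------------------------

def hessian_vesselness(mip: MIPImage, params: VesselnessParams | None = None) -> VesselnessMap:
    """2D Frangi-type vesselness for bright curvilinear structures.

    Per scale sigma: Gaussian second derivatives scaled by sigma**2
    (gamma-normalization), eigenvalues ordered |l1| <= |l2|, and

        V = 0                                          if l2 > 0
        V = exp(-R_B^2 / 2 beta^2) (1 - exp(-S^2 / 2 c^2))   otherwise

    with R_B = l1/l2 and S = sqrt(l1^2 + l2^2).  The final map is the
    pixelwise maximum over scales; ``best_scale`` records the argmax sigma.
    """
    params = params or VesselnessParams()
    img = mip.pixels
    if not np.all(np.isfinite(img)):
        raise ContractError("image contains non-finite pixels")
    if min(img.shape) < 7:
        raise ContractError("image must be at least 7x7")

    # remove the constant component: sampled Gaussian-derivative kernels do
    # not sum to exactly zero, so an intensity offset would leak into the
    # Hessian and break offset invariance
    img = img - img.mean()

    best = np.zeros_like(img, dtype=float)
    best_scale = np.full(img.shape, params.scales[0], dtype=float)
    for sigma in params.scales:
        hrr = ndimage.gaussian_filter(img, sigma, order=(2, 0)) * sigma**2
        hrc = ndimage.gaussian_filter(img, sigma, order=(1, 1)) * sigma**2
        hcc = ndimage.gaussian_filter(img, sigma, order=(0, 2)) * sigma**2

        half_trace = (hrr + hcc) / 2.0
        root = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
        e1 = half_trace + root
        e2 = half_trace - root
        swap = np.abs(e1) > np.abs(e2)
        l1 = np.where(swap, e2, e1)   # |l1| <= |l2|
        l2 = np.where(swap, e1, e2)

        s2 = l1**2 + l2**2
        c = params.c if params.c is not None else 0.5 * np.sqrt(s2.max())
        v = np.zeros_like(img, dtype=float)
        if c > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                rb2 = np.where(l2 != 0, (l1 / np.where(l2 == 0, 1.0, l2)) ** 2, 0.0)
            resp = np.exp(-rb2 / (2 * params.beta**2)) * (1.0 - np.exp(-s2 / (2 * c**2)))
            v = np.where(l2 < 0, resp, 0.0)
        improved = v > best
        best_scale[improved] = sigma
        best = np.maximum(best, v)
    return VesselnessMap(values=np.clip(best, 0.0, 1.0), scales_used=params.scales, best_scale=best_scale)


# ---------------------------------------------------------------------------
# binarization / cleaning
# ---------------------------------------------------------------------------

def binarize_and_clean(
    vmap: VesselnessMap,
    lateral: BinaryMask,
    cfg: VesselCleanConfig | None = None,
) -> BinaryMask:
    """Threshold, close small gaps, fill holes, drop tiny pieces, intersect."""
    cfg = cfg or VesselCleanConfig()
    if vmap.values.shape != lateral.shape:
        raise ContractError("vesselness map and lateral mask must share the raster")
    if lateral.is_empty:
        raise ContractError("lateral breast mask is empty")
    in_mask = vmap.values[lateral.pixels]
    nonzero = in_mask[in_mask > 0]
    if nonzero.size == 0:
        logger.warning("vesselness is zero within the lateral mask; returning empty vessel mask")
        return BinaryMask(np.zeros_like(lateral.pixels), role=MaskRole.VESSEL, case_id=lateral.case_id)
    if cfg.threshold is not None:
        thr = cfg.threshold
    elif np.ptp(nonzero) == 0:
        thr = float(nonzero[0]) / 2
    else:
        thr = float(threshold_otsu(nonzero))
    binary = vmap.values >= thr
    if cfg.closing_radius > 0:
        binary = closing(binary, disk(cfg.closing_radius))
    binary = _fill_small_holes(binary, cfg.max_hole_size)
    if cfg.min_size > 1:
        # drop components strictly smaller than min_size
        binary = remove_small_objects(binary, max_size=cfg.min_size - 1, connectivity=2)
    binary &= lateral.pixels
    if not binary.any():
        logger.warning("no peritumoral vessel detected after cleaning")
    return BinaryMask(binary, role=MaskRole.VESSEL, case_id=lateral.case_id)


def _fill_small_holes(binary: np.ndarray, max_hole_size: int) -> np.ndarray:
    """Fill enclosed background regions smaller than ``max_hole_size`` px.

    A cap keeps genuine anatomy (e.g. a bright blob fully ringed by
    detected curvilinear structure) from being flooded into the vessel mask;
    only the small holes left inside tubes are closed.
    """
    if max_hole_size <= 0:
        return binary
    filled = ndimage.binary_fill_holes(binary)
    holes, n = ndimage.label(filled & ~binary)
    if n == 0:
        return binary
    sizes = np.bincount(holes.ravel())[1:]
    small = np.flatnonzero(sizes < max_hole_size) + 1
    return binary | np.isin(holes, small)


def remove_tumor_overlap(tumor: BinaryMask, vessel: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Erase tumor/vessel intersection from the tumor mask (vessel wins)."""
    if tumor.shape != vessel.shape:
        raise ContractError("masks must share the raster")
    new_tumor = tumor.pixels & ~vessel.pixels
    if not new_tumor.any():
        raise ContractError("tumor mask emptied entirely by vessel overlap removal")
    return (
        BinaryMask(new_tumor, role=MaskRole.TUMOR, case_id=tumor.case_id),
        vessel,
    )


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

def _skeleton_segments(mask: np.ndarray) -> list[np.ndarray]:
    """Skeletonize and split at branch points; returns per-segment coords."""
    skel = skeletonize(mask)
    if not skel.any():
        return []
    nbrs = ndimage.convolve(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant") - skel
    branch = skel & (nbrs > 2)
    body = skel & ~branch
    labeled, n = ndimage.label(body, structure=np.ones((3, 3)))
    segments = [np.argwhere(labeled == k) for k in range(1, n + 1)]
    segments = [s for s in segments if len(s) > 0]
    if not segments:  # degenerate: skeleton made only of junction pixels
        labeled, n = ndimage.label(skel, structure=np.ones((3, 3)))
        segments = [np.argwhere(labeled == k) for k in range(1, n + 1)]
    return segments


def detection_metrics(
    pred: BinaryMask,
    reference: BinaryMask,
    match_radius: float = 2.0,
    coverage: float = 0.5,
) -> DetectionMetrics:
    """Segment-level correct / incorrect / missed detection rates (%).

    A reference skeleton segment is correct when at least ``coverage`` of its
    pixels lie within ``match_radius`` px of the prediction; a predicted
    segment with less than ``coverage`` support from the reference is
    incorrect.
    """
    if pred.shape != reference.shape:
        raise ContractError("masks must share the raster")
    if reference.is_empty:
        raise ContractError("reference vessel mask is empty")

    gt_segments = _skeleton_segments(reference.pixels)
    n_gt = len(gt_segments)
    if pred.is_empty:
        return DetectionMetrics(0.0, 0.0, 100.0, n_gt, 0)

    pred_segments = _skeleton_segments(pred.pixels)
    dist_to_pred = ndimage.distance_transform_edt(~pred.pixels)
    dist_to_ref = ndimage.distance_transform_edt(~reference.pixels)

    n_correct = sum(
        1
        for seg in gt_segments
        if np.mean(dist_to_pred[seg[:, 0], seg[:, 1]] <= match_radius) >= coverage
    )
    n_incorrect = sum(
        1
        for seg in pred_segments
        if np.mean(dist_to_ref[seg[:, 0], seg[:, 1]] <= match_radius) < coverage
    )
    n_pred = len(pred_segments)
    correct = 100.0 * n_correct / n_gt
    missed = 100.0 * (n_gt - n_correct) / n_gt
    incorrect = 100.0 * n_incorrect / n_pred if n_pred else 0.0
    return DetectionMetrics(correct, incorrect, missed, n_gt, n_pred)
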