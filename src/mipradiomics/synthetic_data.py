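"""Synthetic MIP phantoms: breast, heterogeneous tumor, branching vessels.

The generator emulates what the downstream stages need from a subtraction-MIP
of a breast DCE-MRI exam: a smooth half-elliptical enhancing breast region
with low-amplitude background parenchymal enhancement, one irregular
heterogeneous tumor blob, and a small tree of bright curvilinear vessels of
width 1–4 px near the tumor, with known ground-truth masks and a binary
outcome label (1 = pCR analogue).

A controllable *class effect* separates outcomes through exactly the feature
families the downstream analysis selects on real data: for label-0 cases
(non-pCR analogue, the more heterogeneous vasculature) the across-vessel
intensity spread and the tumor's smooth texture amplitude are multiplied by
``1 + class_effect``.  All random draws are made in a fixed order regardless
of the label, so with ``class_effect = 0`` the label has no influence on the
image and the two classes are identical in law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError, GenerationError
from .imaging_io import BinaryMask, MaskRole, MIPImage

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortTable",
    "generate_phantom",
    "generate_cohort",
    "degrade_vessel_mask",
    "derive_seed",
]

# Intensity scale (arbitrary units, roughly subtraction-image-like).
_BREAST_MEAN = 60.0
_BPE_AMP = 8.0        # background parenchymal enhancement amplitude
_BPE_SIGMA = 8.0
_TUMOR_MEAN = 170.0
_TUMOR_TEX_AMP = 18.0  # baseline tumor texture amplitude (scaled by class effect)
_TUMOR_TEX_SIGMA = 2.0
_VESSEL_MEAN = 185.0
_VESSEL_SD = 12.0      # across-vessel intensity spread (scaled by class effect)
_VESSEL_ALONG_AMP = 5.0

# The study prevalence the default cohorts mimic: 100/282 patients achieving
# pCR after neoadjuvant chemotherapy.
DEFAULT_PREVALENCE = 0.355


def derive_seed(base: int, *keys) -> int:
    """Derive a child seed (< 2**31) deterministically from a base seed."""
    ss = np.random.SeedSequence([int(base)] + [abs(hash(k)) % (2**32) for k in keys])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (256, 256)
    vessel_count: int = 5
    vessel_width_range: tuple[int, int] = (1, 4)
    tumor_radius_range: tuple[float, float] = (10.0, 18.0)
    background_noise_sd: float = 4.0
    class_effect: float = 1.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ContractError("image_size must be at least 64x64")
        if self.vessel_width_range[0] < 1:
            raise ContractError("vessel widths must be >= 1 px")
        if self.tumor_radius_range[0] < 3:
            raise ContractError("tumor radius must be >= 3 px")
        if self.class_effect < 0:
            raise ContractError("class_effect must be >= 0")
        if self.background_noise_sd < 0:
            raise ContractError("background_noise_sd must be >= 0")


@dataclass
class Phantom:
    image: MIPImage
    tumor_mask_gt: BinaryMask
    vessel_mask_gt: BinaryMask
    breast_mask_gt: BinaryMask
    label: int

    def __post_init__(self):
        shp = self.image.shape
        for m in (self.tumor_mask_gt, self.vessel_mask_gt, self.breast_mask_gt):
            if m.shape != shp:
                raise ContractError("phantom masks must share the image raster")
        if np.any(self.tumor_mask_gt.pixels & self.vessel_mask_gt.pixels):
            raise ContractError("tumor and vessel ground-truth masks must be disjoint")
        if self.label not in (0, 1):
            raise ContractError("label must be 0 or 1")

    @property
    def case_id(self) -> str:
        return self.image.case_id


@dataclass
class CohortTable:
    """Rows of (case_id, label, cohort) with the realized prevalence."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"case_id", "label", "cohort"}
        if not required.issubset(self.table.columns):
            raise ContractError(f"cohort table needs columns {sorted(required)}")
        if not set(self.table["label"].unique()).issubset({0, 1}):
            raise ContractError("labels must be 0/1")

    @property
    def prevalence(self) -> float:
        return float(self.table["label"].mean())


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-correlated noise field normalized to unit standard deviation."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _rasterize_centerline(points: np.ndarray, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr = np.clip(np.round(points[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(points[:, 1]).astype(int), 0, shape[1] - 1)
    mask[rr, cc] = True
    return mask


def _breast_mask(shape, rng: np.random.Generator) -> np.ndarray:
    """Half-ellipse hanging from the top edge (axial single-breast analogue)."""
    h, w = shape
    a = (0.72 + 0.06 * rng.uniform()) * h   # row semi-axis
    b = (0.42 + 0.04 * rng.uniform()) * w   # col semi-axis
    yy, xx = np.ogrid[:h, :w]
    return ((yy / a) ** 2 + ((xx - w / 2) / b) ** 2) <= 1.0


def _tumor_mask(shape, center, radius, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    ratio = rng.uniform(0.7, 1.0)
    theta = rng.uniform(0, math.pi)
    yy, xx = np.mgrid[:h, :w]
    dy, dx = yy - center[0], xx - center[1]
    u = dy * math.cos(theta) + dx * math.sin(theta)
    v = -dy * math.sin(theta) + dx * math.cos(theta)
    dist = np.sqrt((u / radius) ** 2 + (v / (radius * ratio)) ** 2)
    wobble = _smooth_field(rng, shape, 4.0)
    return (dist + 0.22 * wobble) <= 1.0


def generate_phantom(spec: PhantomSpec, label: int, case_id: str = "phantom") -> Phantom:
    """Generate one phantom; ``spec.seed`` fully determines the output."""
    if label not in (0, 1):
        raise ContractError("label must be 0 or 1")
    shape = tuple(spec.image_size)
    h, w = shape
    rng = np.random.default_rng(spec.seed)

    breast = _breast_mask(shape, rng)
    side = int(rng.integers(0, 2))  # 0 = left half, 1 = right half
    radius = rng.uniform(*spec.tumor_radius_range)
    row = rng.uniform(0.30 * h, 0.50 * h)
    col = rng.uniform(0.18 * w, 0.34 * w) if side == 0 else rng.uniform(0.66 * w, 0.82 * w)
    tumor = _tumor_mask(shape, (row, col), radius, rng)
    tumor &= ndimage.binary_erosion(breast, iterations=3)
    if not tumor.any():  # geometry keeps the center well inside the breast
        raise GenerationError("tumor placement failed")

    # --- vessels: quadratic Bezier trunks with 1-3 branches each -----------
    segments = []  # (centerline mask, width, z-draw, texture-phase)
    half_lo, half_hi = (0.04 * w, 0.46 * w) if side == 0 else (0.54 * w, 0.96 * w)
    for _ in range(spec.vessel_count):
        placed = False
        for _attempt in range(60):
            ang = rng.uniform(0, 2 * math.pi)
            start = np.array([row + (radius + 4) * math.sin(ang), col + (radius + 4) * math.cos(ang)])
            end = np.array([rng.uniform(0.05 * h, 0.85 * h), rng.uniform(half_lo, half_hi)])
            if np.linalg.norm(end - start) < 25:
                continue
            mid = (start + end) / 2
            perp = np.array([-(end - start)[1], (end - start)[0]])
            perp = perp / (np.linalg.norm(perp) + 1e-12)
            ctrl = mid + perp * rng.uniform(-0.25, 0.25) * np.linalg.norm(end - start)
            pts = _bezier_points(start, ctrl, end, 200)
            inside = breast[
                np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1),
                np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1),
            ]
            if inside.mean() < 0.7:
                continue
            trunk_pts = pts
            placed = True
            break
        if not placed:
            raise GenerationError("vessel placement failed after bounded retries")

        n_branch = int(rng.integers(1, 4))
        branch_pts_list = []
        for _b in range(n_branch):
            t0 = rng.uniform(0.25, 0.8)
            p0 = trunk_pts[int(t0 * (len(trunk_pts) - 1))]
            direction = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(15, 40)
            p2 = p0 + length * np.array([math.sin(direction), math.cos(direction)])
            p1 = (p0 + p2) / 2 + rng.uniform(-6, 6, size=2)
            branch_pts_list.append(_bezier_points(p0, p1, p2, 80))

        for pts in [trunk_pts] + branch_pts_list:
            width = int(rng.integers(spec.vessel_width_range[0], spec.vessel_width_range[1] + 1))
            z = float(rng.standard_normal())
            cl = _rasterize_centerline(pts, shape)
            segments.append((cl, width, z))

    vessel = np.zeros(shape, dtype=bool)
    seg_masks = []
    for cl, width, z in segments:
        m = ndimage.binary_dilation(cl, structure=_disk(width // 2)) if width > 1 else cl
        m = m & breast & ~tumor
        seg_masks.append((m, z))
        vessel |= m

    # --- intensity assembly (draw order fixed; label only scales amplitudes)
    hetero = 1.0 + spec.class_effect * (1.0 if label == 0 else 0.0)
    bpe = _smooth_field(rng, shape, _BPE_SIGMA)
    ttex = _smooth_field(rng, shape, _TUMOR_TEX_SIGMA)
    vtex = _smooth_field(rng, shape, 3.0)
    noise = rng.normal(0.0, spec.background_noise_sd, shape)

    img = np.zeros(shape, dtype=float)
    img[breast] = _BREAST_MEAN + _BPE_AMP * bpe[breast]
    img[tumor] = _TUMOR_MEAN + _TUMOR_TEX_AMP * hetero * ttex[tumor]
    for m, z in seg_masks:
        if m.any():
            img[m] = _VESSEL_MEAN + _VESSEL_SD * hetero * z + _VESSEL_ALONG_AMP * vtex[m]
    img += noise
    np.clip(img, 0.0, None, out=img)

    return Phantom(
        image=MIPImage(img, case_id=case_id),
        tumor_mask_gt=BinaryMask(tumor, role=MaskRole.TUMOR, case_id=case_id),
        vessel_mask_gt=BinaryMask(vessel, role=MaskRole.VESSEL, case_id=case_id),
        breast_mask_gt=BinaryMask(breast, role=MaskRole.BREAST, case_id=case_id),
        label=int(label),
    )


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return yy**2 + xx**2 <= radius**2


def generate_cohort(n: int, prevalence: float, spec: PhantomSpec, cohort: str = "train"):
    """Generate ``n`` labeled phantoms with exactly round(n * prevalence) positives.

    Per-case seeds derive deterministically from ``spec.seed``; two calls with
    the same arguments produce identical label sequences and images.
    """
    if n < 2:
        raise ContractError("n must be >= 2")
    if not 0 < prevalence < 1:
        raise ContractError("prevalence must be in (0, 1)")
    n_pos = int(round(n * prevalence))
    if n_pos == 0 or n_pos == n:
        raise ContractError(f"n * prevalence rounds to a degenerate count ({n_pos} of {n})")

    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    shuffle_rng = np.random.default_rng(derive_seed(spec.seed, "labels", cohort))
    shuffle_rng.shuffle(labels)

    phantoms = []
    rows = []
    for i, label in enumerate(labels):
        case_id = f"{cohort}_{i:04d}"
        case_spec = replace(spec, seed=derive_seed(spec.seed, "case", cohort, i))
        phantoms.append(generate_phantom(case_spec, int(label), case_id=case_id))
        rows.append({"case_id": case_id, "label": int(label), "cohort": cohort})
    return phantoms, CohortTable(pd.DataFrame(rows))


def degrade_vessel_mask(
    gt: BinaryMask,
    miss_fraction: float,
    spurious_count: int,
    seed: int = 0,
) -> BinaryMask:
    """Remove whole vessel components and add short spurious tubes.

    Produces controlled inputs for detection-rate evaluation: the removed
    fraction of connected components becomes "missed" reference structure,
    the added tubes (placed clear of the ground truth) become "incorrect"
    detections.
    """
    if not 0 <= miss_fraction <= 1:
        raise ContractError("miss_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labeled, n_comp = ndimage.label(gt.pixels, structure=np.ones((3, 3)))
    out = gt.pixels.copy()
    n_remove = int(round(miss_fraction * n_comp))
    if n_remove > 0:
        drop = rng.choice(np.arange(1, n_comp + 1), size=n_remove, replace=False)
        out[np.isin(labeled, drop)] = False

    h, w = gt.shape
    keepout = ndimage.binary_dilation(gt.pixels, iterations=5)
    for _ in range(int(spurious_count)):
        placed = False
        for _attempt in range(200):
            r0 = rng.integers(2, h - 2)
            c0 = rng.integers(2, w - 2)
            ang = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(10, 20)
            r1 = int(np.clip(r0 + length * math.sin(ang), 0, h - 1))
            c1 = int(np.clip(c0 + length * math.cos(ang), 0, w - 1))
            n_pts = int(length * 2) + 2
            pts = np.stack(
                [np.linspace(r0, r1, n_pts), np.linspace(c0, c1, n_pts)], axis=1
            )
            tube = _rasterize_centerline(pts, gt.shape)
            tube = ndimage.binary_dilation(tube, structure=_disk(1))
            if np.any(tube & keepout) or np.any(tube & out):
                continue
            out |= tube
            placed = True
            break
        if not placed:
            raise GenerationError("spurious tube placement failed after bounded retries")
    return BinaryMask(out, role=MaskRole.VESSEL, case_id=gt.case_id)
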