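"""2D radiomics feature extraction from a MIP image and an ROI mask.

Feature bank (standard reference-set definitions):

* 10 shape-2D features on the original mask,
* 19 first-order statistics,
* 70 texture features: GLCM 24, GLRLM 16, GLSZM 16, GLDM 14,

computed on the original image for every ROI, and additionally on the four
sub-bands (LL, LH, HL, HH) of a single-level undecimated wavelet transform
for tumor ROIs.  Tumor vectors therefore hold 10 + 5 x (19 + 70) = 455
features, vessel vectors 10 + 19 + 70 = 99.  Shape features are computed on
the original mask only; wavelet sub-bands keep the raster size so the ROI
mask applies unchanged.

Gray levels are discretized with a fixed bin width anchored at the in-mask
minimum, which makes every texture feature invariant to constant intensity
shifts.  Texture matrices: GLCM symmetric at distance 1 averaged over the 4
planar angles; GLRLM over 4 directions (averaged); GLSZM with 8-connected
zones; GLDM with Chebyshev distance ``delta`` and tolerance ``alpha``.

The GLDM dependence of a pixel is its count of in-mask neighbors whose level
differs by at most ``alpha`` — a 0-based convention (an isolated pixel has
dependence 0).  Reference toolkits differ here; the 1-based alternative
(counting the center pixel itself) is available via ``dependence_base=1``.
Inverse-dependence emphases use divisor ``max(d, 1)`` so the 0-based
convention stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from skimage.measure import find_contours, perimeter_crofton

from .errors import ContractError
from .imaging_io import BinaryMask, MIPImage

__all__ = [
    "RadiomicsConfig",
    "GrayLevelImage",
    "GLDMMatrix",
    "FeatureVector",
    "discretize",
    "first_order_features",
    "shape2d_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "wavelet_decompose",
    "extract_feature_vector",
    "FIRST_ORDER_NAMES",
    "SHAPE2D_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "WAVELET_BANDS",
    "feature_names",
]

_EPS = np.finfo(float).tiny
WAVELET_BANDS = ("LL", "LH", "HL", "HH")


@dataclass
class RadiomicsConfig:
    bin_width: float = 25.0
    gldm_alpha: float = 0.0
    gldm_delta: int = 1
    dependence_base: int = 0      # 0: neighbor count; 1: count includes center
    wavelet: str = "coif1"

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ContractError("bin_width must be positive")
        if self.gldm_delta < 1:
            raise ContractError("gldm_delta must be >= 1")
        if self.dependence_base not in (0, 1):
            raise ContractError("dependence_base must be 0 or 1")


@dataclass
class GrayLevelImage:
    """Discretized ROI: integer levels 1..n_levels inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    bin_width: float

    def __post_init__(self):
        inside = self.levels[self.levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ContractError("in-mask levels must lie in [1, n_levels]")

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


@dataclass
class GLDMMatrix:
    counts: np.ndarray   # n_levels x (max dependence + 1)
    alpha: float
    delta: int
    base: int = 0

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ContractError("GLDM counts must be non-negative")


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ContractError("names and values lengths differ")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ContractError(f"non-finite feature values: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(image: np.ndarray | MIPImage, mask: np.ndarray | BinaryMask, bin_width: float = 25.0) -> GrayLevelImage:
    """Fixed-bin-width gray levels anchored at the in-mask minimum."""
    arr = image.pixels if isinstance(image, MIPImage) else np.asarray(image, dtype=float)
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ContractError("image and mask shapes differ")
    if not m.any():
        raise ContractError("mask is empty")
    if bin_width <= 0:
        raise ContractError("bin_width must be positive")
    levels = np.zeros(arr.shape, dtype=np.int64)
    vals = arr[m]
    levels[m] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return GrayLevelImage(levels=levels, n_levels=int(levels.max()), bin_width=float(bin_width))


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile", "90Percentile",
    "Maximum", "Mean", "Median", "InterquartileRange", "Range",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "StandardDeviation", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(
    image: np.ndarray | MIPImage,
    mask: np.ndarray | BinaryMask,
    bin_width: float = 25.0,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[str, float]:
    """The 19 standard first-order statistics of the in-mask intensities.

    Skewness and kurtosis of a constant ROI are defined as 0.  Kurtosis is
    the raw fourth standardized moment (3 for a normal distribution).
    """
    arr = image.pixels if isinstance(image, MIPImage) else np.asarray(image, dtype=float)
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ContractError("mask is empty")
    x = arr[m].astype(float)
    n = x.size
    mean = x.mean()
    diff = x - mean
    var = float(np.mean(diff**2))
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    # discretized histogram for entropy / uniformity
    gl = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(gl).astype(float)
    p = p[p > 0] / n
    pixel_area = float(pixel_spacing[0] * pixel_spacing[1])
    energy = float(np.sum(x**2))

    if var > 0:
        skew = float(np.mean(diff**3) / sd**3)
        kurt = float(np.mean(diff**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0

    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(diff))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "StandardDeviation": float(sd),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# shape 2D
# ---------------------------------------------------------------------------

SHAPE2D_NAMES = (
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "SphericalDisproportion", "MaximumDiameter",
    "MajorAxisLength", "MinorAxisLength", "Elongation",
)


def shape2d_features(
    mask: np.ndarray | BinaryMask,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[str, float]:
    """10 standard 2D shape features (components treated as one ROI).

    Mesh surface comes from the 0.5-isocontour polygon (marching squares);
    the perimeter uses the Crofton formula (4 directions), which is unbiased
    for smooth boundaries where polygonal staircase lengths overestimate.
    Axis lengths come from the PCA of physical pixel coordinates
    (4 sqrt(eigenvalue), the full axis of the fitted ellipse).
    """
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ContractError("mask is empty")
    dy, dx = float(pixel_spacing[0]), float(pixel_spacing[1])

    padded = np.pad(m.astype(float), 1)
    contours = find_contours(padded, 0.5)
    area = 0.0
    for c in contours:
        ys = c[:, 0] * dy
        xs = c[:, 1] * dx
        # signed shoelace: outer contours and holes wind oppositely
        area += 0.5 * np.sum(ys[:-1] * xs[1:] - ys[1:] * xs[:-1])
    mesh_surface = abs(area)
    # Crofton assumes isotropic sampling; spacing enters as the mean pitch
    perimeter = float(perimeter_crofton(m, directions=4)) * (dy + dx) / 2.0
    pixel_surface = float(m.sum()) * dy * dx

    coords = np.argwhere(m).astype(float)
    phys = coords * np.array([dy, dx])
    # maximum diameter over hull-ish boundary pixels (all pixels for small ROIs)
    boundary = phys if len(phys) <= 400 else phys[_hull_indices(phys)]
    dif = boundary[:, None, :] - boundary[None, :, :]
    max_diam = float(np.sqrt((dif**2).sum(-1)).max()) if len(boundary) > 1 else 0.0

    centered = phys - phys.mean(axis=0)
    cov = centered.T @ centered / len(phys)
    eig = np.sort(np.linalg.eigvalsh(cov))
    minor = 4.0 * np.sqrt(max(eig[0], 0.0))
    major = 4.0 * np.sqrt(max(eig[1], 0.0))

    sphericity = 2.0 * np.sqrt(np.pi * mesh_surface) / perimeter if perimeter > 0 else 0.0
    return {
        "MeshSurface": mesh_surface,
        "PixelSurface": pixel_surface,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface if mesh_surface > 0 else 0.0,
        "Sphericity": sphericity,
        "SphericalDisproportion": 1.0 / sphericity if sphericity > 0 else 0.0,
        "MaximumDiameter": max_diam,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": np.sqrt(eig[0] / eig[1]) if eig[1] > 0 else 1.0,
    }


def _hull_indices(points: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    try:
        return ConvexHull(points).vertices
    except Exception:  # collinear point sets
        return np.arange(len(points))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

_GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees


def _glcm_matrix(levels: np.ndarray, n_levels: int, offset: tuple[int, int]) -> np.ndarray:
    dr, dc = offset
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    return counts + counts.T  # symmetric


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    total = p.sum()
    if total == 0:
        return {name: 0.0 for name in GLCM_NAMES}
    p = p / total
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(ii * p))
    sig2 = float(np.sum(px * (i - mu) ** 2))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    nz = p > 0
    joint_entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxnz = px > 0
    hx = float(-np.sum(px[pxnz] * np.log2(px[pxnz])))
    pxy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * log_pxy))
    hxy2 = float(-np.sum(pxy * log_pxy))

    da = float(np.sum(k_diff * p_diff))
    diff_ent = float(-np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])))
    sum_ent = float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])))

    corr = 1.0
    if sig2 > 0:
        corr = float((np.sum(ii * jj * p) - mu * mu) / sig2)

    imc1 = 0.0
    if max(hx, hx) > 0:
        imc1 = (joint_entropy - hxy1) / hx
    imc2_arg = 1.0 - np.exp(-2.0 * max(hxy2 - joint_entropy, 0.0))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    mcc = 1.0
    present = px > 0
    if present.sum() > 1:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        q = (psub / pxs[:, None]) @ (psub / pxs[:, None]).T
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        q = (psub / pxs[:, None]) @ (psub.T / pxs[:, None])
        eigs = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(eigs[-2], 0.0))) if len(eigs) > 1 else 1.0

    inv_var = 0.0
    off_diag = np.abs(ii - jj) > 0
    if off_diag.any():
        inv_var = float(np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": joint_entropy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": sum_ent,
        "SumSquares": float(np.sum((ii - mu) ** 2 * p)),
    }


def glcm_features(gl: GrayLevelImage) -> dict[str, float]:
    """24 GLCM features: symmetric, distance 1, averaged over the 4 angles."""
    per_angle = []
    for off in _GLCM_OFFSETS:
        counts = _glcm_matrix(gl.levels, gl.n_levels, off)
        if counts.sum() > 0:
            per_angle.append(_glcm_features_single(counts))
    if not per_angle:  # single-pixel ROI: no pairs in any direction
        base = _glcm_features_single(np.ones((gl.n_levels, gl.n_levels)) * 0.0)
        base.update({"Correlation": 1.0, "MCC": 1.0})
        return base
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _lines_for_direction(levels: np.ndarray, direction: tuple[int, int]):
    h, w = levels.shape
    if direction == (0, 1):
        for r in range(h):
            yield levels[r, :]
    elif direction == (1, 0):
        for c in range(w):
            yield levels[:, c]
    elif direction == (1, 1):
        for off in range(-(h - 1), w):
            yield np.diagonal(levels, offset=off)
    elif direction == (1, -1):
        flipped = levels[:, ::-1]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:  # pragma: no cover
        raise ContractError(f"unsupported direction {direction}")


def _glrlm_matrix(levels: np.ndarray, n_levels: int, direction: tuple[int, int]) -> np.ndarray:
    max_len = max(levels.shape)
    counts = np.zeros((n_levels, max_len), dtype=float)
    for line in _lines_for_direction(levels, direction):
        line = np.asarray(line)
        if line.size == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries, [line.size - 1]))
        for s, e in zip(starts, ends):
            lvl = line[s]
            if lvl > 0:
                counts[lvl - 1, e - s] += 1.0
    return counts


def _run_zone_features(counts: np.ndarray, n_pixels: int, prefix: str) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over an (level, size) count matrix."""
    n_runs = counts.sum()
    names = GLRLM_NAMES if prefix == "run" else GLSZM_NAMES
    if n_runs == 0:
        return {name: 0.0 for name in names}
    ng, max_len = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, max_len + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = counts / n_runs
    pg = counts.sum(axis=1)
    pr = counts.sum(axis=0)
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    nz = p > 0
    feats = [
        float(np.sum(counts / jj**2) / n_runs),
        float(np.sum(counts * jj**2) / n_runs),
        float(np.sum(pg**2) / n_runs),
        float(np.sum(pg**2) / n_runs**2),
        float(np.sum(pr**2) / n_runs),
        float(np.sum(pr**2) / n_runs**2),
        float(n_runs / n_pixels),
        float(np.sum(p * (ii - mu_i) ** 2)),
        float(np.sum(p * (jj - mu_j) ** 2)),
        float(-np.sum(p[nz] * np.log2(p[nz]))),
        float(np.sum(counts / ii**2) / n_runs),
        float(np.sum(counts * ii**2) / n_runs),
        float(np.sum(counts / (ii**2 * jj**2)) / n_runs),
        float(np.sum(counts * ii**2 / jj**2) / n_runs),
        float(np.sum(counts * jj**2 / ii**2) / n_runs),
        float(np.sum(counts * ii**2 * jj**2) / n_runs),
    ]
    return dict(zip(names, feats))


def glrlm_features(gl: GrayLevelImage) -> dict[str, float]:
    """16 run-length features over 4 directions, feature values averaged."""
    n_pixels = int(gl.mask.sum())
    per_dir = [
        _run_zone_features(_glrlm_matrix(gl.levels, gl.n_levels, d), n_pixels, "run")
        for d in ((0, 1), (1, 1), (1, 0), (1, -1))
    ]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def _glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    n_pixels = int((levels > 0).sum())
    counts = np.zeros((n_levels, max(n_pixels, 1)), dtype=float)
    structure = np.ones((3, 3), dtype=int)  # 8-connected zones
    for level in range(1, n_levels + 1):
        labeled, n_zones = ndimage.label(levels == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            counts[level - 1, s - 1] += 1.0
    return counts


def glszm_features(gl: GrayLevelImage) -> dict[str, float]:
    """16 size-zone features (8-connected zones, rotation invariant)."""
    n_pixels = int(gl.mask.sum())
    counts = _glszm_matrix(gl.levels, gl.n_levels)
    return _run_zone_features(counts, n_pixels, "zone")


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_matrix(gl: GrayLevelImage, alpha: float = 0.0, delta: int = 1, base: int = 0) -> GLDMMatrix:
    """Dependence counts: for each in-mask pixel, the number of in-mask
    neighbors within Chebyshev distance ``delta`` whose level differs by at
    most ``alpha``; counts accumulated at (level, dependence)."""
    levels = gl.levels
    mask = gl.mask
    dep = np.zeros(levels.shape, dtype=np.int64)
    h, w = levels.shape
    for dr in range(-delta, delta + 1):
        for dc in range(-delta, delta + 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            a = levels[r0:r1, c0:c1]
            b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[r0:r1, c0:c1] += ok
    max_dep = int(dep[mask].max()) if mask.any() else 0
    counts = np.zeros((gl.n_levels, max_dep + 1), dtype=float)
    np.add.at(counts, (levels[mask] - 1, dep[mask]), 1.0)
    return GLDMMatrix(counts=counts, alpha=alpha, delta=delta, base=base)


def gldm_features(m: GLDMMatrix) -> dict[str, float]:
    """14 gray-level dependence features, normalized by total count."""
    counts = m.counts
    total = counts.sum()
    if total == 0:
        raise ContractError("GLDM matrix has zero total count")
    ng, nd = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    d = np.arange(nd, dtype=float) + float(m.base)
    d_inv = np.maximum(d, 1.0)   # keeps 0-based inverse emphases finite
    ii, dd = np.meshgrid(i, d, indexing="ij")
    _, dd_inv = np.meshgrid(i, d_inv, indexing="ij")
    p = counts / total
    pg = counts.sum(axis=1)
    pd = counts.sum(axis=0)
    pgn = pg / total
    pdn = pd / total
    mu_i = float(np.sum(pgn * i))
    mu_d = float(np.sum(pdn * d))
    nz = p > 0
    return {
        "SmallDependenceEmphasis": float(np.sum(counts / dd_inv**2) / total),
        "LargeDependenceEmphasis": float(np.sum(counts * dd**2) / total),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / total),
        "DependenceNonUniformity": float(np.sum(pd**2) / total),
        "DependenceNonUniformityNormalized": float(np.sum(pd**2) / total**2),
        "GrayLevelVariance": float(np.sum(pgn * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(pdn * (d - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
        "LowGrayLevelEmphasis": float(np.sum(pgn / i**2)),
        "HighGrayLevelEmphasis": float(np.sum(pgn * i**2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(counts / (ii**2 * dd_inv**2)) / total),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(counts * ii**2 / dd_inv**2) / total),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(counts * dd**2 / ii**2) / total),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(counts * ii**2 * dd**2) / total),
    }


# ---------------------------------------------------------------------------
# wavelet decomposition
# ---------------------------------------------------------------------------

def wavelet_decompose(image: np.ndarray | MIPImage, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated 2D wavelet transform; sub-bands keep the
    raster size so ROI masks apply unchanged.  Band naming: first letter =
    row-axis filter, second = column-axis filter (L = lowpass, H = highpass).
    """
    arr = image.pixels if isinstance(image, MIPImage) else np.asarray(image, dtype=float)
    if min(arr.shape) < 8:
        raise ContractError("image must be at least 8x8 for the wavelet transform")
    pad_r = arr.shape[0] % 2
    pad_c = arr.shape[1] % 2
    padded = np.pad(arr, ((0, pad_r), (0, pad_c)), mode="reflect")
    (ll, (lh, hl, hh)), = pywt.swt2(padded, wavelet, level=1, norm=True)
    h, w = arr.shape
    return {"LL": ll[:h, :w], "LH": lh[:h, :w], "HL": hl[:h, :w], "HH": hh[:h, :w]}


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _texture_features(channel: np.ndarray, mask: np.ndarray, cfg: RadiomicsConfig) -> dict[str, float]:
    gl = discretize(channel, mask, cfg.bin_width)
    out = {}
    out.update({f"glcm_{k}": v for k, v in glcm_features(gl).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(gl).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(gl).items()})
    gldm = gldm_features(gldm_matrix(gl, cfg.gldm_alpha, cfg.gldm_delta, cfg.dependence_base))
    out.update({f"gldm_{k}": v for k, v in gldm.items()})
    return out


def feature_names(roi_type: str) -> tuple[str, ...]:
    """The deterministic feature order for a tumor (455) or vessel (99) ROI."""
    names = [f"original_shape2D_{n}" for n in SHAPE2D_NAMES]
    channels = ["original"]
    if roi_type == "tumor":
        channels += [f"wavelet-{b}" for b in WAVELET_BANDS]
    elif roi_type != "vessel":
        raise ContractError(f"roi_type must be 'tumor' or 'vessel', got {roi_type!r}")
    for ch in channels:
        names += [f"{ch}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        names += [f"{ch}_glcm_{n}" for n in GLCM_NAMES]
        names += [f"{ch}_glrlm_{n}" for n in GLRLM_NAMES]
        names += [f"{ch}_glszm_{n}" for n in GLSZM_NAMES]
        names += [f"{ch}_gldm_{n}" for n in GLDM_NAMES]
    return tuple(names)


def extract_feature_vector(
    mip: MIPImage,
    mask: BinaryMask,
    roi_type: str,
    config: RadiomicsConfig | None = None,
) -> FeatureVector:
    """Extract the full ordered feature vector for one ROI.

    Tumor ROIs: 455 features (shape + 5 channels of first-order + texture);
    vessel ROIs: 99 (original channel only).  Both counts are asserted on
    every call.
    """
    cfg = config or RadiomicsConfig()
    if mask.is_empty:
        raise ContractError("ROI mask is empty")
    if mip.shape != mask.shape:
        raise ContractError("image and mask must share the raster")

    # crop to the mask bounding box (plus margin) for texture speed; the
    # wavelet transform runs on the full image first, then is cropped too.
    rows, cols = np.nonzero(mask.pixels)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub_mask = mask.pixels[r0:r1, c0:c1]

    channels: dict[str, np.ndarray] = {"original": mip.pixels[r0:r1, c0:c1]}
    if roi_type == "tumor":
        bands = wavelet_decompose(mip.pixels, cfg.wavelet)
        for b in WAVELET_BANDS:
            channels[f"wavelet-{b}"] = bands[b][r0:r1, c0:c1]

    values: dict[str, float] = {}
    shape = shape2d_features(mask.pixels, mip.pixel_spacing)
    values.update({f"original_shape2D_{k}": v for k, v in shape.items()})
    for ch_name, ch in channels.items():
        fo = first_order_features(ch, sub_mask, cfg.bin_width, mip.pixel_spacing)
        values.update({f"{ch_name}_firstorder_{k}": v for k, v in fo.items()})
        tex = _texture_features(ch, sub_mask, cfg)
        values.update({f"{ch_name}_{k}": v for k, v in tex.items()})

    names = feature_names(roi_type)
    expected = 455 if roi_type == "tumor" else 99
    if len(names) != expected or set(names) != set(values):
        raise ContractError(
            f"feature-count contract violated: built {len(values)} values for "
            f"{len(names)} names (expected {expected})"
        )
    return FeatureVector(names=names, values=np.array([values[n] for n in names]))
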