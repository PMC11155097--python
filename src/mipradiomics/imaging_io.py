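"""I/O and basic image algebra for DCE-MRI volumes, MIPs and masks.

Volumes are kept in ``(slice, row, col)`` axis order with 0-based indexing;
the axial maximum intensity projection (MIP) reduces axis 0.  Intensities stay
in native arbitrary units — normalization happens only at feature scaling.
Only the pre-contrast and *first* post-contrast phases are consumed: the first
post-contrast subtraction MIP shows the greatest lesion conspicuity and the
best angiographic effect, which is why the vessel analysis runs on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "MaskRole",
    "DCESeries",
    "MIPImage",
    "BinaryMask",
    "load_volume",
    "save_volume",
    "compute_subtraction",
    "compute_axial_mip",
    "read_mask",
    "write_mask",
    "load_mip",
    "save_mip",
]


class MaskRole(str, Enum):
    BREAST = "breast"
    LATERAL_BREAST = "lateral_breast"
    TUMOR = "tumor"
    VESSEL = "vessel"


@dataclass
class DCESeries:
    """Pre-contrast and first post-contrast volumes of one case."""

    pre_volume: np.ndarray
    post_volume: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""

    def __post_init__(self):
        self.pre_volume = np.asarray(self.pre_volume, dtype=float)
        self.post_volume = np.asarray(self.post_volume, dtype=float)
        if self.pre_volume.shape != self.post_volume.shape:
            raise ContractError(
                f"pre/post shapes differ: {self.pre_volume.shape} vs {self.post_volume.shape}"
            )
        if self.pre_volume.ndim != 3:
            raise ContractError("volumes must be 3D (slice, row, col)")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ContractError(f"voxel spacing must be positive, got {self.voxel_spacing}")


@dataclass
class MIPImage:
    """2D axial maximum intensity projection (non-negative, finite)."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    case_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ContractError("MIP must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ContractError("MIP contains non-finite values")
        if np.any(self.pixels < 0):
            raise ContractError("MIP contains negative values")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ContractError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean raster on the MIP grid with a semantic role."""

    pixels: np.ndarray
    role: MaskRole = MaskRole.TUMOR
    case_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ContractError("mask must be 2D")
        self.role = MaskRole(self.role)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def load_volume(path, format: str = "nifti"):
    """Load a 3D volume; returns ``(array, (dz, dy, dx) spacing)``.

    The array is returned in (slice, row, col) order.  NIfTI data (stored
    i, j, k = col, row, slice) is transposed accordingly.  Negative spacing
    signs in the affine are normalized to absolute values with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    raise ContractError(f"unknown volume format {format!r}")


def _load_nifti(path: Path):
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
    except Exception as exc:  # pragma: no cover - nibabel raises varied types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[:, :, np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    diag = np.diag(img.affine)[:3]
    signed = zooms * np.sign(np.where(diag == 0, 1.0, diag))
    if np.any(signed < 0):
        logger.warning("%s: negative spacing in affine, normalized to absolute values", path)
    spacing_xyz = np.abs(zooms)
    # (x, y, z) -> (slice, row, col)
    volume = np.transpose(data, (2, 1, 0))
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    if any(s <= 0 for s in spacing):
        raise FormatError(f"non-positive voxel spacing in {path}: {spacing}")
    return volume, spacing


def _load_dicom_dir(path: Path):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise IOError(f"no files in DICOM directory {path}")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception as exc:
            raise IOError(f"could not read DICOM file {f}: {exc}") from exc

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets])
    pixel_spacings = {tuple(float(v) for v in getattr(ds, "PixelSpacing", (1.0, 1.0))) for ds in datasets}
    if len(pixel_spacings) != 1:
        raise FormatError("inconsistent in-plane PixelSpacing across slices")
    dy, dx = pixel_spacings.pop()
    if len(datasets) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise FormatError("duplicate or non-increasing slice positions")
        if gaps.max() - gaps.min() > 1e-3 * max(gaps.mean(), 1e-12):
            raise FormatError(
                f"inconsistent slice spacing (gaps {gaps.min():.4g}..{gaps.max():.4g}); "
                "a slice may be missing"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    volume = np.stack([ds.pixel_array.astype(float) for ds in datasets], axis=0)
    return volume, (dz, float(dy), float(dx))


def save_volume(volume: np.ndarray, spacing, path) -> None:
    """Write a (slice, row, col) volume as NIfTI with the given (dz, dy, dx)."""
    import nibabel as nib

    volume = np.asarray(volume, dtype=float)
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    # (slice, row, col) -> (x, y, z) storage order
    nib.save(nib.Nifti1Image(np.transpose(volume, (2, 1, 0)), affine), str(path))


# ---------------------------------------------------------------------------
# subtraction and MIP
# ---------------------------------------------------------------------------

def compute_subtraction(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Voxelwise post − pre enhancement, negatives clamped to 0."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ContractError(f"shape mismatch: {pre.shape} vs {post.shape}")
    return np.clip(post - pre, 0.0, None)


def compute_axial_mip(volume: np.ndarray, spacing=None, case_id: str = "") -> MIPImage:
    """Pixelwise maximum along the slice axis of a (slice, row, col) volume."""
    volume = np.asarray(volume, dtype=float)
    if volume.size == 0 or volume.ndim != 3:
        raise ContractError("volume must be a non-empty 3D array")
    pixel_spacing = (1.0, 1.0) if spacing is None else (float(spacing[-2]), float(spacing[-1]))
    return MIPImage(volume.max(axis=0), pixel_spacing=pixel_spacing, case_id=case_id)


# ---------------------------------------------------------------------------
# 2D masks and MIP files
# ---------------------------------------------------------------------------

def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def read_mask(path, role=MaskRole.TUMOR, case_id: str = "", expected_shape=None) -> BinaryMask:
    """Read a 2D mask (NIfTI or PNG); any nonzero pixel becomes True."""
    path = Path(path)
    if _is_nifti(path):
        arr, _ = _load_nifti(path)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise FormatError(f"mask {path} is not 2D after squeeze")
        # stored as (slice=1, row, col) -> already (row, col) after squeeze
        pixels = arr != 0
    else:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(str(path))) != 0
        if pixels.ndim == 3:  # collapse any color channels
            pixels = pixels.any(axis=-1)
    mask = BinaryMask(pixels, role=role, case_id=case_id)
    if expected_shape is not None and tuple(mask.shape) != tuple(expected_shape):
        raise ContractError(f"mask shape {mask.shape} != expected {tuple(expected_shape)}")
    if mask.is_empty and MaskRole(role) is MaskRole.VESSEL:
        logger.warning("%s: all-zero vessel mask accepted (vessel absent)", path)
    return mask


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as 0/1 values: 8-bit PNG or NIfTI by extension."""
    path = Path(path)
    data = mask.pixels.astype(np.uint8)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.transpose(data[np.newaxis], (2, 1, 0)), np.eye(4)), str(path))
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), data)


def load_mip(path, case_id: str = "") -> MIPImage:
    """Read a 2D MIP from NIfTI, PNG (8/16-bit) or 16-bit TIFF."""
    path = Path(path)
    if _is_nifti(path):
        arr, spacing = _load_nifti(path)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise FormatError(f"MIP {path} is not 2D")
        return MIPImage(arr, pixel_spacing=(spacing[1], spacing[2]), case_id=case_id)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    return MIPImage(np.asarray(arr, dtype=float), case_id=case_id)


def save_mip(mip: MIPImage, path) -> None:
    """Write a MIP: NIfTI (float), 16-bit TIFF or 16-bit PNG by extension."""
    path = Path(path)
    if _is_nifti(path):
        dy, dx = mip.pixel_spacing
        save_volume(mip.pixels[np.newaxis], (1.0, dy, dx), path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), np.clip(np.round(mip.pixels), 0, 65535).astype(np.uint16))
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), np.clip(np.round(mip.pixels), 0, 65535).astype(np.uint16))
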