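"""Image-volume data model, NIfTI I/O and grid preprocessing.

Volumes are 3-D scalar grids indexed ``(i, j, k)`` with axis-aligned
world coordinates: ``world = origin + index * spacing`` (mm).  CT-like
volumes carry Hounsfield units; MR volumes carry arbitrary magnitudes.
Oblique orientations are not supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class Modality(str, Enum):
    CT = "CT"
    MR_WATER = "MR_WATER"
    MR_FAT = "MR_FAT"
    MR_IP = "MR_IP"
    MR_OP = "MR_OP"
    SCT = "SCT"
    LABEL = "LABEL"
    MASK = "MASK"


#: Hounsfield clamp applied to CT-like data on ingest; guards the 300 HU
#: bone-candidate rule and histogram metrics against scanner padding values.
HU_CLAMP = (-1100.0, 3100.0)

#: Out-of-support fill value per modality family (air-equivalent for CT).
CT_FILL = -1000.0
MR_FILL = 0.0


def fill_value(modality: Modality) -> float:
    if modality in (Modality.CT, Modality.SCT):
        return CT_FILL
    return MR_FILL


class VolumeFormatError(ValueError):
    """Raised for malformed volume files or invalid grid metadata."""


@dataclass
class ImageVolume:
    """3-D scalar image with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"volume data must be 3-D with positive dims, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        """New volume on the same grid with replaced voxel data."""
        return replace(self, data=data, modality=modality or self.modality)

    def clamp_hu(self) -> "ImageVolume":
        """Clamp CT-like intensities into the supported HU range."""
        if self.modality not in (Modality.CT, Modality.SCT):
            return self
        return self.with_data(np.clip(self.data, *HU_CLAMP))


@dataclass
class MDixonSet:
    """The four co-registered mDixon channels on one shared grid."""

    water: ImageVolume
    fat: ImageVolume
    ip: ImageVolume
    op: ImageVolume

    def __post_init__(self) -> None:
        for name in ("fat", "ip", "op"):
            vol = getattr(self, name)
            if not self.water.same_grid(vol):
                raise VolumeFormatError(f"mDixon channel {name} is not on the water grid")

    @property
    def channels(self) -> tuple[ImageVolume, ImageVolume, ImageVolume, ImageVolume]:
        return (self.water, self.fat, self.ip, self.op)


@dataclass
class ROIMask:
    """Boolean mask on an image grid, e.g. a body outline or an organ ROI."""

    mask: np.ndarray
    label: str = "roi"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise VolumeFormatError("ROI mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing))

    def to_volume(self) -> ImageVolume:
        return ImageVolume(
            self.mask.astype(np.uint8), self.spacing, self.origin, Modality.MASK
        )

    @staticmethod
    def from_volume(vol: ImageVolume, label: str = "roi") -> "ROIMask":
        return ROIMask(vol.data > 0.5, label, vol.spacing, vol.origin)


@dataclass
class GridSpec:
    """Target grid for resampling: shape, spacing and origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(n < 1 for n in self.shape):
            raise VolumeFormatError(f"degenerate target shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"target spacing must be positive, got {self.spacing}")

    @staticmethod
    def of(vol: ImageVolume) -> "GridSpec":
        return GridSpec(vol.shape, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, modality: Modality | None = None) -> ImageVolume:
    """Read a NIfTI volume; spacing/origin come from the header.

    The modality tag is taken (in order of precedence) from the argument,
    from a sidecar JSON written by :func:`write_volume`, else defaults to CT.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if modality is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            modality = Modality(meta.get("modality", "CT"))
        else:
            modality = Modality.CT
    return ImageVolume(data, tuple(float(z) for z in zooms), origin, modality)


def write_volume(
    vol: ImageVolume, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a NIfTI with a sidecar JSON recording modality and provenance.

    Data, spacing and origin round-trip exactly through
    :func:`read_volume` (no rescale slope/intercept is applied).
    """
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    img.header.set_zooms(vol.spacing)
    # disable scaling so integer/float HU values survive bit-exactly
    img.header["scl_slope"] = 1.0
    img.header["scl_inter"] = 0.0
    nib.save(img, str(path))
    meta = {"modality": vol.modality.value}
    if provenance:
        meta["provenance"] = provenance
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_field(vectors_mm: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a displacement field as a 4-D vector NIfTI (mm components)."""
    affine = np.diag(list(grid.spacing) + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(vectors_mm, dtype=np.float32), affine), str(path))


def read_field(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 3:
        raise VolumeFormatError(f"{path}: expected a 4-D 3-vector field, got {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, GridSpec(data.shape[:3], zooms, origin)


# ---------------------------------------------------------------------------
# Grid operations


def resample_to_grid(
    vol: ImageVolume, target: GridSpec, interpolation: str = "linear"
) -> ImageVolume:
    """Resample a volume onto a target grid.

    Linear interpolation for intensities, nearest for labels/masks.
    Voxels outside the source support take the modality fill value
    (CT/sCT: -1000 HU, MR: 0, labels/masks: 0).
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    if vol.modality in (Modality.LABEL, Modality.MASK):
        cval = 0.0
    else:
        cval = fill_value(vol.modality)
    idx = [
        (target.origin[a] + np.arange(target.shape[a]) * target.spacing[a] - vol.origin[a])
        / vol.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), coords, order=order, mode="constant", cval=cval
    )
    if np.issubdtype(vol.data.dtype, np.integer) and order == 0:
        out = out.astype(vol.data.dtype)
    return ImageVolume(out, target.spacing, target.origin, vol.modality)


def crop_axial(vol: ImageVolume, k0: int, k1: int) -> ImageVolume:
    """Keep axial slices ``[k0, k1)``; origin shifts by ``k0 * spacing_k``."""
    nk = vol.shape[2]
    if not (0 <= k0 < k1 <= nk):
        raise ValueError(f"invalid slice range [{k0}, {k1}) for {nk} slices")
    origin = (vol.origin[0], vol.origin[1], vol.origin[2] + k0 * vol.spacing[2])
    return ImageVolume(vol.data[:, :, k0:k1].copy(), vol.spacing, origin, vol.modality)


class EmptyMaskError(ValueError):
    """Raised when body extraction finds nothing above threshold."""


def body_mask(vol: ImageVolume, ct_threshold_hu: float = -400.0) -> ROIMask:
    """Extract the body outline as the largest connected component.

    CT/sCT volumes are thresholded at ``ct_threshold_hu``; MR in-phase
    volumes at an automatic Otsu threshold.  The largest 3-D connected
    component is kept and holes are filled slice-wise, so interior gas
    pockets end up inside the mask while exterior air is excluded.
    """
    data = np.asarray(vol.data, dtype=float)
    if vol.modality in (Modality.CT, Modality.SCT):
        fg = data > ct_threshold_hu
    elif vol.modality == Modality.MR_IP:
        from skimage.filters import threshold_otsu

        fg = data > threshold_otsu(data)
    else:
        raise ValueError(f"body_mask expects CT/SCT or MR_IP, got {vol.modality}")
    if not fg.any():
        raise EmptyMaskError("no voxels above the body threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
    filled = np.empty_like(fg)
    for k in range(fg.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    return ROIMask(filled, "body", vol.spacing, vol.origin)
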