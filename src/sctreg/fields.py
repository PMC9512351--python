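"""Dense displacement fields and backward warping.

A field lives on the *fixed* grid and stores one 3-vector per voxel in
mm.  Warping uses the backward convention: the warped image at fixed
voxel position ``x`` samples the moving image at ``x + u(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import GridSpec, ImageVolume, Modality, ROIMask, fill_value, read_field, write_field


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on a fixed image grid."""

    vectors: np.ndarray  # (ni, nj, nk, 3), mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError(f"field must be (ni,nj,nk,3), got {self.vectors.shape}")
        if not np.isfinite(self.vectors).all():
            raise ValueError("field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    @staticmethod
    def zero(grid: GridSpec) -> "DisplacementField":
        return DisplacementField(
            np.zeros(tuple(grid.shape) + (3,)), grid.spacing, grid.origin
        )

    def negated(self) -> "DisplacementField":
        return DisplacementField(-self.vectors, self.spacing, self.origin)

    def save(self, path: str | Path) -> None:
        write_field(self.vectors, self.grid, path)

    @staticmethod
    def load(path: str | Path) -> "DisplacementField":
        vectors, grid = read_field(path)
        return DisplacementField(vectors, grid.spacing, grid.origin)


def warp_image(
    moving: ImageVolume, field: DisplacementField, interpolation: str = "linear"
) -> ImageVolume:
    """Backward-warp ``moving`` by ``field``: out(x) = moving(x + u(x)).

    Output lives on the field's grid.  Samples outside the moving
    support take the modality fill value.
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    cval = 0.0 if moving.modality in (Modality.LABEL, Modality.MASK) else fill_value(moving.modality)
    idx = np.meshgrid(
        *[np.arange(n, dtype=float) for n in field.shape], indexing="ij"
    )
    coords = []
    for a in range(3):
        world = field.origin[a] + idx[a] * field.spacing[a] + field.vectors[..., a]
        coords.append((world - moving.origin[a]) / moving.spacing[a])
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), coords, order=order, mode="constant", cval=cval
    )
    if np.issubdtype(moving.data.dtype, np.integer) and order == 0:
        out = out.astype(moving.data.dtype)
    return ImageVolume(out, field.spacing, field.origin, moving.modality)


def warp_mask(mask: ROIMask, field: DisplacementField) -> ROIMask:
    """Nearest-neighbour warp of a boolean ROI mask."""
    vol = mask.to_volume()
    warped = warp_image(vol, field, interpolation="nearest")
    return ROIMask(warped.data > 0.5, mask.label, warped.spacing, warped.origin)
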