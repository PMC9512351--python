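"""Paired CT + mDixon abdominopelvic phantoms with known ground truth.

The generator rasterizes an analytic body: an elliptical trunk with a
subcutaneous fat ring, two kidneys wrapped in perirenal fat, a bony
spine, femoral-head analogs, a bladder and a rectum tube (both with
pelvic-fat shells) and interior gas pockets.  Each voxel belongs to
exactly one of five classes (background air, interior air cavity, fat,
soft tissue, bone).  CT values are piecewise-constant Hounsfield units
plus Gaussian noise; the four mDixon channels follow per-class
water/fat signal fractions with the in-phase channel ``water + fat``
and the opposed-phase channel ``|water - fat|``, so the fat/soft
interfaces show the phase-cancellation dark line that real Dixon
imaging exhibits.  A misaligned "second scanner" acquisition is
emulated by warping with a known smooth, invertibility-checked
deformation.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, warp_image, warp_mask
from .metrics import jacobian_determinant
from .volumes import GridSpec, HU_CLAMP, ImageVolume, MDixonSet, Modality, ROIMask

# Tissue classes, in the fixed order used throughout the package.
BACKGROUND_AIR, AIR_CAVITY, FAT, SOFT, BONE = 0, 1, 2, 3, 4
CLASS_NAMES = ("background_air", "air_cavity", "fat", "soft", "bone")

#: Default piecewise-constant CT values (HU) and noise sd per class.
DEFAULT_HU_TABLE = {
    "background_air": (-1000.0, 20.0),
    "air_cavity": (-1000.0, 20.0),
    "fat": (-100.0, 20.0),
    "soft": (40.0, 20.0),
    "bone": (700.0, 20.0),
}

#: (water fraction, fat fraction) of the maximum MR magnitude per class.
#: Bone and air are both dark, which is what makes them hard to separate
#: from MR alone and exercises the CT-corrected classifier stage.
DEFAULT_MR_SIGNAL_TABLE = {
    "background_air": (0.0, 0.0),
    "air_cavity": (0.0, 0.0),
    "fat": (0.10, 0.90),
    "soft": (0.85, 0.10),
    "bone": (0.20, 0.05),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject."""

    shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 5.0)
    seed: int = 0
    hu_table: dict = dc_field(default_factory=lambda: dict(DEFAULT_HU_TABLE))
    mr_signal_table: dict = dc_field(default_factory=lambda: dict(DEFAULT_MR_SIGNAL_TABLE))
    mr_scale: float = 1000.0
    ct_noise_sd: float | None = None  # overrides hu_table sigmas when set
    mr_noise_sd: float = 50.0

    def noiseless(self) -> "PhantomSpec":
        spec = PhantomSpec(
            shape=self.shape,
            spacing=self.spacing,
            seed=self.seed,
            hu_table={k: (mu, 0.0) for k, (mu, _) in self.hu_table.items()},
            mr_signal_table=dict(self.mr_signal_table),
            mr_scale=self.mr_scale,
            ct_noise_sd=0.0,
            mr_noise_sd=0.0,
        )
        return spec

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing)


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: labels, ROI masks, optional field."""

    labels: ImageVolume
    rois: list[ROIMask]
    true_field: DisplacementField | None = None

    def body(self) -> ROIMask:
        return ROIMask(
            self.labels.data != BACKGROUND_AIR,
            "body",
            self.labels.spacing,
            self.labels.origin,
        )

    def roi(self, label: str) -> ROIMask:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Analytic shapes (world coordinates normalized to the grid extent)


def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * s - n * s / 2.0
        for n, s in zip(spec.shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _cylinder_z(x, y, z, center_xy, radius, z0, z1) -> np.ndarray:
    return (
        (((x - center_xy[0]) / radius) ** 2 + ((y - center_xy[1]) / radius) ** 2) <= 1.0
    ) & (z >= z0) & (z <= z1)


def make_labels(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize the organ set into a single-class-per-voxel label map.

    Organ positions and sizes carry a small seed-dependent anatomical
    jitter (a few percent of the grid extent) so that differently
    seeded phantoms are genuinely different subjects, not just noise
    realizations.  Organs are clipped to the soft-tissue interior of
    the body, mirroring how anatomy is bounded by the body wall.
    """
    x, y, z = _coords_mm(spec)
    ext = [n * s for n, s in zip(spec.shape, spec.spacing)]
    zmin, zmax = z.min(), z.max()
    zspan = zmax - zmin
    rng = np.random.default_rng(spec.seed + 13)

    def jc() -> float:  # center jitter, fraction of extent
        return float(rng.uniform(-0.015, 0.015))

    def js() -> float:  # size jitter, multiplicative
        return float(rng.uniform(0.94, 1.06))

    body_semi = (0.38 * js() * ext[0], 0.30 * js() * ext[1])
    body = ((x / body_semi[0]) ** 2 + (y / body_semi[1]) ** 2) <= 1.0
    inner = ((x / (0.86 * body_semi[0])) ** 2 + (y / (0.86 * body_semi[1])) ** 2) <= 1.0

    labels = np.full(spec.shape, BACKGROUND_AIR, dtype=np.int16)
    labels[body] = FAT          # subcutaneous ring ...
    labels[inner] = SOFT        # ... surrounding the soft-tissue interior

    def paint(mask: np.ndarray, cls: int, name: str) -> np.ndarray:
        mask = mask & inner  # organs stay inside the body wall
        if not mask.any():
            raise ValueError(f"organ '{name}' fell outside the body interior")
        labels[mask] = cls
        return mask

    # kidneys with perirenal fat shells
    kid_semi = (0.07 * js() * ext[0], 0.055 * js() * ext[1], 0.16 * js() * zspan)
    kid_z = zmin + (0.62 + jc()) * zspan
    rois: list[ROIMask] = []
    for side, name in ((-1, "right_kidney"), (+1, "left_kidney")):
        c = ((side * 0.17 + jc()) * ext[0], (0.04 + jc()) * ext[1], kid_z)
        shell = _ellipsoid(x, y, z, c, tuple(1.45 * np.asarray(kid_semi)))
        paint(shell, FAT, name + "_fat")
        organ = paint(_ellipsoid(x, y, z, c, kid_semi), SOFT, name)
        rois.append(ROIMask(organ, name, spec.spacing))

    # bony spine, posterior midline, full axial span
    paint(
        _cylinder_z(x, y, z, (jc() * ext[0], (0.17 + jc()) * ext[1]),
                    0.065 * js() * ext[0], zmin, zmax),
        BONE, "spine",
    )

    # femoral-head analogs (bone spheres, inferior slices)
    fem_r = 0.055 * js() * ext[0]
    fem_z = zmin + (0.14 + jc()) * zspan
    for side, name in ((-1, "right_femoral_head"), (+1, "left_femoral_head")):
        c = ((side * 0.24 + jc()) * ext[0], (0.02 + jc()) * ext[1], fem_z)
        organ = paint(_ellipsoid(x, y, z, c, (fem_r, fem_r, fem_r)), BONE, name)
        rois.append(ROIMask(organ, name, spec.spacing))

    # bladder (soft sphere in pelvic fat); bladder filling varies a lot
    # between scan sessions, so its size jitter is the largest
    bl_c = (jc() * ext[0], (-0.12 + jc()) * ext[1], zmin + (0.18 + jc()) * zspan)
    bl_r = 0.085 * float(rng.uniform(0.85, 1.15)) * ext[0]
    paint(_ellipsoid(x, y, z, bl_c, (1.35 * bl_r,) * 3), FAT, "bladder_fat")
    organ = paint(_ellipsoid(x, y, z, bl_c, (bl_r,) * 3), SOFT, "bladder")
    rois.append(ROIMask(organ, "bladder", spec.spacing))

    # rectum tube (soft wall in fat, gas-filled lumen)
    re_xy = (jc() * ext[0], (0.06 + jc()) * ext[1])
    re_z0, re_z1 = zmin + 0.05 * zspan, zmin + (0.32 + jc()) * zspan
    paint(_cylinder_z(x, y, z, re_xy, 0.055 * ext[0], re_z0, re_z1), FAT, "rectum_fat")
    tube = paint(_cylinder_z(x, y, z, re_xy, 0.04 * ext[0], re_z0, re_z1),
                 SOFT, "rectum")
    lumen = paint(_cylinder_z(x, y, z, re_xy, 0.018 * ext[0], re_z0, re_z1),
                  AIR_CAVITY, "rectal_gas")
    rois.append(ROIMask(tube & ~lumen, "rectum", spec.spacing))

    # lung bases at the superior end of the field of view
    for side in (-1, +1):
        c = ((side * 0.16 + jc()) * ext[0], (-0.06 + jc()) * ext[1],
             zmax + 0.04 * zspan)
        paint(
            _ellipsoid(x, y, z, c,
                       (0.12 * js() * ext[0], 0.11 * js() * ext[1],
                        0.22 * js() * zspan)) & (z <= zmax),
            AIR_CAVITY, "lung_base",
        )

    # bowel-gas pockets
    for cx, cy, cz, r in (
        (-0.12, -0.10, 0.55, 0.06),
        (0.10, -0.06, 0.45, 0.05),
        (0.0, -0.13, 0.62, 0.045),
    ):
        paint(
            _ellipsoid(
                x, y, z,
                ((cx + jc()) * ext[0], (cy + jc()) * ext[1],
                 zmin + (cz + jc()) * zspan),
                (r * js() * ext[0],) * 3,
            ),
            AIR_CAVITY, "gas_pocket",
        )

    label_vol = ImageVolume(labels, spec.spacing, (0.0, 0.0, 0.0), Modality.LABEL)
    return PhantomTruth(label_vol, rois)


def make_phantom(spec: PhantomSpec) -> tuple[PhantomTruth, ImageVolume, MDixonSet]:
    """Generate ground-truth labels with paired CT and mDixon volumes."""
    truth = make_labels(spec)
    labels = truth.labels.data
    rng = np.random.default_rng(spec.seed)

    hu = np.zeros(spec.shape)
    sd = np.zeros(spec.shape)
    for code, name in enumerate(CLASS_NAMES):
        mu, sigma = spec.hu_table[name]
        if spec.ct_noise_sd is not None:
            sigma = spec.ct_noise_sd
        sel = labels == code
        hu[sel] = mu
        sd[sel] = sigma
    ct_data = hu + sd * rng.standard_normal(spec.shape)
    ct = ImageVolume(np.clip(ct_data, *HU_CLAMP), spec.spacing, (0, 0, 0), Modality.CT)

    wf = np.zeros(spec.shape)
    ff = np.zeros(spec.shape)
    for code, name in enumerate(CLASS_NAMES):
        w, f = spec.mr_signal_table[name]
        sel = labels == code
        wf[sel] = w * spec.mr_scale
        ff[sel] = f * spec.mr_scale
    clean = {"water": wf, "fat": ff, "ip": wf + ff, "op": np.abs(wf - ff)}
    channels = {}
    for name, arr in clean.items():
        noisy = arr + spec.mr_noise_sd * rng.standard_normal(spec.shape)
        channels[name] = np.clip(noisy, 0.0, None)
    mdixon = MDixonSet(
        water=ImageVolume(channels["water"], spec.spacing, (0, 0, 0), Modality.MR_WATER),
        fat=ImageVolume(channels["fat"], spec.spacing, (0, 0, 0), Modality.MR_FAT),
        ip=ImageVolume(channels["ip"], spec.spacing, (0, 0, 0), Modality.MR_IP),
        op=ImageVolume(channels["op"], spec.spacing, (0, 0, 0), Modality.MR_OP),
    )
    return truth, ct, mdixon


# ---------------------------------------------------------------------------
# Ground-truth deformations


def random_smooth_deformation(
    grid: GridSpec,
    amplitude_mm: float,
    smoothness_mm: float,
    seed: int,
    max_halvings: int = 8,
    weight: np.ndarray | None = None,
) -> DisplacementField:
    """Smooth random displacement field with positive Jacobian everywhere.

    White-noise vectors are convolved with an isotropic Gaussian of the
    stated smoothness (mm) and rescaled so the maximum magnitude equals
    ``amplitude_mm``.  An optional ``weight`` in [0, 1] (e.g. a soft
    body mask) tapers the field before rescaling, concentrating the
    deformation where there is anatomy; the weight is blurred with the
    same smoothness so it cannot introduce sharper structure than the
    field itself.  If the Jacobian determinant is not positive at every
    voxel the amplitude is halved and the field rescaled, up to
    ``max_halvings`` times.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(tuple(grid.shape) + (3,))
    sigma_vox = [smoothness_mm / s for s in grid.spacing]
    smooth = np.stack(
        [ndimage.gaussian_filter(noise[..., a], sigma=sigma_vox) for a in range(3)],
        axis=-1,
    )
    if weight is not None:
        w = ndimage.gaussian_filter(np.asarray(weight, float), sigma=sigma_vox)
        wmax = w.max()
        if wmax > 0:
            smooth = smooth * (w / wmax)[..., None]
    mag = np.linalg.norm(smooth, axis=-1).max()
    if amplitude_mm == 0 or mag == 0:
        return DisplacementField.zero(grid)
    base = smooth / mag
    amp = float(amplitude_mm)
    for _ in range(max_halvings + 1):
        field = DisplacementField(base * amp, grid.spacing, grid.origin)
        if jacobian_determinant(field).min > 0:
            return field
        amp /= 2.0
    raise RuntimeError(
        f"could not build an invertible field at amplitude {amplitude_mm} mm"
    )


def deform_phantom(
    truth: PhantomTruth,
    ct: ImageVolume,
    mdixon: MDixonSet,
    field: DisplacementField,
) -> tuple[ImageVolume, MDixonSet, list[ROIMask]]:
    """Warp a phantom by a field, emulating repositioning between scanners.

    Intensity volumes are warped with linear interpolation, ROI masks
    with nearest-neighbour.  The output pair is the misaligned "other
    scanner" acquisition; with backward warping, ``moved(x) =
    original(x + u(x))``, so ``u`` is exactly the field a registration
    with the moved volume as *fixed* image should recover.
    """
    if tuple(field.shape) != tuple(ct.shape):
        raise ValueError("field grid does not match the phantom grid")
    ct_moved = warp_image(ct, field, "linear")
    md_moved = MDixonSet(
        water=warp_image(mdixon.water, field, "linear"),
        fat=warp_image(mdixon.fat, field, "linear"),
        ip=warp_image(mdixon.ip, field, "linear"),
        op=warp_image(mdixon.op, field, "linear"),
    )
    rois_moved = [warp_mask(r, field) for r in truth.rois]
    return ct_moved, md_moved, rois_moved


def warp_labels(truth: PhantomTruth, field: DisplacementField) -> ImageVolume:
    """Nearest-neighbour warp of the label map (for moved-pair truth)."""
    return warp_image(truth.labels, field, "nearest")
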