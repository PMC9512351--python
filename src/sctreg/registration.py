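"""Rigid and block-matching deformable registration.

The deformable algorithm is multiscale block matching: at each pyramid
level the volume is tiled into blocks, each block's displacement is
updated greedily by testing the 27 integer-voxel candidate offsets
{-1, 0, 1}^3 around its current displacement, and the per-block updates
are blended trilinearly into a dense field that is Gaussian-regularized
and accumulated.  The similarity is SSD (minimized; the same-modality
case, e.g. synthetic CT vs measured CT) or per-block joint-histogram
mutual information (maximized; the multimodal case).

Conventions: the fixed image defines the grid; fields are backward
displacements in mm (see :mod:`sctreg.fields`).  The pyramid
downsamples in-plane only, because axial slices are typically much
coarser (5 mm) than the in-plane spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, warp_image
from .volumes import GridSpec, ImageVolume, Modality, fill_value

# 27 candidate offsets; the zero offset first so ties keep the block still.
_OFFSETS = np.array(
    sorted(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
        key=lambda o: (o != (0, 0, 0), o),
    ),
    dtype=int,
)


@dataclass
class RigidTransform:
    """6-parameter transform: Euler rotation about the volume center plus
    translation, both in world mm.

    Rotation order is extrinsic x-y-z: ``R = Rz @ Ry @ Rx`` applied to
    ``x - center``.  Warping is backward: the resampled image at fixed
    position ``x`` reads the moving image at ``R (x - c) + c + t``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    @staticmethod
    def identity(center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform(center=center)


@dataclass
class DIRConfig:
    """Block-matching configuration."""

    levels: int = 3
    block_size: tuple[int, int, int] = (8, 8, 4)
    max_iterations: int = 10
    outer_passes: int = 1  # re-warp + integer-search passes per level
    #: dense-field regularization; the slice-axis sigma is larger because
    #: per-block slice decisions are quantized to the coarse slice
    #: spacing and need averaging over the deformation's smoothness scale
    smoothing_sigma_vox: float | tuple[float, float, float] = (4.0, 4.0, 6.0)
    tolerance_vox: float = 0.01
    similarity: str = "ssd"  # or "mi"
    mi_bins: int = 16
    gate: float = 0.2  # minimum relative improvement to move a block
    refine: bool = True  # extra finest-level pass with half-size blocks

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if any(b < 2 for b in self.block_size):
            raise ValueError("block size must be >= 2 per axis")
        if self.similarity not in ("ssd", "mi"):
            raise ValueError(f"unknown similarity '{self.similarity}'")

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "block_size": list(self.block_size),
            "max_iterations": self.max_iterations,
            "smoothing_sigma_vox": self.smoothing_sigma_vox,
            "tolerance_vox": self.tolerance_vox,
            "similarity": self.similarity,
            "mi_bins": self.mi_bins,
            "gate": self.gate,
        }


# ---------------------------------------------------------------------------
# Rigid registration (joint-histogram MI, derivative-free descent)


def volume_center_mm(vol: ImageVolume) -> tuple[float, float, float]:
    return tuple(
        vol.origin[a] + (vol.shape[a] - 1) * vol.spacing[a] / 2.0 for a in range(3)
    )


def apply_rigid(
    vol: ImageVolume,
    transform: RigidTransform,
    interpolation: str = "linear",
    target: GridSpec | None = None,
) -> ImageVolume:
    """Resample a volume under a rigid transform (backward sampling)."""
    order = {"linear": 1, "nearest": 0}[interpolation]
    grid = target or GridSpec.of(vol)
    R = transform.matrix()
    c = np.asarray(transform.center)
    t = np.asarray(transform.translation)
    Sf = np.diag(grid.spacing)
    Sm_inv = np.diag([1.0 / s for s in vol.spacing])
    M = Sm_inv @ R @ Sf
    b = Sm_inv @ (R @ (np.asarray(grid.origin) - c) + c + t - np.asarray(vol.origin))
    cval = 0.0 if vol.modality in (Modality.LABEL, Modality.MASK) else fill_value(vol.modality)
    out = ndimage.affine_transform(
        np.asarray(vol.data, float), M, offset=b, output_shape=grid.shape,
        order=order, mode="constant", cval=cval,
    )
    return ImageVolume(out, grid.spacing, grid.origin, vol.modality)


def _downsample_inplane(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(data, float)
    ni, nj, nk = data.shape
    ci, cj = (ni // factor) * factor, (nj // factor) * factor
    d = np.asarray(data[:ci, :cj, :], float)
    return d.reshape(ci // factor, factor, cj // factor, factor, nk).mean(axis=(1, 3))


def _mi_from_joint(h: np.ndarray) -> float:
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _overlap_exists(fixed: ImageVolume, moving: ImageVolume) -> bool:
    for a in range(3):
        f0 = fixed.origin[a]
        f1 = f0 + (fixed.shape[a] - 1) * fixed.spacing[a]
        m0 = moving.origin[a]
        m1 = m0 + (moving.shape[a] - 1) * moving.spacing[a]
        if min(f1, m1) < max(f0, m0):
            return False
    return True


def rigid_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    bins: int = 64,
    levels: tuple[int, ...] = (4, 2),
    translation_steps_mm: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0, 0.5),
    rotation_steps_rad: tuple[float, ...] = (0.07, 0.035, 0.018, 0.009),
) -> RigidTransform:
    """Six-parameter rigid alignment maximizing joint-histogram MI.

    Derivative-free coordinate descent with shrinking steps over an
    in-plane pyramid; deterministic given the inputs.  Works for
    same-modality and multimodal pairs alike.
    """
    if not _overlap_exists(fixed, moving):
        raise ValueError("volumes do not overlap; MI undefined on empty overlap")
    center = volume_center_mm(fixed)
    params = np.zeros(6)  # rx, ry, rz, tx, ty, tz

    def _objective(level_fixed: ImageVolume, p: np.ndarray) -> float:
        T = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
        warped = apply_rigid(moving, T, "linear", GridSpec.of(level_fixed))
        x = level_fixed.data.ravel()
        y = warped.data.ravel()
        if x.min() == x.max() or y.min() == y.max():
            return 0.0
        h, _, _ = np.histogram2d(x, y, bins=bins)
        return _mi_from_joint(h)

    for factor in levels:
        lf_data = _downsample_inplane(np.asarray(fixed.data, float), factor)
        lf = ImageVolume(
            lf_data,
            (fixed.spacing[0] * factor, fixed.spacing[1] * factor, fixed.spacing[2]),
            (
                fixed.origin[0] + (factor - 1) / 2.0 * fixed.spacing[0],
                fixed.origin[1] + (factor - 1) / 2.0 * fixed.spacing[1],
                fixed.origin[2],
            ),
            fixed.modality,
        )
        best = _objective(lf, params)
        n_steps = max(len(translation_steps_mm), len(rotation_steps_rad))
        for s in range(n_steps):
            t_step = translation_steps_mm[min(s, len(translation_steps_mm) - 1)]
            r_step = rotation_steps_rad[min(s, len(rotation_steps_rad) - 1)]
            improved = True
            while improved:
                improved = False
                for axis in range(6):
                    step = r_step if axis < 3 else t_step
                    for direction in (+1.0, -1.0):
                        trial = params.copy()
                        trial[axis] += direction * step
                        val = _objective(lf, trial)
                        if val > best + 1e-12:
                            best, params = val, trial
                            improved = True
    return RigidTransform(tuple(params[:3]), tuple(params[3:]), center)


# ---------------------------------------------------------------------------
# Block matching


def _block_reduce_sum(arr: np.ndarray, bs: tuple[int, int, int]) -> np.ndarray:
    nb = [math.ceil(n / b) for n, b in zip(arr.shape, bs)]
    pad = [(0, nb[a] * bs[a] - arr.shape[a]) for a in range(3)]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad, mode="edge")
    return arr.reshape(
        nb[0], bs[0], nb[1], bs[1], nb[2], bs[2]
    ).sum(axis=(1, 3, 5))


def _shift_with_fill(arr: np.ndarray, offset: np.ndarray, cval: float) -> np.ndarray:
    """``out(x) = arr(x + offset)`` with constant fill outside."""
    out = np.full_like(arr, cval)
    src, dst = [], []
    for a, o in enumerate(offset):
        n = arr.shape[a]
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _block_mi_scores(
    fixed_bins: np.ndarray,
    moving_binner,
    warped: np.ndarray,
    offset: np.ndarray,
    block_ids: np.ndarray,
    n_blocks: int,
    bins: int,
    cval: float,
) -> np.ndarray:
    shifted = _shift_with_fill(warped, offset, cval)
    mb = moving_binner(shifted)
    joint = (block_ids * bins + fixed_bins) * bins + mb
    counts = np.bincount(joint.ravel(), minlength=n_blocks * bins * bins)
    counts = counts.reshape(n_blocks, bins, bins).astype(float)
    totals = counts.sum(axis=(1, 2), keepdims=True)
    totals[totals == 0] = 1.0
    p = counts / totals
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    return np.nansum(term, axis=(1, 2))


class _LevelMatcher:
    """Per-level state for the greedy 27-offset block search.

    ``allow_z`` disables slice-axis candidates; the pyramid only
    downsamples in-plane, so coarse levels see the same 5 mm slice
    quantum with less in-plane evidence, and slice-axis search is
    reserved for the finest level.
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        config: DIRConfig,
        allow_z: bool = True,
    ):
        self.fixed = fixed
        self.moving = moving
        self.config = config
        self.allow_z = allow_z
        self.bs = config.block_size
        self.nb = tuple(math.ceil(n / b) for n, b in zip(fixed.shape, self.bs))
        self.cval = fill_value(moving.modality)
        self._inplane_index = {
            (o[0], o[1]): i for i, o in enumerate(_OFFSETS) if o[2] == 0
        }
        if config.similarity == "mi":
            bins = config.mi_bins
            f = np.asarray(fixed.data, float)
            m = np.asarray(moving.data, float)
            f_edges = np.linspace(f.min(), f.max() + 1e-9, bins + 1)
            m_edges = np.linspace(
                min(m.min(), self.cval), m.max() + 1e-9, bins + 1
            )
            pad = [(0, self.nb[a] * self.bs[a] - fixed.shape[a]) for a in range(3)]
            fp = np.pad(f, pad, mode="edge")
            self._pad = pad
            self.fixed_bins = np.clip(
                np.searchsorted(f_edges, fp, side="right") - 1, 0, bins - 1
            )
            self.m_edges = m_edges
            ids = np.arange(int(np.prod(self.nb))).reshape(self.nb)
            self.block_ids = np.repeat(
                np.repeat(np.repeat(ids, self.bs[0], 0), self.bs[1], 1), self.bs[2], 2
            )

    def _bin_moving(self, arr: np.ndarray) -> np.ndarray:
        arr = np.pad(arr, self._pad, mode="edge")
        return np.clip(
            np.searchsorted(self.m_edges, arr, side="right") - 1,
            0,
            self.config.mi_bins - 1,
        )

    def _all_scores(self, warped: np.ndarray) -> np.ndarray:
        fixed = np.asarray(self.fixed.data, float)
        scores = np.empty((len(_OFFSETS), int(np.prod(self.nb))))
        for oi, off in enumerate(_OFFSETS):
            if self.config.similarity == "ssd":
                shifted = _shift_with_fill(warped, off, self.cval)
                d = fixed - shifted
                scores[oi] = _block_reduce_sum(d * d, self.bs).ravel()
            else:
                scores[oi] = -_block_mi_scores(
                    self.fixed_bins, self._bin_moving, warped, off,
                    self.block_ids, int(np.prod(self.nb)),
                    self.config.mi_bins, self.cval,
                )
        return scores

    def best_offsets(self, warped: np.ndarray) -> tuple[np.ndarray, float, float]:
        """Gated greedy offset per block; returns (offsets, score@zero, score@best).

        Scores are aggregate block SSD for the SSD similarity and
        aggregate negative MI for the MI similarity, so lower is always
        better and the zero offset is always among the candidates.  A
        block only moves when the winning offset improves on staying
        put by the configured relative margin, and its slice-axis
        component is kept only when it improves on the corresponding
        in-plane-only offset by the same margin; this keeps blocks
        without structure along an axis (noise, or anatomy invariant
        along the slice direction) from random-walking.
        """
        scores = self._all_scores(warped)
        gate = self.config.gate
        s_zero = scores[0]
        if not self.allow_z:
            scores = np.where(
                (_OFFSETS[:, 2] != 0)[:, None], np.inf, scores
            )
        best_idx = np.argmin(scores, axis=0)
        best = scores[best_idx, np.arange(scores.shape[1])]
        # overall gate vs staying put (relative for SSD, absolute sign-
        # safe margin for negative-MI scores)
        if self.config.similarity == "ssd":
            accept = best < (1.0 - gate) * s_zero
        else:
            accept = best < s_zero - gate * np.abs(s_zero)
        best_idx = np.where(accept, best_idx, 0)
        # slice-axis gate vs the same in-plane offset with dz = 0
        offs = _OFFSETS[best_idx]
        inplane_idx = np.array(
            [self._inplane_index[tuple(o[:2])] for o in offs]
        )
        s_inplane = scores[inplane_idx, np.arange(scores.shape[1])]
        s_best = scores[best_idx, np.arange(scores.shape[1])]
        if self.config.similarity == "ssd":
            keep_z = s_best < (1.0 - gate) * s_inplane
        else:
            keep_z = s_best < s_inplane - gate * np.abs(s_inplane)
        best_idx = np.where(offs[:, 2] == 0, best_idx, np.where(keep_z, best_idx, inplane_idx))
        chosen = scores[best_idx, np.arange(scores.shape[1])]
        offsets = _OFFSETS[best_idx].reshape(self.nb + (3,))
        return offsets, float(s_zero.sum()), float(chosen.sum())


def _blocks_to_dense(block_vals: np.ndarray, bs: tuple[int, int, int],
                     shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear blend of block-center values onto the voxel grid."""
    coords = np.meshgrid(
        *[(np.arange(shape[a]) - (bs[a] - 1) / 2.0) / bs[a] for a in range(3)],
        indexing="ij",
    )
    out = np.empty(shape + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            block_vals[..., c].astype(float), coords, order=1, mode="nearest"
        )
    return out


def _apply_block_shifts(
    arr: np.ndarray, block_disp: np.ndarray, bs: tuple[int, int, int], cval: float
) -> np.ndarray:
    """Shift every voxel by its block's integer displacement (exact gather)."""
    shape = arr.shape
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    gathered = []
    valid = np.ones(shape, dtype=bool)
    for a in range(3):
        per_voxel = np.repeat(
            np.repeat(np.repeat(block_disp[..., a], bs[0], 0), bs[1], 1), bs[2], 2
        )[: shape[0], : shape[1], : shape[2]]
        target = idx[a] + per_voxel
        valid &= (target >= 0) & (target < shape[a])
        gathered.append(np.clip(target, 0, shape[a] - 1))
    out = arr[tuple(gathered)]
    out[~valid] = cval
    return out


def _parabolic_subvoxel(
    matcher: "_LevelMatcher", warped: np.ndarray, block_disp: np.ndarray
) -> np.ndarray:
    """Per-axis quadratic fit of the block score around the integer optimum.

    Fits ``s(-1), s(0), s(+1)`` along each axis and returns the vertex
    offset clipped to half a voxel; zero wherever the fit is not convex.
    """
    scores = matcher._all_scores(warped)
    lut = {tuple(o): i for i, o in enumerate(_OFFSETS)}
    s0 = scores[lut[(0, 0, 0)]]
    frac = np.zeros(block_disp.shape)
    for a in range(3):
        if a == 2 and not matcher.allow_z:
            continue
        minus = np.zeros(3, int)
        minus[a] = -1
        plus = -minus
        sm = scores[lut[tuple(minus)]]
        sp = scores[lut[tuple(plus)]]
        denom = sm - 2.0 * s0 + sp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (sm - sp) / denom
            # predicted improvement at the vertex; must clear the same
            # relative gate as the integer search and stay physical
            # (no more than the whole current score), so an exact
            # minimum (e.g. identical images) is never perturbed
            gain = 0.125 * (sm - sp) ** 2 / np.abs(denom)
        ok = (
            (denom > 0)
            & np.isfinite(delta)
            & (gain > matcher.config.gate * np.abs(s0))
            & (gain <= np.abs(s0))
        )
        delta = np.where(ok, delta, 0.0)
        frac[..., a] = np.clip(delta, -0.5, 0.5).reshape(block_disp.shape[:3])
    return frac


def block_match_dir(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: DIRConfig | None = None,
    return_trace: bool = False,
):
    """Multiscale block-matching deformable registration.

    Returns the backward displacement field (mm, on the fixed grid) that
    maps the fixed image's coordinates into the moving image.  With
    ``return_trace`` a per-iteration convergence log is also returned.

    Per level, the moving image is first warped by the field carried
    over from the coarser level; block displacements for the residual
    are integer-valued state, advanced greedily by the gated 27-offset
    search and evaluated by exact integer shifts, so the search cannot
    creep through interpolation effects.  After the integer search
    settles, a per-axis quadratic fit of the block scores supplies the
    sub-voxel fraction, and the block field is blended trilinearly and
    Gaussian-smoothed into the dense residual.
    """
    config = config or DIRConfig()
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed and moving must share a grid; resample first")
    if np.ptp(np.asarray(fixed.data, float)) == 0:
        import warnings

        warnings.warn("fixed image is constant; returning a zero field")
        f = DisplacementField.zero(GridSpec.of(fixed))
        return (f, []) if return_trace else f

    trace: list[dict] = []
    field_mm = None
    for level in range(config.levels - 1, -1, -1):
        factor = 2**level
        lf_data = _downsample_inplane(np.asarray(fixed.data, float), factor)
        lm_data = _downsample_inplane(np.asarray(moving.data, float), factor)
        spacing = (fixed.spacing[0] * factor, fixed.spacing[1] * factor, fixed.spacing[2])
        origin = (
            fixed.origin[0] + (factor - 1) / 2.0 * fixed.spacing[0],
            fixed.origin[1] + (factor - 1) / 2.0 * fixed.spacing[1],
            fixed.origin[2],
        )
        lf = ImageVolume(lf_data, spacing, origin, fixed.modality)
        lm = ImageVolume(lm_data, spacing, origin, moving.modality)
        if field_mm is None:
            field_mm = np.zeros(lf.shape + (3,))
        else:
            field_mm = np.stack(
                [
                    ndimage.zoom(
                        field_mm[..., c],
                        [lf.shape[a] / field_mm.shape[a] for a in range(3)],
                        order=1, mode="nearest", grid_mode=False,
                    )
                    for c in range(3)
                ],
                axis=-1,
            )
        field_mm = _match_at_level(
            lf, lm, field_mm, config, config.block_size,
            _sigma3(config.smoothing_sigma_vox), level == 0, level, trace,
        )
    if config.refine:
        # one extra finest-level pass with half-size blocks for local
        # detail the coarse block tiling cannot express
        lf = ImageVolume(np.asarray(fixed.data, float), fixed.spacing,
                         fixed.origin, fixed.modality)
        lm = ImageVolume(np.asarray(moving.data, float), moving.spacing,
                         moving.origin, moving.modality)
        half_bs = tuple(max(2, b // 2) for b in config.block_size)
        half_sigma = tuple(max(0.5, s / 2) for s in _sigma3(config.smoothing_sigma_vox))
        field_mm = _match_at_level(
            lf, lm, field_mm, config, half_bs, half_sigma, True, -1, trace,
            max_iterations=min(config.max_iterations, 4),
        )
    field = DisplacementField(field_mm, fixed.spacing, fixed.origin)
    return (field, trace) if return_trace else field


def _sigma3(sigma) -> tuple[float, float, float]:
    if np.isscalar(sigma):
        return (float(sigma),) * 3
    return tuple(float(s) for s in sigma)


def _match_at_level(
    lf: ImageVolume,
    lm: ImageVolume,
    field_mm: np.ndarray,
    config: DIRConfig,
    block_size: tuple[int, int, int],
    sigma: tuple[float, float, float],
    allow_z: bool,
    level: int,
    trace: list,
    max_iterations: int | None = None,
) -> np.ndarray:
    """Run the gated integer block search at one pyramid level."""
    import dataclasses

    level_cfg = dataclasses.replace(config, block_size=block_size)
    matcher = _LevelMatcher(lf, lm, level_cfg, allow_z=allow_z)
    cval = fill_value(lm.modality)
    max_it = max_iterations or config.max_iterations
    for outer in range(config.outer_passes):
        carried = warp_image(
            lm, DisplacementField(field_mm, lf.spacing, lf.origin), "linear"
        ).data
        block_disp = np.zeros(matcher.nb + (3,), dtype=int)
        for it in range(max_it):
            warped = _apply_block_shifts(carried, block_disp, block_size, cval)
            offsets, score_zero, score_best = matcher.best_offsets(warped)
            block_disp = block_disp + offsets
            update_vox = float(np.mean(np.linalg.norm(offsets, axis=-1)))
            trace.append(
                {
                    "level": level,
                    "pass": outer,
                    "iteration": it,
                    "score_zero_offset": score_zero,
                    "score_best_offset": score_best,
                    "mean_update_vox": update_vox,
                }
            )
            if update_vox < config.tolerance_vox:
                break
        warped = _apply_block_shifts(carried, block_disp, block_size, cval)
        frac = _parabolic_subvoxel(matcher, warped, block_disp)
        residual_mm = (block_disp + frac) * np.asarray(lf.spacing)
        dense = _blocks_to_dense(residual_mm, block_size, lf.shape)
        for c in range(3):
            dense[..., c] = ndimage.gaussian_filter(dense[..., c], sigma=sigma)
        field_mm = field_mm + dense
        if float(np.abs(residual_mm).max()) == 0.0:
            break
    return field_mm


def register_mr_via_sct(
    mr_op: ImageVolume,
    sct: ImageVolume,
    mct: ImageVolume,
    config: DIRConfig | None = None,
) -> tuple[ImageVolume, DisplacementField, ImageVolume]:
    """Register MR to CT through its synthetic-CT intermediate.

    The sCT shares the MR grid by construction (it is derived from the
    MR), so the same-modality field from the sCT-to-CT registration
    applies verbatim to the MR.  Returns ``(registered MR, field,
    warped sCT)``; the warped sCT supports SSD/MAD evaluation.
    """
    config = config or DIRConfig(similarity="ssd")
    if sct.shape != mr_op.shape or not np.allclose(sct.spacing, mr_op.spacing):
        raise ValueError("sCT must share the MR grid exactly")
    if mct.shape != sct.shape or not np.allclose(mct.spacing, sct.spacing):
        from .volumes import resample_to_grid

        mct = resample_to_grid(mct, GridSpec.of(sct), "linear")
    field = block_match_dir(fixed=mct, moving=sct, config=config)
    mr_registered = warp_image(mr_op, field, "linear")
    sct_warped = warp_image(sct, field, "linear")
    return mr_registered, field, sct_warped
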