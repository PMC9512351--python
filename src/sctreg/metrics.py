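"""Quantitative registration-evaluation metrics.

Global intensity metrics (SSD, MAD, mutual information, local phase
difference), landmark metrics (modified Hausdorff distance, Dice
similarity index) and Jacobian-determinant statistics of displacement
fields.  Conventions:

* SSD and MAD are means per voxel inside a mask (HU^2 / HU for CT-like
  pairs), so they are comparable across volumes of different size.
* Mutual information is reported in nats from a joint histogram with
  global min-max bin edges.
* LPD is the amplitude-weighted mean wrapped local-phase difference over
  a bank of 6 quadrature (monogenic, log-Gabor) filters, in radians; it
  is invariant to positive affine intensity maps of either image.
* The Jacobian determinant is det(I + du/dx) of the backward-warp map,
  central differences in mm, one-sided at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .fields import DisplacementField
from .volumes import ImageVolume, ROIMask


# ---------------------------------------------------------------------------
# Intensity metrics


def _check_pair(a: ImageVolume, b: ImageVolume, mask: ROIMask | None) -> np.ndarray:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if mask is None:
        return np.ones(a.shape, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask grid mismatch")
    if not mask.mask.any():
        raise ValueError("empty evaluation mask")
    return mask.mask


def ssd_metric(a: ImageVolume, b: ImageVolume, mask: ROIMask | None = None) -> float:
    """Mean squared intensity difference per voxel inside the mask."""
    m = _check_pair(a, b, mask)
    d = np.asarray(a.data, float)[m] - np.asarray(b.data, float)[m]
    return float(np.mean(d * d))


def mad_metric(a: ImageVolume, b: ImageVolume, mask: ROIMask | None = None) -> float:
    """Mean absolute intensity difference per voxel inside the mask."""
    m = _check_pair(a, b, mask)
    d = np.asarray(a.data, float)[m] - np.asarray(b.data, float)[m]
    return float(np.mean(np.abs(d)))


def mutual_information(
    a: ImageVolume, b: ImageVolume, mask: ROIMask | None = None, bins: int = 64
) -> float:
    """Mutual information (nats) from a ``bins``x``bins`` joint histogram.

    Bin edges span each image's global min-max range inside the mask.  A
    constant image has zero marginal entropy, hence MI 0.
    """
    m = _check_pair(a, b, mask)
    x = np.asarray(a.data, float)[m]
    y = np.asarray(b.data, float)[m]
    if x.min() == x.max() or y.min() == y.max():
        return 0.0
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# Local phase (monogenic signal) and LPD


def _loggabor_bank(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    wavelengths_mm: np.ndarray,
    sigma_ratio: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Radial log-Gabor filters and Riesz multipliers on the FFT grid."""
    freqs = [np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    fr = np.sqrt(fx * fx + fy * fy + fz * fz)
    fr_safe = np.where(fr == 0, 1.0, fr)
    radial = []
    for lam in wavelengths_mm:
        f0 = 1.0 / lam
        g = np.exp(-(np.log(fr_safe / f0) ** 2) / (2 * np.log(sigma_ratio) ** 2))
        g[fr == 0] = 0.0  # zero DC: phase must not depend on brightness
        radial.append(g)
    riesz = [1j * f / fr_safe for f in (fx, fy, fz)]
    return radial, riesz


def local_phase(
    vol: ImageVolume,
    n_freqs: int = 6,
    wavelength_range_mm: tuple[float, float] = (4.0, 64.0),
    sigma_ratio: float = 0.55,
) -> tuple[np.ndarray, np.ndarray]:
    """Monogenic-signal local phase and amplitude at ``n_freqs`` scales.

    Returns ``(phase, amplitude)``, each shaped ``(n_freqs,) + vol.shape``.
    Phase lies in (-pi, pi]; its sign follows the local orientation with
    the sign fixed so the dominant Riesz axis points positively, which
    makes the phase advance monotonically along a plane wave.  Amplitude
    is the monogenic energy envelope; phase is invariant to positive
    affine intensity maps because the filters have no DC response.
    """
    shape = vol.shape
    extent = [n * s for n, s in zip(shape, vol.spacing)]
    lam = np.geomspace(wavelength_range_mm[0], wavelength_range_mm[1], n_freqs)
    if max(lam) > max(extent):
        raise ValueError(
            f"volume extent {extent} mm is smaller than the coarsest wavelength {max(lam)} mm"
        )
    radial, riesz = _loggabor_bank(shape, vol.spacing, lam, sigma_ratio)
    F = np.fft.fftn(np.asarray(vol.data, float))
    phases = np.empty((n_freqs,) + shape)
    amps = np.empty((n_freqs,) + shape)
    for i, g in enumerate(radial):
        even = np.fft.ifftn(F * g).real
        odd = np.stack([np.fft.ifftn(F * g * r).real for r in riesz], axis=-1)
        odd_mag = np.linalg.norm(odd, axis=-1)
        # orientation sign: dominant Riesz component axis taken positive
        dom = np.argmax(np.abs(odd), axis=-1)
        sign = np.sign(np.take_along_axis(odd, dom[..., None], axis=-1)[..., 0])
        sign = np.where(sign == 0, 1.0, sign)
        phases[i] = np.arctan2(sign * odd_mag, even)
        amps[i] = np.sqrt(even * even + odd_mag * odd_mag)
    return phases, amps


def lpd_metric(
    a: ImageVolume,
    b: ImageVolume,
    mask: ROIMask | None = None,
    n_freqs: int = 6,
    wavelength_range_mm: tuple[float, float] = (4.0, 64.0),
) -> float:
    """Amplitude-weighted mean wrapped local-phase difference (radians).

    Weight for each voxel/frequency is the geometric mean of the two
    amplitudes, so structureless regions contribute little.
    """
    m = _check_pair(a, b, mask)
    pa, aa = local_phase(a, n_freqs, wavelength_range_mm)
    pb, ab = local_phase(b, n_freqs, wavelength_range_mm)
    diff = np.abs(np.angle(np.exp(1j * (pa - pb))))
    w = np.sqrt(aa * ab)
    w = w * m[None]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total amplitude; images carry no band-pass structure")
    return float((diff * w).sum() / total)


# ---------------------------------------------------------------------------
# Landmark metrics


@dataclass
class ContourPointSet:
    """Point cloud of contour/surface coordinates in world mm."""

    points: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("contour set must be a non-empty (M, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("contour coordinates must be finite")

    @staticmethod
    def from_mask(mask: ROIMask) -> "ContourPointSet":
        """Boundary voxels (6-connectivity surface) in world coordinates."""
        m = mask.mask
        if not m.any():
            raise ValueError(f"ROI '{mask.label}' is empty")
        eroded = ndimage.binary_erosion(
            m, structure=ndimage.generate_binary_structure(3, 1)
        )
        surface = m & ~eroded
        idx = np.argwhere(surface)
        pts = np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
        return ContourPointSet(pts)


def mhd(a: ContourPointSet, b: ContourPointSet) -> float:
    """Modified Hausdorff distance (mm).

    The maximum of the two directed mean closest-point distances:
    ``max(mean_x min_y d(x,y), mean_y min_x d(x,y))``.
    """
    ta, tb = cKDTree(a.points), cKDTree(b.points)
    d_ab = tb.query(a.points)[0].mean()
    d_ba = ta.query(b.points)[0].mean()
    return float(max(d_ab, d_ba))


def dsi(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity index ``2|A∩B| / (|A| + |B|)`` in [0, 1]."""
    if a.shape != b.shape:
        raise ValueError("mask grid mismatch")
    na, nb = int(a.mask.sum()), int(b.mask.sum())
    if na + nb == 0:
        raise ValueError("both masks empty")
    inter = int((a.mask & b.mask).sum())
    return 2.0 * inter / (na + nb)


# ---------------------------------------------------------------------------
# Jacobian determinant


@dataclass
class JDVolume:
    """Jacobian-determinant map of a deformation with summary statistics."""

    jd: np.ndarray
    stats: dict

    @property
    def min(self) -> float:
        return self.stats["min"]

    @property
    def max(self) -> float:
        return self.stats["max"]


def jacobian_determinant(field: DisplacementField) -> JDVolume:
    """det(I + du/dx) per voxel, with the band statistics used in reports.

    ``u`` is the backward displacement in mm; derivatives are taken with
    respect to world mm via central differences (one-sided at the grid
    boundary).  JD > 1 marks local expansion, < 1 shrinkage, <= 0 folding.
    """
    if min(field.shape) < 3:
        raise ValueError("field grid must be at least 3 voxels per axis")
    grads = np.empty(field.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(field.vectors[..., i], *field.spacing, edge_order=1)
        for j in range(3):
            grads[..., i, j] = gi[j]
    jac = grads + np.eye(3)
    jd = np.linalg.det(jac)
    n = jd.size
    stats = {
        "min": float(jd.min()),
        "max": float(jd.max()),
        "mean": float(jd.mean()),
        "frac_095_105": float(((jd >= 0.95) & (jd <= 1.05)).sum() / n),
        "frac_085_115": float(((jd >= 0.85) & (jd <= 1.15)).sum() / n),
    }
    return JDVolume(jd, stats)


# ---------------------------------------------------------------------------
# Combined report


@dataclass
class MetricsReport:
    """One evaluation of a registered pair: global, landmark and JD stats."""

    ssd: float | None = None
    mad: float | None = None
    mi: float | None = None
    lpd: float | None = None
    roi_mhd_mm: dict = dc_field(default_factory=dict)
    roi_dsi: dict = dc_field(default_factory=dict)
    jd_stats: dict = dc_field(default_factory=dict)
    flags: dict = dc_field(default_factory=dict)
    config_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "ssd": self.ssd,
            "mad": self.mad,
            "mi": self.mi,
            "lpd": self.lpd,
            "roi_mhd_mm": self.roi_mhd_mm,
            "roi_dsi": self.roi_dsi,
            "jd_stats": self.jd_stats,
            "flags": self.flags,
            "config_hash": self.config_hash,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source: str | Path) -> "MetricsReport":
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
            source = Path(source).read_text()
        return MetricsReport(**json.loads(source))


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def evaluate_pair(
    fixed_ct: ImageVolume,
    registered_mr: ImageVolume | None = None,
    sct_warped: ImageVolume | None = None,
    field: DisplacementField | None = None,
    rois_fixed: list[ROIMask] | None = None,
    rois_moving_warped: list[ROIMask] | None = None,
    body: ROIMask | None = None,
    exclude_end_slices: int = 0,
    mi_bins: int = 64,
) -> MetricsReport:
    """Full quantitative evaluation of one registered pair.

    SSD/MAD compare the warped synthetic CT with the measured CT inside
    the body mask; MI and LPD compare the registered MR with the CT;
    MHD/DSI compare warped moving-side ROIs with fixed-side ROIs; JD
    statistics summarize the deformation field.  ``exclude_end_slices``
    drops that many axial slices at each end of the field of view from
    the intensity metrics (registration near FOV ends is ill-posed when
    anatomy leaves one volume's support).
    """
    from .volumes import body_mask as extract_body

    if body is None:
        body = extract_body(fixed_ct)
    mask = body.mask.copy()
    if exclude_end_slices > 0:
        mask[:, :, :exclude_end_slices] = False
        mask[:, :, mask.shape[2] - exclude_end_slices:] = False
    eval_mask = ROIMask(mask, "body_eval", body.spacing, body.origin)

    report = MetricsReport(
        flags={"exclude_end_slices": exclude_end_slices, "mi_bins": mi_bins},
        config_hash=_config_hash(
            {"exclude_end_slices": exclude_end_slices, "mi_bins": mi_bins}
        ),
    )
    if sct_warped is not None:
        report.ssd = ssd_metric(sct_warped, fixed_ct, eval_mask)
        report.mad = mad_metric(sct_warped, fixed_ct, eval_mask)
    if registered_mr is not None:
        report.mi = mutual_information(registered_mr, fixed_ct, eval_mask, bins=mi_bins)
        report.lpd = lpd_metric(registered_mr, fixed_ct, eval_mask)
    if rois_fixed and rois_moving_warped:
        for rf, rm in zip(rois_fixed, rois_moving_warped):
            name = rf.label
            report.roi_mhd_mm[name] = mhd(
                ContourPointSet.from_mask(rf), ContourPointSet.from_mask(rm)
            )
            report.roi_dsi[name] = dsi(rf, rm)
    if field is not None:
        report.jd_stats = jacobian_determinant(field).stats
    return report
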