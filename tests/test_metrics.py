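"""Evaluation metrics vs brute-force and analytic oracles."""

import json

import numpy as np
import pytest
from scipy import ndimage

from sctreg.fields import DisplacementField
from sctreg.metrics import (
    ContourPointSet,
    MetricsReport,
    dsi,
    evaluate_pair,
    jacobian_determinant,
    local_phase,
    lpd_metric,
    mad_metric,
    mhd,
    mutual_information,
    ssd_metric,
)
from sctreg.volumes import GridSpec, ImageVolume, Modality, ROIMask


def _pair(seed=0, shape=(12, 10, 8)):
    rng = np.random.default_rng(seed)
    a = ImageVolume(rng.normal(0, 100, shape), (2, 2, 5))
    b = ImageVolume(rng.normal(0, 100, shape), (2, 2, 5))
    mask = ROIMask(rng.random(shape) > 0.3, "m", (2, 2, 5))
    return a, b, mask


class TestIntensityMetrics:
    def test_identical_images_are_zero(self):
        a, _, mask = _pair()
        assert ssd_metric(a, a, mask) == 0.0
        assert mad_metric(a, a, mask) == 0.0

    def test_constant_offsets(self):
        a, _, mask = _pair(1)
        b = a.with_data(a.data + 10.0)
        assert ssd_metric(a, b, mask) == pytest.approx(100.0)
        c = a.with_data(a.data - 25.0)
        assert mad_metric(a, c, mask) == pytest.approx(25.0)

    def test_brute_force_equality(self):
        a, b, mask = _pair(2)
        ssd_sum, mad_sum, n = 0.0, 0.0, 0
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                for k in range(a.shape[2]):
                    if mask.mask[i, j, k]:
                        d = a.data[i, j, k] - b.data[i, j, k]
                        ssd_sum += d * d
                        mad_sum += abs(d)
                        n += 1
        assert ssd_metric(a, b, mask) == pytest.approx(ssd_sum / n, rel=1e-9)
        assert mad_metric(a, b, mask) == pytest.approx(mad_sum / n, rel=1e-9)

    def test_grid_mismatch_and_empty_mask(self):
        a, b, mask = _pair(3)
        with pytest.raises(ValueError):
            ssd_metric(a, ImageVolume(b.data[:-1], b.spacing))
        with pytest.raises(ValueError):
            mad_metric(a, b, ROIMask(np.zeros(a.shape, bool)))


class TestMutualInformation:
    def test_perfect_dependence_equals_marginal_entropy(self):
        rng = np.random.default_rng(4)
        # discrete values centered in distinct histogram bins
        vals = rng.integers(0, 8, (20, 20, 10)).astype(float)
        a = ImageVolume(vals, (1, 1, 1))
        b = ImageVolume(2.0 * vals + 5.0, (1, 1, 1))  # strictly monotone remap
        mi = mutual_information(a, b, bins=8)
        p = np.bincount(vals.astype(int).ravel(), minlength=8) / vals.size
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(entropy, rel=1e-9)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(5)
        shape = (100, 100, 100)
        a = ImageVolume(rng.random(shape), (1, 1, 1))
        b = ImageVolume(rng.random(shape), (1, 1, 1))
        mi = mutual_information(a, b, bins=64)
        assert mi < 0.01  # sampling bias ~ (bins-1)^2 / (2N) nats

    def test_symmetry(self):
        a, b, mask = _pair(6)
        assert mutual_information(a, b, mask) == pytest.approx(
            mutual_information(b, a, mask), abs=1e-12
        )

    def test_constant_image_returns_zero(self):
        a, _, _ = _pair(7)
        flat = a.with_data(np.zeros(a.shape))
        assert mutual_information(a, flat) == 0.0


class TestLocalPhase:
    SPACING = (2.0, 2.0, 5.0)

    def _sinusoid(self, lam, shape=(64, 64, 24)):
        x = np.arange(shape[0]) * self.SPACING[0]
        data = np.broadcast_to(
            np.sin(2 * np.pi * x / lam)[:, None, None], shape
        ).copy() * 100.0
        return ImageVolume(data, self.SPACING, modality=Modality.MR_OP)

    def test_phase_advances_linearly_along_wave(self):
        lam_bank = np.geomspace(4, 64, 6)
        i = int(np.argmin(np.abs(lam_bank - 16.0)))
        vol = self._sinusoid(lam_bank[i])
        phase, amp = local_phase(vol)
        line = phase[i][16:48, 32, 12]
        steps = np.abs(np.angle(np.exp(1j * np.diff(line))))
        expected = 2 * np.pi * self.SPACING[0] / lam_bank[i]
        np.testing.assert_allclose(steps, expected, rtol=0.02)
        mid_amp = amp[i][16:48, 32, 12]
        assert mid_amp.std() / mid_amp.mean() < 0.05

    def test_phase_invariant_to_scaling(self):
        vol = self._sinusoid(16.0)
        p1, _ = local_phase(vol)
        p2, _ = local_phase(vol.with_data(vol.data * 3.7))
        # compare as angles: +pi and -pi are the same phase
        wrapped = np.abs(np.angle(np.exp(1j * (p1 - p2))))
        assert wrapped.max() < 1e-9

    def test_constant_volume_has_no_amplitude(self):
        vol = ImageVolume(np.full((64, 64, 24), 55.0), self.SPACING)
        _, amp = local_phase(vol)
        assert np.abs(amp).max() < 1e-8

    def test_too_small_volume_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            local_phase(vol)


class TestLPD:
    def _textured(self, seed=8, shape=(64, 64, 24)):
        rng = np.random.default_rng(seed)
        data = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0) * 100 + 500
        return ImageVolume(data, (2.0, 2.0, 5.0), modality=Modality.MR_OP)

    def test_identical_images_zero(self):
        a = self._textured()
        assert lpd_metric(a, a) == 0.0

    def test_invariant_to_positive_affine_map(self):
        a = self._textured(9)
        b = a.with_data(2.0 * a.data + 100.0)
        assert lpd_metric(a, b) < 1e-6

    def test_quarter_wavelength_shift_gives_half_pi(self):
        lam_bank = np.geomspace(4, 64, 6)
        i = int(np.argmin(np.abs(lam_bank - 16.0)))
        lam = lam_bank[i]
        shape = (64, 64, 24)
        x = np.arange(shape[0]) * 2.0
        mk = lambda shift: ImageVolume(
            np.broadcast_to(
                np.sin(2 * np.pi * (x - shift) / lam)[:, None, None], shape
            ).copy(),
            (2.0, 2.0, 5.0),
            modality=Modality.MR_OP,
        )
        pa, _ = local_phase(mk(0.0))
        pb, _ = local_phase(mk(lam / 4.0))
        diff = np.abs(np.angle(np.exp(1j * (pa[i] - pb[i]))))
        assert diff[16:48, 16:48, 8:16].mean() == pytest.approx(np.pi / 2, rel=0.02)


class TestLandmarkMetrics:
    def test_mhd_trivial_and_analytic(self):
        a = ContourPointSet([[0.0, 0.0, 0.0]])
        assert mhd(a, a) == 0.0
        b = ContourPointSet([[3.0, 4.0, 0.0]])
        assert mhd(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_mhd_asymmetric_sets_brute_force(self):
        a = ContourPointSet([[0, 0, 0], [10, 0, 0]])
        b = ContourPointSet([[0, 1, 0]])
        # directed means: ((1 + sqrt(101))/2, 1); outer max
        expected = max((1 + np.sqrt(101)) / 2, 1.0)
        assert mhd(a, b) == pytest.approx(expected, rel=1e-12)
        assert mhd(a, b) == mhd(b, a)

    def test_dsi_examples(self):
        m = np.zeros((10, 10, 2), bool)
        m[:5] = True
        a = ROIMask(m)
        assert dsi(a, a) == 1.0
        other = ROIMask(~m)
        assert dsi(a, other) == 0.0
        half = np.zeros((10, 10, 2), bool)
        half[2:7] = True  # |A|=|B|=100, overlap 60 of 100 -> generic check
        b = ROIMask(half)
        inter = (m & half).sum()
        assert dsi(a, b) == pytest.approx(2 * inter / (m.sum() + half.sum()))

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            ContourPointSet(np.empty((0, 3)))
        with pytest.raises(ValueError):
            dsi(ROIMask(np.zeros((3, 3, 3), bool)), ROIMask(np.zeros((3, 3, 3), bool)))

    def test_contour_from_mask_is_surface_in_world_mm(self):
        m = np.zeros((9, 9, 5), bool)
        m[3:6, 3:6, 1:4] = True
        mask = ROIMask(m, "cube", (2.0, 2.0, 5.0), (1.0, 1.0, 1.0))
        pts = ContourPointSet.from_mask(mask)
        assert len(pts.points) == 26  # 3x3x3 cube minus interior voxel
        assert pts.points[:, 0].min() == pytest.approx(1.0 + 3 * 2.0)


class TestJacobian:
    def test_zero_field(self):
        f = DisplacementField.zero(GridSpec((8, 8, 6), (2, 2, 5)))
        jd = jacobian_determinant(f)
        np.testing.assert_allclose(jd.jd, 1.0, atol=1e-12)
        assert jd.stats["frac_095_105"] == 1.0
        assert jd.stats["frac_085_115"] == 1.0

    def test_linear_field_analytic_determinant(self):
        grid = GridSpec((10, 10, 8), (2.0, 2.0, 5.0))
        coords = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(grid.shape, grid.spacing)],
            indexing="ij",
        )
        vec = 0.1 * np.stack(coords, axis=-1)
        jd = jacobian_determinant(DisplacementField(vec, grid.spacing))
        np.testing.assert_allclose(jd.jd[1:-1, 1:-1, 1:-1], 1.331, atol=1e-9)

    def test_matches_independent_stencil_oracle(self):
        from sctreg.phantom import random_smooth_deformation

        grid = GridSpec((24, 24, 12), (2.0, 2.0, 5.0))
        f = random_smooth_deformation(grid, 6.0, 20.0, seed=12)
        jd = jacobian_determinant(f).jd
        u = f.vectors
        sp = grid.spacing
        inner = np.s_[1:-1, 1:-1, 1:-1]
        J = np.zeros(tuple(n - 2 for n in grid.shape) + (3, 3))
        for i in range(3):
            J[..., i, 0] = (u[2:, 1:-1, 1:-1, i] - u[:-2, 1:-1, 1:-1, i]) / (2 * sp[0])
            J[..., i, 1] = (u[1:-1, 2:, 1:-1, i] - u[1:-1, :-2, 1:-1, i]) / (2 * sp[1])
            J[..., i, 2] = (u[1:-1, 1:-1, 2:, i] - u[1:-1, 1:-1, :-2, i]) / (2 * sp[2])
        J += np.eye(3)
        oracle = np.linalg.det(J)
        np.testing.assert_allclose(jd[inner], oracle, atol=1e-6)

    def test_composition_approximates_product(self):
        from sctreg.fields import warp_image
        from sctreg.phantom import random_smooth_deformation

        grid = GridSpec((32, 32, 16), (2.0, 2.0, 5.0))
        f1 = random_smooth_deformation(grid, 2.0, 40.0, seed=13)
        f2 = random_smooth_deformation(grid, 2.0, 40.0, seed=14)
        # compose backward maps: u(x) = u2(x) + u1(x + u2(x))
        idx = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
        coords = [
            idx[a] + f2.vectors[..., a] / grid.spacing[a] for a in range(3)
        ]
        u1_at = np.stack(
            [
                ndimage.map_coordinates(f1.vectors[..., a], coords, order=1, mode="nearest")
                for a in range(3)
            ],
            axis=-1,
        )
        comp = DisplacementField(f2.vectors + u1_at, grid.spacing)
        jd_comp = jacobian_determinant(comp).jd
        jd_prod = jacobian_determinant(f1).jd * jacobian_determinant(f2).jd
        inner = np.s_[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(jd_comp[inner], jd_prod[inner], rtol=0.02)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(
                DisplacementField(np.zeros((2, 8, 8, 3)), (1, 1, 1))
            )

    def test_stats_consistent_with_recount(self):
        from sctreg.phantom import random_smooth_deformation

        f = random_smooth_deformation(GridSpec((16, 16, 8), (2, 2, 5)), 5.0, 20.0, seed=15)
        jd = jacobian_determinant(f)
        n = jd.jd.size
        assert jd.stats["frac_095_105"] == pytest.approx(
            ((jd.jd >= 0.95) & (jd.jd <= 1.05)).sum() / n
        )
        assert jd.stats["mean"] == pytest.approx(jd.jd.mean())


class TestReport:
    def test_json_round_trip(self, tmp_path):
        rep = MetricsReport(
            ssd=1234.5,
            mad=25.25,
            mi=0.5,
            lpd=0.75,
            roi_mhd_mm={"left_kidney": 1.5},
            roi_dsi={"left_kidney": 0.9},
            jd_stats={"min": 0.8, "max": 1.3},
            flags={"exclude_end_slices": 2},
            config_hash="abc123",
        )
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = MetricsReport.from_json(path)
        assert back == rep
        assert json.loads(rep.to_json()) == rep.to_dict()

    def test_evaluate_pair_on_phantom(self, small_phantom):
        truth, ct, md = small_phantom
        rep = evaluate_pair(
            fixed_ct=ct,
            registered_mr=md.op,
            sct_warped=ct.with_data(ct.data + 10.0, Modality.SCT),
            rois_fixed=truth.rois[:2],
            rois_moving_warped=truth.rois[:2],
        )
        assert rep.ssd == pytest.approx(100.0)
        assert rep.mad == pytest.approx(10.0)
        assert all(v == 0.0 for v in rep.roi_mhd_mm.values())
        assert all(v == 1.0 for v in rep.roi_dsi.values())
        assert rep.mi > 0
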