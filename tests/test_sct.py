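"""Feature extraction, knowledge-leveraged clustering, classification
and synthetic-CT reconstruction."""

import numpy as np
import pytest

from conftest import small_spec
from sctreg.phantom import make_phantom
from sctreg.sct import (
    ClassPrototypes,
    FeatureMap,
    HUAssignment,
    MissingClassError,
    NoBoneCandidatesError,
    SCTConfig,
    T_AIR,
    T_BONE,
    T_FAT,
    T_SOFT,
    TISSUE_CLASSES,
    correct_labels_with_ct,
    extract_features,
    fcm,
    fit_subject_prototypes,
    fuzzy_partition,
    fwhm_to_sigma_mm,
    labels_to_volume,
    reference_prototypes,
    synthesize_ct,
    train_alsvm,
)
from sctreg.volumes import ImageVolume, MDixonSet, Modality, ROIMask

KERNEL_2D = np.outer([1, 2, 1], [1, 2, 1]) / 16.0


def _mdixon_from_arrays(water, fat, spacing=(2.0, 2.0, 5.0)):
    water = np.asarray(water, float)
    fat = np.asarray(fat, float)
    mk = lambda d, m: ImageVolume(d, spacing, modality=m)
    return MDixonSet(
        water=mk(water, Modality.MR_WATER),
        fat=mk(fat, Modality.MR_FAT),
        ip=mk(water + fat, Modality.MR_IP),
        op=mk(np.abs(water - fat), Modality.MR_OP),
    )


def _full_mask(shape, spacing=(2.0, 2.0, 5.0)):
    return ROIMask(np.ones(shape, bool), "all", spacing)


class TestFeatures:
    def test_constant_channel_gives_constant_texture(self):
        md = _mdixon_from_arrays(np.full((6, 6, 3), 123.0), np.zeros((6, 6, 3)))
        fm = extract_features(md, _full_mask((6, 6, 3)))
        raw = fm.raw()
        np.testing.assert_allclose(raw[:, 0], 123.0, atol=1e-9)  # weights sum to 1
        np.testing.assert_allclose(raw[:, 2], 123.0, atol=1e-9)  # IP = water

    def test_position_feature_is_cell_center(self):
        shape = (16, 16, 16)
        md = _mdixon_from_arrays(np.zeros(shape), np.zeros(shape))
        fm = extract_features(md, _full_mask(shape), grid_partition=8)
        raw = fm.raw()
        first = np.all(fm.index_map < 2, axis=1)  # cell 0 on every axis
        np.testing.assert_allclose(raw[first][:, 4:], 0.5 / 8, atol=1e-12)

    def test_impulse_texture_matches_hand_convolution(self):
        # single-slice 5x5 impulse; oracle: direct 3x3 weighted sum
        img = np.zeros((5, 5, 1))
        img[2, 2, 0] = 9.0
        md = _mdixon_from_arrays(img, np.zeros_like(img))
        fm = extract_features(md, _full_mask((5, 5, 1)))
        raw = fm.raw()
        oracle = np.zeros((5, 5))
        for i in range(1, 4):
            for j in range(1, 4):
                patch = img[i - 1 : i + 2, j - 1 : j + 2, 0]
                oracle[i, j] = (patch * KERNEL_2D).sum()
        got = np.zeros((5, 5))
        got[fm.index_map[:, 0], fm.index_map[:, 1]] = raw[:, 0]
        np.testing.assert_allclose(got[1:4, 1:4], oracle[1:4, 1:4], atol=1e-12)

    def test_standardization_round_trip(self):
        rng = np.random.default_rng(0)
        md = _mdixon_from_arrays(
            rng.uniform(0, 1000, (8, 8, 4)), rng.uniform(0, 1000, (8, 8, 4))
        )
        fm = extract_features(md, _full_mask((8, 8, 4)))
        assert np.allclose(fm.features.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(fm.features.std(axis=0), 1, atol=1e-9)
        other = (np.zeros(7), np.full(7, 2.0))
        back = fm.renormalized(other).renormalized(fm.normalization)
        np.testing.assert_allclose(back.features, fm.features, atol=1e-9)

    def test_empty_mask_rejected(self):
        md = _mdixon_from_arrays(np.zeros((4, 4, 2)), np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            extract_features(md, ROIMask(np.zeros((4, 4, 2), bool)))


def _feature_map(x):
    x = np.asarray(x, float)
    n = len(x)
    return FeatureMap(
        x, np.zeros((n, 3), int), (np.zeros(7), np.ones(7)), (1, 1, 1), (1, 1, 1)
    )


class TestPrototypes:
    def test_bone_centroid_is_mean_of_candidates(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=7)
        x = np.concatenate([np.tile(v, (40, 1)), rng.normal(2, 0.3, (300, 7))])
        ct_vals = np.concatenate([np.full(40, 800.0), rng.normal(0, 50, 300)])
        fm = _feature_map(x)
        ct = ImageVolume(ct_vals.reshape(-1, 1, 1) * 0 + 1, (1, 1, 1))
        # bypass grid sampling: patch values_at via a matching volume
        fm.shape = (len(x), 1, 1)
        fm.index_map = np.stack(
            [np.arange(len(x)), np.zeros(len(x), int), np.zeros(len(x), int)], axis=1
        )
        ct = ImageVolume(ct_vals.reshape(-1, 1, 1), (1, 1, 1))
        protos = fit_subject_prototypes(fm, ct)
        np.testing.assert_allclose(protos.centroids[T_BONE], v, atol=1e-12)

    def test_no_bone_candidates_error(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 7))
        fm = _feature_map(x)
        fm.shape = (100, 1, 1)
        fm.index_map = np.stack(
            [np.arange(100), np.zeros(100, int), np.zeros(100, int)], axis=1
        )
        ct = ImageVolume(np.full((100, 1, 1), 200.0), (1, 1, 1))
        with pytest.raises(NoBoneCandidatesError):
            fit_subject_prototypes(fm, ct)

    def test_fcm_recovers_separated_gaussians(self):
        rng = np.random.default_rng(3)
        centers = np.stack([np.zeros(7), np.eye(7)[0], 2 * np.eye(7)[0]])
        x = np.concatenate([rng.normal(c, 0.05, (300, 7)) for c in centers])
        got, u = fcm(x, 3, seed=0)
        got = got[np.argsort(got[:, 0])]
        np.testing.assert_allclose(got, centers, atol=0.05)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_reference_prototypes_averaging(self):
        rng = np.random.default_rng(4)
        protos = [ClassPrototypes(rng.normal(size=(4, 7))) for _ in range(5)]
        ref = reference_prototypes(protos)
        oracle = np.mean([p.centroids for p in protos], axis=0)
        np.testing.assert_allclose(ref.centroids, oracle, atol=1e-12)

    def test_reference_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=(4, 7))
        assert np.allclose(
            reference_prototypes(
                [ClassPrototypes(c), ClassPrototypes(-c)]
            ).centroids,
            0.0,
        )
        protos = [ClassPrototypes(rng.normal(size=(4, 7))) for _ in range(4)]
        a = reference_prototypes(protos).centroids
        b = reference_prototypes(protos[::-1]).centroids
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_single_subject_identity(self):
        c = ClassPrototypes(np.arange(28.0).reshape(4, 7))
        np.testing.assert_array_equal(
            reference_prototypes([c]).centroids, c.centroids
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            reference_prototypes([])


class TestFuzzyPartition:
    PROTOS = ClassPrototypes(
        np.stack([np.eye(7)[0] * 3, np.eye(7)[1] * 3, np.eye(7)[2] * 3, np.zeros(7)])
    )

    def test_centroid_coincidence(self):
        u, hard = fuzzy_partition(_feature_map([self.PROTOS.centroids[T_FAT]]), self.PROTOS)
        np.testing.assert_allclose(u[0], [0, 0, 1, 0], atol=1e-12)
        assert hard[0] == T_FAT

    def test_equidistant_point_gets_uniform_membership(self):
        protos = ClassPrototypes(
            np.stack([np.eye(7)[i] for i in range(4)])  # all at distance sqrt(2) from center...
        )
        center = protos.centroids.mean(axis=0)
        u, _ = fuzzy_partition(_feature_map([center]), protos)
        np.testing.assert_allclose(u[0], 0.25, atol=1e-12)

    def test_matches_independent_membership_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 7))
        u, hard = fuzzy_partition(_feature_map(x), self.PROTOS)
        d2 = ((x[:, None, :] - self.PROTOS.centroids[None]) ** 2).sum(axis=2)
        oracle = np.empty_like(u)
        for i in range(len(x)):
            for c in range(4):
                oracle[i, c] = 1.0 / np.sum(d2[i, c] / d2[i])
        np.testing.assert_allclose(u, oracle, atol=1e-10)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(hard, np.argmax(oracle, axis=1))


class TestALSVM:
    def _separable(self, n=900, seed=0):
        rng = np.random.default_rng(seed)
        centers = {T_BONE: np.full(7, 4.0), T_AIR: np.zeros(7), T_SOFT: np.full(7, -4.0)}
        xs, ys = [], []
        for cls, c in centers.items():
            xs.append(rng.normal(c, 0.2, (n // 3, 7)))
            ys.append(np.full(n // 3, cls))
        return np.concatenate(xs), np.concatenate(ys)

    def test_separable_training_accuracy(self):
        x, y = self._separable()
        ct_vals = np.where(y == T_BONE, 700.0, np.where(y == T_AIR, -1000.0, 40.0))
        svm = train_alsvm(x, y, ct_vals, SCTConfig(seed=0))
        assert (svm.predict(x) == y).mean() >= 0.99

    def test_ct_correction_relabels_air_as_bone(self):
        labels = np.array([T_AIR, T_AIR, T_SOFT, T_FAT])
        ct_vals = np.array([800.0, -900.0, 40.0, -100.0])
        out = correct_labels_with_ct(labels, ct_vals)
        assert out[0] == T_BONE  # air voxel with CT 800 HU becomes bone
        assert out[1] == T_AIR
        assert out[2] == T_SOFT
        assert out[3] == T_FAT  # fat is final from the fuzzy step

    def test_missing_class_error(self):
        x, y = self._separable()
        ct_vals = np.full(len(y), 40.0)  # everything soft after correction
        with pytest.raises(MissingClassError):
            train_alsvm(x, y, ct_vals, SCTConfig(seed=0))


class TestVotingAndSynthesis:
    def _unit(self, target_cls):
        """A TDO unit that predicts `target_cls` for features near zero."""
        from sklearn.svm import SVC

        from sctreg.sct import TDOUnit

        rng = np.random.default_rng(target_cls)
        other = T_SOFT if target_cls != T_SOFT else T_AIR
        x = np.concatenate([rng.normal(0, 0.1, (50, 7)), rng.normal(8, 0.1, (50, 7))])
        y = np.array([target_cls] * 50 + [other] * 50)
        svm = SVC(kernel="rbf", gamma="scale").fit(x, y)
        far = ClassPrototypes(np.full((4, 7), 50.0) + np.arange(4)[:, None])
        return TDOUnit(far, svm)

    def test_single_unit_equals_its_prediction(self):
        from sctreg.sct import TDOEnsemble, predict_tissue

        unit = self._unit(T_BONE)
        ens = TDOEnsemble([unit], None, (np.zeros(7), np.ones(7)), unit.prototypes)
        fm = _feature_map(np.random.default_rng(0).normal(0, 0.1, (30, 7)))
        np.testing.assert_array_equal(predict_tissue(fm, ens), unit.vote(fm.features))

    def test_majority_vote(self):
        from sctreg.sct import TDOEnsemble, predict_tissue

        units = [self._unit(T_BONE), self._unit(T_BONE), self._unit(T_AIR)]
        ens = TDOEnsemble(units, None, (np.zeros(7), np.ones(7)), units[0].prototypes)
        fm = _feature_map(np.zeros((5, 7)))
        assert np.all(predict_tissue(fm, ens) == T_BONE)

    def test_tie_break_precedence(self):
        from sctreg.sct import TDOEnsemble, predict_tissue

        # one bone vote vs one air vote: precedence soft > fat > air > bone
        units = [self._unit(T_BONE), self._unit(T_AIR)]
        ens = TDOEnsemble(units, None, (np.zeros(7), np.ones(7)), units[0].prototypes)
        fm = _feature_map(np.zeros((3, 7)))
        assert np.all(predict_tissue(fm, ens) == T_AIR)

    def test_all_air_labels_give_constant_sct(self):
        labels = ImageVolume(
            np.full((8, 8, 4), T_AIR, dtype=np.int16), (2, 2, 5),
            modality=Modality.LABEL,
        )
        sct = synthesize_ct(labels)
        np.testing.assert_allclose(sct.data, -1000.0, atol=1e-9)

    def test_fwhm_to_sigma(self):
        assert fwhm_to_sigma_mm(2.5) == pytest.approx(1.0616, abs=1e-4)

    def test_step_profile_matches_erf_oracle(self):
        from scipy.special import erf

        # soft|bone step along i; 0.5 mm voxels so the discrete Gaussian
        # approximates the continuous convolution closely
        n, h = 256, 0.25
        labels = np.full((n, 9, 3), T_SOFT, dtype=np.int16)
        labels[n // 2 :] = T_BONE
        vol = ImageVolume(labels, (h, 4.0, 4.0), modality=Modality.LABEL)
        hu = HUAssignment()
        sct = synthesize_ct(vol, hu)
        sigma = fwhm_to_sigma_mm(hu.fwhm_mm)
        x = ((np.arange(n) + 0.5) - n / 2) * h  # mm from the step
        soft, bone = hu.values["soft"], hu.values["bone"]
        expected = soft + (bone - soft) * 0.5 * (1 + erf(x / (sigma * np.sqrt(2))))
        np.testing.assert_allclose(sct.data[:, 4, 1], expected, atol=1.0)

    def test_sct_values_bounded_by_hu_table(self, small_phantom):
        truth, _, _ = small_phantom
        from conftest import tissue_truth_codes

        codes = tissue_truth_codes(truth).astype(np.int16)
        labels = ImageVolume(codes, truth.labels.spacing, modality=Modality.LABEL)
        sct = synthesize_ct(labels)
        hu = HUAssignment().values
        assert sct.data.min() >= hu["air"] - 1e-9
        assert sct.data.max() <= hu["bone"] + 1e-9

    def test_missing_class_in_hu_map(self):
        with pytest.raises(ValueError):
            HUAssignment(values={"air": -1000, "fat": -100, "soft": 40})


class TestEndToEnd:
    def test_held_out_phantom_accuracy(self, small_phantom):
        """Train on three compact phantoms, classify a fourth."""
        from conftest import tissue_truth_codes
        from sctreg.sct import make_sct, train_sct_model

        subjects = []
        for s in (21, 22, 23):
            truth, ct, md = make_phantom(small_spec(seed=s))
            subjects.append((md, ct, truth.body()))
        model = train_sct_model(subjects, SCTConfig(seed=0))
        truth, ct, md = small_phantom
        mask = truth.body()
        labels_vol, sct = make_sct(md, model, mask)
        codes = tissue_truth_codes(truth)
        acc = (labels_vol.data[mask.mask] == codes[mask.mask]).mean()
        assert acc >= 0.90
        assert sct.modality == Modality.SCT
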