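"""Synthetic-CT generation from mDixon MR by tissue classification.

The pipeline maps MR voxels to one of four tissue classes — bone, air,
fat, soft tissue — and assigns each class a Hounsfield value:

1. **Features.**  Each voxel gets a 7-vector: one local texture feature
   per mDixon channel (3x3 in-plane normalized-weight convolution) plus
   three coarse position features from a grid-partition of the volume.
2. **Knowledge-leveraged fuzzy clustering.**  Per training subject, the
   bone prototype is seeded from the paired CT (mean feature of voxels
   above 300 HU); fuzzy c-means on the remaining voxels yields air, fat
   and soft prototypes.  Averaging across subjects gives referenced
   class prototypes.
3. **SVM with CT label correction.**  Fat is taken from the fuzzy
   partition (Dixon separates fat robustly); the remaining voxels are
   classified bone/air/soft by an RBF SVM trained on labels corrected
   against the paired CT (bone above 300 HU, air below -400 HU, soft
   otherwise), with a margin-prioritized subsample standing in for the
   active-learning query loop.
4. **Ensemble voting.**  Each per-subject unit (fat rule + SVM) votes,
   a pooled kNN classifier adds one vote, majority wins with ties
   broken soft > fat > air > bone.
5. **HU assignment** and Gaussian smoothing (2.5 mm FWHM) produce the
   synthetic CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from sklearn.cluster import kmeans_plusplus
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .volumes import ImageVolume, MDixonSet, Modality, ROIMask

# Four-class taxonomy, fixed order used for prototypes and memberships.
TISSUE_CLASSES = ("bone", "air", "fat", "soft")
T_BONE, T_AIR, T_FAT, T_SOFT = 0, 1, 2, 3

#: Tie-break precedence for ensemble voting: errs toward the most
#: prevalent, least HU-distorting class.
VOTE_PRECEDENCE = (T_SOFT, T_FAT, T_AIR, T_BONE)


@dataclass
class SCTConfig:
    """Tunable parameters of the synthesis pipeline."""

    grid_partition: int = 8
    bone_hu_threshold: float = 300.0
    air_hu_threshold: float = -400.0
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    svm_initial_size: int = 3000
    svm_margin_fraction: float = 0.2
    svm_random_fraction: float = 0.1
    svm_cap: int = 6000
    knn_k: int = 5
    knn_max_exemplars: int = 50_000
    seed: int = 0


@dataclass
class HUAssignment:
    """Hounsfield value per tissue class plus the smoothing width."""

    values: dict = dc_field(
        default_factory=lambda: {"air": -1000.0, "fat": -100.0, "soft": 40.0, "bone": 700.0}
    )
    fwhm_mm: float = 2.5

    def __post_init__(self) -> None:
        missing = set(TISSUE_CLASSES) - set(self.values)
        if missing:
            raise ValueError(f"HU assignment missing classes {sorted(missing)}")
        v = self.values
        if not (v["air"] < v["fat"] < v["soft"] < v["bone"]):
            raise ValueError("HU values must be ordered air < fat < soft < bone")


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    """Gaussian sigma equivalent to a full-width-at-half-maximum."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Feature extraction


@dataclass
class FeatureMap:
    """Per-voxel 7-component features for voxels inside a body mask.

    ``features`` holds standardized columns (zero mean, unit variance
    over the mask); ``normalization`` records the (mean, scale) used so
    train and test can share one scaling.  ``index_map`` holds the
    (i, j, k) voxel index of each row.
    """

    features: np.ndarray  # (N, 7), standardized
    index_map: np.ndarray  # (N, 3) int
    normalization: tuple[np.ndarray, np.ndarray]  # (mean(7,), scale(7,))
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    @property
    def n(self) -> int:
        return len(self.features)

    def raw(self) -> np.ndarray:
        mean, scale = self.normalization
        return self.features * scale + mean

    def renormalized(self, normalization: tuple[np.ndarray, np.ndarray]) -> "FeatureMap":
        """Re-standardize with foreign statistics (e.g. a trained model's)."""
        mean, scale = normalization
        return FeatureMap(
            (self.raw() - mean) / scale,
            self.index_map,
            (np.asarray(mean, float), np.asarray(scale, float)),
            self.shape,
            self.spacing,
        )

    def values_at(self, vol: ImageVolume) -> np.ndarray:
        """Sample a same-grid volume at the feature rows' voxels."""
        if vol.shape != self.shape:
            raise ValueError("volume grid does not match the feature map")
        i, j, k = self.index_map.T
        return np.asarray(vol.data, float)[i, j, k]


def extract_features(
    mdixon: MDixonSet, mask: ROIMask, grid_partition: int = 8
) -> FeatureMap:
    """Build the 7-feature map: 4 texture + 3 position columns.

    Texture is a 3x3 in-plane convolution of each channel with the
    normalized binomial kernel ``[1 2 1; 2 4 2; 1 2 1] / 16`` (the
    slice axis is excluded because of its coarse spacing; the center
    weighting keeps partial-volume mixing at tissue borders small).
    The raw position feature per axis is the voxel's grid-cell center
    coordinate, ``(cell + 0.5) / grid_partition`` in [0, 1].  All seven
    columns are then standardized over the mask.
    """
    if grid_partition < 1:
        raise ValueError("grid_partition must be >= 1")
    if not mask.mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(mask.mask)
    kernel_1d = np.array([1.0, 2.0, 1.0]) / 4.0
    cols = []
    for vol in mdixon.channels:
        tex = ndimage.correlate1d(
            np.asarray(vol.data, float), kernel_1d, axis=0, mode="nearest"
        )
        tex = ndimage.correlate1d(tex, kernel_1d, axis=1, mode="nearest")
        cols.append(tex[mask.mask])
    shape = mdixon.water.shape
    for a in range(3):
        cells = np.minimum(
            (idx[:, a] * grid_partition) // shape[a], grid_partition - 1
        )
        cols.append((cells + 0.5) / grid_partition)
    raw = np.stack(cols, axis=1)
    mean = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale[scale == 0] = 1.0
    return FeatureMap(
        (raw - mean) / scale, idx, (mean, scale), shape, mdixon.water.spacing
    )


def pool_normalization(maps: list[FeatureMap]) -> tuple[np.ndarray, np.ndarray]:
    """Combined mean/scale over the union of several subjects' features."""
    ns = np.array([m.n for m in maps], dtype=float)
    means = np.stack([m.normalization[0] for m in maps])
    variances = np.stack([m.normalization[1] ** 2 for m in maps])
    w = ns[:, None] / ns.sum()
    mean = (w * means).sum(axis=0)
    second = (w * (variances + means**2)).sum(axis=0)
    scale = np.sqrt(np.maximum(second - mean**2, 0.0))
    scale[scale == 0] = 1.0
    return mean, scale


# ---------------------------------------------------------------------------
# Prototypes: CT-seeded bone + fuzzy c-means for the rest


@dataclass
class ClassPrototypes:
    """Class centroids in normalized feature space, rows ordered
    (bone, air, fat, soft)."""

    centroids: np.ndarray  # (4, 7)
    provenance: str = "subject"

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != len(TISSUE_CLASSES):
            raise ValueError("prototypes need one row per tissue class")
        if not np.isfinite(self.centroids).all():
            raise ValueError("prototypes must be finite")


class NoBoneCandidatesError(ValueError):
    """Paired CT contains no voxels above the bone threshold."""


def fcm(
    x: np.ndarray,
    n_clusters: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    init: np.ndarray | None = None,
    anchor: np.ndarray | None = None,
    anchor_weight: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means, optionally anchored to knowledge centroids.

    With an ``anchor`` the objective gains a quadratic penalty pulling
    each centroid toward its knowledge value, weighted by
    ``anchor_weight`` (in units of membership mass); the centroid update
    becomes a weighted mean of the data term and the anchor.  This is
    the transfer mechanism that lets externally-derived class knowledge
    (here: paired-CT intensity windows) survive the m=2 tendency to
    absorb minority clusters into splits of the dominant one.

    Returns ``(centroids, memberships)``; raises if the centroid update
    has not converged (max shift below ``tol``) within ``max_iter``.
    """
    x = np.asarray(x, dtype=float)
    if init is not None:
        centroids = np.asarray(init, dtype=float).copy()
    elif anchor is not None:
        centroids = np.asarray(anchor, dtype=float).copy()
    else:
        centroids, _ = kmeans_plusplus(x, n_clusters, random_state=seed)
    power = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        u = _memberships(x, centroids, power)
        um = u**m
        num = um.T @ x
        den = um.sum(axis=0)[:, None]
        if anchor is not None and anchor_weight > 0:
            num = num + anchor_weight * np.asarray(anchor, float)
            den = den + anchor_weight
        new = num / den
        shift = np.abs(new - centroids).max()
        centroids = new
        if shift < tol:
            return centroids, _memberships(x, centroids, power)
    raise RuntimeError(f"FCM did not converge within {max_iter} iterations")


def _memberships(x: np.ndarray, centroids: np.ndarray, power: float) -> np.ndarray:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
    rows = zero.any(axis=1)
    if rows.any():
        u[rows] = 0.0
        # membership 1 on (the first) coincident centroid
        first = np.argmax(zero[rows], axis=1)
        u[np.nonzero(rows)[0], first] = 1.0
    return u


def fit_subject_prototypes(
    features: FeatureMap,
    paired_ct: ImageVolume,
    bone_hu_threshold: float = 300.0,
    config: SCTConfig | None = None,
) -> ClassPrototypes:
    """Knowledge-leveraged prototypes for one training subject.

    The bone centroid is the arithmetic mean of features whose paired CT
    exceeds ``bone_hu_threshold``; fuzzy c-means on the remaining voxels
    yields three clusters that are assigned to air (lowest population
    mean CT), fat (higher fat-channel centroid of the remaining two) and
    soft (the remainder).

    The clustering also leverages the paired CT beyond the bone rule:
    knowledge centroids — feature means of voxels inside CT windows
    typical of air (< -400 HU), fat (-400..-30 HU) and soft tissue
    (>= -30 HU) — both initialize the FCM and anchor its centroid
    update.  Without the anchor, a minority class such as interior air
    (a few percent of body voxels) is absorbed and the m=2 objective
    splits the dominant soft cluster instead.  Falls back to plain
    k-means++-seeded FCM when a window is empty.
    """
    config = config or SCTConfig()
    ct_vals = features.values_at(paired_ct)
    bone_sel = ct_vals > bone_hu_threshold
    if not bone_sel.any():
        raise NoBoneCandidatesError(
            f"no paired-CT voxels above {bone_hu_threshold} HU"
        )
    bone_centroid = features.features[bone_sel].mean(axis=0)
    rest = features.features[~bone_sel]
    rest_ct = ct_vals[~bone_sel]
    windows = [rest_ct < -400.0, (rest_ct >= -400.0) & (rest_ct < -30.0), rest_ct >= -30.0]
    anchor = None
    weight = 0.0
    if all(w.any() for w in windows):
        anchor = np.stack([rest[w].mean(axis=0) for w in windows])
        weight = len(rest) / 3.0
    centroids, u = fcm(
        rest, 3, m=config.fcm_m, tol=config.fcm_tol,
        max_iter=config.fcm_max_iter, seed=config.seed,
        anchor=anchor, anchor_weight=weight,
    )
    hard = np.argmax(u, axis=1)
    mean_ct = np.array([
        rest_ct[hard == c].mean() if (hard == c).any() else np.inf for c in range(3)
    ])
    air_c = int(np.argmin(mean_ct))
    others = [c for c in range(3) if c != air_c]
    # fat channel texture is column 1 of the feature vector
    fat_c = max(others, key=lambda c: centroids[c, 1])
    soft_c = next(c for c in others if c != fat_c)
    ordered = np.stack(
        [bone_centroid, centroids[air_c], centroids[fat_c], centroids[soft_c]]
    )
    return ClassPrototypes(ordered, provenance="subject")


def reference_prototypes(per_subject: list[ClassPrototypes]) -> ClassPrototypes:
    """Element-wise mean of per-subject prototypes (class order fixed)."""
    if not per_subject:
        raise ValueError("no subject prototypes to average")
    stack = np.stack([p.centroids for p in per_subject])
    return ClassPrototypes(stack.mean(axis=0), provenance="referenced")


def fuzzy_partition(
    features: FeatureMap, prototypes: ClassPrototypes, m: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy memberships (rows sum to 1) and hard labels for fixed centroids."""
    u = _memberships(features.features, prototypes.centroids, 2.0 / (m - 1.0))
    return u, np.argmax(u, axis=1)


# ---------------------------------------------------------------------------
# SVM with CT label correction


class MissingClassError(ValueError):
    """A tissue class is absent from the corrected training labels."""


def correct_labels_with_ct(
    hard_labels: np.ndarray,
    ct_values: np.ndarray,
    bone_hu_threshold: float = 300.0,
    air_hu_threshold: float = -400.0,
) -> np.ndarray:
    """CT-derived label correction for training.

    Fat assignments from the fuzzy step are kept.  Every non-fat voxel
    is relabeled from the paired CT: bone above the bone threshold, air
    below the air threshold, soft tissue otherwise.
    """
    out = np.asarray(hard_labels).copy()
    nonfat = out != T_FAT
    out[nonfat & (ct_values > bone_hu_threshold)] = T_BONE
    out[nonfat & (ct_values < air_hu_threshold)] = T_AIR
    mid = nonfat & (ct_values <= bone_hu_threshold) & (ct_values >= air_hu_threshold)
    out[mid] = T_SOFT
    return out


def train_alsvm(
    features: np.ndarray,
    hard_labels: np.ndarray,
    ct_values: np.ndarray,
    config: SCTConfig | None = None,
) -> SVC:
    """Train the bone/air/soft SVM on CT-corrected, margin-prioritized data.

    ``hard_labels`` are fuzzy-partition labels; fat rows are excluded
    (fat is final after the fuzzy step).  Labels are corrected against
    the paired CT, then an initial RBF fit ranks samples by decision
    margin and the final SVM is trained on the 20% closest to the
    boundary plus a 10% random floor (capped), emulating the
    active-learning focus on ambiguous bone/air voxels.
    """
    config = config or SCTConfig()
    rng = np.random.default_rng(config.seed)
    corrected = correct_labels_with_ct(
        hard_labels, ct_values, config.bone_hu_threshold, config.air_hu_threshold
    )
    sel = corrected != T_FAT
    x, y = np.asarray(features, float)[sel], corrected[sel]
    present = set(np.unique(y))
    missing = {T_BONE, T_AIR, T_SOFT} - present
    if missing:
        raise MissingClassError(
            f"classes absent from corrected labels: "
            f"{[TISSUE_CLASSES[c] for c in sorted(missing)]}"
        )

    def _fit(xs: np.ndarray, ys: np.ndarray) -> SVC:
        svm = SVC(
            C=config.svm_c, gamma=config.svm_gamma, kernel="rbf",
            decision_function_shape="ovr", random_state=config.seed,
        )
        svm.fit(xs, ys)
        return svm

    n = len(x)
    init_idx = rng.permutation(n)[: min(config.svm_initial_size, n)]
    # stratify: make sure every class reaches the initial fit
    for c in (T_BONE, T_AIR, T_SOFT):
        if not (y[init_idx] == c).any():
            init_idx = np.concatenate([init_idx, np.nonzero(y == c)[0][:50]])
    initial = _fit(x[init_idx], y[init_idx])
    scores = initial.decision_function(x)
    if scores.ndim == 1:
        margin = np.abs(scores)
    else:
        part = np.sort(scores, axis=1)
        margin = part[:, -1] - part[:, -2]
    n_margin = max(int(config.svm_margin_fraction * n), 1)
    chosen = np.argsort(margin)[:n_margin]
    n_rand = max(int(config.svm_random_fraction * n), 1)
    pool = np.setdiff1d(np.arange(n), chosen, assume_unique=False)
    extra = rng.choice(pool, size=min(n_rand, len(pool)), replace=False)
    idx = np.concatenate([chosen, extra])
    for c in (T_BONE, T_AIR, T_SOFT):
        if not (y[idx] == c).any():
            idx = np.concatenate([idx, np.nonzero(y == c)[0][:50]])
    if len(idx) > config.svm_cap:
        idx = rng.choice(idx, size=config.svm_cap, replace=False)
        for c in (T_BONE, T_AIR, T_SOFT):
            if not (y[idx] == c).any():
                idx = np.concatenate([idx, np.nonzero(y == c)[0][:50]])
    return _fit(x[idx], y[idx])


# ---------------------------------------------------------------------------
# Ensemble and prediction


@dataclass
class TDOUnit:
    """One tissue-distinguishable operator: fat rule + 3-class SVM."""

    prototypes: ClassPrototypes
    svm: SVC

    def vote(self, features: np.ndarray) -> np.ndarray:
        fmap = FeatureMap(
            features, np.zeros((len(features), 3), int),
            (np.zeros(7), np.ones(7)), (1, 1, 1), (1.0, 1.0, 1.0),
        )
        u, _ = fuzzy_partition(fmap, self.prototypes)
        labels = np.full(len(features), T_SOFT, dtype=np.int64)
        is_fat = np.argmax(u, axis=1) == T_FAT
        labels[is_fat] = T_FAT
        if (~is_fat).any():
            labels[~is_fat] = self.svm.predict(features[~is_fat])
        return labels


@dataclass
class TDOEnsemble:
    """Trained model: per-subject TDO units, pooled kNN, shared scaling."""

    units: list[TDOUnit]
    knn: KNeighborsClassifier | None
    normalization: tuple[np.ndarray, np.ndarray]
    reference: ClassPrototypes
    hu: HUAssignment = dc_field(default_factory=HUAssignment)
    config: SCTConfig = dc_field(default_factory=SCTConfig)
    version: str = "sctreg-tdo-1"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("ensemble needs at least one TDO unit")


def predict_tissue(features: FeatureMap, ensemble: TDOEnsemble) -> np.ndarray:
    """Majority vote of all TDO units plus the pooled kNN classifier.

    Returns one tissue code per feature row.  Ties are broken by the
    precedence soft > fat > air > bone.
    """
    x = features.features
    votes = [unit.vote(x) for unit in ensemble.units]
    if ensemble.knn is not None:
        votes.append(ensemble.knn.predict(x).astype(np.int64))
    counts = np.zeros((len(x), len(TISSUE_CLASSES)), dtype=np.int32)
    for v in votes:
        np.add.at(counts, (np.arange(len(x)), v), 1)
    best = counts.max(axis=1)
    winner = np.empty(len(x), dtype=np.int64)
    winner.fill(T_SOFT)
    # walk precedence from lowest to highest priority so that higher
    # priority classes overwrite on ties
    for c in reversed(VOTE_PRECEDENCE):
        winner = np.where(counts[:, c] == best, c, winner)
    return winner


def labels_to_volume(
    features: FeatureMap, labels: np.ndarray, outside: int = T_AIR
) -> ImageVolume:
    """Paint per-row tissue codes back onto the grid (outside mask = air)."""
    data = np.full(features.shape, outside, dtype=np.int16)
    i, j, k = features.index_map.T
    data[i, j, k] = labels
    return ImageVolume(data, features.spacing, (0.0, 0.0, 0.0), Modality.LABEL)


def synthesize_ct(
    labels: ImageVolume, hu: HUAssignment | None = None
) -> ImageVolume:
    """Map tissue codes to HU and smooth with the configured FWHM."""
    hu = hu or HUAssignment()
    lut = np.array([hu.values[c] for c in TISSUE_CLASSES])
    data = lut[np.asarray(labels.data, dtype=np.int64)]
    sigma_mm = fwhm_to_sigma_mm(hu.fwhm_mm)
    sigma_vox = [sigma_mm / s for s in labels.spacing]
    smoothed = ndimage.gaussian_filter(data.astype(float), sigma=sigma_vox)
    return ImageVolume(smoothed, labels.spacing, labels.origin, Modality.SCT)


# ---------------------------------------------------------------------------
# End-to-end training / synthesis


def train_sct_model(
    subjects: list[tuple[MDixonSet, ImageVolume, ROIMask]],
    config: SCTConfig | None = None,
    hu: HUAssignment | None = None,
) -> TDOEnsemble:
    """Train the full ensemble from aligned (mDixon, CT, body-mask) pairs."""
    config = config or SCTConfig()
    rng = np.random.default_rng(config.seed)
    raw_maps = [
        extract_features(md, mask, config.grid_partition) for md, ct, mask in subjects
    ]
    norm = pool_normalization(raw_maps)
    maps = [m.renormalized(norm) for m in raw_maps]

    protos = [
        fit_subject_prototypes(fm, ct, config.bone_hu_threshold, config)
        for fm, (_, ct, _) in zip(maps, subjects)
    ]
    reference = reference_prototypes(protos)

    units: list[TDOUnit] = []
    ex_feats, ex_labels = [], []
    for fm, (_, ct, _) in zip(maps, subjects):
        _, hard = fuzzy_partition(fm, reference)
        ct_vals = fm.values_at(ct)
        svm = train_alsvm(fm.features, hard, ct_vals, config)
        units.append(TDOUnit(reference, svm))
        corrected = correct_labels_with_ct(
            hard, ct_vals, config.bone_hu_threshold, config.air_hu_threshold
        )
        keep = min(config.knn_max_exemplars, fm.n)
        pick = rng.permutation(fm.n)[:keep]
        ex_feats.append(fm.features[pick])
        ex_labels.append(corrected[pick])

    knn = None
    if config.knn_k > 0:
        knn = KNeighborsClassifier(n_neighbors=config.knn_k)
        knn.fit(np.concatenate(ex_feats), np.concatenate(ex_labels))
    return TDOEnsemble(units, knn, norm, reference, hu or HUAssignment(), config)


def make_sct(
    mdixon: MDixonSet, model: TDOEnsemble, mask: ROIMask
) -> tuple[ImageVolume, ImageVolume]:
    """Classify a new subject's MR and synthesize its CT.

    Returns ``(label volume, synthetic CT)``.  Features are standardized
    with the model's training statistics; voxels outside the body mask
    are set to air before HU assignment.
    """
    fm = extract_features(mdixon, mask, model.config.grid_partition)
    fm = fm.renormalized(model.normalization)
    labels = predict_tissue(fm, model)
    label_vol = labels_to_volume(fm, labels)
    return label_vol, synthesize_ct(label_vol, model.hu)


def save_model(model: TDOEnsemble, path) -> None:
    """Serialize a trained ensemble (joblib bundle with a version tag)."""
    import joblib

    joblib.dump({"version": model.version, "model": model}, path)


def load_model(path) -> TDOEnsemble:
    import joblib

    bundle = joblib.load(path)
    if bundle.get("version") != "sctreg-tdo-1":
        raise ValueError(f"unsupported model bundle version: {bundle.get('version')}")
    return bundle["model"]
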