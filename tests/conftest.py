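import numpy as np
import pytest

from sctreg.phantom import PhantomSpec, make_phantom
from sctreg.pipeline import train_model_for_seeds
from sctreg.sct import SCTConfig


#: Compact grid used by unit tests: same anisotropy regime as the
#: default phantom (coarse slices), a quarter of the voxels.
SMALL_SHAPE = (64, 64, 20)
SMALL_SPACING = (2.5, 2.5, 6.0)


def small_spec(seed: int = 7, **kw) -> PhantomSpec:
    return PhantomSpec(shape=SMALL_SHAPE, spacing=SMALL_SPACING, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_phantom():
    """One seeded compact phantom: (truth, ct, mdixon)."""
    return make_phantom(small_spec(seed=7))


@pytest.fixture(scope="session")
def small_phantom_noiseless():
    return make_phantom(small_spec(seed=7).noiseless())


@pytest.fixture(scope="session")
def default_model():
    """Tissue classifier trained on three default-size phantoms.

    Session-scoped: training is the most expensive fixture and is
    shared by the registration-quality and method-ordering tests.
    """
    return train_model_for_seeds([100, 101, 102], {}, SCTConfig(seed=0))


def tissue_truth_codes(truth):
    """Map phantom label codes to the classifier's 4-class codes."""
    from sctreg.phantom import AIR_CAVITY, BACKGROUND_AIR, BONE, FAT, SOFT
    from sctreg.sct import T_AIR, T_BONE, T_FAT, T_SOFT

    lut = np.empty(5, dtype=np.int64)
    lut[BACKGROUND_AIR] = T_AIR
    lut[AIR_CAVITY] = T_AIR
    lut[FAT] = T_FAT
    lut[SOFT] = T_SOFT
    lut[BONE] = T_BONE
    return lut[np.asarray(truth.labels.data, dtype=np.int64)]
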