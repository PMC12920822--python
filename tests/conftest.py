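import numpy as np
import pytest

from rotomics.phantoms import PhantomSpec, make_phantom
from rotomics.preprocess import PreprocessConfig, preprocess_pair
from rotomics.study import extract_cohort_features, make_aniso_cohort, make_control_cohort

#: rotation-set labels used by the desk-scale studies (subset of the full
#: 17-set protocol, scaled for CI budgets)
TEST_LABELS = tuple(range(0, 90, 10))
CONTROL_LABELS = (0, 10, 20, 40, 60, 80)


@pytest.fixture(scope="session")
def aniso_features():
    """Feature table of the anisotropic (positive-control) cohort: n=30
    patients x 9 rotation sets x 1688 features."""
    cohort = make_aniso_cohort(30, seed=11)
    return extract_cohort_features(cohort, TEST_LABELS, rotation_seed=23)


@pytest.fixture(scope="session")
def control_features():
    """Feature table of the rotation-invariant negative-control cohort."""
    cohort = make_control_cohort(30, seed=12)
    return extract_cohort_features(cohort, CONTROL_LABELS, rotation_seed=29,
                                   normalize=False)


@pytest.fixture()
def small_pair():
    """One small textured lesion, preprocessed to isotropic 1 mm."""
    spec = PhantomSpec(grid_shape=(24, 24, 12), spacing=(1, 1, 2),
                       lesion_radii=(6, 6, 5), texture_wavelength=4.0,
                       noise_sd=5.0, seed=7)
    pair = make_phantom(spec)
    pair.patient_id = "P0"
    return preprocess_pair(pair, PreprocessConfig(crop_margin=4, bin_width=0.25),
                           target_spacing=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
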