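import numpy as np
import pytest

from hsibrain import CohortConfig, SpectralCube, LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A 6x5 cube with 8 bands on a uniform grid."""
    values = rng.random((6, 5, 8))
    wavelengths = np.linspace(500.0, 570.0, 8)
    return SpectralCube(values=values, wavelengths=wavelengths,
                        patient_id="P01", image_id="P01-01")


@pytest.fixture
def small_labels(rng):
    labels = rng.integers(0, 5, size=(6, 5))
    return LabelMap(labels=labels, patient_id="P01", image_id="P01-01")


@pytest.fixture
def tiny_cohort_config():
    """A miniature cohort: 3 patients, 4 images, 33x33 px, 64 bands."""
    return CohortConfig(
        n_patients=3,
        images_per_patient=(2, 1, 1),
        image_size=(33, 33),
        n_bands=64,
        label_sparsity=0.5,
        seed=7,
    )


def make_separable_patches(rng, n=80, patch=7, bands=12):
    """Four-class patches whose classes differ by per-band spectral offsets."""
    labels = np.repeat(np.arange(1, 5), n // 4)
    offsets = {1: 0.0, 2: 1.5, 3: -1.5, 4: 3.0}
    patches = rng.normal(0, 0.25, (len(labels), patch, patch, bands))
    for i, c in enumerate(labels):
        patches[i] += offsets[c]
    perm = rng.permutation(len(labels))
    return patches[perm], labels[perm]
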