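"""Shared fixtures: a small synthetic blob dataset and a CNN trained on it.

The trained classifier is session-scoped because several localization and
cropping checks reuse it; everything is seeded so the suite is
deterministic run to run.
"""

import numpy as np
import pytest

from fundcam.estimators import CNNClassifier
from fundcam.synthetic import SyntheticSpec, generate_dataset

TOY_SPEC = SyntheticSpec(image_size=32, n_classes=2, label_prevalence=0.5,
                         blob_radius=(5.0, 8.0), blob_intensity=(0.6, 0.9),
                         noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def toy_data():
    dataset, masks = generate_dataset(TOY_SPEC, 100)
    return dataset, masks


@pytest.fixture(scope="session")
def toy_arrays(toy_data):
    dataset, masks = toy_data
    return dataset.images_array(), dataset.label_matrix(), masks


@pytest.fixture(scope="session")
def trained_toy_clf(toy_arrays):
    X, y, _ = toy_arrays
    clf = CNNClassifier(epochs=30, batch_size=8, lr_init=1e-2, seed=1)
    clf.fit(X, y)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
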