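import numpy as np
import pytest

from vbmorph import mlp, synthgen
from vbmorph.io import feature_matrix


def circle_contour(r=50.0, n=512, centre=(0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.c_[centre[0] + r * np.cos(theta), centre[1] + r * np.sin(theta)]


def ellipse_contour(a, b, angle=0.0, centre=(0.0, 0.0), n=256):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(theta)
    y = b * np.sin(theta)
    c, s = np.cos(angle), np.sin(angle)
    return np.c_[centre[0] + c * x - s * y, centre[1] + s * x + c * y]


@pytest.fixture(scope="session")
def default_cohort():
    """85-scene synthetic cohort with the study's class proportions.

    Session-scoped: generation runs the full image pipeline and takes about
    a minute; it is shared by the end-to-end tests.
    """
    scenes, table = synthgen.generate_cohort(seed=7)
    return scenes, table


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    _, table = default_cohort
    X, labels = feature_matrix(table)
    return X, labels


@pytest.fixture(scope="session")
def two_cluster_data():
    """Linearly separable 2-class toy set: two well-separated Gaussians."""
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, size=(20, 9))
    b = rng.normal(8, 1, size=(20, 9))
    X = np.vstack([a, b])
    labels = ["a"] * 20 + ["b"] * 20
    return X, labels


@pytest.fixture()
def trained_toy_model(two_cluster_data):
    X, labels = two_cluster_data
    model, _ = mlp.mlp_train(X, labels, hidden=4, cfg=mlp.TrainConfig(seed=3, max_iter=500))
    return model
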