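"""Shared fixtures: synthetic data, featurized sets and a trained model.

Expensive fixtures are session-scoped so the trained network is reused
across test modules.
"""

import numpy as np
import pytest

import anchoreeg as ae


@pytest.fixture(scope="session")
def synth_cfg():
    return ae.SynthConfig()


@pytest.fixture(scope="session")
def small_trials(synth_cfg):
    """10 trials per class at the reference generator conditions."""
    return ae.simulate_dataset(synth_cfg, n_per_class=10, seed=123)


@pytest.fixture(scope="session")
def reference_anchor_set():
    return ae.AnchorSet()  # anchors (16,32,64,128,256), stride 8, 257 bins


@pytest.fixture(scope="session")
def small_features(small_trials, reference_anchor_set):
    return ae.featurize_trials(
        small_trials, reference_anchor_set, soi_window=ae.SOIWindow(3.0, 5.5)
    )


@pytest.fixture(scope="session")
def trained_model(small_features):
    """Skip-Net trained to convergence on the small synthetic set."""
    spec = ae.SkipNetSpec(132, 78, 2)
    model = ae.build_skipnet(spec, seed=7)
    ae.train(model, small_features, ae.TrainConfig(max_epochs=15, seed=7))
    return model


class LinearSoftmaxModel:
    """Analytic two-class fixture: logits = [0, w.x + b].

    Signed margin of a point is (w.x + b) / ||w||; the cross-entropy
    gradient w.r.t. the input is (p1 - 1{label=1}) * w, so a gradient-norm
    step of magnitude m moves the margin by exactly m toward the boundary.
    """

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = float(b)

    def _logit(self, x):
        return float(np.dot(self.w.ravel(), np.asarray(x, float).ravel()) + self.b)

    def predict(self, x):
        z = self._logit(x)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.array([1.0 - p1, p1])

    def cost_gradient(self, x, label):
        p1 = self.predict(x)[1]
        coef = p1 - (1.0 if label == 1 else 0.0)
        return (coef * self.w).reshape(np.asarray(x).shape)

    def margin(self, x):
        return self._logit(x) / np.linalg.norm(self.w)


class FixedGradientModel:
    """Fixture whose cost gradient is a constant matrix (possibly zero)."""

    def __init__(self, g, n_classes=2):
        self.g = np.asarray(g, dtype=np.float64)
        self.n_classes = n_classes

    def predict(self, x):
        return np.full(self.n_classes, 1.0 / self.n_classes)

    def cost_gradient(self, x, label):
        return self.g.copy()


@pytest.fixture
def linear_model():
    return LinearSoftmaxModel([3.0, 4.0])


@pytest.fixture
def fixed_gradient_model():
    return FixedGradientModel
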