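"""Gradient-norm adversarial augmentation (GNAA) and the FGSM comparator.

GNAA perturbs an input one step along the *Frobenius-normalized* gradient
of the classifier's cross-entropy cost with respect to that input:

    x_new = x + eps * g / ||g||_F,      g = d(cost)/dx .

Because the gradient points toward the decision boundary, small steps
produce inputs that are almost perfectly correlated with the original yet
harder for the classifier — used both to *augment* training data (label
preserved) and to census "adversarial pockets": training inputs whose
prediction flips under a perturbation of magnitude beta (default 0.01,
the empirically chosen crafting budget).

The fast gradient sign method (FGSM) is kept as the comparator: it steps
``eps * sign(g)`` instead, discarding every gradient magnitude and hence
the per-feature importance information GNAA retains.

Any object satisfying the :class:`GradientModel` contract works here —
``predict(x)`` returning class probabilities and ``cost_gradient(x,
label)`` returning the cost gradient at the input in inference mode —
not just the Skip-Net.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import EmptyInputError, ZeroGradientError

__all__ = [
    "GradientModel",
    "Perturbation",
    "AdversarialReport",
    "DEFAULT_BETA",
    "gnaa_perturb",
    "craft_adversarial",
    "fgsm_perturb",
    "count_pockets",
    "augment_dataset",
    "perturb_feature_sets",
]

logger = logging.getLogger(__name__)

#: Crafting budget for the adversarial-pocket census.
DEFAULT_BETA = 0.01

_ZERO_GRAD_TOL = 1e-12


@runtime_checkable
class GradientModel(Protocol):
    """The contract adversarial operations require of a classifier."""

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class-probability vector for an input."""

    def cost_gradient(self, x: np.ndarray, label) -> np.ndarray:
        """Gradient of the cross-entropy data term w.r.t. ``x`` (inference
        mode); same shape as ``x``."""


@dataclass
class Perturbation:
    """An input, its perturbed version, and the step that separates them."""

    original: np.ndarray
    perturbed: np.ndarray
    magnitude: float
    direction: np.ndarray  # unit Frobenius norm (GNAA) or sign pattern (FGSM)

    @property
    def delta(self) -> np.ndarray:
        return self.perturbed - self.original


@dataclass
class AdversarialReport:
    """Result of the adversarial-pocket census over a dataset."""

    n_inputs: int
    n_flipped: int
    beta: float
    correlations: list[float] = field(default_factory=list)
    per_class_flips: dict[int, int] = field(default_factory=dict)

    def correlation_quantiles(self, qs=(0.0, 0.25, 0.5, 0.75, 1.0)) -> dict[str, float]:
        if not self.correlations:
            return {}
        vals = np.quantile(self.correlations, qs)
        return {f"q{int(100 * q)}": float(v) for q, v in zip(qs, vals)}


def gnaa_perturb(
    model: GradientModel, x: np.ndarray, label: int, magnitude: float
) -> Perturbation:
    """One gradient-norm step of the given Frobenius magnitude.

    The perturbed input satisfies ``||x_new - x||_F == magnitude`` exactly
    (up to float rounding) whenever the gradient is nonzero; a numerically
    zero gradient has no direction and raises
    :class:`~anchoreeg.errors.ZeroGradientError`.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    g = np.asarray(model.cost_gradient(x, label), dtype=np.float64)
    norm = float(np.linalg.norm(g))
    if norm < _ZERO_GRAD_TOL:
        raise ZeroGradientError(
            "cost gradient is numerically zero; no perturbation direction"
        )
    direction = g / norm
    return Perturbation(x, x + magnitude * direction, float(magnitude), direction)


def craft_adversarial(
    model: GradientModel, x: np.ndarray, label: int, beta: float = DEFAULT_BETA
) -> Perturbation:
    """GNAA step at the adversarial crafting budget (default beta = 0.01)."""
    return gnaa_perturb(model, x, label, beta)


def fgsm_perturb(
    model: GradientModel, x: np.ndarray, label: int, epsilon: float
) -> Perturbation:
    """Fast-gradient-sign step: x + epsilon * sign(g); sign(0) = 0.

    Unlike GNAA this never fails on a zero gradient — the input passes
    through unchanged — and every delta entry is in {-eps, 0, +eps}.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(x, dtype=np.float64)
    g = np.asarray(model.cost_gradient(x, label), dtype=np.float64)
    direction = np.sign(g)
    return Perturbation(x, x + epsilon * direction, float(epsilon), direction)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    sa, sb = a.std(), b.std()
    if sa < 1e-30 or sb < 1e-30:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _iter_examples(dataset):
    """Yield (image, label) pairs from FeatureSets or (x, label) pairs."""
    for item in dataset:
        if hasattr(item, "images"):
            for im in item.images:
                yield im.values, item.label
        else:
            yield item[0], item[1]


def count_pockets(
    model: GradientModel, dataset, beta: float = DEFAULT_BETA
) -> AdversarialReport:
    """Census of adversarial pockets at crafting budget ``beta``.

    For every input the model currently classifies correctly, craft the
    beta-perturbed version and count it as a pocket if the predicted class
    flips; the Pearson correlation between original and perturbed input is
    recorded to show how indistinguishable the pair remains.  Inputs with
    zero gradient are skipped with a logged warning.  ``beta = 0`` means no
    perturbation, hence no flips.
    """
    examples = list(_iter_examples(dataset))
    if not examples:
        raise EmptyInputError("pocket census needs a non-empty dataset")
    n_inputs = 0
    n_flipped = 0
    n_zero_grad = 0
    correlations: list[float] = []
    per_class: dict[int, int] = {}
    for x, label in examples:
        pred = int(np.argmax(model.predict(x)))
        if pred != label:
            continue
        n_inputs += 1
        if beta == 0:
            correlations.append(1.0)
            continue
        try:
            pert = craft_adversarial(model, x, label, beta)
        except ZeroGradientError:
            n_zero_grad += 1
            continue
        correlations.append(_pearson(pert.original, pert.perturbed))
        if int(np.argmax(model.predict(pert.perturbed))) != label:
            n_flipped += 1
            per_class[label] = per_class.get(label, 0) + 1
    if n_zero_grad:
        logger.warning(
            "%d input(s) with zero gradient skipped in pocket census", n_zero_grad
        )
    return AdversarialReport(n_inputs, n_flipped, float(beta), correlations, per_class)


def augment_dataset(
    model: GradientModel,
    dataset: list,
    epsilon: float = 0.1,
    copies: int = 1,
    seed: int = 0,
):
    """Enlarge a feature dataset with GNAA-perturbed copies.

    Requires a model already trained on ``dataset``.  The result holds the
    original examples plus, per copy, one ``epsilon``-magnitude
    gradient-norm perturbation of every example with its label preserved;
    zero-gradient examples pass through unperturbed with a warning.  The
    output order is shuffled with ``seed``.  FeatureSet inputs yield
    FeatureSets (every anchor image perturbed independently); plain
    ``(x, label)`` pairs yield pairs.
    """
    from .anchored_stft import FeatureImage, FeatureSet

    if copies < 0:
        raise ValueError("copies must be >= 0")
    n_zero_grad = [0]
    out = list(dataset)
    for c in range(copies):
        for item in dataset:
            if hasattr(item, "images"):
                new_images = []
                for im in item.images:
                    new_images.append(
                        FeatureImage(
                            _perturb_or_pass(
                                model, im.values, item.label, epsilon, n_zero_grad
                            ),
                            im.anchor_length,
                            list(im.row_layout),
                        )
                    )
                out.append(
                    FeatureSet(new_images, item.label, f"{item.trial_id}-aug{c + 1}")
                )
            else:
                x, label = item
                out.append(
                    (_perturb_or_pass(model, x, label, epsilon, n_zero_grad), label)
                )
    if n_zero_grad[0]:
        logger.warning(
            "%d example(s) with zero gradient passed through unperturbed",
            n_zero_grad[0],
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def perturb_feature_sets(model: GradientModel, feature_sets: list, beta: float = DEFAULT_BETA):
    """Adversarially perturbed copies of feature sets, labels kept.

    Every anchor image is crafted at budget ``beta`` against ``model``
    using its trial's true label; zero-gradient images pass through.  Used
    to measure a classifier's accuracy under adversarial perturbation.
    """
    from .anchored_stft import FeatureImage, FeatureSet

    counter = [0]
    out = []
    for fs in feature_sets:
        images = [
            FeatureImage(
                _perturb_or_pass(model, im.values, fs.label, beta, counter),
                im.anchor_length,
                list(im.row_layout),
            )
            for im in fs.images
        ]
        out.append(FeatureSet(images, fs.label, fs.trial_id))
    if counter[0]:
        logger.warning("%d image(s) with zero gradient left unperturbed", counter[0])
    return out


def _perturb_or_pass(model, x, label, epsilon, counter):
    try:
        return gnaa_perturb(model, x, label, epsilon).perturbed
    except ZeroGradientError:
        counter[0] += 1
        return np.asarray(x, dtype=np.float64).copy()
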