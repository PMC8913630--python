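"""Majority-vote inference, evaluation metrics and end-to-end orchestration.

At inference time every anchor image of a trial is classified
independently and the trial's label is the majority vote over the N
per-anchor predictions; N is odd by construction, which rules out ties in
the two-class case.  With more than two classes a tie between modes is
still possible (e.g. 2-2-1 over five anchors) and is broken in favour of
the tied class with the largest summed softmax probability.

Evaluation reports accuracy and Cohen's kappa against a balanced chance
level:  kappa = (accuracy - 1/n_classes) / (1 - 1/n_classes), so a
two-class accuracy of 0.895 gives kappa 0.790 and a four-class accuracy
of 0.691 gives 0.588.

:func:`run_pipeline` wires the full workflow together: SOI extraction ->
anchored-STFT featurization -> trial-level split -> Skip-Net training ->
optional GNAA augmentation and retraining -> voted evaluation on held-out
trials.  Every random draw derives from the config seed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .anchored_stft import AnchorSet, BandSpec, FeatureSet, featurize_trials
from .errors import ConfigError, EmptyInputError, ParityError
from .signal_core import SOIWindow, TrialSet
from .skipnet import SkipNet, SkipNetSpec, TrainConfig, build_skipnet, train

__all__ = [
    "PredictionResult",
    "EvalResult",
    "predict_trial",
    "kappa",
    "evaluate",
    "split_trials",
    "kfold_indices",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Per-anchor predictions and the voted label for one trial."""

    trial_id: str
    per_anchor_labels: list[int]
    per_anchor_probs: list[np.ndarray]
    voted_label: int
    tie_broken: bool = False


@dataclass
class EvalResult:
    """Voted-classification quality over a trial collection."""

    accuracy: float
    kappa: float
    n_trials: int
    confusion: np.ndarray  # (n_classes, n_classes), rows = true class


def predict_trial(model: SkipNet, feature_set: FeatureSet) -> PredictionResult:
    """Vote the trial label from its per-anchor predictions.

    The number of anchor images must be odd.  Multi-class mode ties are
    broken by the largest summed probability among the tied classes and
    flagged via ``tie_broken``.
    """
    n = len(feature_set.images)
    if n % 2 == 0:
        raise ParityError(f"{n} anchors: an odd count is required to vote")
    probs = [np.asarray(model.predict(im.values)) for im in feature_set.images]
    labels = [int(np.argmax(p)) for p in probs]
    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == top)
    if len(tied) == 1:
        return PredictionResult(feature_set.trial_id, labels, probs, tied[0])
    summed = {lab: sum(float(p[lab]) for p in probs) for lab in tied}
    winner = max(tied, key=lambda lab: summed[lab])
    return PredictionResult(feature_set.trial_id, labels, probs, winner, True)


def kappa(accuracy: float, n_classes: int, random_accuracy: float | None = None) -> float:
    """Chance-corrected accuracy.

    With balanced classes (the default) the chance level is 1/n_classes;
    an explicit ``random_accuracy`` overrides it for unbalanced sets.
    """
    if n_classes < 2:
        raise ValueError("kappa needs at least two classes")
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    chance = 1.0 / n_classes if random_accuracy is None else random_accuracy
    return (accuracy - chance) / (1.0 - chance)


def evaluate(
    model: SkipNet, features: list[FeatureSet], n_classes: int | None = None
) -> EvalResult:
    """Voted accuracy, kappa and confusion matrix over labelled trials."""
    if not features:
        raise EmptyInputError("nothing to evaluate")
    if n_classes is None:
        n_classes = model.spec.n_classes
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for fs in features:
        result = predict_trial(model, fs)
        confusion[fs.label, result.voted_label] += 1
    n = int(confusion.sum())
    acc = float(np.trace(confusion)) / n
    return EvalResult(acc, kappa(acc, n_classes), n, confusion)


# ---------------------------------------------------------------------------
# Trial-level splits
# ---------------------------------------------------------------------------

def split_trials(
    trial_set: TrialSet, test_fraction: float, seed: int
) -> tuple[TrialSet, TrialSet]:
    """Shuffled, stratified trial-level holdout split.

    Trials are split as whole units (all anchor images of a trial stay on
    one side) and per class, so both sides stay balanced.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError("split.test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    labels = trial_set.labels
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return trial_set.subset(sorted(train_idx)), trial_set.subset(sorted(test_idx))


def kfold_indices(n_trials: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint, exhaustive test folds over trial indices."""
    if k < 2 or k > n_trials:
        raise ConfigError(f"split.k={k} invalid for {n_trials} trials")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    return [np.sort(fold) for fold in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, in one validated place."""

    soi: SOIWindow = field(default_factory=lambda: SOIWindow(3.0, 5.5))
    anchor_set: AnchorSet = field(default_factory=AnchorSet)
    bands: list[BandSpec] | None = None
    common_rows: int = 22
    scale: str = "amplitude"
    normalize: str = "minmax"
    train_config: TrainConfig = field(default_factory=TrainConfig)
    test_fraction: float = 0.2
    augment: bool = False
    augment_epsilon: float = 0.1
    augment_copies: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a plain (YAML/JSON-loaded) mapping, reporting schema
        violations with dotted field paths."""
        cfg = cls()
        try:
            if "soi" in raw:
                cfg.soi = SOIWindow(raw["soi"]["t_start"], raw["soi"]["t_end"])
        except (KeyError, TypeError) as e:
            raise ConfigError(f"soi.t_start/soi.t_end: {e}")
        if "featurize" in raw:
            f = raw["featurize"]
            try:
                cfg.anchor_set = AnchorSet(
                    lengths=tuple(f.get("anchors", (16, 32, 64, 128, 256))),
                    stride=f.get("stride"),
                    focal=f.get("focal", "corner"),
                    window_shape=f.get("window", "hann"),
                    n_unique_fft=f.get("n_unique_fft", 257),
                )
            except Exception as e:
                raise ConfigError(f"featurize.anchors/stride: {e}")
            if "bands" in f:
                try:
                    cfg.bands = [
                        BandSpec(b["name"], b["f_low"], b["f_high"])
                        for b in f["bands"]
                    ]
                except (KeyError, TypeError) as e:
                    raise ConfigError(f"featurize.bands[*].name/f_low/f_high: {e}")
            cfg.common_rows = int(f.get("common_rows", 22))
            cfg.scale = f.get("scale", "amplitude")
            cfg.normalize = f.get("normalize", "minmax")
        if "train" in raw:
            try:
                cfg.train_config = TrainConfig(**raw["train"])
            except TypeError as e:
                raise ConfigError(f"train.*: {e}")
        if "split" in raw:
            cfg.test_fraction = float(raw["split"].get("test_fraction", 0.2))
        if "augment" in raw:
            a = raw["augment"]
            cfg.augment = bool(a.get("enabled", True))
            cfg.augment_epsilon = float(a.get("epsilon", 0.1))
            cfg.augment_copies = int(a.get("copies", 1))
        cfg.seed = int(raw.get("seed", 0))
        return cfg


def run_pipeline(trials: TrialSet, config: PipelineConfig) -> tuple[EvalResult, dict]:
    """The full workflow on one trial collection.

    SOIs are cut and featurized, trials are split (whole-trial, stratified)
    into train and test, a Skip-Net is trained on the training images, and
    — when augmentation is enabled — the trained model generates GNAA
    copies of the training set and a fresh model is retrained on the
    enlarged set.  The returned EvalResult is computed by majority voting
    on the held-out trials; the artifacts dict carries the trained model
    and both feature splits.
    """
    from .gnaa import augment_dataset

    if len(trials) == 0:
        raise EmptyInputError("no trials to run on")
    n_classes = trials.n_classes

    logger.info("featurizing %d trials", len(trials))
    train_trials, test_trials = split_trials(trials, config.test_fraction, config.seed)
    feat_kwargs = dict(
        anchor_set=config.anchor_set,
        soi_window=config.soi,
        bands=config.bands,
        common_rows=config.common_rows,
        scale=config.scale,
        normalize=config.normalize,
    )
    train_feats = featurize_trials(train_trials, **feat_kwargs)
    test_feats = featurize_trials(test_trials, **feat_kwargs)

    h, w = train_feats[0].images[0].shape
    spec = SkipNetSpec(h, w, n_classes)
    cfg = config.train_config
    logger.info("training Skip-Net (%d x %d, %d classes)", h, w, n_classes)
    model = train(build_skipnet(spec, cfg.seed), train_feats, cfg)

    if config.augment and config.augment_copies > 0:
        logger.info(
            "GNAA augmentation: eps=%g, copies=%d",
            config.augment_epsilon,
            config.augment_copies,
        )
        augmented = augment_dataset(
            model,
            train_feats,
            epsilon=config.augment_epsilon,
            copies=config.augment_copies,
            seed=cfg.seed,
        )
        model = train(build_skipnet(spec, cfg.seed), augmented, cfg)

    result = evaluate(model, test_feats, n_classes)
    artifacts = {
        "model": model,
        "train_features": train_feats,
        "test_features": test_feats,
        "train_trials": train_trials,
        "test_trials": test_trials,
    }
    return result, artifacts
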