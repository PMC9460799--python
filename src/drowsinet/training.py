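"""Training and evaluation of the drowsiness models.

The recipe: categorical cross-entropy, plain SGD (no momentum) with a
staircase exponential learning-rate schedule (initial rate 0.01, decay every
1000 steps; decay rate 0.9 for the fusion model and 0.75 for the eye and face
models), a hard cap of 10,000 optimizer steps, and four iterations of
subject-level stratified 70/30 train/test resampling. Accuracies are reported
per class at an operating point of 0.5 on the drowsy probability plus their
average; ranking quality via ROC/AUC.

Splitting is by *subject*: no frame of a test subject ever appears in
training, so the classifier cannot lean on subject identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .nn import Network, softmax

__all__ = [
    "DECAY_RATES",
    "TrainConfig",
    "FoldSplit",
    "EvalReport",
    "TrainLog",
    "crossentropy_loss",
    "lr_schedule",
    "make_folds",
    "train_model",
    "evaluate",
    "frames_to_arrays",
]

CLASSES = ("alert", "drowsy")  # class index 0, 1

#: Published decay rates: 0.9 for the fusion model, 0.75 for the eye model.
#: The face model's rate is not stated anywhere; 0.75 is assumed (as for eye).
DECAY_RATES = {"face": 0.75, "eye": 0.75, "fusion": 0.9, "eye+gender": 0.75}


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    decay_steps: int = 1000
    decay_rate: float = 0.9
    max_steps: int = 10_000
    batch_size: int = 32
    operating_point: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.decay_rate < 1:
            raise ValueError(f"decay_rate must be in (0, 1), got {self.decay_rate}")
        if self.max_steps <= 0:
            raise ValueError(f"max_steps must be positive, got {self.max_steps}")

    @classmethod
    def for_input_type(cls, input_type: str, **overrides) -> "TrainConfig":
        overrides.setdefault("decay_rate", DECAY_RATES[input_type])
        return cls(**overrides)


@dataclass(frozen=True)
class FoldSplit:
    iteration_index: int  # 1..4
    train_subjects: frozenset[int]
    test_subjects: frozenset[int]

    def __post_init__(self):
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subject sets overlap")


@dataclass
class EvalReport:
    per_class_accuracy: dict[str, float]  # percent
    average_accuracy: float  # percent; unweighted class mean by default
    frame_weighted_accuracy: float  # percent; overall fraction correct
    roc_points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass
class TrainLog:
    steps: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.steps, "loss": self.loss, "lr": self.lr})


def crossentropy_loss(targets: np.ndarray, predictions: np.ndarray,
                      floor: float = 1e-7) -> float:
    """Categorical cross-entropy -sum_i y_i log p_i for one sample.

    ``targets`` must be one-hot; predictions are clipped at ``floor`` before
    the log, so the loss of a confident wrong prediction stays finite.
    """
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.shape != p.shape:
        raise ValueError("targets and predictions must have the same shape")
    if not (np.all((t == 0) | (t == 1)) and np.isclose(t.sum(), 1.0)):
        raise ValueError("targets must be one-hot")
    return float(-np.sum(t * np.log(np.clip(p, floor, None))))


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Staircase exponential decay: lr * rate^floor(step / decay_steps)."""
    if step < 0:
        raise ValueError(f"step must be >= 0, got {step}")
    return config.initial_lr * config.decay_rate ** (step // config.decay_steps)


def make_folds(manifest: pd.DataFrame, seed: int = 0, n_iterations: int = 4,
               test_fraction: float = 0.3) -> list[FoldSplit]:
    """Four independent subject-level stratified 70/30 splits.

    Each iteration draws ``test_fraction`` of the subjects of *each class*
    (at least one per class) into the test partition. Deterministic under
    ``seed``. Raises if a class would be missing from any partition.
    """
    subjects = manifest[["subject_id", "label"]].drop_duplicates()
    if subjects.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    by_class = {c: subjects.loc[subjects["label"] == c, "subject_id"].to_numpy()
                for c in subjects["label"].unique()}
    if len(by_class) < 2:
        raise ValueError("both classes must be present among subjects")
    n_subjects = subjects.shape[0]
    # total test size is test_fraction of all subjects; spread over classes
    # proportionally (largest remainder), at least one subject per class
    total_test = max(len(by_class), int(round(test_fraction * n_subjects)))
    class_names = sorted(by_class)
    quotas = {c: test_fraction * len(by_class[c]) / test_fraction / n_subjects * total_test
              for c in class_names}
    n_test = {c: max(1, int(np.floor(quotas[c]))) for c in class_names}
    remainders = sorted(class_names, key=lambda c: quotas[c] - np.floor(quotas[c]),
                        reverse=True)
    for c in remainders:
        if sum(n_test.values()) >= total_test:
            break
        n_test[c] += 1
    for c in class_names:
        if n_test[c] >= len(by_class[c]):
            raise ValueError(f"class {c!r} would be absent from training")
    rng = np.random.default_rng(seed)
    folds = []
    for it in range(1, n_iterations + 1):
        test: set[int] = set()
        for c in class_names:
            test |= set(rng.choice(by_class[c], size=n_test[c], replace=False).tolist())
        train = set(subjects["subject_id"]) - test
        folds.append(FoldSplit(it, frozenset(train), frozenset(test)))
    return folds


def frames_to_arrays(inputs: list[np.ndarray], labels: list[str] | np.ndarray,
                     classes: tuple[str, str] = CLASSES) -> tuple[np.ndarray, np.ndarray]:
    """Stack uint8 network inputs into (n, r, c, 3) floats in [0, 1] plus
    one-hot targets ordered by ``classes``."""
    x = np.stack(inputs).astype(np.float32) / 255.0
    idx = np.array([classes.index(l) for l in labels])
    y = np.eye(len(classes), dtype=np.float32)[idx]
    return x, y


def train_model(network: Network, x: np.ndarray, y: np.ndarray,
                config: TrainConfig, log_every: int = 50) -> TrainLog:
    """SGD training loop: shuffled minibatches until ``max_steps``.

    ``x`` are inputs in [0, 1], ``y`` one-hot targets. Aborts on NaN loss.
    Identical network seed, data and config reproduce identical weights.
    """
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    step = 0
    while step < config.max_steps:
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            if step >= config.max_steps:
                break
            batch = order[start : start + config.batch_size]
            if batch.size < 2:
                continue  # batch statistics need at least 2 samples
            lr = lr_schedule(step, config)
            loss = network.loss_and_backward(x[batch], y[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at step {step} (lr={lr}); "
                    "inspect inputs or lower the learning rate"
                )
            network.sgd_step(lr)
            if step % log_every == 0 or step == config.max_steps - 1:
                log.steps.append(step)
                log.loss.append(loss)
                log.lr.append(lr)
            step += 1
    return log


def evaluate(network: Network, x: np.ndarray, y: np.ndarray,
             operating_point: float = 0.5, batch_size: int = 64) -> EvalReport:
    """Accuracy at the operating point, ROC by threshold sweep, trapezoidal AUC.

    The positive class is index 1 (drowsy); a sample is called drowsy when its
    drowsy probability exceeds ``operating_point``. ``average_accuracy`` is
    the unweighted mean of the two per-class accuracies;
    ``frame_weighted_accuracy`` is the plain fraction correct.
    """
    true_idx = np.argmax(y, axis=1)
    if len(np.unique(true_idx)) < 2:
        raise ValueError("ROC/AUC undefined on a single-class test set")
    scores = np.concatenate(
        [softmax(network.forward(x[i : i + batch_size]), axis=-1)[:, 1]
         for i in range(0, x.shape[0], batch_size)]
    )
    pred_idx = (scores > operating_point).astype(int)
    per_class = {}
    for ci, cname in enumerate(CLASSES):
        m = true_idx == ci
        per_class[cname] = float(100.0 * np.mean(pred_idx[m] == ci))
    fpr, tpr, _ = roc_curve(true_idx, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return EvalReport(
        per_class_accuracy=per_class,
        average_accuracy=float(np.mean(list(per_class.values()))),
        frame_weighted_accuracy=float(100.0 * np.mean(pred_idx == true_idx)),
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
    )
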