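"""The binary "larger or smaller than 32 pixels" decision.

Two interchangeable implementations sit behind one contract:

* an analytic oracle (hard or logistic-soft) whose ground truth comes
  from a caller-supplied lookup — the test double that lets the scale
  search be validated exactly;
* a small trainable neural reference model — a fixed geometric front
  end (average-pooled patch + oriented max-projection profiles) feeding
  one hidden layer — trained per-mini-batch with checkpoint selection on
  validation accuracy, for end-to-end demonstration on CPU.

An optional three-member majority cascade mirrors a stacked-classifier
deployment; all downstream logic consumes a single probability.
"""

from __future__ import annotations

import copy
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .framing import SIZE_THRESHOLD_PX, Frame, SizeLabel

__all__ = [
    "SizeClassifier",
    "TrainingProtocol",
    "OracleSizeClassifier",
    "oracle_classifier",
    "phantom_size_lookup",
    "TrainedSizeClassifier",
    "train_classifier",
    "evaluate_accuracy",
    "CascadeClassifier",
    "train_cascade",
    "save_model",
    "load_model",
]


@runtime_checkable
class SizeClassifier(Protocol):
    """Contract: a pure map from a frame to P(lesion > 32 px)."""

    metadata: str

    def predict_prob(self, frame: Frame) -> float: ...


@dataclass(frozen=True)
class TrainingProtocol:
    """Mini-batch training schedule with best-validation checkpointing.

    One iteration is one mini-batch parameter update. Validation accuracy
    is evaluated every ``eval_interval`` updates and the checkpoint with
    the maximum accuracy is returned (ties go to the earliest).
    """

    iterations: int = 500
    batch_size: int = 32
    eval_interval: int = 10
    rng_seed: int = 0
    hidden_units: int = 128
    learning_rate: float = 3e-3
    pool: int = 4  # average-pooling factor for the image part of the front end

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch_size < 1 or self.eval_interval < 1:
            raise ValueError("iterations, batch_size and eval_interval must be >= 1")


class OracleSizeClassifier:
    """Analytic classifier backed by a ground-truth apparent-size lookup.

    Hard variant: probability 1 if the looked-up apparent size exceeds
    32 px, else 0. Soft variant: a logistic in (apparent − 32) with
    configurable slope (probability 0.5 exactly at the boundary),
    monotone non-decreasing in apparent size.
    """

    def __init__(
        self,
        lookup: Callable[[Frame], float],
        soft: bool = False,
        slope: float = 1.0,
    ) -> None:
        self._lookup = lookup
        self.soft = soft
        self.slope = slope
        self.metadata = f"oracle(soft={soft}, slope={slope})"

    def apparent_size(self, frame: Frame) -> float:
        size = self._lookup(frame)
        if size is None:
            raise KeyError("ground-truth lookup undefined for this frame")
        return float(size)

    def predict_prob(self, frame: Frame) -> float:
        size = self.apparent_size(frame)
        if self.soft:
            return float(1.0 / (1.0 + np.exp(-self.slope * (size - SIZE_THRESHOLD_PX))))
        return 1.0 if size > SIZE_THRESHOLD_PX else 0.0


def oracle_classifier(
    lookup: Callable[[Frame], float], soft: bool = False, slope: float = 1.0
) -> OracleSizeClassifier:
    return OracleSizeClassifier(lookup, soft=soft, slope=slope)


def phantom_size_lookup(true_diameter_cm: float, spacing_cm: float) -> Callable[[Frame], float]:
    """Apparent size of a known-diameter lesion in any frame of its slice:
    ``(true_diameter / spacing) × frame.magnification``."""
    m_px = true_diameter_cm / spacing_cm
    return lambda frame: m_px * frame.magnification


PROJECTION_ANGLES_DEG = tuple(np.arange(8) * 22.5)


def _pool_features(patch: np.ndarray, pool: int) -> np.ndarray:
    n = patch.shape[0]
    assert n % pool == 0
    return patch.reshape(n // pool, pool, n // pool, pool).mean(axis=(1, 3)).ravel()


def _featurize(patch: np.ndarray, pool: int) -> np.ndarray:
    """Fixed geometric front end for the trainable head.

    Concatenates the ``pool``×``pool`` average-pooled patch with
    max-projection profiles at 8 orientations (profiles binned to 64):
    the profiles expose the lesion's extent along each direction, the
    pooled image its overall layout. The patch is lightly smoothed first
    so single noise pixels cannot dominate a max-projection.
    """
    from scipy import ndimage

    p = ndimage.gaussian_filter(np.asarray(patch, dtype=float), 1.0)
    parts = [_pool_features(p, pool)]
    for ang in PROJECTION_ANGLES_DEG:
        q = p if ang == 0 else ndimage.rotate(p, ang, reshape=False, order=1, mode="constant", cval=0.0)
        prof = q.max(axis=0)
        parts.append(prof.reshape(64, prof.shape[0] // 64).mean(axis=1))
    return np.concatenate(parts)


def _frame_features(frame: Frame, pool: int) -> np.ndarray:
    # the front end is fixed, so features can be memoized on the frame;
    # cascade members and repeated evaluations then share one computation
    cache = getattr(frame, "_feature_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(frame, "_feature_cache", cache)
    if pool not in cache:
        cache[pool] = _featurize(np.asarray(frame.patch, dtype=float), pool)
    return cache[pool]


def _frames_to_xy(frames: Sequence[Frame], pool: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([_frame_features(f, pool) for f in frames])
    y = np.array([1 if f.label is SizeLabel.LARGER else 0 for f in frames])
    return X, y


class TrainedSizeClassifier:
    """Neural reference model wrapping the selected best checkpoint.

    Features come from a fixed geometric front end (average-pooled patch
    plus 8-orientation max-projection profiles), standardized per feature
    with statistics frozen from the training set.
    """

    def __init__(
        self,
        mlp,
        pool: int,
        feature_mean: np.ndarray | None = None,
        feature_sd: np.ndarray | None = None,
        metadata: str = "",
        history: list | None = None,
    ):
        self._mlp = mlp
        self.pool = pool
        self.feature_mean = feature_mean
        self.feature_sd = feature_sd
        self.metadata = metadata
        self.history = history or []  # (iteration, loss, val_accuracy)
        self.n_updates = 0
        self.best_val_accuracy = float("nan")
        self.best_iteration = -1

    def _features(self, frame: Frame) -> np.ndarray:
        x = _frame_features(frame, self.pool)
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_sd
        return x

    def predict_prob(self, frame: Frame) -> float:
        return float(self._mlp.predict_proba(self._features(frame)[None, :])[0, 1])

    def predict_prob_batch(self, frames: Sequence[Frame]) -> np.ndarray:
        X = np.stack([self._features(f) for f in frames])
        return self._mlp.predict_proba(X)[:, 1]


def train_classifier(
    train_frames: Sequence[Frame],
    val_frames: Sequence[Frame],
    protocol: TrainingProtocol = TrainingProtocol(),
) -> TrainedSizeClassifier:
    """Train the reference model and return the best-validation checkpoint.

    Runs ``protocol.iterations`` mini-batch updates of size
    ``protocol.batch_size`` (sampled with replacement from the training
    frames, seeded), evaluating validation accuracy every
    ``eval_interval`` updates; the parameters with the highest validation
    accuracy are returned, earliest iteration winning ties. Reproducible
    for a fixed ``rng_seed``.
    """
    from sklearn.neural_network import MLPClassifier

    if len(val_frames) == 0:
        raise ValueError("validation set must be non-empty")
    if any(f.label is None for f in list(train_frames) + list(val_frames)):
        raise ValueError("all frames must be labeled")
    Xtr, ytr = _frames_to_xy(train_frames, protocol.pool)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both SMALLER and LARGER frames")
    Xval, yval = _frames_to_xy(val_frames, protocol.pool)
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0) + 1e-6
    Xtr = (Xtr - mean) / sd
    Xval = (Xval - mean) / sd

    mlp = MLPClassifier(
        hidden_layer_sizes=(protocol.hidden_units,),
        solver="adam",
        learning_rate_init=protocol.learning_rate,
        random_state=protocol.rng_seed,
        max_iter=1,
        warm_start=False,
    )
    rng = np.random.default_rng(protocol.rng_seed)
    classes = np.array([0, 1])

    best_params = None
    best_acc = -1.0
    best_iter = -1
    history = []
    for it in range(1, protocol.iterations + 1):
        idx = rng.integers(0, len(Xtr), size=protocol.batch_size)
        mlp.partial_fit(Xtr[idx], ytr[idx], classes=classes)
        if it % protocol.eval_interval == 0 or it == protocol.iterations:
            acc = float(np.mean(mlp.predict(Xval) == yval))
            history.append((it, float(mlp.loss_), acc))
            if acc > best_acc:
                best_acc = acc
                best_iter = it
                best_params = (copy.deepcopy(mlp.coefs_), copy.deepcopy(mlp.intercepts_))

    mlp.coefs_, mlp.intercepts_ = best_params
    clf = TrainedSizeClassifier(
        mlp,
        pool=protocol.pool,
        feature_mean=mean,
        feature_sd=sd,
        metadata=json.dumps(
            {
                "iterations": protocol.iterations,
                "batch_size": protocol.batch_size,
                "rng_seed": protocol.rng_seed,
                "best_val_accuracy": best_acc,
                "best_iteration": best_iter,
            }
        ),
        history=history,
    )
    clf.n_updates = protocol.iterations
    clf.best_val_accuracy = best_acc
    clf.best_iteration = best_iter
    return clf


def evaluate_accuracy(clf: SizeClassifier, frames: Sequence[Frame]) -> float:
    """Fraction of frames where ``predict_prob > 0.5`` matches the label."""
    if len(frames) == 0:
        raise ValueError("frames must be non-empty")
    if any(f.label is None for f in frames):
        raise ValueError("all frames must be labeled")
    if isinstance(clf, TrainedSizeClassifier):
        probs = clf.predict_prob_batch(frames)
    else:
        probs = np.array([clf.predict_prob(f) for f in frames])
    pred = probs > 0.5
    truth = np.array([f.label is SizeLabel.LARGER for f in frames])
    return float(np.mean(pred == truth))


class CascadeClassifier:
    """Combine three (or more) member classifiers into one decision.

    ``vote="soft"`` averages member probabilities (the default: it keeps
    the combined response smooth for flip interpolation); ``vote="hard"``
    takes the majority of thresholded labels.
    """

    def __init__(self, members: Sequence[SizeClassifier], vote: str = "soft"):
        if len(members) < 1:
            raise ValueError("cascade needs at least one member")
        if vote not in ("soft", "hard"):
            raise ValueError("vote must be 'soft' or 'hard'")
        self.members = list(members)
        self.vote = vote
        self.metadata = f"cascade(n={len(members)}, vote={vote})"

    def predict_prob(self, frame: Frame) -> float:
        probs = [m.predict_prob(frame) for m in self.members]
        if self.vote == "hard":
            return float(np.mean([1.0 if p > 0.5 else 0.0 for p in probs]))
        return float(np.mean(probs))


def train_cascade(
    train_frames: Sequence[Frame],
    val_frames: Sequence[Frame],
    protocol: TrainingProtocol = TrainingProtocol(),
    n_members: int = 3,
    vote: str = "soft",
) -> CascadeClassifier:
    """Train a cascade of independently-seeded reference models.

    Member ``j`` runs the same protocol with ``rng_seed + j``; averaging
    their probabilities damps the seed-to-seed calibration wobble of a
    single 500-iteration training run.
    """
    import dataclasses

    members = [
        train_classifier(
            train_frames,
            val_frames,
            dataclasses.replace(protocol, rng_seed=protocol.rng_seed + j),
        )
        for j in range(n_members)
    ]
    return CascadeClassifier(members, vote=vote)


def save_model(clf: TrainedSizeClassifier, path: str | Path) -> Path:
    """Persist a trained model artifact (pickle + JSON metadata sidecar)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(clf, fh)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        fh.write(clf.metadata)
    return path


def load_model(path: str | Path) -> TrainedSizeClassifier:
    with open(path, "rb") as fh:
        return pickle.load(fh)
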