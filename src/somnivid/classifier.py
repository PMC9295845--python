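"""Binary mouse-vs-background patch classifier.

The detection stage needs only a confidence score in [0, 1] for each cropped
ROI, so the backbone is pluggable. Two scikit-learn backbones ship with the
package:

* ``"logistic"`` (default) — logistic regression on downsampled-intensity +
  shape features, trained by minibatch SGD on the cross-entropy loss with a
  fixed learning rate, mirroring the published training protocol
  (80/20 split, lr 0.001, 50 epochs).
* ``"mlp"`` — a small multilayer perceptron on the same features; used to
  check that staging is insensitive to the backbone choice.

A deep ``"resnet18"`` backbone slot exists but requires torch, which this
distribution does not depend on; requesting it without torch raises
ImportError. No claim of parity with any externally trained network is made.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize

PATCH_SIZE = 64

BACKBONES = ("logistic", "mlp", "resnet18")


@dataclass
class TrainConfig:
    """Training protocol; defaults follow the published recipe."""

    split_fraction: float = 0.8
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    momentum: float = 0.9
    patch_size_px: int = PATCH_SIZE
    backbone: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError(f"split_fraction must be in (0,1), got {self.split_fraction}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")


@dataclass
class TrainReport:
    epoch_loss: list[float]
    train_accuracy: float
    validation_accuracy: float
    n_train: int
    n_validation: int
    config: TrainConfig


def _prepare_patch(patch: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    """Grayscale patch -> fixed-size float image in [0, 1]."""
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.ndim == 3:  # collapse replicated channels
        patch = patch.mean(axis=-1)
    if patch.shape != (size, size):
        patch = resize(patch, (size, size), preserve_range=True, anti_aliasing=True)
    return patch / 255.0


def _features(patch: np.ndarray) -> np.ndarray:
    """8x8 downsampled intensities plus simple shape/intensity statistics."""
    small = resize(patch, (8, 8), preserve_range=True, anti_aliasing=True).ravel()
    dev = np.abs(patch - np.median(patch))
    try:
        fg = dev > threshold_otsu(dev) if dev.max() > 1e-6 else np.zeros_like(dev, bool)
    except ValueError:
        fg = np.zeros_like(dev, dtype=bool)
    stats = np.array([
        patch.mean(), patch.std(),
        dev.mean(), dev.max(),
        fg.mean(),                                  # foreground fill fraction
        patch[fg].mean() if fg.any() else patch.mean(),
    ])
    return np.concatenate([small, stats])


class PatchClassifier:
    """Scores a grayscale patch with mouse confidence in [0, 1]."""

    def __init__(self, model, scaler, backbone: str, patch_size: int = PATCH_SIZE,
                 seed: int = 0):
        self.model = model
        self.scaler = scaler
        self.backbone = backbone
        self.patch_size = patch_size
        self.seed = seed

    def score_patch(self, patch: np.ndarray) -> float:
        x = _features(_prepare_patch(patch, self.patch_size))[None, :]
        p = self.model.predict_proba(self.scaler.transform(x))[0, 1]
        return float(np.clip(p, 0.0, 1.0))

    def save(self, path) -> None:
        """Pickle + JSON sidecar (backbone, patch size, training seed)."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {"backbone": self.backbone, "patch_size_px": self.patch_size,
                   "seed": self.seed, "format": "somnivid-patch-classifier-v1"}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} is not a saved PatchClassifier")
        return obj


class ConstantClassifier:
    """Degenerate classifier returning a fixed score; testing aid."""

    def __init__(self, score: float = 1.0):
        self._score = float(score)

    def score_patch(self, patch: np.ndarray) -> float:
        if np.asarray(patch).size == 0:
            raise ValueError("empty patch")
        return self._score


def score_patch(classifier, patch: np.ndarray) -> float:
    """Functional form of ``classifier.score_patch`` (confidence in [0, 1])."""
    if np.asarray(patch).size == 0:
        raise ValueError("empty patch")
    return float(classifier.score_patch(patch))


def _make_estimator(config: TrainConfig):
    if config.backbone == "logistic":
        from sklearn.linear_model import SGDClassifier
        return SGDClassifier(loss="log_loss", learning_rate="constant",
                             eta0=config.learning_rate, alpha=1e-4,
                             random_state=config.seed)
    if config.backbone == "mlp":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(hidden_layer_sizes=(32,), solver="sgd",
                             learning_rate_init=config.learning_rate * 100,
                             momentum=config.momentum, batch_size=config.batch_size,
                             max_iter=1, warm_start=True, random_state=config.seed)
    if config.backbone == "resnet18":
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "the 'resnet18' backbone requires torch, which is not installed; "
                "use backbone='logistic' or 'mlp'") from exc
        raise NotImplementedError(
            "deep backbone training is not bundled; plug in a torch model via "
            "the PatchClassifier interface")
    raise ValueError(config.backbone)


def train_classifier(labeled_patches, config: TrainConfig | None = None
                     ) -> tuple[PatchClassifier, TrainReport]:
    """Train a patch classifier from ``[(patch, label), ...]`` pairs.

    Labels are 1 (mouse) / 0 (background); both classes must be present.
    The data are split ``split_fraction`` / rest by the config seed and the
    model is fit by minibatch SGD on cross-entropy for ``config.epochs``
    passes; the report carries the per-epoch training loss and the final
    train/validation accuracies.
    """
    from sklearn.metrics import log_loss
    from sklearn.preprocessing import StandardScaler

    config = config or TrainConfig()
    if len(labeled_patches) < 4:
        raise ValueError("need at least 4 labeled patches")
    y = np.array([int(lab) for _, lab in labeled_patches])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both mouse and background patches")
    X = np.stack([_features(_prepare_patch(p, config.patch_size_px))
                  for p, _ in labeled_patches])

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(y))
    n_train = int(round(config.split_fraction * len(y)))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split ended up single-class; reshuffle the seed")

    scaler = StandardScaler().fit(X[train_idx])
    Xt, yt = scaler.transform(X[train_idx]), y[train_idx]
    Xv, yv = scaler.transform(X[val_idx]), y[val_idx]

    est = _make_estimator(config)
    classes = np.array([0, 1])
    epoch_loss: list[float] = []
    epoch_rng = np.random.default_rng(config.seed + 1)
    for _ in range(config.epochs):
        perm = epoch_rng.permutation(len(yt))
        if config.backbone == "mlp":
            est.partial_fit(Xt[perm], yt[perm], classes=classes)
        else:
            for start in range(0, len(perm), config.batch_size):
                batch = perm[start:start + config.batch_size]
                est.partial_fit(Xt[batch], yt[batch], classes=classes)
        epoch_loss.append(float(log_loss(yt, est.predict_proba(Xt), labels=classes)))

    clf = PatchClassifier(est, scaler, config.backbone, config.patch_size_px,
                          config.seed)
    report = TrainReport(
        epoch_loss=epoch_loss,
        train_accuracy=float((est.predict(Xt) == yt).mean()),
        validation_accuracy=float((est.predict(Xv) == yv).mean()) if len(yv) else float("nan"),
        n_train=int(n_train),
        n_validation=int(len(y) - n_train),
        config=config,
    )
    return clf, report


def split_membership(n: int, config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expose the train/validation index split implied by a config seed."""
    order = np.random.default_rng(config.seed).permutation(n)
    n_train = int(round(config.split_fraction * n))
    return order[:n_train], order[n_train:]


def harvest_training_patches(truth, scenario, n_pos: int = 100, n_neg: int = 100,
                             seed: int = 0, patch_px: int | None = None):
    """Sample labeled patches from rendered simulator frames.

    Patches are harvested the same way the detector produces them at run
    time: candidate ROIs are extracted from rendered frames and cropped by
    their bounding boxes, then labeled positive when the candidate centroid
    lies on the true mouse position and negative otherwise (distractor
    blobs — food, water gel, shadows). Returns ``[(patch, label), ...]``
    suitable for :func:`train_classifier`.
    """
    from .simulate import render_frame
    from .vision import VisionParams, extract_roi_candidates

    rng = np.random.default_rng(seed)
    vp = VisionParams(expected_mouse_area_px=scenario.expected_mouse_area_px())
    r_mouse = scenario.mouse_radius_px
    n_frames = truth.trajectory.shape[0]
    pos: list = []
    neg: list = []
    for _ in range(20 * (n_pos + n_neg)):
        if len(pos) >= n_pos and len(neg) >= n_neg:
            break
        i = int(rng.integers(n_frames))
        frame = render_frame(truth, scenario, i)
        for cand in extract_roi_candidates(frame, vp):
            d = float(np.hypot(cand.centroid[0] - truth.trajectory[i, 0],
                               cand.centroid[1] - truth.trajectory[i, 1]))
            if d <= 1.5 * r_mouse and len(pos) < n_pos:
                pos.append((cand.crop(frame), 1))
            elif d > 3 * r_mouse and len(neg) < n_neg:
                neg.append((cand.crop(frame), 0))
    if not pos or not neg:
        raise RuntimeError("patch harvest failed to find both classes")
    return pos + neg


def load_train_config(path) -> TrainConfig:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return TrainConfig(**data)


def dump_train_config(config: TrainConfig, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
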