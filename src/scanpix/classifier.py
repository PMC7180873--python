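"""Viewer classification from encoded fixation images.

Assembles PI/MI/LI rasters into a labeled image dataset, performs a
group-aware stratified 80/20 split (all three images derived from one
scanpath stay in the same partition, otherwise siblings leak across the
split and inflate accuracy), trains the compact convolutional classifier,
and reports per-class precision/recall/F1 with macro means and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import IMAGE_KINDS, EncodedImageSet
from . import nn

SUPPORTED_BACKBONES = ("small_cnn",)
#: Backbone names recognized for forward compatibility but not trainable
#: here: they denote large ImageNet-pretrained networks whose weights this
#: package does not ship.
KNOWN_UNSUPPORTED = ("vgg16", "vgg19", "inception_resnet", "googlenet", "resnet50")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "small_cnn"
    pretrained: bool = False
    epochs: int = 100
    learning_rate: float = 0.0001
    momentum: float = 0.9
    batch_size: int = 16
    split_fraction: float = 0.80
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


#: Training settings used by the pipeline for the from-scratch compact net.
#: The published fine-tuning protocol (100 epochs at lr 1e-4) targets large
#: pretrained backbones; a small net trained from random init wants a larger
#: step and far fewer passes.
DESK_TRAIN_CONFIG = TrainConfig(epochs=15, learning_rate=0.01)


@dataclass
class Sample:
    image: np.ndarray  # (H, W, 3) uint8
    label: str
    subject: str
    stimulus: str
    kind: str  # PI | MI | LI


@dataclass
class LabeledImageDataset:
    samples: list[Sample]

    def __post_init__(self) -> None:
        if self.samples:
            shape = self.samples[0].image.shape
            for s in self.samples:
                if s.image.shape != shape:
                    raise ValueError(
                        f"inconsistent image dimensions: {s.image.shape} vs {shape}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({s.label for s in self.samples}))

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def groups(self) -> list[tuple[str, str]]:
        return [(s.subject, s.stimulus) for s in self.samples]

    def to_arrays(self, classes: tuple[str, ...] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(N, 3, H, W) float32 in [0, 1] and integer class indices.

        The rasters are sparse with a structural zero background, so the
        scaling keeps zero at zero rather than centering.
        """
        classes = classes or self.classes
        x = np.stack([s.image for s in self.samples]).astype(np.float32)
        x = x.transpose(0, 3, 1, 2) / 255.0
        y = np.array([classes.index(s.label) for s in self.samples])
        return x, y


def build_dataset(image_sets: list[EncodedImageSet]) -> LabeledImageDataset:
    """Each encoded scanpath contributes its PI, MI and LI rasters as three
    independently labeled samples."""
    if not image_sets:
        raise ValueError("no image sets")
    samples: list[Sample] = []
    for iset in image_sets:
        if iset.label is None:
            raise ValueError(
                f"image set {iset.subject}/{iset.stimulus} has no class label"
            )
        for kind, img in iset.images().items():
            samples.append(Sample(img, iset.label, iset.subject, iset.stimulus, kind))
    return LabeledImageDataset(samples)


def split_dataset(
    dataset: LabeledImageDataset,
    fraction: float = 0.80,
    seed: int = 0,
) -> tuple[LabeledImageDataset, LabeledImageDataset]:
    """Stratified, group-aware train/test split.

    Groups are (subject, stimulus) scanpaths; the split is drawn over groups
    within each class so that every group's three sibling images land in the
    same partition and class proportions are preserved.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    per_class: dict[str, int] = {}
    for s in dataset.samples:
        per_class[s.label] = per_class.get(s.label, 0) + 1
    if any(n < 5 for n in per_class.values()):
        raise ValueError("need at least 5 samples per class to split")

    group_label: dict[tuple[str, str], str] = {}
    for s in dataset.samples:
        group_label[(s.subject, s.stimulus)] = s.label
    rng = np.random.default_rng(seed)
    train_groups: set[tuple[str, str]] = set()
    for cls in sorted(set(group_label.values())):
        groups = sorted(g for g, lab in group_label.items() if lab == cls)
        order = rng.permutation(len(groups))
        n_train = int(np.floor(fraction * len(groups) + 0.5))
        train_groups.update(groups[i] for i in order[:n_train])

    train = [s for s in dataset.samples if (s.subject, s.stimulus) in train_groups]
    test = [s for s in dataset.samples if (s.subject, s.stimulus) not in train_groups]
    return LabeledImageDataset(train), LabeledImageDataset(test)


@dataclass
class TrainedModel:
    net: nn.Sequential
    classes: tuple[str, ...]
    config: TrainConfig
    loss_trace: list[float]
    input_hw: tuple[int, int]

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class indices for (N, 3, H, W) inputs."""
        preds = []
        for start in range(0, len(x), batch_size):
            logits = self.net.forward(x[start:start + batch_size])
            preds.append(logits.argmax(axis=1))
        return np.concatenate(preds)


def train_classifier(train: LabeledImageDataset, config: TrainConfig | None = None) -> TrainedModel:
    """Train the two-way viewer classifier; returns the model and per-epoch loss.

    Only the from-scratch ``small_cnn`` backbone is trainable; the large
    ImageNet-pretrained architectures are recognized names but their weights
    are not distributed with this package.
    """
    config = config or DESK_TRAIN_CONFIG
    if config.backbone in KNOWN_UNSUPPORTED:
        raise ValueError(
            f"backbone {config.backbone!r} requires pretrained weights that are "
            f"not distributed with this package; supported: {SUPPORTED_BACKBONES}"
        )
    if config.backbone not in SUPPORTED_BACKBONES:
        raise ValueError(f"unknown backbone {config.backbone!r}")
    classes = train.classes
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    x, y = train.to_arrays(classes)
    h, w = x.shape[2], x.shape[3]
    rng = np.random.default_rng(config.seed)
    net = nn.small_cnn((h, w), len(classes), rng)
    opt = nn.SGD(net, lr=config.learning_rate, momentum=config.momentum)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(x[idx])
            loss, grad = nn.softmax_cross_entropy(logits, y[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return TrainedModel(net, classes, config, trace, (h, w))


@dataclass
class ConfusionCounts:
    """Binary confusion counts, indexed [true class, predicted class]."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # (n_classes, n_classes) int

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def tp(self, cls: str) -> int:
        i = self.classes.index(cls)
        return int(self.matrix[i, i])

    def fp(self, cls: str) -> int:
        i = self.classes.index(cls)
        return int(self.matrix[:, i].sum() - self.matrix[i, i])

    def fn(self, cls: str) -> int:
        i = self.classes.index(cls)
        return int(self.matrix[i, :].sum() - self.matrix[i, i])

    def tn(self, cls: str) -> int:
        return self.total - self.tp(cls) - self.fp(cls) - self.fn(cls)


def evaluate_classifier(model: TrainedModel, test: LabeledImageDataset) -> ConfusionCounts:
    """Accumulate confusion counts of argmax predictions on the test set."""
    if not len(test):
        raise ValueError("empty test set")
    x, y = test.to_arrays(model.classes)
    if (x.shape[2], x.shape[3]) != model.input_hw:
        raise ValueError(
            f"test images {x.shape[2:]} do not match model input {model.input_hw}"
        )
    pred = model.predict(x)
    k = len(model.classes)
    matrix = np.zeros((k, k), dtype=int)
    np.add.at(matrix, (y, pred), 1)
    return ConfusionCounts(model.classes, matrix)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1, their macro means, and accuracy."""

    classes: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                }
                for c in self.classes
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "accuracy": self.accuracy,
            "undefined": self.undefined,
        }

    def rounded(self, ndigits: int = 2) -> dict:
        """Report layout rounded for presentation (per-class rows + MEAN row)."""
        out = self.to_dict()
        for c in self.classes:
            for k in ("precision", "recall", "f1"):
                out["per_class"][c][k] = round(out["per_class"][c][k], ndigits)
        for k in ("precision", "recall", "f1"):
            out["macro"][k] = round(out["macro"][k], 3)
        out["accuracy"] = round(out["accuracy"], ndigits)
        return out


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("no predictions to score")
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    f1: dict[str, float] = {}
    undefined: list[str] = []
    for c in counts.classes:
        tp, fp, fn = counts.tp(c), counts.fp(c), counts.fn(c)
        if tp + fp == 0:
            precision[c] = 0.0
            undefined.append(f"precision[{c}]")
        else:
            precision[c] = tp / (tp + fp)
        if tp + fn == 0:
            recall[c] = 0.0
            undefined.append(f"recall[{c}]")
        else:
            recall[c] = tp / (tp + fn)
        f1[c] = f1_score(precision[c], recall[c])
    k = len(counts.classes)
    return MetricsReport(
        classes=counts.classes,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=sum(precision.values()) / k,
        macro_recall=sum(recall.values()) / k,
        macro_f1=sum(f1.values()) / k,
        accuracy=float(np.trace(counts.matrix)) / counts.total,
        undefined=undefined,
    )
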