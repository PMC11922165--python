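"""Binary bleeding / non-bleeding classification harness.

The harness is classifier-agnostic: anything with ``fit(images, labels)``
and ``predict(images)`` over lists of (H, W, 3) float or uint8 rasters can
be evaluated. Two reference classifiers are provided — a band-energy
logistic baseline and a compact convolutional classifier (seeded random
3×3 filters with a logistic head) standing in for large transfer-learned
networks at desk scale. Metrics follow the usual confusion-count
definitions with "bleeding" as the positive class; zero-denominator
metrics are reported as ``None``, never silently as zero.
"""

from __future__ import annotations

import dataclasses
from typing import Protocol, Sequence

import numpy as np
from scipy.signal import convolve
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import datasets
from .band_selection import BandConfiguration, render_band_image, slice_cube
from .synthetic import LabeledFrameSet

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "metrics_from_counts",
    "counts_from_predictions",
    "BandEnergyClassifier",
    "ConvReferenceClassifier",
    "small_cnn_reference",
    "preprocess_frames",
    "patient_level_split",
    "evaluate_configuration",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN tallies ("bleeding" is the positive class)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class MetricSet:
    """Accuracy, precision, recall, specificity, F1 (fractions in [0, 1]).

    A metric whose denominator is zero is ``None`` (undefined), not 0.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None

    def as_dict(self, ndigits: int | None = None) -> dict[str, float | None]:
        d = dataclasses.asdict(self)
        if ndigits is not None:
            d = {
                k: (None if v is None else round(v, ndigits)) for k, v in d.items()
            }
        return d


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Compute the five evaluation metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        specificity=ratio(c.tn, c.tn + c.fp),
        f1=f1,
    )


def counts_from_predictions(
    labels: Sequence[int], predictions: Sequence[int]
) -> ConfusionCounts:
    """Tally a 2×2 confusion matrix from aligned binary sequences."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


class FrameClassifier(Protocol):
    """Contract every pluggable classifier must satisfy."""

    def fit(self, images: Sequence[np.ndarray], labels: Sequence[int]) -> "FrameClassifier": ...

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray: ...


def _as_float_images(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = []
    for im in images:
        raw = np.asarray(im)
        if raw.ndim != 3 or raw.shape[2] != 3:
            raise ValueError("classifier inputs must be (H, W, 3) rasters")
        a = raw.astype(float)
        if raw.dtype == np.uint8:
            a /= 255.0
        out.append(a)
    return out


class BandEnergyClassifier:
    """Logistic regression on simple per-channel intensity statistics.

    Features per frame: mean, standard deviation and 10th/90th percentile
    of each RGB channel (12 features), standardized. Deterministic.
    """

    def __init__(self, seed: int = 0, c: float = 1.0) -> None:
        self.seed = seed
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=c, max_iter=2000, random_state=seed),
        )

    def _features(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = []
        for a in _as_float_images(images):
            px = a.reshape(-1, 3)
            q10, q90 = np.percentile(px, [10, 90], axis=0)
            feats.append(
                np.concatenate([px.mean(axis=0), px.std(axis=0), q10, q90])
            )
        return np.array(feats)

    def fit(self, images, labels):
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training split contains a single class")
        self._model.fit(self._features(images), y)
        return self

    def predict(self, images) -> np.ndarray:
        return self._model.predict(self._features(images))


class ConvReferenceClassifier:
    """Compact convolutional classifier: fixed seeded 3×3 filter bank + logistic head.

    A desk-scale reference exposing the same contract as any pluggable
    classifier: ``n_filters`` random 3×3×3 kernels (drawn once from the
    seed), ReLU, 2×2 average pooling, then mean/max pooled responses and
    channel means feed a standardized logistic regression. Training is
    deterministic per seed.
    """

    def __init__(self, seed: int = 0, n_filters: int = 8, c: float = 1.0) -> None:
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, 3, 3, 3)) / 3.0
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=c, max_iter=2000, random_state=seed),
        )

    def _features(self, images: Sequence[np.ndarray]) -> np.ndarray:
        feats = []
        for a in _as_float_images(images):
            maps = []
            for f in self.filters:
                resp = sum(
                    convolve(a[:, :, ch], f[ch], mode="valid") for ch in range(3)
                )
                resp = np.maximum(resp, 0.0)  # ReLU
                h, w = resp.shape
                resp = resp[: h - h % 2, : w - w % 2]
                pooled = 0.25 * (
                    resp[0::2, 0::2] + resp[1::2, 0::2]
                    + resp[0::2, 1::2] + resp[1::2, 1::2]
                )
                maps.append([pooled.mean(), pooled.max()])
            feat = np.concatenate(
                [np.array(maps).ravel(), a.reshape(-1, 3).mean(axis=0)]
            )
            feats.append(feat)
        return np.array(feats)

    def fit(self, images, labels):
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training split contains a single class")
        self._model.fit(self._features(images), y)
        return self

    def predict(self, images) -> np.ndarray:
        return self._model.predict(self._features(images))


def small_cnn_reference(
    frames: LabeledFrameSet,
    config: BandConfiguration,
    seed: int = 0,
    min_frames: int = 8,
    illuminant: np.ndarray | None = None,
) -> ConvReferenceClassifier:
    """Train the compact convolutional reference on band-rendered frames."""
    if len(frames) < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {len(frames)}")
    images = preprocess_frames(frames, config, illuminant)
    clf = ConvReferenceClassifier(seed=seed)
    clf.fit(images, frames.labels())
    return clf


def preprocess_frames(
    frames: LabeledFrameSet,
    config: BandConfiguration,
    illuminant: np.ndarray | None = None,
    render_mode: str = "display",
) -> list[np.ndarray]:
    """Slice each frame's cube to the configuration and render to float RGB.

    Frames without a cube are only usable with the passthrough (white
    light) configuration, for which the stored raster is returned.
    ``render_mode``: "display" renormalizes brightness inside the selected
    bands; "true" keeps true relative brightness.
    """
    if illuminant is None:
        illuminant = datasets.illuminant("led")
    if render_mode not in {"display", "true"}:
        raise ValueError("render_mode must be 'display' or 'true'")
    images = []
    for f in frames.frames:
        if f.cube is None:
            if not config.is_passthrough:
                raise ValueError(
                    f"frame {f.frame_id} has no cube; cannot apply {config.name}"
                )
            images.append(np.asarray(f.image, dtype=float) / 255.0)
            continue
        sliced = slice_cube(f.cube, config, mode="mask")
        images.append(
            render_band_image(
                sliced,
                BandConfiguration("passthrough"),
                illuminant,
                display_renormalize=False,
                quantize=False,
            )
            if render_mode == "true"
            else render_band_image(
                f.cube, config, illuminant, display_renormalize=True, quantize=False
            )
        )
    return images


def patient_level_split(
    frames: LabeledFrameSet, test_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split frame indices by patient so no patient spans train and test.

    The split is stratified by each patient's majority label so that, when
    a class has more than one patient, both splits see both classes.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[int]] = {}
    for i, f in enumerate(frames.frames):
        by_patient.setdefault(f.patient_id, []).append(i)
    labels = frames.labels()
    strata: dict[int, list[str]] = {}
    for p, idx in sorted(by_patient.items()):
        majority = int(np.round(labels[idx].mean()))
        strata.setdefault(majority, []).append(p)
    test_idx: list[int] = []
    for cls_patients in strata.values():
        rng.shuffle(cls_patients)
        n_frames = sum(len(by_patient[p]) for p in cls_patients)
        target = test_fraction * n_frames
        taken = 0
        for p in cls_patients:
            if taken >= target or len(cls_patients) - cls_patients.index(p) <= 1:
                break
            test_idx.extend(by_patient[p])
            taken += len(by_patient[p])
        if taken == 0 and len(cls_patients) > 1:
            test_idx.extend(by_patient[cls_patients[0]])
    test = np.array(sorted(test_idx), dtype=int)
    train = np.array(sorted(set(range(len(frames))) - set(test_idx)), dtype=int)
    return train, test


def evaluate_configuration(
    frames: LabeledFrameSet,
    config: BandConfiguration,
    classifier: FrameClassifier | None = None,
    test_fraction: float = 0.3,
    seed: int = 0,
    illuminant: np.ndarray | None = None,
) -> tuple[MetricSet, ConfusionCounts]:
    """Train and evaluate one band configuration end to end.

    Frames are band-rendered, split at patient level, the classifier is
    fitted on the training split and scored on the held-out split.
    Deterministic for a given seed and classifier.
    """
    if classifier is None:
        classifier = BandEnergyClassifier(seed=seed)
    images = preprocess_frames(frames, config, illuminant)
    labels = frames.labels()
    train, test = patient_level_split(frames, test_fraction, seed)
    if len(np.unique(labels[train])) < 2:
        raise ValueError("training split contains a single class")
    classifier.fit([images[i] for i in train], labels[train])
    predictions = classifier.predict([images[i] for i in test])
    counts = counts_from_predictions(labels[test], predictions)
    return metrics_from_counts(counts), counts
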