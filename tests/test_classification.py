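"""Confusion counts, evaluation metrics, and the classification harness."""

import numpy as np
import pytest

from specband.band_selection import configuration_by_name
from specband.classification import (
    BandEnergyClassifier,
    ConfusionCounts,
    ConvReferenceClassifier,
    counts_from_predictions,
    evaluate_configuration,
    metrics_from_counts,
    patient_level_split,
    preprocess_frames,
    small_cnn_reference,
)
from specband.synthetic import LabeledFrame, LabeledFrameSet, make_tissue_frames

# Seven evaluated band datasets: confusion counts (tp, fp, tn, fn) under the
# predicted-class-totals reading, against the published metric table.
# Agreement is to one unit in the last printed digit: the final row prints
# two values at 2 d.p. and its specificity one ulp below the rounded quotient.
TABLE_ROWS = [
    ("wli", (95, 26, 126, 19), (0.831, 0.785, 0.833, 0.829, 0.809)),
    ("540-780", (57, 64, 118, 27), (0.658, 0.471, 0.679, 0.648, 0.556)),
    ("470-500+540-780", (37, 84, 139, 6), (0.662, 0.306, 0.860, 0.623, 0.451)),
    ("470-500", (72, 49, 120, 25), (0.722, 0.595, 0.742, 0.710, 0.661)),
    ("405-415+470-500+540-590", (94, 27, 102, 43), (0.737, 0.777, 0.686, 0.791, 0.729)),
    ("405-415", (97, 24, 137, 8), (0.880, 0.802, 0.924, 0.851, 0.858)),
    ("405-415+535-545", (69, 52, 113, 32), (0.684, 0.57, 0.683, 0.684, 0.62)),
]


class TestMetricsFromCounts:
    @pytest.mark.parametrize("name,counts,expected", TABLE_ROWS)
    def test_reproduces_published_metric_table(self, name, counts, expected):
        m = metrics_from_counts(ConfusionCounts(*counts))
        computed = (m.accuracy, m.precision, m.recall, m.specificity, m.f1)
        for got, want in zip(computed, expected):
            digits = len(f"{want!r}".split(".")[1])
            assert abs(round(got, digits) - want) <= 10.0 ** (-digits) + 1e-12

    def test_degenerate_denominators_are_undefined_not_zero(self):
        m = metrics_from_counts(ConfusionCounts(0, 0, 10, 0))
        assert m.accuracy == 1.0
        assert m.precision is None
        assert m.recall is None
        assert m.specificity == 1.0
        assert m.f1 is None

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_accuracy_invariant_under_class_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fp + tn + fn == 0:
                continue
            a = metrics_from_counts(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            b = metrics_from_counts(ConfusionCounts(int(tn), int(fn), int(tp), int(fp)))
            assert a.accuracy == pytest.approx(b.accuracy)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            m = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))
            assert min(m.precision, m.recall) - 1e-12 <= m.f1
            assert m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestCountsFromPredictions:
    def test_perfect_predictions(self):
        labels = [1] * 5 + [0] * 5
        c = counts_from_predictions(labels, labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 5, 0)

    def test_all_positive_predictions(self):
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        c = counts_from_predictions(labels, [1] * 10)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 7, 0, 0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        preds = rng.integers(0, 2, 200)
        c = counts_from_predictions(labels, preds)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for y, p in zip(labels, preds):
            key = ("t" if y == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            counts_from_predictions([0, 1], [1])


@pytest.fixture(scope="module")
def tissue_frames():
    return make_tissue_frames(12, 12, (16, 16), seed=5)


class TestHarness:
    def test_patient_level_split_has_no_leakage(self, tissue_frames):
        train, test = patient_level_split(tissue_frames, 0.3, seed=0)
        patients = np.array(tissue_frames.patients())
        assert set(patients[train]).isdisjoint(set(patients[test]))
        assert len(train) + len(test) == len(tissue_frames)
        assert len(test) > 0

    def test_perfect_oracle_scores_perfectly(self, tissue_frames):
        class Oracle:
            def __init__(self, frames):
                self._lookup = {
                    im.tobytes(): f.label
                    for im, f in zip(
                        preprocess_frames(frames, configuration_by_name("wli")),
                        frames.frames,
                    )
                }

            def fit(self, images, labels):
                return self

            def predict(self, images):
                return np.array([self._lookup[im.tobytes()] for im in images])

        metrics, _ = evaluate_configuration(
            tissue_frames, configuration_by_name("wli"), Oracle(tissue_frames)
        )
        assert metrics.accuracy == 1.0

    def test_majority_class_classifier_near_chance(self, tissue_frames):
        class Majority:
            def fit(self, images, labels):
                vals, counts = np.unique(np.asarray(labels), return_counts=True)
                self._mode = int(vals[np.argmax(counts)])
                return self

            def predict(self, images):
                return np.full(len(images), self._mode)

        metrics, counts = evaluate_configuration(
            tissue_frames, configuration_by_name("wli"), Majority()
        )
        # balanced test split → majority voting sits near 0.5
        assert abs(metrics.accuracy - 0.5) <= 0.25

    def test_single_class_training_split_rejected(self):
        frames = make_tissue_frames(0, 12, (16, 16), seed=6)
        with pytest.raises(ValueError, match="single class"):
            evaluate_configuration(frames, configuration_by_name("wli"))

    def test_deterministic_given_seed(self, tissue_frames):
        out = [
            evaluate_configuration(
                tissue_frames,
                configuration_by_name("cfg6"),
                BandEnergyClassifier(seed=3),
                seed=3,
            )[1]
            for _ in range(2)
        ]
        assert out[0] == out[1]


class TestConvReference:
    def test_same_seed_same_predictions(self, tissue_frames):
        images = preprocess_frames(tissue_frames, configuration_by_name("wli"))
        labels = tissue_frames.labels()
        p1 = ConvReferenceClassifier(seed=11).fit(images, labels).predict(images)
        p2 = ConvReferenceClassifier(seed=11).fit(images, labels).predict(images)
        assert np.array_equal(p1, p2)

    def test_separable_two_color_frames(self):
        rng = np.random.default_rng(7)
        frames = []
        for i in range(24):
            label = i % 2
            base = np.array([0.8, 0.2, 0.2]) if label else np.array([0.2, 0.2, 0.8])
            im = np.clip(base + rng.normal(0, 0.05, (16, 16, 3)), 0, 1)
            frames.append(
                LabeledFrame(
                    image=np.round(im * 255).astype(np.uint8),
                    label=label,
                    frame_id=f"f{i}",
                    patient_id=f"p{i}",
                )
            )
        fs = LabeledFrameSet(frames)
        clf = small_cnn_reference(fs, configuration_by_name("wli"), seed=0)
        images = preprocess_frames(fs, configuration_by_name("wli"))
        acc = np.mean(clf.predict(images) == fs.labels())
        assert acc >= 0.95

    def test_label_shuffle_gives_chance_accuracy(self):
        rng = np.random.default_rng(8)
        images = [rng.uniform(0, 1, (16, 16, 3)) for _ in range(40)]
        labels = np.array([0, 1] * 20)
        shuffled = rng.permutation(labels)
        clf = ConvReferenceClassifier(seed=0).fit(images[:30], shuffled[:30])
        acc = np.mean(clf.predict(images[30:]) == shuffled[30:])
        assert abs(acc - 0.5) <= 0.35

    def test_too_few_frames_rejected(self):
        frames = make_tissue_frames(2, 2, (16, 16), seed=9)
        with pytest.raises(ValueError, match="at least"):
            small_cnn_reference(frames, configuration_by_name("wli"), min_frames=8)
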