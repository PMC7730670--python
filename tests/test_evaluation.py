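"""Confusion matrices, one-vs-all metrics, AUC and patient-disjoint folds."""

import numpy as np
import pytest

from hsibrain import (
    BG,
    BV,
    NT,
    TT,
    ConfusionMatrix,
    CrossValSummary,
    LabelMap,
    MetricsReport,
    SpectralCube,
    confusion_from_predictions,
    lopocv,
    per_class_metrics,
    render_classification_map,
    roc_auc_one_vs_all,
)
from hsibrain.errors import SizeError, ValidationError
from hsibrain.evaluation import LopocvConfig
from hsibrain.io import load_reference_class_counts
from hsibrain.models import TrainConfig


def brute_force_confusion(truth, predicted):
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth, predicted):
        counts[t - 1][p - 1] += 1
    return counts


def concordance_auc(scores, binary):
    """O(n^2) pairwise concordance with half credit for ties."""
    pos = scores[binary == 1]
    neg = scores[binary == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([1, 2, 3, 4, 2, 2])
        cm = confusion_from_predictions(y, y)
        assert np.trace(cm.counts) == 6
        assert cm.counts.sum() == 6

    def test_constant_prediction_single_column(self, rng):
        y = rng.integers(1, 5, 30)
        cm = confusion_from_predictions(y, np.full(30, 4))
        assert cm.counts[:, :3].sum() == 0
        assert cm.counts[:, 3].sum() == 30

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            t = rng.integers(1, 5, 50)
            p = rng.integers(1, 5, 50)
            np.testing.assert_array_equal(
                confusion_from_predictions(t, p).counts, brute_force_confusion(t, p)
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_from_predictions(np.array([1, 2]), np.array([1]))

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValidationError):
            confusion_from_predictions(np.array([0]), np.array([1]))


class TestPerClassMetrics:
    def test_direct_substitution_example(self):
        # one-vs-all for NT: TP=8, FN=2, FP=0, TN=90
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 8
        counts[0, 1] = 2
        counts[1, 1] = 90
        report = per_class_metrics(ConfusionMatrix(counts))
        assert report.metric(NT, "sensitivity") == pytest.approx(0.8)
        assert report.metric(NT, "specificity") == pytest.approx(1.0)

    def test_perfect_diagonal_all_ones(self):
        report = per_class_metrics(ConfusionMatrix(np.diag([5, 5, 5, 5])))
        assert report.overall_accuracy == 1.0
        for code in (NT, TT, BV, BG):
            assert report.metric(code, "sensitivity") == 1.0
            assert report.metric(code, "specificity") == 1.0
            assert report.metric(code, "accuracy") == 1.0

    def test_absent_class_sensitivity_is_na(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 10  # only NT present
        report = per_class_metrics(ConfusionMatrix(counts))
        assert report.metric(TT, "sensitivity") is None
        assert report.metric(TT, "specificity") == 1.0  # TN support exists

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            per_class_metrics(ConfusionMatrix(np.zeros((4, 4), dtype=int)))

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        """Trace/total and one-vs-all ratios agree exactly on 1,000 matrices."""
        for _ in range(1000):
            counts = rng.integers(0, 20, (4, 4))
            if counts.sum() == 0:
                continue
            report = per_class_metrics(ConfusionMatrix(counts))
            total = counts.sum()
            assert report.overall_accuracy == np.trace(counts) / total
            for k, code in enumerate((NT, TT, BV, BG)):
                tp = counts[k, k]
                fn = counts[k].sum() - tp
                fp = counts[:, k].sum() - tp
                tn = total - tp - fn - fp
                sens = tp / (tp + fn) if tp + fn else None
                spec = tn / (tn + fp) if tn + fp else None
                assert report.metric(code, "sensitivity") == sens
                assert report.metric(code, "specificity") == spec
                assert report.metric(code, "accuracy") == (tp + tn) / total


class TestAuc:
    def test_one_hot_scores_give_auc_one(self):
        truth = np.array([1, 2, 3, 4, 1, 2])
        scores = np.zeros((6, 4))
        scores[np.arange(6), truth - 1] = 1.0
        aucs = roc_auc_one_vs_all(scores, truth)
        assert all(aucs[c] == 1.0 for c in (1, 2, 3, 4))

    def test_constant_scores_give_chance_level(self):
        truth = np.array([1, 2, 1, 2, 1, 2])
        scores = np.full((6, 4), 0.25)
        aucs = roc_auc_one_vs_all(scores, truth)
        assert aucs[1] == pytest.approx(0.5)
        assert aucs[2] == pytest.approx(0.5)

    def test_absent_class_is_na(self):
        truth = np.array([1, 1, 2])
        scores = np.random.default_rng(0).dirichlet(np.ones(4), 3)
        assert roc_auc_one_vs_all(scores, truth)[3] is None

    def test_matches_concordance_oracle(self, rng):
        """AUC equals the O(n^2) tie-aware concordance count to 1e-12."""
        for _ in range(25):
            n = int(rng.integers(10, 60))
            truth = rng.integers(1, 5, n)
            if len(np.unique(truth)) < 2:
                continue
            scores = rng.dirichlet(np.ones(4), n)
            scores = np.round(scores, 2)  # induce ties
            aucs = roc_auc_one_vs_all(scores, truth)
            for code in np.unique(truth):
                binary = (truth == code).astype(int)
                if binary.min() == binary.max():
                    continue
                expected = concordance_auc(scores[:, code - 1], binary)
                assert abs(aucs[code] - expected) < 1e-12


class TestCrossValSummary:
    def _report(self, acc, tt_sens):
        per_class = {c: {"sensitivity": None, "specificity": None,
                         "auc": None, "accuracy": None} for c in (1, 2, 3, 4)}
        per_class[TT]["sensitivity"] = tt_sens
        return MetricsReport(acc, per_class)

    def test_na_folds_excluded_from_mean_and_std(self):
        summary = CrossValSummary([
            self._report(0.8, 0.5), self._report(0.6, None), self._report(1.0, 0.7),
        ])
        mean, std = summary.mean_std("sensitivity", TT)
        assert mean == pytest.approx(0.6)
        assert std == pytest.approx(np.std([0.5, 0.7]))
        mean_acc, _ = summary.mean_std("overall_accuracy")
        assert mean_acc == pytest.approx((0.8 + 0.6 + 1.0) / 3)

    def test_all_na_gives_nan(self):
        summary = CrossValSummary([self._report(0.5, None)])
        mean, std = summary.mean_std("sensitivity", TT)
        assert np.isnan(mean) and np.isnan(std)


class _MajoritySpectrumClassifier:
    """Deterministic stand-in model: class = argmin distance to class means."""

    def __init__(self, n_bands, seed):
        self.means = None

    def fit(self, patches, labels, config=None):
        self.means = {}
        for c in np.unique(labels):
            self.means[c] = patches[labels == c].mean(axis=(0, 1, 2))
        return self

    def predict_proba(self, patches):
        spectra = patches.mean(axis=(1, 2))
        out = np.zeros((len(patches), 4))
        for i, s in enumerate(spectra):
            d = {c: np.linalg.norm(s - m) for c, m in self.means.items()}
            scores = np.full(4, -1e6)
            for c, dist in d.items():
                scores[c - 1] = -dist
            e = np.exp(scores - scores.max())
            out[i] = e / e.sum()
        return out


class TestLopocv:
    def _toy_dataset(self, rng, patients=("A", "A", "B", "C")):
        dataset = []
        for i, pid in enumerate(patients):
            values = rng.random((22, 22, 5)) + 0.1
            cube = SpectralCube(values, np.linspace(500, 540, 5),
                                patient_id=pid, image_id=f"{pid}-{i}",
                                stage="averaged")
            labels = LabelMap(rng.integers(0, 5, (22, 22)),
                              patient_id=pid, image_id=f"{pid}-{i}")
            dataset.append((cube, labels))
        return dataset

    def test_one_fold_per_patient(self, rng):
        dataset = self._toy_dataset(rng)
        summary = lopocv(dataset, _MajoritySpectrumClassifier,
                         LopocvConfig(patch_size=11, n_select=None,
                                      train=TrainConfig(epochs=1)))
        assert len(summary.reports) == 3
        assert [r.patient_id for r in summary.reports] == ["A", "B", "C"]

    def test_single_patient_rejected(self, rng):
        dataset = self._toy_dataset(rng, patients=("A", "A"))
        with pytest.raises(ValidationError):
            lopocv(dataset, _MajoritySpectrumClassifier,
                   LopocvConfig(n_select=None, train=TrainConfig(epochs=1)))

    def test_reference_image_list_groups_into_nine_folds(self):
        """The packaged 12-image summary spans exactly nine patients."""
        table = load_reference_class_counts()
        assert len(table.patient_ids()) == 9


class TestRenderMap:
    def test_quadrant_cube_painted_by_prediction(self, rng):
        # classifier trained on quadrant-pure patches predicts each quadrant
        values = np.zeros((22, 22, 3))
        values[:11, :11] += 1.0
        values[:11, 11:] += 2.0
        values[11:, :11] += 3.0
        values[11:, 11:] += 4.0
        cube = SpectralCube(values + rng.random((22, 22, 3)) * 0.01,
                            np.array([500.0, 510.0, 520.0]), stage="averaged")
        clf = _MajoritySpectrumClassifier(3, 0)
        patches = np.stack([
            values[:11, :11], values[:11, 11:], values[11:, :11], values[11:, 11:]
        ])
        clf.fit(patches, np.array([1, 2, 3, 4]))
        rgb, codes = render_classification_map(clf, cube, patch_size=11)
        assert codes[0, 0] == 1 and codes[0, 21] == 2
        assert codes[21, 0] == 3 and codes[21, 21] == 4

    def test_constant_bg_prediction_paints_black(self, rng):
        class AlwaysBg:
            def predict_proba(self, patches):
                out = np.zeros((len(patches), 4))
                out[:, 3] = 1.0
                return out

        cube = SpectralCube(rng.random((11, 11, 2)), np.array([500.0, 510.0]),
                            stage="averaged")
        rgb, codes = render_classification_map(AlwaysBg(), cube, patch_size=11)
        assert np.all(codes == 4)
        np.testing.assert_allclose(rgb, 0.0)  # BG renders black

    def test_margins_left_unlabeled(self, rng):
        cube = SpectralCube(rng.random((13, 13, 2)), np.array([500.0, 510.0]),
                            stage="averaged")

        class AlwaysNt:
            def predict_proba(self, patches):
                out = np.zeros((len(patches), 4))
                out[:, 0] = 1.0
                return out

        rgb, codes = render_classification_map(AlwaysNt(), cube, patch_size=11)
        assert np.all(codes[:11, :11] == 1)
        assert np.all(codes[11:, :] == 0) and np.all(codes[:, 11:] == 0)
        np.testing.assert_allclose(rgb[12, 12], [1.0, 1.0, 1.0])  # white margin

    def test_palette_matches_annotation_colors(self):
        from hsibrain.io import render_label_colors

        img = render_label_colors(np.array([[1, 2], [3, 4]]))
        np.testing.assert_allclose(img[0, 0], [0.0, 0.8, 0.0])  # NT green
        np.testing.assert_allclose(img[0, 1], [1.0, 0.0, 0.0])  # TT red
        np.testing.assert_allclose(img[1, 0], [0.0, 0.0, 1.0])  # BV blue
        np.testing.assert_allclose(img[1, 1], [0.0, 0.0, 0.0])  # BG black

    def test_cube_smaller_than_patch_rejected(self, rng):
        cube = SpectralCube(rng.random((5, 5, 2)), np.array([500.0, 510.0]),
                            stage="averaged")
        with pytest.raises(SizeError):
            render_classification_map(_MajoritySpectrumClassifier(2, 0), cube,
                                      patch_size=11)
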