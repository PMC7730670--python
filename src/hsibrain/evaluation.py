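"""Leave-one-patient-out evaluation, per-class metrics and map rendering.

Metrics follow the one-vs-all reduction per class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

with the overall multiclass accuracy taken as trace/total of the confusion
matrix.  A metric whose denominator has no support in the truth set (e.g.
tumor sensitivity in a patient without labeled tumor pixels) is reported as
n/a (``None``), never as zero, and n/a folds are excluded from cross-fold
means and standard deviations.  Per-class AUC is one-vs-all, trapezoidal over
all score thresholds, with ties credited one half.

Cross-validation is patient-disjoint: each fold holds out *all* images of one
patient, and band selection, normalization statistics and training use
training-fold data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

from . import band_selection as bs
from .cube import CLASS_CODES, CLASS_NAMES, LabelMap, SpectralCube
from .errors import SizeError, ValidationError
from .io import render_label_colors
from .models import TrainConfig
from .patching import PatchSet, compute_band_stats, extract_patches, normalize_patches


@dataclass
class ConfusionMatrix:
    """4 x 4 count matrix; rows = true class, columns = predicted (NT, TT, BV, BG)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValidationError(f"confusion matrix must be 4x4, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_all(self, code: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against the rest."""
        k = code - 1
        tp = int(self.counts[k, k])
        fn = int(self.counts[k].sum() - tp)
        fp = int(self.counts[:, k].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion_from_predictions(truth: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    """Cross-tabulate true vs. predicted class codes (both in {1..4})."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValidationError("truth and prediction lengths differ")
    for name, arr in (("truth", truth), ("prediction", predicted)):
        if arr.size and not np.isin(arr, CLASS_CODES).all():
            raise ValidationError(f"{name} contains codes outside {{1..4}}")
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (truth - 1, predicted - 1), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Per-fold metrics; ``None`` marks a metric with no support (n/a)."""

    overall_accuracy: float | None
    per_class: dict[int, dict[str, float | None]]  # code -> metric name -> value
    fold_id: str = ""
    patient_id: str = ""

    def metric(self, code: int, name: str) -> float | None:
        return self.per_class[code][name]


def per_class_metrics(cm: ConfusionMatrix, fold_id: str = "", patient_id: str = "") -> MetricsReport:
    """One-vs-all accuracy/sensitivity/specificity per class plus overall accuracy."""
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")
    per_class: dict[int, dict[str, float | None]] = {}
    for code in CLASS_CODES:
        tp, fn, fp, tn = cm.one_vs_all(code)
        per_class[code] = {
            "accuracy": (tp + tn) / cm.total,
            "sensitivity": tp / (tp + fn) if (tp + fn) > 0 else None,
            "specificity": tn / (tn + fp) if (tn + fp) > 0 else None,
            "auc": None,
        }
    overall = float(np.trace(cm.counts)) / cm.total
    return MetricsReport(overall, per_class, fold_id=fold_id, patient_id=patient_id)


def roc_auc_one_vs_all(scores: np.ndarray, truth: np.ndarray) -> dict[int, float | None]:
    """Per-class one-vs-all AUC from a probability matrix.

    Classes absent from the truth (or covering all of it) get ``None``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    if len(scores) != len(truth):
        raise ValidationError("scores and truth lengths differ")
    out: dict[int, float | None] = {}
    for code in CLASS_CODES:
        binary = (truth == code).astype(int)
        if binary.min() == binary.max():  # absent class or degenerate truth
            out[code] = None
        else:
            out[code] = float(roc_auc_score(binary, scores[:, code - 1]))
    return out


@dataclass
class CrossValSummary:
    """Per-fold reports plus n/a-aware mean and standard deviation."""

    reports: list[MetricsReport]

    def _collect(self, getter: Callable[[MetricsReport], float | None]) -> np.ndarray:
        vals = [getter(r) for r in self.reports]
        return np.array([v for v in vals if v is not None], dtype=np.float64)

    def mean_std(self, metric: str, code: int | None = None) -> tuple[float, float]:
        """Fold mean and (population) std of a metric, skipping n/a folds.

        ``metric`` is ``"overall_accuracy"`` or a per-class name with ``code``.
        """
        if code is None:
            vals = self._collect(lambda r: r.overall_accuracy)
        else:
            vals = self._collect(lambda r: r.per_class[code][metric])
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std())

    def as_table(self) -> "object":
        """Summary rows per fold (pandas DataFrame) mirroring the per-patient layout."""
        import pandas as pd

        rows = []
        for r in self.reports:
            row = {"fold": r.fold_id, "patient": r.patient_id, "accuracy": r.overall_accuracy}
            for code in CLASS_CODES:
                for m in ("sensitivity", "specificity", "auc"):
                    row[f"{m}_{CLASS_NAMES[code]}"] = r.per_class[code][m]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LopocvConfig:
    """Configuration of one cross-validated pipeline run."""

    patch_size: int = 11
    n_select: int | None = None  # None: skip band selection
    aco_ants: int = 5
    aco_generations: int = 4
    aco_max_pixels: int = 600  # labeled-pixel subsample for the SVM fitness
    band_selection_scope: str = "per-fold"  # "per-fold" (leakage-safe) or "global"
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def _labeled_pixels(
    items: list[tuple[SpectralCube, LabelMap]], max_pixels: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced labeled-pixel subsample for the band-selection objective.

    Equal per-class counts make the SVM subset accuracy sensitive to every
    tissue class: under the cohort's natural imbalance a subset that ignores
    the rare tumor class entirely would still score high, and the search
    would discard the tumor-discriminative wavelengths.
    """
    xs, ys = [], []
    for cube, labels in items:
        mask = labels.labels > 0
        xs.append(cube.values[mask])
        ys.append(labels.labels[mask])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    codes = np.unique(y)
    per_class = max(2, max_pixels // len(codes))
    keep = []
    for code in codes:
        idx = np.flatnonzero(y == code)
        take = min(per_class, len(idx))
        keep.append(rng.choice(idx, size=take, replace=False) if len(idx) > take else idx)
    keep = np.concatenate(keep)
    return x[keep], y[keep]


def _select_bands_for(
    items: list[tuple[SpectralCube, LabelMap]], config: LopocvConfig, seed: int
) -> bs.BandSubset | None:
    if config.n_select is None:
        return None
    rng = np.random.default_rng(seed)
    x, y = _labeled_pixels(items, config.aco_max_pixels, rng)
    return bs.aco_select_bands(
        x, y, n_select=config.n_select,
        ants=config.aco_ants, generations=config.aco_generations,
        seed=seed, wavelengths=items[0][0].wavelengths,
    )


def lopocv(
    dataset: list[tuple[SpectralCube, LabelMap]],
    classifier_factory: Callable[[int, int], object],
    config: LopocvConfig,
) -> CrossValSummary:
    """Leave-one-patient-out cross-validation of the full pipeline.

    ``dataset`` holds prepared (calibrated/averaged) cubes with their label
    maps; patient identity is read from the cubes.  ``classifier_factory`` is
    called as ``factory(n_bands, seed)`` for every fold and must return an
    object with the shared fit/predict_proba contract.
    """
    patients = []
    for cube, labels in dataset:
        if cube.patient_id not in patients:
            patients.append(cube.patient_id)
    if len(patients) < 2:
        raise ValidationError("cross-validation requires at least two patients")

    global_subset = None
    if config.n_select is not None and config.band_selection_scope == "global":
        global_subset = _select_bands_for(dataset, config, config.seed)

    reports: list[MetricsReport] = []
    for fold_idx, held_out in enumerate(patients):
        train_items = [(c, l) for c, l in dataset if c.patient_id != held_out]
        test_items = [(c, l) for c, l in dataset if c.patient_id == held_out]
        assert not {c.patient_id for c, _ in train_items} & {c.patient_id for c, _ in test_items}

        subset = global_subset
        if config.n_select is not None and config.band_selection_scope == "per-fold":
            subset = _select_bands_for(train_items, config, config.seed + fold_idx)

        def prepare(items):
            sets = []
            for cube, labels in items:
                c = cube if subset is None else bs.apply_band_subset(cube, subset)
                sets.append(extract_patches(c, labels, config.patch_size))
            return PatchSet.concatenate(sets)

        train_set = prepare(train_items)
        test_set = prepare(test_items)
        stats = compute_band_stats(train_set)
        train_set = normalize_patches(train_set, stats)
        test_set = normalize_patches(test_set, stats)

        clf = classifier_factory(train_set.band_count, config.train.seed + fold_idx)
        clf.fit(train_set.patches, train_set.labels, config.train)

        probs = clf.predict_proba(test_set.patches)
        predicted = np.argmax(probs, axis=1) + 1
        cm = confusion_from_predictions(test_set.labels, predicted)
        report = per_class_metrics(cm, fold_id=f"fold-{fold_idx}", patient_id=held_out)
        for code, auc in roc_auc_one_vs_all(probs, test_set.labels).items():
            report.per_class[code]["auc"] = auc
        reports.append(report)
    return CrossValSummary(reports)


def render_classification_map(
    model,
    cube: SpectralCube,
    subset: bs.BandSubset | None = None,
    patch_size: int = 11,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict every full tile of a cube and paint it with its class color.

    Returns ``(rgb, codes)``: an (H, W, 3) float image (green/red/blue/black
    for NT/TT/BV/BG, white margins) and the (H, W) predicted-code image with
    0 on the remainder margins.
    """
    c = cube if subset is None else bs.apply_band_subset(cube, subset)
    rows, cols, bands = c.shape
    n_r, n_c = rows // patch_size, cols // patch_size
    if n_r == 0 or n_c == 0:
        raise SizeError(f"cube {rows}x{cols} smaller than one {patch_size}-pixel patch")

    tiles = np.stack([
        c.values[r * patch_size:(r + 1) * patch_size, cc * patch_size:(cc + 1) * patch_size, :]
        for r in range(n_r) for cc in range(n_c)
    ])
    if stats is not None:
        tiles = (tiles - stats[0]) / stats[1]
    predicted = np.argmax(model.predict_proba(tiles), axis=1) + 1

    codes = np.zeros((rows, cols), dtype=np.int64)
    k = 0
    for r in range(n_r):
        for cc in range(n_c):
            codes[r * patch_size:(r + 1) * patch_size,
                  cc * patch_size:(cc + 1) * patch_size] = predicted[k]
            k += 1
    return render_label_colors(codes), codes
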