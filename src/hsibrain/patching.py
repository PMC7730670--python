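"""Tiling of labeled cubes into non-overlapping spectral-spatial patches.

An image is tiled into P x P tiles anchored at the top-left corner; remainder
rows/columns are dropped.  Each tile's label is the modal class among its
*labeled* pixels (unlabeled pixels do not vote); tiles without any labeled
pixel are discarded.  Equal modal counts break by the tumor-sensitive
priority TT > BV > NT > BG, because a missed tumor patch is the clinically
costly error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cube import CLASS_CODES, LabelMap, SpectralCube, check_aligned
from .errors import SizeError, ValidationError

#: Patch edge length used by the reference pipeline.
DEFAULT_PATCH_SIZE = 11

#: Modal-count tie-break priority (first wins).
TIE_PRIORITY = (2, 3, 1, 4)  # TT > BV > NT > BG


@dataclass
class PatchSet:
    """Labeled spectral-spatial patches tagged by patient and image."""

    patches: np.ndarray  # (N, P, P, B)
    labels: np.ndarray  # (N,) codes in {1..4}
    patient_ids: list[str]
    image_ids: list[str]

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 4 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValidationError(f"patches must be (N, P, P, B), got {self.patches.shape}")
        n = len(self.patches)
        if not (len(self.labels) == len(self.patient_ids) == len(self.image_ids) == n):
            raise ValidationError("patches, labels and ids must have equal length")
        if n and not np.isin(self.labels, CLASS_CODES).all():
            raise ValidationError("patch labels must be in {1..4}")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]

    @property
    def band_count(self) -> int:
        return self.patches.shape[3]

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels, minlength=5)
        return {c: int(counts[c]) for c in CLASS_CODES}

    def subset(self, mask: np.ndarray) -> "PatchSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return PatchSet(
            patches=self.patches[idx],
            labels=self.labels[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            image_ids=[self.image_ids[i] for i in idx],
        )

    @staticmethod
    def concatenate(sets: list["PatchSet"]) -> "PatchSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValidationError("cannot concatenate empty patch sets")
        return PatchSet(
            patches=np.concatenate([s.patches for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            patient_ids=[p for s in sets for p in s.patient_ids],
            image_ids=[i for s in sets for i in s.image_ids],
        )


def majority_label(tile_labels: np.ndarray) -> int:
    """Modal class among labeled pixels of a tile, 0 if none are labeled.

    Ties break by :data:`TIE_PRIORITY`.
    """
    counts = np.bincount(tile_labels.ravel(), minlength=5)
    counts[0] = 0
    top = counts.max()
    if top == 0:
        return 0
    for code in TIE_PRIORITY:
        if counts[code] == top:
            return code
    raise AssertionError("unreachable")


def extract_patches(
    cube: SpectralCube, labels: LabelMap, patch_size: int = DEFAULT_PATCH_SIZE
) -> PatchSet:
    """Tile a cube into non-overlapping labeled patches (see module docstring)."""
    check_aligned(cube, labels)
    patch_size = int(patch_size)
    if patch_size < 1:
        raise SizeError("patch_size must be >= 1")
    rows, cols, bands = cube.shape
    n_r, n_c = rows // patch_size, cols // patch_size

    patches, patch_labels = [], []
    for r in range(n_r):
        for c in range(n_c):
            rs, cs = r * patch_size, c * patch_size
            tile_lab = labels.labels[rs : rs + patch_size, cs : cs + patch_size]
            code = majority_label(tile_lab)
            if code == 0:
                continue
            patches.append(cube.values[rs : rs + patch_size, cs : cs + patch_size, :])
            patch_labels.append(code)

    n = len(patches)
    return PatchSet(
        patches=np.asarray(patches).reshape(n, patch_size, patch_size, bands),
        labels=np.asarray(patch_labels, dtype=np.int64),
        patient_ids=[cube.patient_id] * n,
        image_ids=[cube.image_id] * n,
    )


def compute_band_stats(train: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean and standard deviation over all pixels of a training set.

    Zero-variance bands are floored at 1e-8 (a warning is issued) so that
    standardization stays finite.
    """
    pixels = train.patches.reshape(-1, train.band_count)
    mean = pixels.mean(axis=0)
    std = pixels.std(axis=0)
    if np.any(std < 1e-8):
        warnings.warn("zero-variance band(s) encountered; flooring std at 1e-8")
        std = np.maximum(std, 1e-8)
    return mean, std


def normalize_patches(pset: PatchSet, stats: tuple[np.ndarray, np.ndarray]) -> PatchSet:
    """Standardize patches per band using training-fold statistics.

    Test folds must be standardized with the *training* statistics so that no
    information leaks across the patient split.
    """
    mean, std = stats
    return PatchSet(
        patches=(pset.patches - mean) / std,
        labels=pset.labels,
        patient_ids=list(pset.patient_ids),
        image_ids=list(pset.image_ids),
    )
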