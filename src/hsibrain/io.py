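"""Readers and writers for label maps, class-count tables and RGB composites.

Label maps travel either as indexed PNG (palette: white = unlabeled, then
green/red/blue/black for NT/TT/BV/BG) or as integer CSV.  Class-count tables
are CSV with one row per acquired image; the annotation summary of the in vivo
brain cohort this package models ships as a packaged fixture.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .cube import CLASS_CODES, CLASS_NAMES, CLASS_PALETTE, LabelMap, SpectralCube, UNLABELED
from .errors import RangeError, ValidationError

_VALID_CODES = (UNLABELED, *CLASS_CODES)


# ---------------------------------------------------------------------------
# Label maps


def write_label_map(label_map: LabelMap, path: str) -> None:
    """Write a label map as indexed PNG (``.png``) or integer CSV (anything else)."""
    path = str(path)
    if path.lower().endswith(".png"):
        img = Image.fromarray(label_map.labels.astype(np.uint8), mode="P")
        palette = []
        for code in _VALID_CODES:
            palette.extend(int(round(255 * v)) for v in CLASS_PALETTE[code])
        img.putpalette(palette + [0] * (768 - len(palette)))
        img.save(path)
    else:
        np.savetxt(path, label_map.labels, fmt="%d", delimiter=",")


def read_label_map(path: str, patient_id: str = "", image_id: str = "") -> LabelMap:
    """Read a label map written by :func:`write_label_map`.

    Raises
    ------
    ValidationError
        If codes outside {0..4} occur; the offending codes are listed.
    """
    path = str(path)
    if path.lower().endswith(".png"):
        labels = np.asarray(Image.open(path), dtype=np.int64)
    else:
        labels = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    bad = np.setdiff1d(np.unique(labels), _VALID_CODES)
    if bad.size:
        raise ValidationError(f"label file {path} contains unknown codes: {bad.tolist()}")
    return LabelMap(labels=labels, patient_id=patient_id, image_id=image_id)


def render_label_colors(labels: np.ndarray) -> np.ndarray:
    """Map a 2-D code array to an (H, W, 3) float RGB image using the fixed palette."""
    out = np.zeros(labels.shape + (3,), dtype=np.float64)
    for code in _VALID_CODES:
        out[labels == code] = CLASS_PALETTE[code]
    return out


# ---------------------------------------------------------------------------
# Class-count tables


@dataclass
class ClassCountTable:
    """Per-image labeled-pixel counts for the four tissue classes."""

    table: pd.DataFrame  # columns: image_id, NT, TT, BV, BG

    def __post_init__(self) -> None:
        cols = ["image_id", "NT", "TT", "BV", "BG"]
        missing = [c for c in cols if c not in self.table.columns]
        if missing:
            raise ValidationError(f"class-count table missing columns {missing}")
        self.table = self.table[cols].reset_index(drop=True)
        if self.table["image_id"].duplicated().any():
            raise ValidationError("class-count table has duplicate image_ids")
        counts = self.table[["NT", "TT", "BV", "BG"]]
        if (counts.to_numpy() < 0).any():
            raise ValidationError("class-count table has negative counts")

    def __len__(self) -> int:
        return len(self.table)

    def totals(self) -> dict[str, int]:
        """Column totals over all images."""
        return {c: int(self.table[c].sum()) for c in ("NT", "TT", "BV", "BG")}

    def patient_ids(self) -> list[str]:
        """Distinct patients, taking the prefix before '-' of each image_id."""
        seen: list[str] = []
        for image_id in self.table["image_id"]:
            pid = str(image_id).split("-")[0]
            if pid not in seen:
                seen.append(pid)
        return seen


def load_class_count_table(path: str) -> ClassCountTable:
    """Load a class-count CSV with columns image_id, NT, TT, BV, BG."""
    return ClassCountTable(pd.read_csv(path, dtype={"image_id": str}))


def load_reference_class_counts() -> ClassCountTable:
    """The packaged annotation summary of the 12-image, 9-patient brain cohort."""
    ref = importlib.resources.files("hsibrain") / "data" / "cohort_class_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return load_class_count_table(str(path))


# ---------------------------------------------------------------------------
# RGB composites


def make_rgb_composite(
    cube: SpectralCube, rgb_wavelengths: tuple[float, float, float] = (700.0, 550.0, 470.0)
) -> np.ndarray:
    """Build a false-color image from three wavelengths (nearest band each).

    Each channel is the nearest-band slice min-max rescaled to [0, 1]; ties in
    the nearest-band search break to the lower band index.  Constant bands map
    to mid-gray 0.5.
    """
    lo, hi = float(cube.wavelengths[0]), float(cube.wavelengths[-1])
    out = np.empty(cube.values.shape[:2] + (3,), dtype=np.float64)
    for ch, wl in enumerate(rgb_wavelengths):
        if not (lo <= wl <= hi):
            raise RangeError(f"wavelength {wl} nm outside cube range [{lo}, {hi}] nm")
        band = cube.values[:, :, cube.nearest_band(wl)]
        span = band.max() - band.min()
        out[:, :, ch] = 0.5 if span == 0 else (band - band.min()) / span
    return out


__all__ = [
    "ClassCountTable",
    "load_class_count_table",
    "load_reference_class_counts",
    "make_rgb_composite",
    "read_label_map",
    "render_label_colors",
    "write_label_map",
    "CLASS_NAMES",
]
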