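"""Core in-memory data model: spectral cubes, label maps and class codes.

A hyperspectral cube is stored as a single (row, col, band) float array with a
strictly increasing wavelength axis in nanometres.  Interleave variants
(BIL/BSQ/BIP) exist only on disk; see :mod:`hsibrain.envi`.

Tissue classes follow the intraoperative annotation convention: normal tissue
(NT), tumor tissue (TT), blood vessels (BV) and background (BG), with code 0
reserved for unlabeled pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

#: Label codes.
UNLABELED, NT, TT, BV, BG = 0, 1, 2, 3, 4

#: Class codes in reporting order (NT, TT, BV, BG).
CLASS_CODES = (NT, TT, BV, BG)

CLASS_NAMES = {NT: "NT", TT: "TT", BV: "BV", BG: "BG"}

#: Display palette (RGB in [0, 1]): green/red/blue/black for the four tissue
#: classes, white for unlabeled pixels.
CLASS_PALETTE = {
    UNLABELED: (1.0, 1.0, 1.0),
    NT: (0.0, 0.8, 0.0),
    TT: (1.0, 0.0, 0.0),
    BV: (0.0, 0.0, 1.0),
    BG: (0.0, 0.0, 0.0),
}

#: Processing stages in their only permitted order.
STAGES = ("raw", "reflectance", "trimmed", "averaged", "selected")


def _stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


@dataclass
class SpectralCube:
    """A (rows, cols, bands) reflectance/radiance array with wavelength axis.

    Parameters
    ----------
    values
        Non-negative float array indexed (row, col, band).
    wavelengths
        Strictly increasing band-centre wavelengths in nm, one per band.
    patient_id, image_id
        Acquisition identity used for patient-disjoint cross-validation.
    stage
        Processing stage; transitions may only move forward through
        ``raw -> reflectance -> trimmed -> averaged -> selected``.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    patient_id: str = ""
    image_id: str = ""
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"cube values must be 3-D, got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValidationError(
                f"wavelength count {self.wavelengths.shape} does not match "
                f"band dimension {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("cube values must be finite")
        _stage_index(self.stage)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def advanced(self, stage: str, values=None, wavelengths=None) -> "SpectralCube":
        """Return a copy at a later processing stage (forward-only)."""
        if _stage_index(stage) < _stage_index(self.stage):
            raise ValidationError(
                f"stage may not move backward: {self.stage!r} -> {stage!r}"
            )
        out = replace(self, stage=stage)
        if values is not None:
            out.values = np.asarray(values, dtype=np.float64)
        if wavelengths is not None:
            out.wavelengths = np.asarray(wavelengths, dtype=np.float64)
        out.__post_init__()
        return out

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band closest to ``wavelength_nm``; ties to the lower index."""
        d = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(d))  # argmin returns the first (lower) index on ties


@dataclass
class LabelMap:
    """Per-pixel class annotation aligned with a companion cube."""

    labels: np.ndarray
    patient_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError(f"label map must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValidationError("label codes must be integers")
            self.labels = self.labels.astype(np.int64)
        bad = np.setdiff1d(np.unique(self.labels), [UNLABELED, *CLASS_CODES])
        if bad.size:
            raise ValidationError(f"unknown label codes present: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[int, int]:
        """Pixel count per tissue class (unlabeled excluded)."""
        flat = np.bincount(self.labels.ravel(), minlength=5)
        return {c: int(flat[c]) for c in CLASS_CODES}


def check_aligned(cube: SpectralCube, labels: LabelMap) -> None:
    """Raise if a cube and a label map do not share spatial dimensions."""
    from .errors import AlignmentError

    if cube.values.shape[:2] != labels.labels.shape:
        raise AlignmentError(
            f"cube spatial shape {cube.values.shape[:2]} != label map shape {labels.labels.shape}"
        )
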