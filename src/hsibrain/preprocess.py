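"""Reflectance calibration, extreme-band trimming and band-group averaging.

Calibration removes illumination and dark-current effects:

    R = (I_raw - I_dark) / (I_white - I_dark)

where the white reference is a standard tile captured under the acquisition
illumination and the dark reference is a closed-shutter capture.  Both may be
a single per-band spectrum (broadcast over pixels) or a full cube.

The sensor's extreme bands are noisy; trimming keeps only the bands whose
wavelength lies in a closed nm window (default 440-902 nm).  Dimensionality is
further reduced by averaging consecutive non-overlapping groups of bands
(default eight), applied to the full uncut spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import SpectralCube
from .errors import CalibrationError, RangeError, SizeError

#: Default noisy-band trim window, nm.
DEFAULT_KEEP_NM = (440.0, 902.0)

#: Default band-averaging group size.
DEFAULT_GROUP_SIZE = 8

#: Native band grid of the VNIR pushbroom sensor modelled here: 826 bands over
#: 400-1000 nm.  The grid is piecewise linear with band 55 (1-based) at
#: 440 nm and band 699 at 902 nm, so that the closed trim window [440, 902]
#: retains exactly 645 bands (the sensor's spectral sampling is slightly
#: denser mid-range than at the extremes).
SENSOR_N_BANDS = 826


def sensor_wavelength_grid(n_bands: int = SENSOR_N_BANDS) -> np.ndarray:
    """Wavelength grid (nm) of the modelled 826-band VNIR sensor.

    For the native 826-band count the grid interpolates linearly between the
    anchor points (band 1, 400 nm), (band 55, 440 nm), (band 699, 902 nm),
    (band 826, 1000 nm).  Other band counts fall back to a uniform grid.
    """
    if n_bands == SENSOR_N_BANDS:
        idx = np.arange(1, n_bands + 1, dtype=np.float64)
        return np.interp(idx, [1.0, 55.0, 699.0, 826.0], [400.0, 440.0, 902.0, 1000.0])
    return np.linspace(400.0, 1000.0, n_bands)


@dataclass
class CalibrationReferences:
    """White-tile and dark (closed shutter) reference captures.

    ``white`` and ``dark`` are either per-band spectra of shape (bands,) or
    full cubes of shape (rows, cols, bands); they must broadcast against the
    raw cube.  ``white - dark`` must be strictly positive wherever used.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)


def calibrate_reflectance(raw: SpectralCube, refs: CalibrationReferences) -> SpectralCube:
    """Convert raw sensor counts to reflectance against white/dark references.

    Raises
    ------
    CalibrationError
        If ``white - dark`` is non-positive at any applied position; the
        first offending positions are reported.
    """
    denom = refs.white - refs.dark
    denom_b = np.broadcast_to(denom, raw.values.shape)
    bad = denom_b <= 0
    if bad.any():
        positions = np.argwhere(bad)[:5].tolist()
        raise CalibrationError(
            f"white - dark non-positive at {int(bad.sum())} positions, e.g. {positions}"
        )
    reflectance = (raw.values - refs.dark) / denom
    return raw.advanced("reflectance", values=reflectance)


def uncalibrate(reflectance: SpectralCube, refs: CalibrationReferences) -> SpectralCube:
    """Invert calibration: raw = R * (white - dark) + dark (synthesis helper)."""
    raw = reflectance.values * (refs.white - refs.dark) + refs.dark
    out = SpectralCube(
        values=raw,
        wavelengths=reflectance.wavelengths,
        patient_id=reflectance.patient_id,
        image_id=reflectance.image_id,
        stage="raw",
    )
    return out


def trim_noisy_bands(
    cube: SpectralCube, keep_nm: tuple[float, float] = DEFAULT_KEEP_NM
) -> SpectralCube:
    """Keep only bands whose wavelength lies in the closed window ``keep_nm``.

    On the native 826-band sensor grid the default window retains 645 bands.
    """
    lo, hi = float(keep_nm[0]), float(keep_nm[1])
    mask = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not mask.any():
        raise RangeError(f"no band falls inside keep window [{lo}, {hi}] nm")
    return cube.advanced(
        "trimmed", values=cube.values[:, :, mask], wavelengths=cube.wavelengths[mask]
    )


def average_band_groups(cube: SpectralCube, group_size: int = DEFAULT_GROUP_SIZE) -> SpectralCube:
    """Replace consecutive non-overlapping groups of bands by their mean.

    A trailing incomplete group is discarded (826 bands with groups of eight
    give 103).  The output wavelength of a group is the mean wavelength of its
    members.
    """
    group_size = int(group_size)
    if group_size < 1:
        raise SizeError("group_size must be >= 1")
    n_groups = cube.n_bands // group_size
    if n_groups == 0:
        raise SizeError(f"group_size {group_size} exceeds band count {cube.n_bands}")
    n_used = n_groups * group_size
    rows, cols, _ = cube.shape
    values = cube.values[:, :, :n_used].reshape(rows, cols, n_groups, group_size).mean(axis=3)
    wavelengths = cube.wavelengths[:n_used].reshape(n_groups, group_size).mean(axis=1)
    return cube.advanced("averaged", values=values, wavelengths=wavelengths)
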