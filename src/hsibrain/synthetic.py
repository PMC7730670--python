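"""Synthetic hyperspectral brain cohorts with controlled class structure.

The generator emulates the statistical shape of an intraoperative VNIR
brain dataset — 826 bands over 400-1000 nm, four sparsely labeled and
strongly imbalanced classes (normal tissue, tumor, blood vessels,
background), several images per patient with shared per-patient spectral
perturbations — without any claim of radiometric accuracy.  Class mean
spectra are sums of Gaussian bumps on a linear baseline:

* NT: smooth tissue-like curve rising toward the NIR;
* TT: the NT curve plus a difference term supported in 600-800 nm whose
  magnitude is scaled by a separability knob in [0, 1] (at 0 the two
  classes are spectrally identical — the hard failure mode where tumor
  recall collapses);
* BV: a hemoglobin-like signature with double absorption dips near
  540/575 nm;
* BG: low flat reflectance.

Spatial class layout comes from quantile-thresholded smoothed random
fields (blob-like regions), so tiles near class borders genuinely mix
classes.  Raw sensor counts are synthesized by inverting the reflectance
calibration against generated white/dark references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube import BG, BV, LabelMap, NT, SpectralCube, TT
from .errors import ConfigError, RangeError
from .preprocess import CalibrationReferences, uncalibrate, sensor_wavelength_grid

#: Class prevalence proportional to the labeled-pixel totals of the cohort
#: this generator models (NT : TT : BV : BG = 35396 : 12366 : 27558 : 40486).
DEFAULT_PREVALENCE = {NT: 0.305, TT: 0.107, BV: 0.238, BG: 0.350}

#: Images per patient replicating the modelled cohort's multiplicity
#: (12 images over 9 patients).
DEFAULT_MULTIPLICITY = (2, 1, 2, 1, 1, 2, 1, 1, 1)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions."""

    n_patients: int = 9
    images_per_patient: tuple = DEFAULT_MULTIPLICITY
    image_size: tuple[int, int] = (64, 64)
    n_bands: int = 826
    class_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    label_sparsity: float = 0.15
    separability: float = 1.0
    noise_sd: float = 0.01
    patient_perturbation: float = 0.05
    illumination_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.separability <= 1.0):
            raise ConfigError("separability must lie in [0, 1]")
        if not (0.0 <= self.label_sparsity <= 1.0):
            raise ConfigError("label_sparsity must lie in [0, 1]")
        total = sum(self.class_prevalence.values())
        if total > 1.0 + 1e-9:
            raise ConfigError(f"class prevalences sum to {total:.3f} > 1")
        if min(self.image_size) < 1:
            raise ConfigError("image size must be positive")
        if isinstance(self.images_per_patient, int):
            self.images_per_patient = (self.images_per_patient,) * self.n_patients
        if len(self.images_per_patient) != self.n_patients:
            raise ConfigError("images_per_patient length must equal n_patients")

    @property
    def wavelengths(self) -> np.ndarray:
        return sensor_wavelength_grid(self.n_bands)


@dataclass
class SignatureModel:
    """Per-class mean spectra plus the nuisance scales of the generator."""

    wavelengths: np.ndarray
    class_spectra: dict  # code -> (B,) mean reflectance
    patient_perturbation: float
    noise_sd: float
    illumination_amplitude: float

    def spectrum(self, code: int) -> np.ndarray:
        return self.class_spectra[code]


def make_class_signatures(config: CohortConfig, rng: np.random.Generator) -> SignatureModel:
    """Build the four class mean spectra for one cohort.

    Bump amplitudes get a small reproducible jitter so cohorts differ between
    seeds; the NT-TT difference is a fixed shape inside 600-800 nm scaled by
    ``config.separability`` (0 gives identical NT and TT spectra).
    """
    wl = config.wavelengths
    j = lambda: 1.0 + 0.1 * rng.standard_normal()  # noqa: E731 - amplitude jitter

    nt = (
        0.16 + 0.00030 * (wl - 400.0)
        + 0.10 * j() * _gauss(wl, 520.0, 45.0)
        + 0.12 * j() * _gauss(wl, 860.0, 90.0)
    )
    tt_delta = (
        0.14 * _gauss(wl, 650.0, 22.0)
        - 0.09 * _gauss(wl, 730.0, 26.0)
        + 0.05 * _gauss(wl, 780.0, 15.0)
    )
    tt = nt + config.separability * tt_delta
    bv = (
        0.10 + 0.00040 * (wl - 400.0)
        + 0.22 * j() * _gauss(wl, 640.0, 120.0)
        - 0.11 * j() * _gauss(wl, 540.0, 9.0)
        - 0.11 * j() * _gauss(wl, 575.0, 9.0)
    )
    bg = np.full_like(wl, 0.08) + 0.02 * _gauss(wl, 700.0, 250.0)

    spectra = {NT: nt, TT: tt, BV: bv, BG: bg}
    for code, s in spectra.items():
        spectra[code] = np.clip(s, 0.0, 1.2)
    return SignatureModel(
        wavelengths=wl,
        class_spectra=spectra,
        patient_perturbation=config.patient_perturbation,
        noise_sd=config.noise_sd,
        illumination_amplitude=config.illumination_amplitude,
    )


def _patient_gain(model: SignatureModel, config: CohortConfig, patient_index: int) -> np.ndarray:
    """Smooth multiplicative spectral perturbation shared by a patient's images."""
    prng = np.random.default_rng([config.seed % (2**31), 1009, patient_index])
    wl = model.wavelengths
    curve = np.zeros_like(wl)
    for _ in range(3):
        curve += prng.standard_normal() * _gauss(wl, prng.uniform(450, 950), prng.uniform(60, 150))
    return 1.0 + model.patient_perturbation * curve


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, sigma: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")


def _class_layout(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Blob-like class regions: argmax over per-class smoothed random fields.

    Each class gets an independent smoothed Gaussian field plus an additive
    bias; the biases are iterated so the realized class fractions approach the
    prevalence targets.  Argmax of competing fields yields compact blobby
    regions for every class (no shell geometry), so patch tiles near borders
    genuinely mix classes.
    """
    rows, cols = config.image_size
    codes = (NT, TT, BV, BG)
    targets = np.array([config.class_prevalence[c] for c in codes], dtype=float)
    targets = targets / targets.sum()
    sigma = max(2.0, min(rows, cols) / 8.0)
    fields = np.stack([_smooth_field((rows, cols), rng, sigma) for _ in codes])
    fields /= fields.std(axis=(1, 2), keepdims=True)
    bias = np.zeros(len(codes))
    for _ in range(40):
        winner = np.argmax(fields + bias[:, None, None], axis=0)
        fracs = np.bincount(winner.ravel(), minlength=len(codes)) / winner.size
        bias += 1.5 * (targets - fracs)
    winner = np.argmax(fields + bias[:, None, None], axis=0)
    return np.asarray(codes, dtype=np.int64)[winner]


def generate_patient_image(
    model: SignatureModel,
    config: CohortConfig,
    patient_index: int,
    rng: np.random.Generator,
    patient_id: str = "",
    image_id: str = "",
) -> tuple[SpectralCube, CalibrationReferences, LabelMap]:
    """Synthesize one raw cube + references + sparse label map for a patient."""
    rows, cols = config.image_size
    wl = model.wavelengths
    layout = _class_layout(config, rng)

    gain = _patient_gain(model, config, patient_index)
    illum = 1.0 + model.illumination_amplitude * _smooth_field(
        (rows, cols), rng, sigma=max(2.0, min(rows, cols) / 4.0)
    )

    reflectance = np.empty((rows, cols, len(wl)))
    for code in (NT, TT, BV, BG):
        reflectance[layout == code] = model.spectrum(code) * gain
    reflectance *= illum[:, :, None]
    if model.noise_sd > 0:
        reflectance += rng.normal(0.0, model.noise_sd, size=reflectance.shape)
    np.clip(reflectance, 0.0, None, out=reflectance)

    white = 3000.0 * (0.85 + 0.15 * _gauss(wl, 620.0, 220.0))
    dark = 80.0 + 20.0 * _gauss(wl, 520.0, 300.0)
    refs = CalibrationReferences(white=white, dark=dark)

    refl_cube = SpectralCube(
        values=reflectance, wavelengths=wl,
        patient_id=patient_id, image_id=image_id, stage="reflectance",
    )
    raw = uncalibrate(refl_cube, refs)

    labeled = rng.random((rows, cols)) < config.label_sparsity
    labels = LabelMap(
        labels=np.where(labeled, layout, 0),
        patient_id=patient_id, image_id=image_id,
    )
    return raw, refs, labels


@dataclass
class CohortItem:
    """One synthetic acquisition: raw cube, its references and its labels."""

    raw: SpectralCube
    refs: CalibrationReferences
    labels: LabelMap
    patient_id: str
    image_id: str


def generate_cohort(config: CohortConfig) -> list[CohortItem]:
    """Generate the full cohort (default: 12 images over 9 patients).

    Per-patient spectral perturbations are shared across that patient's
    images; everything is reproducible bit-for-bit from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = make_class_signatures(config, rng)
    cohort: list[CohortItem] = []
    for p in range(config.n_patients):
        patient_id = f"P{p + 1:02d}"
        for k in range(config.images_per_patient[p]):
            image_id = f"{patient_id}-{k + 1:02d}"
            raw, refs, labels = generate_patient_image(
                model, config, p, rng, patient_id=patient_id, image_id=image_id
            )
            cohort.append(CohortItem(raw, refs, labels, patient_id, image_id))
    return cohort


def degrade_illumination(cube: SpectralCube, cutoff_nm: float, scale_nm: float = 150.0) -> SpectralCube:
    """Attenuate reflectance smoothly above a cutoff wavelength.

    Models an acquisition whose infrared illumination was filtered: the gain is
    1 below the cutoff and decays monotonically (Gaussian tail of width
    ``scale_nm``) beyond it, producing an out-of-distribution image.
    """
    wl = cube.wavelengths
    if not (wl[0] <= cutoff_nm <= wl[-1]):
        raise RangeError(f"cutoff {cutoff_nm} nm outside cube range [{wl[0]}, {wl[-1]}] nm")
    excess = np.maximum(wl - cutoff_nm, 0.0)
    gain = np.exp(-0.5 * (excess / scale_nm) ** 2)
    return SpectralCube(
        values=cube.values * gain,
        wavelengths=wl,
        patient_id=cube.patient_id,
        image_id=cube.image_id,
        stage=cube.stage,
    )


def make_informative_window_pixels(
    n_bands: int = 103,
    window: tuple[int, int] = (10, 20),
    n_per_class: int = 150,
    noise_sd: float = 1.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled pixel spectra where only a known band window discriminates.

    Bands inside ``window`` (half-open index range) each carry an independent
    random class-mean pattern of the given amplitude, so classes are only
    weakly separable on any single band and every window band contributes
    complementary information; all other bands are pure noise.  Used to probe
    whether a band-selection search recovers the informative window.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window
    y = np.repeat(np.arange(1, 5), n_per_class)
    x = rng.normal(0.0, noise_sd, (len(y), n_bands))
    class_means = rng.normal(0.0, amplitude, (hi - lo, 4))
    x[:, lo:hi] += class_means[:, y - 1].T
    return x, y
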