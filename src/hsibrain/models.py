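"""The spectral-spatial classifiers: hybrid 3D-2D CNN and its baselines.

Five classifiers share one train/predict contract so the evaluation stage is
classifier-agnostic:

* ``hybrid``     - four valid 3-D convolutions (joint spatial-spectral), a
                   reshape folding the spectral axis into channels, two
                   same-padded 2-D convolutions, then three dense layers
                   ending in a 4-way softmax;
* ``2dcnn``      - three 2-D convolutions (spectral axis as input channels),
                   one average pooling, three dense layers, softmax;
* ``1ddnn``      - a pixel-wise dense net with hidden widths 28 and 40 (ReLU),
                   softmax output;
* ``svm``        - one-vs-rest linear SVM on flattened patch intensities;
* ``hybrid+svm`` - the trained hybrid network as a feature extractor (output
                   of its last convolutional layer) feeding a linear SVM.

Class probability order is always (NT, TT, BV, BG) = codes (1, 2, 3, 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .cube import CLASS_CODES
from .errors import ArchitectureError, StateError, ValidationError
from .nn import (
    AvgPool2D,
    Conv2D,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MergeSpectral,
    Network,
    ReLU,
    softmax,
)
from .patching import PatchSet

N_CLASSES = 4


@dataclass
class HybridArchSpec:
    """Architecture of the hybrid network: exactly 4 + 2 convolutions, 3 dense.

    ``conv3d_layers`` entries are (filters, (kh, kw, kb)); 3-D convolutions are
    valid (unpadded).  ``conv2d_layers`` entries are (filters, (kh, kw)); the
    2-D stage uses same padding so the small 11 x 11 spatial extent survives.
    The final dense width must be 4 (softmax over NT, TT, BV, BG).
    """

    input_shape: tuple[int, int, int] = (11, 11, 100)
    conv3d_layers: tuple = ((8, (3, 3, 7)), (16, (3, 3, 5)), (32, (3, 3, 3)), (32, (3, 3, 3)))
    conv2d_layers: tuple = ((64, (3, 3)), (64, (3, 3)))
    dense_layers: tuple = (256, 128, 4)
    dropout: float = 0.4

    def __post_init__(self) -> None:
        if len(self.conv3d_layers) != 4:
            raise ValidationError("hybrid spec requires exactly four 3-D conv layers")
        if len(self.conv2d_layers) != 2:
            raise ValidationError("hybrid spec requires exactly two 2-D conv layers")
        if len(self.dense_layers) != 3 or self.dense_layers[-1] != N_CLASSES:
            raise ValidationError("hybrid spec requires three dense layers ending in width 4")

    @classmethod
    def small(cls, n_bands: int, patch_size: int = 11) -> "HybridArchSpec":
        """Reduced-filter preset for quick single-CPU experiments.

        Spatial and spectral kernels shrink to fit whatever extent the
        previous valid convolutions leave, so the preset stays buildable for
        small patches or few bands.
        """
        filters = (4, 8, 8, 8)
        spatial, spectral = patch_size, n_bands
        conv3d = []
        for f, kb_default in zip(filters, (7, 5, 3, 3)):
            kh = 3 if spatial >= 3 else 1
            kb = min(kb_default, spectral)
            conv3d.append((f, (kh, kh, kb)))
            spatial -= kh - 1
            spectral -= kb - 1
        return cls(
            input_shape=(patch_size, patch_size, n_bands),
            conv3d_layers=tuple(conv3d),
            conv2d_layers=((16, (3, 3)), (16, (3, 3))),
            dense_layers=(64, 32, 4),
            dropout=0.2,
        )


@dataclass
class TrainConfig:
    """Training regimen shared by the network classifiers."""

    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    class_weighting: str | None = None  # None or "inverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


class NetworkClassifier:
    """A layer-engine network wrapped in the shared classifier contract."""

    def __init__(self, network: Network, kind: str, input_shape: tuple) -> None:
        self.network = network
        self.kind = kind  # "hybrid" | "2dcnn" | "1ddnn"
        self.input_shape = input_shape
        self.class_codes = CLASS_CODES
        self.trained = False
        self.feature_layer_end: int | None = None  # layers[:end] = conv feature stack

    # -- input adaptation ---------------------------------------------------
    def _to_input(self, patches: np.ndarray) -> np.ndarray:
        from .nn import DTYPE

        patches = np.asarray(patches, dtype=DTYPE)
        if self.kind == "hybrid":
            if patches.shape[1:] != self.input_shape:
                raise ValidationError(
                    f"patch shape {patches.shape[1:]} != expected {self.input_shape}"
                )
            return patches[..., None]  # single input channel
        if self.kind == "2dcnn":
            if patches.shape[1:] != self.input_shape:
                raise ValidationError(
                    f"patch shape {patches.shape[1:]} != expected {self.input_shape}"
                )
            return patches
        # 1ddnn: accept pixel spectra (N, B) or patches (N, P, P, B) -> center pixel
        if patches.ndim == 4:
            c = patches.shape[1] // 2
            patches = patches[:, c, c, :]
        if patches.shape[1:] != self.input_shape:
            raise ValidationError(
                f"spectrum length {patches.shape[1:]} != expected {self.input_shape}"
            )
        return patches

    # -- contract -----------------------------------------------------------
    def fit(self, patches: np.ndarray, labels: np.ndarray, config: TrainConfig) -> "NetworkClassifier":
        x = self._to_input(patches)
        labels = np.asarray(labels)
        if len(labels) == 0:
            raise ValidationError("training set is empty")
        if len(np.unique(labels)) < 2:
            raise ValidationError("training requires at least two classes")
        y = np.zeros((len(labels), N_CLASSES))
        y[np.arange(len(labels)), labels - 1] = 1.0
        class_weights = None
        if config.class_weighting == "inverse":
            freq = y.sum(axis=0)
            w = np.where(freq > 0, 1.0 / np.maximum(freq, 1), 0.0)
            class_weights = w * (y.sum() / max((w * freq).sum(), 1e-12))
        rng = np.random.default_rng(config.seed)
        self.network.fit(
            x, y, epochs=config.epochs, batch_size=config.batch_size, lr=config.lr,
            rng=rng, class_weights=class_weights,
        )
        self.trained = True
        return self

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("classifier has not been trained")
        return self.network.predict_proba(self._to_input(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(patches), axis=1) + 1

    def extract_features(self, patches: np.ndarray) -> np.ndarray:
        """Flattened activations of the last convolutional layer."""
        if not self.trained:
            raise StateError("feature extraction requires a trained model")
        if self.feature_layer_end is None:
            raise StateError(f"{self.kind} model has no convolutional feature stack")
        out = self.network.forward(self._to_input(patches), train=False,
                                   upto=self.feature_layer_end)
        return out.reshape(len(out), -1)

    @property
    def loss_history(self) -> list[float]:
        return self.network.loss_history

    def parameter_count(self) -> int:
        return int(sum(p.size for layer in self.network.layers for p in layer.params))


def build_hybrid_cnn(spec: HybridArchSpec | None = None, seed: int = 0) -> NetworkClassifier:
    """Assemble the untrained hybrid 3D-2D network from an architecture spec."""
    spec = spec or HybridArchSpec()
    rng = np.random.default_rng(seed)
    p1, p2, b = spec.input_shape
    layers = []
    shape = (p1, p2, b, 1)
    for li, (filters, kernel) in enumerate(spec.conv3d_layers):
        conv = Conv3D(shape[3], filters, kernel, rng, layer_index=li)
        shape = conv.out_shape(shape)
        layers += [conv, ReLU()]
    merge = MergeSpectral()
    shape = merge.out_shape(shape)
    layers.append(merge)
    for li, (filters, kernel) in enumerate(spec.conv2d_layers, start=len(spec.conv3d_layers)):
        conv = Conv2D(shape[2], filters, kernel, rng, layer_index=li)
        shape = conv.out_shape(shape)
        layers += [conv, ReLU()]
    feature_end = len(layers)
    flat = Flatten()
    shape = flat.out_shape(shape)
    layers.append(flat)
    dim = shape[0]
    for i, width in enumerate(spec.dense_layers):
        layers.append(Dense(dim, width, rng))
        if i < len(spec.dense_layers) - 1:
            layers += [ReLU(), Dropout(spec.dropout, rng)]
        dim = width
    clf = NetworkClassifier(Network(layers, N_CLASSES), "hybrid", spec.input_shape)
    clf.feature_layer_end = feature_end
    return clf


def build_2d_cnn(
    input_shape: tuple[int, int, int],
    filters: tuple[int, int, int] = (16, 32, 32),
    dense: tuple[int, int, int] = (128, 64, 4),
    seed: int = 0,
) -> NetworkClassifier:
    """2-D baseline: three same-padded convolutions over the spatial axes with
    the spectral axis as input channels, one average pooling, three dense layers."""
    rng = np.random.default_rng(seed)
    p1, p2, b = input_shape
    layers = []
    shape = (p1, p2, b)
    for li, f in enumerate(filters):
        conv = Conv2D(shape[2], f, (3, 3), rng, layer_index=li)
        shape = conv.out_shape(shape)
        layers += [conv, ReLU()]
    feature_end = len(layers)
    pool = AvgPool2D()
    shape = pool.out_shape(shape)
    layers.append(pool)
    flat = Flatten()
    shape = flat.out_shape(shape)
    layers.append(flat)
    dim = shape[0]
    if dense[-1] != N_CLASSES:
        raise ValidationError("final dense width must be 4")
    for i, width in enumerate(dense):
        layers.append(Dense(dim, width, rng))
        if i < len(dense) - 1:
            layers += [ReLU()]
        dim = width
    clf = NetworkClassifier(Network(layers, N_CLASSES), "2dcnn", input_shape)
    clf.feature_layer_end = feature_end
    return clf


def build_1d_dnn(n_bands: int, hidden: tuple[int, int] = (28, 40), seed: int = 0) -> NetworkClassifier:
    """Pixel-wise dense baseline: hidden widths 28 and 40, ReLU, 4-way softmax."""
    rng = np.random.default_rng(seed)
    layers = [
        Dense(n_bands, hidden[0], rng), ReLU(),
        Dense(hidden[0], hidden[1], rng), ReLU(),
        Dense(hidden[1], N_CLASSES, rng),
    ]
    return NetworkClassifier(Network(layers, N_CLASSES), "1ddnn", (n_bands,))


def train_classifier(
    model: NetworkClassifier, train: PatchSet | tuple, config: TrainConfig
) -> NetworkClassifier:
    """Train any network classifier on a patch set (or an (X, y) pair)."""
    if isinstance(train, PatchSet):
        return model.fit(train.patches, train.labels, config)
    x, y = train
    return model.fit(x, y, config)


def predict_proba(model, patches: PatchSet | np.ndarray) -> np.ndarray:
    """Class-probability matrix, columns in (NT, TT, BV, BG) order."""
    x = patches.patches if isinstance(patches, PatchSet) else patches
    return model.predict_proba(x)


def extract_features(model: NetworkClassifier, patches: PatchSet | np.ndarray) -> np.ndarray:
    """Flattened last-conv-layer activations, one row per patch."""
    x = patches.patches if isinstance(patches, PatchSet) else patches
    return model.extract_features(x)


class SvmClassifier:
    """One-vs-rest linear SVM behind the shared classifier contract.

    Probability scores are the softmax of the per-class decision margins;
    classes absent from the training set receive probability zero.
    """

    def __init__(self, C: float = 1.0, flatten: bool = True) -> None:
        self.C = C
        self.flatten = flatten
        self.class_codes = CLASS_CODES
        self.trained = False
        self._svm: LinearSVC | None = None
        self._present: np.ndarray | None = None

    def _to_features(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return x.reshape(len(x), -1) if self.flatten and x.ndim > 2 else x

    def fit(self, features: np.ndarray, labels: np.ndarray, config=None) -> "SvmClassifier":
        features = self._to_features(features)
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise ValidationError("SVM training requires at least two classes")
        self._svm = LinearSVC(C=self.C, dual=False, max_iter=5000, random_state=0)
        self._svm.fit(features, labels)
        self._present = np.asarray(self._svm.classes_, dtype=np.int64)
        self.trained = True
        return self

    def decision_margins(self, features: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("SVM has not been trained")
        features = self._to_features(features)
        df = self._svm.decision_function(features)
        if df.ndim == 1:  # binary problem: margin for the second class
            df = np.column_stack([-df, df])
        return df

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        df = self.decision_margins(features)
        probs_present = softmax(df)
        out = np.zeros((len(df), N_CLASSES))
        out[:, self._present - 1] = probs_present
        return out

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(features), axis=1) + 1


def train_svm(features: np.ndarray, labels: np.ndarray, C: float = 1.0) -> SvmClassifier:
    """Train a one-vs-rest linear SVM on arbitrary feature rows."""
    flatten = np.asarray(features).ndim > 2
    return SvmClassifier(C=C, flatten=flatten).fit(features, labels)


class HybridSvmClassifier:
    """Transfer-learning variant: the trained hybrid network's last-conv
    activations feed a one-vs-rest linear SVM in place of the softmax head."""

    def __init__(self, spec: HybridArchSpec, seed: int = 0, C: float = 1.0) -> None:
        self.backbone = build_hybrid_cnn(spec, seed=seed)
        self.svm = SvmClassifier(C=C, flatten=False)
        self.class_codes = CLASS_CODES
        self.trained = False

    def fit(self, patches: np.ndarray, labels: np.ndarray, config: TrainConfig) -> "HybridSvmClassifier":
        self.backbone.fit(patches, labels, config)
        feats = self.backbone.extract_features(patches)
        self.svm.fit(feats, labels)
        self.trained = True
        return self

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise StateError("classifier has not been trained")
        return self.svm.predict_proba(self.backbone.extract_features(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(patches), axis=1) + 1


MODEL_NAMES = ("hybrid", "2dcnn", "1ddnn", "svm", "hybrid+svm")


def classifier_factory(model: str, patch_size: int = 11, preset: str = "small"):
    """Return ``factory(n_bands, seed)`` for a model name (see MODEL_NAMES)."""
    if model not in MODEL_NAMES:
        raise ValidationError(f"unknown model {model!r}; choose from {MODEL_NAMES}")

    def hybrid_spec(n_bands: int) -> HybridArchSpec:
        if preset == "small":
            return HybridArchSpec.small(n_bands, patch_size)
        return HybridArchSpec(input_shape=(patch_size, patch_size, n_bands))

    def factory(n_bands: int, seed: int):
        if model == "hybrid":
            return build_hybrid_cnn(hybrid_spec(n_bands), seed=seed)
        if model == "2dcnn":
            return build_2d_cnn((patch_size, patch_size, n_bands), seed=seed)
        if model == "1ddnn":
            return build_1d_dnn(n_bands, seed=seed)
        if model == "svm":
            return SvmClassifier(flatten=True)
        return HybridSvmClassifier(hybrid_spec(n_bands), seed=seed)

    return factory
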