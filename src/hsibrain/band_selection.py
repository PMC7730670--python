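"""Ant-colony-optimization band selection with a linear-SVM fitness.

Ants walk a fully connected graph whose vertices are candidate spectral
bands; a route of ``n_select`` distinct vertices is one candidate band
subset.  Transition preferences combine an edge pheromone matrix tau and a
per-band heuristic desirability eta:

    P(next = j | at i) ∝ tau_ij^alpha * eta_j^beta    (j unvisited)

After each generation the best route of that generation deposits pheromone on
its edges while all edges evaporate:

    tau_ij <- rho * tau_ij + Q * F(f_best)   (edge on the best route)
    tau_ij <- rho * tau_ij                   (otherwise)

The fitness f of a route is the held-out accuracy of a linear SVM trained on
the restricted features, so the search is supervised.  The heuristic eta
defaults to the per-band Fisher discriminant ratio (between-class variance
over within-class variance), normalized to mean one, which gives the beta
exponent something meaningful to weight; a uniform eta is available for a
pheromone-only search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from .errors import SizeError, StateError, ValidationError

#: Search configuration used in the reference experiments.
DEFAULT_ANTS = 30
DEFAULT_GENERATIONS = 30
DEFAULT_ALPHA = 1.0
DEFAULT_BETA = 10.0
DEFAULT_RHO = 0.5
DEFAULT_Q = 10.0
TAU_MIN = 0.05


@dataclass
class PheromoneGraph:
    """Pheromone state of the band-selection graph."""

    tau: np.ndarray  # symmetric positive (n, n)
    eta: np.ndarray  # positive per-band desirability (n,)
    rho: float = DEFAULT_RHO
    Q: float = DEFAULT_Q
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    tau_min: float = TAU_MIN

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.eta = np.asarray(self.eta, dtype=np.float64)
        n = self.tau.shape[0]
        if self.tau.shape != (n, n):
            raise ValidationError("tau must be square")
        if self.eta.shape != (n,):
            raise ValidationError("eta length must match tau dimension")
        if np.any(self.tau <= 0) or np.any(self.eta <= 0):
            raise ValidationError("tau and eta entries must be positive")
        if not (0 < self.rho <= 1):
            raise ValidationError("rho must lie in (0, 1]")

    @property
    def n_vertices(self) -> int:
        return self.tau.shape[0]

    @classmethod
    def uniform(cls, n_bands: int, eta: np.ndarray | None = None, **kw) -> "PheromoneGraph":
        tau = np.ones((n_bands, n_bands))
        if eta is None:
            eta = np.ones(n_bands)
        return cls(tau=tau, eta=eta, **kw)


@dataclass
class AntRoute:
    """One ant's route: an ordered set of distinct band indices plus fitness."""

    band_indices: list[int]
    fitness: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.band_indices)) != len(self.band_indices):
            raise ValidationError("route contains duplicate band indices")


@dataclass
class BandSubset:
    """Final output of band selection: sorted distinct indices + wavelengths."""

    indices: np.ndarray
    wavelengths: np.ndarray | None = None
    fitness: float = float("nan")

    def __post_init__(self) -> None:
        self.indices = np.asarray(sorted(int(i) for i in self.indices), dtype=np.int64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValidationError("band subset indices must be distinct")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.indices)


def fisher_ratio(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-band Fisher discriminant ratio, normalized to mean one.

    Ratio of the between-class variance of class means to the pooled
    within-class variance, per band; a small floor keeps values positive.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    overall = features.mean(axis=0)
    between = np.zeros(features.shape[1])
    within = np.zeros(features.shape[1])
    for c in classes:
        sel = features[labels == c]
        w = len(sel) / len(features)
        between += w * (sel.mean(axis=0) - overall) ** 2
        within += w * sel.var(axis=0)
    ratio = between / np.maximum(within, 1e-12)
    ratio = np.maximum(ratio, 1e-9)
    return ratio / ratio.mean()


def _check_features(features: np.ndarray, labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValidationError("at least two classes are required")
    if len(features) != len(labels):
        raise ValidationError("features and labels differ in length")


def make_fitness_split(
    features: np.ndarray, labels: np.ndarray, seed: int, test_size: float = 0.3
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation split fixed per run, used for route fitness."""
    return train_test_split(
        np.asarray(features, dtype=np.float64),
        np.asarray(labels),
        test_size=test_size,
        random_state=seed % (2**31),
        stratify=labels,
    )


def evaluate_subset(
    features: np.ndarray,
    labels: np.ndarray,
    band_indices: Sequence[int],
    *,
    split=None,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Held-out accuracy of a linear SVM restricted to ``band_indices``.

    ``split`` may carry a precomputed (X_train, X_val, y_train, y_val) tuple
    so that every route in one search run is scored on the same partition.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    _check_features(features, labels)
    idx = np.asarray(list(band_indices), dtype=np.int64)
    if idx.size == 0:
        raise ValidationError("band subset must be non-empty")
    if idx.min() < 0 or idx.max() >= features.shape[1]:
        raise ValidationError(
            f"band index out of range [0, {features.shape[1]}): {idx.min()}..{idx.max()}"
        )
    if split is None:
        split = make_fitness_split(features, labels, seed)
    X_tr, X_val, y_tr, y_val = split
    clf = LinearSVC(C=C, dual=False, max_iter=5000, random_state=0)
    clf.fit(X_tr[:, idx], y_tr)
    return float(np.mean(clf.predict(X_val[:, idx]) == y_val))


def construct_route(
    graph: PheromoneGraph, n_select: int, rng: np.random.Generator
) -> AntRoute:
    """Sample one route of ``n_select`` distinct vertices.

    The first vertex is drawn with probability proportional to
    (row-sum of tau)^alpha * eta^beta; each subsequent vertex j is drawn among
    unvisited vertices with probability proportional to tau_ij^alpha * eta_j^beta.
    """
    n = graph.n_vertices
    if n_select > n:
        raise SizeError(f"cannot select {n_select} bands from {n}")
    eta_pow = graph.eta**graph.beta
    visited = np.zeros(n, dtype=bool)

    start_w = graph.tau.sum(axis=1) ** graph.alpha * eta_pow
    current = int(rng.choice(n, p=start_w / start_w.sum()))
    route = [current]
    visited[current] = True

    for _ in range(n_select - 1):
        w = graph.tau[current] ** graph.alpha * eta_pow
        w[visited] = 0.0
        total = w.sum()
        if total <= 0:  # numerically degenerate row: fall back to uniform
            w = (~visited).astype(np.float64)
            total = w.sum()
        current = int(rng.choice(n, p=w / total))
        route.append(current)
        visited[current] = True
    return AntRoute(band_indices=route)


def update_pheromone(
    graph: PheromoneGraph, best: AntRoute, F: Callable[[float], float] = lambda f: f
) -> PheromoneGraph:
    """Evaporate all edges and deposit on the generation-best route (in place).

    tau' = rho * tau everywhere; every edge whose two endpoints both belong to
    the best route gains Q * F(f_best) — the deposit covers the clique of the
    selected subset, not only consecutively traversed pairs, since route order
    is irrelevant to the band subset.  Entries are floored at ``tau_min`` to
    keep every edge reachable.
    """
    if best.fitness is None:
        raise StateError("best route must be evaluated before depositing pheromone")
    graph.tau *= graph.rho
    delta = graph.Q * F(best.fitness)
    members = np.asarray(best.band_indices, dtype=np.int64)
    ii, jj = np.meshgrid(members, members, indexing="ij")
    off_diag = ii != jj
    graph.tau[ii[off_diag], jj[off_diag]] += delta
    np.maximum(graph.tau, graph.tau_min, out=graph.tau)
    return graph


def aco_select_bands(
    features: np.ndarray,
    labels: np.ndarray,
    n_select: int = 100,
    *,
    ants: int = DEFAULT_ANTS,
    generations: int = DEFAULT_GENERATIONS,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    rho: float = DEFAULT_RHO,
    Q: float = DEFAULT_Q,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    heuristic: str = "uniform",
    n_splits: int = 3,
    F: Callable[[float], float] = lambda f: f,
) -> BandSubset:
    """Supervised ACO band selection.

    Runs ``ants`` route constructions per generation for ``generations``
    rounds, scoring each route by linear-SVM held-out accuracy averaged over
    ``n_splits`` fixed stratified splits (averaging damps fitness noise, so
    the returned optimum is less subject to selection bias), depositing
    pheromone for the per-generation best, and returning the globally best
    subset (ties resolved to the earliest found).  Fully reproducible for a
    fixed seed.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    _check_features(features, labels)
    n_bands = features.shape[1]
    if n_select > n_bands:
        raise SizeError(f"cannot select {n_select} bands from {n_bands}")
    if wavelengths is not None and len(wavelengths) != n_bands:
        raise ValidationError("wavelengths length must equal feature band count")

    rng = np.random.default_rng(seed)
    eta = fisher_ratio(features, labels) if heuristic == "fisher" else np.ones(n_bands)
    graph = PheromoneGraph.uniform(n_bands, eta=eta, rho=rho, Q=Q, alpha=alpha, beta=beta)
    splits = [make_fitness_split(features, labels, seed + 1000 * k) for k in range(n_splits)]

    cache: dict[tuple[int, ...], float] = {}
    best_route: AntRoute | None = None
    best_fitness = -np.inf

    for _ in range(generations):
        gen_best: AntRoute | None = None
        for _ in range(ants):
            route = construct_route(graph, n_select, rng)
            key = tuple(sorted(route.band_indices))
            if key not in cache:
                cache[key] = float(np.mean(
                    [evaluate_subset(features, labels, key, split=sp) for sp in splits]
                ))
            route.fitness = cache[key]
            if gen_best is None or route.fitness > gen_best.fitness:
                gen_best = route
            if route.fitness > best_fitness:  # strict: earliest equal-fitness wins
                best_fitness = route.fitness
                best_route = route
        update_pheromone(graph, gen_best, F)

    assert best_route is not None
    indices = np.asarray(sorted(best_route.band_indices), dtype=np.int64)
    return BandSubset(
        indices=indices,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[indices],
        fitness=best_fitness,
    )


def bands_to_ranges(
    subset: BandSubset | Sequence[int], grid_wavelengths: np.ndarray
) -> list[tuple[float, float]]:
    """Merge selected bands adjacent on the candidate grid into closed nm intervals.

    Returns a sorted list of (low_nm, high_nm) pairs; a singleton band becomes
    a zero-width interval.
    """
    indices = subset.indices if isinstance(subset, BandSubset) else np.asarray(sorted(subset))
    if len(indices) == 0:
        raise ValidationError("band subset is empty")
    grid = np.asarray(grid_wavelengths, dtype=np.float64)
    ranges: list[tuple[float, float]] = []
    start = prev = int(indices[0])
    for i in map(int, indices[1:]):
        if i == prev + 1:
            prev = i
            continue
        ranges.append((float(grid[start]), float(grid[prev])))
        start = prev = i
    ranges.append((float(grid[start]), float(grid[prev])))
    return ranges


def apply_band_subset(cube, subset: BandSubset):
    """Restrict a cube to the selected bands (stage becomes ``selected``)."""
    idx = subset.indices
    if idx.max() >= cube.n_bands:
        raise ValidationError(
            f"subset index {int(idx.max())} out of range for {cube.n_bands}-band cube"
        )
    return cube.advanced(
        "selected", values=cube.values[:, :, idx], wavelengths=cube.wavelengths[idx]
    )
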