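"""Self-organizing map on a hexagonal sheet lattice.

Implements Kohonen's competitive learning in both its sequential
(stochastic) and batch forms, with random and linear (PCA-plane)
initialization and four neighborhood kernels (gaussian, bubble, cut
gaussian, Epanechnikov), following the SOM-toolbox conventions: the map is
a non-toroidal sheet of hexagonal units, neighborhood kernels act on
Euclidean distance between unit positions in the hexagonal embedding, and
map quality is summarized by the quantization error (mean distance from a
case to its best-matching unit) and the topographic error (fraction of
cases whose two best units are not lattice neighbors).

Grid sizing follows the heuristic m = ceil(units_factor * sqrt(n)) total
units with the height/width ratio tracking the square root of the ratio of
the two leading data-covariance eigenvalues, which reproduces a 12 x 6 map
for n = 194 cases with an eigenvalue ratio near 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HexGrid",
    "TrainingPhase",
    "TrainingSchedule",
    "TrainedSOM",
    "map_size",
    "eigenvalue_ratio",
    "init_random",
    "init_linear",
    "bmu",
    "bmu_pairs",
    "neighborhood",
    "train_som",
    "quantization_error",
    "topographic_error",
    "default_schedule",
]

NEIGHBORHOOD_KINDS = ("gaussian", "bubble", "cutgauss", "ep")
TRAINING_MODES = ("sequential", "batch")
INIT_METHODS = ("random", "linear")


class HexGrid:
    """A height x width sheet of hexagonal units.

    Units are indexed row-major.  Unit (r, c) is embedded in the plane at
    x = c + 0.5 * (r mod 2), y = r * sqrt(3)/2, so lattice neighbors are at
    Euclidean distance exactly 1 and each interior unit has six neighbors.
    """

    def __init__(self, height: int, width: int):
        if height < 1 or width < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.height = int(height)
        self.width = int(width)
        r, c = np.divmod(np.arange(self.n_units), self.width)
        x = c + 0.5 * (r % 2)
        y = r * (math.sqrt(3.0) / 2.0)
        self.coords = np.column_stack([x, y])
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        self.distances = np.sqrt((diff**2).sum(axis=2))
        self.adjacency = (self.distances > 0.5) & (self.distances < 1.001)

    @property
    def n_units(self) -> int:
        return self.height * self.width

    def __repr__(self) -> str:  # pragma: no cover
        return f"HexGrid({self.height}x{self.width})"


def eigenvalue_ratio(data: np.ndarray, cap: float = 100.0) -> float:
    """Ratio of the two leading covariance eigenvalues, capped at ``cap``."""
    cov = np.cov(np.asarray(data, dtype=float), rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eig[1] <= 0:
        return cap
    return float(min(eig[0] / eig[1], cap))


def map_size(
    n: int, eig_ratio: float, units_factor: float = 5.0
) -> tuple[int, int]:
    """Heuristic (height, width) for n cases and an eigenvalue ratio.

    Total units m = ceil(units_factor * sqrt(n)); the width is chosen so
    the height/width ratio approximates sqrt(eig_ratio) with
    height * width >= m.
    """
    if n < 2:
        raise ValueError("need at least 2 cases to size a map")
    if eig_ratio < 1:
        raise ValueError("eig_ratio must be >= 1 (lambda1 >= lambda2)")
    m = math.ceil(units_factor * math.sqrt(n))
    side_ratio = math.sqrt(eig_ratio)
    width = max(1, round(math.sqrt(m / side_ratio)))
    height = max(1, math.ceil(m / width))
    return height, width


@dataclass(frozen=True)
class TrainingPhase:
    epochs: int
    sigma0: float
    sigmaf: float
    eta0: float = 0.5  # used by sequential training only

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.sigma0 >= self.sigmaf >= 0:
            raise ValueError("need sigma0 >= sigmaf >= 0")
        if not 0 <= self.eta0 <= 1:
            raise ValueError("eta0 must lie in [0, 1]")


@dataclass(frozen=True)
class TrainingSchedule:
    mode: str  # sequential | batch
    neighborhood: str  # gaussian | bubble | cutgauss | ep
    init: str  # random | linear
    phases: tuple[TrainingPhase, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in TRAINING_MODES:
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.neighborhood not in NEIGHBORHOOD_KINDS:
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.init not in INIT_METHODS:
            raise ValueError(f"unknown initialization {self.init!r}")
        if not self.phases:
            raise ValueError("at least one training phase is required")


def default_schedule(
    grid: HexGrid,
    n_samples: int,
    mode: str = "batch",
    neighborhood: str = "gaussian",
    init: str = "linear",
    seed: int = 0,
) -> TrainingSchedule:
    """SOM-toolbox style two-phase schedule for a grid and sample size.

    Rough phase: radius from max(height, width)/4 down to 1 with a high
    learning rate; fine-tune phase: radius 1 down to 0.5 with a low
    learning rate.  Epoch counts scale as 10 m/n (rough) and 40 m/n
    (fine-tune) with a floor of 5.
    """
    m = grid.n_units
    rough_epochs = max(5, round(10 * m / max(n_samples, 1)))
    fine_epochs = max(5, round(40 * m / max(n_samples, 1)))
    sigma0 = max(max(grid.height, grid.width) / 4.0, 1.0)
    return TrainingSchedule(
        mode=mode,
        neighborhood=neighborhood,
        init=init,
        phases=(
            TrainingPhase(rough_epochs, sigma0, 1.0, eta0=0.5),
            TrainingPhase(fine_epochs, 1.0, 0.5, eta0=0.05),
        ),
        seed=seed,
    )


@dataclass
class TrainedSOM:
    """A trained map: grid, codebook, schedule and quality errors."""

    grid: HexGrid
    weights: np.ndarray  # (n_units, dim)
    schedule: TrainingSchedule
    quantization_error: float
    topographic_error: float
    variable_names: tuple[str, ...] | None = None

    @property
    def score(self) -> float:
        """Model-selection score: QE x TE (lower is better)."""
        return self.quantization_error * self.topographic_error


# ---------------------------------------------------------------------------
# Initialization

def init_random(grid: HexGrid, data: np.ndarray, seed: int) -> np.ndarray:
    """Codebook drawn uniformly within each variable's observed range."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("data must be non-empty")
    rng = np.random.default_rng(seed)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    return rng.uniform(lo, hi, size=(grid.n_units, data.shape[1]))


def init_linear(grid: HexGrid, data: np.ndarray) -> np.ndarray:
    """Codebook spanning the plane of the two leading principal axes.

    Weights vary linearly with the grid row (first axis) and column
    (second axis), are scaled by the axis standard deviations, and are
    centered on the data mean.  Rank-1 data degrades to a single axis.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("linear initialization needs >= 2 cases and >= 2 variables")
    mean = data.mean(axis=0)
    centered = data - mean
    # SVD-based principal axes; singular values give component scales.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scales = s / math.sqrt(max(data.shape[0] - 1, 1))
    axes = vt[:2]
    if scales[1] <= 1e-12 * max(scales[0], 1.0):
        import warnings

        warnings.warn("rank-1 data: second linear-init axis set to zero")
        axes = np.vstack([axes[0], np.zeros_like(axes[0])])
        scales = np.array([scales[0], 0.0])
    hcoef = (
        np.linspace(-1.0, 1.0, grid.height) if grid.height > 1 else np.zeros(1)
    )
    wcoef = (
        np.linspace(-1.0, 1.0, grid.width) if grid.width > 1 else np.zeros(1)
    )
    rows, cols = np.divmod(np.arange(grid.n_units), grid.width)
    weights = (
        mean
        + np.outer(hcoef[rows] * scales[0], axes[0])
        + np.outer(wcoef[cols] * scales[1], axes[1])
    )
    return weights


# ---------------------------------------------------------------------------
# Winner selection and neighborhood kernels

def bmu(weights: np.ndarray, x: np.ndarray) -> tuple[int, int]:
    """Best and second-best matching units for one case.

    Ties are broken by the lower unit index (np.argmin convention).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector contains non-finite values")
    d2 = ((weights - x) ** 2).sum(axis=1)
    first = int(np.argmin(d2))
    if len(d2) == 1:
        return first, first
    d2 = d2.copy()
    d2[first] = np.inf
    return first, int(np.argmin(d2))


def bmu_pairs(weights: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first/second BMU indices for every case."""
    data = np.asarray(data, dtype=float)
    d2 = (
        (data**2).sum(axis=1)[:, None]
        - 2.0 * data @ weights.T
        + (weights**2).sum(axis=1)[None, :]
    )
    first = np.argmin(d2, axis=1)
    if weights.shape[0] == 1:
        return first, first
    d2[np.arange(len(data)), first] = np.inf
    second = np.argmin(d2, axis=1)
    return first, second


def neighborhood(kind: str, d: np.ndarray | float, sigma: float) -> np.ndarray:
    """Neighborhood kernel value(s) for lattice distance(s) d at radius sigma.

    gaussian: exp(-d^2 / (2 sigma^2)); bubble: 1[d <= sigma];
    cutgauss: gaussian truncated to d <= sigma; ep: max(0, 1 - (d/sigma)^2).
    A non-positive sigma degenerates to the winner-only indicator 1[d == 0].
    """
    d = np.asarray(d, dtype=float)
    if sigma <= 0:
        return (d == 0).astype(float)
    if kind == "gaussian":
        return np.exp(-(d**2) / (2.0 * sigma**2))
    if kind == "bubble":
        return (d <= sigma).astype(float)
    if kind == "cutgauss":
        return np.exp(-(d**2) / (2.0 * sigma**2)) * (d <= sigma)
    if kind == "ep":
        return np.maximum(0.0, 1.0 - (d / sigma) ** 2)
    raise ValueError(f"unknown neighborhood kind {kind!r}")


# ---------------------------------------------------------------------------
# Training

def _linear_decay(start: float, end: float, step: int, total: int) -> float:
    if total <= 1:
        return start
    return start + (end - start) * (step / (total - 1))


def _train_sequential(
    weights: np.ndarray,
    data: np.ndarray,
    grid: HexGrid,
    schedule: TrainingSchedule,
) -> np.ndarray:
    rng = np.random.default_rng(schedule.seed)
    n = data.shape[0]
    weights = weights.copy()
    for phase in schedule.phases:
        total_steps = phase.epochs * n
        step = 0
        for _ in range(phase.epochs):
            order = rng.permutation(n)
            for i in order:
                eta = _linear_decay(phase.eta0, 0.0, step, total_steps)
                sigma = _linear_decay(phase.sigma0, phase.sigmaf, step, total_steps)
                x = data[i]
                winner = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                h = neighborhood(
                    schedule.neighborhood, grid.distances[winner], sigma
                )
                weights += (eta * h)[:, None] * (x - weights)
                step += 1
    return weights


def _train_batch(
    weights: np.ndarray,
    data: np.ndarray,
    grid: HexGrid,
    schedule: TrainingSchedule,
) -> np.ndarray:
    n = data.shape[0]
    weights = weights.copy()
    for phase in schedule.phases:
        for epoch in range(phase.epochs):
            sigma = _linear_decay(phase.sigma0, phase.sigmaf, epoch, phase.epochs)
            winners, _ = bmu_pairs(weights, data)
            # Per-unit sufficient statistics of assigned cases.
            sums = np.zeros_like(weights)
            np.add.at(sums, winners, data)
            hits = np.bincount(winners, minlength=grid.n_units).astype(float)
            h = neighborhood(schedule.neighborhood, grid.distances, sigma)
            numer = h @ sums
            denom = h @ hits
            updated = denom > 1e-12
            weights[updated] = numer[updated] / denom[updated, None]
    return weights


def quantization_error(weights: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance from each case to its best-matching unit."""
    data = np.asarray(data, dtype=float)
    first, _ = bmu_pairs(weights, data)
    return float(np.linalg.norm(data - weights[first], axis=1).mean())


def topographic_error(
    weights: np.ndarray, data: np.ndarray, grid: HexGrid
) -> float:
    """Fraction of cases whose first and second BMUs are not adjacent."""
    if grid.n_units == 1:
        return 0.0
    first, second = bmu_pairs(weights, np.asarray(data, dtype=float))
    return float(np.mean(~grid.adjacency[first, second]))


def train_som(
    data: np.ndarray,
    grid: HexGrid,
    schedule: TrainingSchedule,
    variable_names: tuple[str, ...] | None = None,
) -> TrainedSOM:
    """Initialize and train a map, returning the codebook and its errors."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("training data must be non-empty")
    if not np.all(np.isfinite(data)):
        raise ValueError("training data contains missing or non-finite values")
    if schedule.init == "random":
        weights = init_random(grid, data, schedule.seed)
    else:
        weights = init_linear(grid, data)
    if schedule.mode == "sequential":
        weights = _train_sequential(weights, data, grid, schedule)
    else:
        weights = _train_batch(weights, data, grid, schedule)
    return TrainedSOM(
        grid=grid,
        weights=weights,
        schedule=schedule,
        quantization_error=quantization_error(weights, data),
        topographic_error=topographic_error(weights, data, grid),
        variable_names=variable_names,
    )
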