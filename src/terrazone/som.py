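"""Self-organizing map engine.

A SOM arranges k-dimensional input vectors onto a small 2-D lattice of
nodes, each holding a prototype ("codebook") vector m_i.  Training draws
input rows one at a time; the winning node c is the one with the smallest
Euclidean distance to the input,

    ||x - m_c|| = min_i ||x - m_i||,

and every node is pulled toward the input,

    m_i(t+1) = m_i(t) + h_ci(t) [x(t) - m_i(t)],

with a Gaussian neighborhood h_ci(t) = alpha(t) exp(-d_lat(c,i)^2 / 2 sigma(t)^2)
whose learning rate alpha and radius sigma decay linearly within each
training phase.  After training, the unified distance matrix (U-matrix)
maps the distances between lattice-neighbor prototypes; ridges of large
distance mark boundaries between groups of similar field locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .terrain import FeatureMatrix

_SQRT3_2 = np.sqrt(3.0) / 2.0


class SOMTrainingError(RuntimeError):
    pass


def lattice_coordinates(rows: int, cols: int, topology: str) -> np.ndarray:
    """Planar coordinates of each node, row-major node order.

    Hexagonal lattices use odd-row offset coordinates (odd rows shifted
    +0.5, row spacing sqrt(3)/2) so each interior node has six equidistant
    neighbors at distance 1.
    """
    r, c = np.divmod(np.arange(rows * cols), cols)
    if topology == "hexagonal":
        x = c + 0.5 * (r % 2)
        y = r * _SQRT3_2
    elif topology == "rectangular":
        x, y = c.astype(float), r.astype(float)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return np.column_stack([x, y]).astype(float)


@dataclass
class SOMCodebook:
    """Lattice of prototype vectors (normalized feature units)."""

    rows: int
    cols: int
    topology: str
    vectors: np.ndarray  # N x k, node i at lattice (i // cols, i % cols)
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        n = self.rows * self.cols
        if n < 2:
            raise ValueError("SOM lattice needs at least 2 nodes")
        if self.vectors.shape[0] != n:
            raise ValueError("vectors must have rows*cols rows")
        if not np.isfinite(self.vectors).all():
            raise ValueError("node vectors must be finite")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def lattice_coords(self) -> np.ndarray:
        return lattice_coordinates(self.rows, self.cols, self.topology)


@dataclass
class Phase:
    """One linear-decay training phase."""

    t_max: int
    alpha0: float
    alpha_end: float
    sigma0: float
    sigma_end: float

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        for a, b, name in (
            (self.alpha0, self.alpha_end, "learning rate"),
            (self.sigma0, self.sigma_end, "radius"),
        ):
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} must stay positive")
            if b > a:
                raise ValueError(f"{name} must be non-increasing within a phase")


@dataclass
class TrainingSchedule:
    phases: list[Phase]
    rng_seed: int = 0
    neighborhood_kind: str = "gaussian"

    @classmethod
    def default(cls, n_inputs: int, rows: int, cols: int, seed: int = 0) -> "TrainingSchedule":
        """Two-phase rough+fine schedule scaled to the data size.

        Rough ordering: sigma max(rows, cols)/4 -> 1, alpha 0.5 -> 0.05,
        over 10 n steps; fine tuning: sigma 1 -> 0.1, alpha 0.05 -> 0.01,
        over 40 n steps.
        """
        sigma0 = max(max(rows, cols) / 4.0, 1.0)
        return cls(
            phases=[
                Phase(10 * n_inputs, 0.5, 0.05, sigma0, 1.0),
                Phase(40 * n_inputs, 0.05, 0.01, 1.0, 0.1),
            ],
            rng_seed=seed,
        )


def default_grid_shape(fm: FeatureMatrix) -> tuple[int, int]:
    """Heuristic lattice size: ~5*sqrt(n) nodes, side ratio from the data.

    The row:column ratio follows the square root of the ratio of the two
    largest eigenvalues of the feature covariance, so the lattice is
    elongated the way the data cloud is.
    """
    n = fm.n
    munits = int(np.ceil(5.0 * np.sqrt(n)))
    xc = fm.data - fm.data.mean(axis=0)
    eigvals = np.linalg.eigvalsh(np.cov(xc, rowvar=False))
    e1, e2 = eigvals[-1], eigvals[-2] if len(eigvals) > 1 else eigvals[-1]
    ratio = np.sqrt(e1 / e2) if e2 > 0 else 1.0
    ratio = float(np.clip(ratio, 1.0, 4.0))
    rows = max(2, int(round(np.sqrt(munits * ratio))))
    cols = max(2, int(round(munits / rows)))
    return rows, cols


def init_codebook(
    fm: FeatureMatrix,
    rows: int,
    cols: int,
    topology: str = "hexagonal",
    seed: int | None = None,
    mode: str = "linear",
) -> SOMCodebook:
    """Initialize the codebook.

    ``mode="linear"`` (default, deterministic): node vectors are laid out on
    the plane spanned by the first two principal components of the data,
    spanning +-2 SD along each.  ``mode="random"``: node vectors are input
    rows sampled with the given seed.
    """
    if rows * cols < 2:
        raise ValueError("SOM lattice needs at least 2 nodes")
    lattice_coordinates(rows, cols, topology)  # validates topology
    X = fm.data
    if mode == "random":
        rng = np.random.default_rng(seed)
        vecs = X[rng.integers(0, fm.n, rows * cols)].copy()
        return SOMCodebook(rows, cols, topology, vecs, fm.columns)
    if mode != "linear":
        raise ValueError(f"unknown init mode {mode!r}")
    if fm.k < 2:
        warnings.warn("k < 2: falling back to random initialization")
        return init_codebook(fm, rows, cols, topology, seed, mode="random")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    sd1, sd2 = np.sqrt(max(eigvals[-1], 0.0)), np.sqrt(max(eigvals[-2], 0.0))
    v1, v2 = eigvecs[:, -1], eigvecs[:, -2]
    a = np.linspace(-2.0, 2.0, cols) if cols > 1 else np.zeros(1)
    b = np.linspace(-2.0, 2.0, rows) if rows > 1 else np.zeros(1)
    bb, aa = np.meshgrid(b, a, indexing="ij")
    vecs = (
        mean
        + aa.reshape(-1, 1) * sd1 * v1
        + bb.reshape(-1, 1) * sd2 * v2
    )
    return SOMCodebook(rows, cols, topology, vecs, fm.columns)


def find_bmu_node(x: np.ndarray, cb: SOMCodebook) -> tuple[int, float]:
    """Winning node for one input: argmin_i ||x - m_i|| (ties -> lowest i)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != cb.k:
        raise ValueError(f"input has dimension {x.shape[0]}, codebook expects {cb.k}")
    d = np.linalg.norm(cb.vectors - x, axis=1)
    i = int(np.argmin(d))
    return i, float(d[i])


def bmu_indices(X: np.ndarray, cb: SOMCodebook) -> np.ndarray:
    """Winning node index for each row of X (vectorized winner rule)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != cb.k:
        raise ValueError("dimension mismatch")
    return np.argmin(cdist(X, cb.vectors, "sqeuclidean"), axis=1)


# updates with neighborhood weight below this fraction of alpha are skipped;
# exp(-z) <= 1e-12 there, numerically irrelevant to the prototypes
_H_CUTOFF_LOG = 2.0 * np.log(1e12)


def train(
    cb: SOMCodebook,
    fm: FeatureMatrix,
    sched: TrainingSchedule | None = None,
    check_every: int = 4096,
) -> SOMCodebook:
    """Sequential SOM training; returns a new codebook.

    One input row is drawn per step (seeded RNG), the winner found by the
    smallest-distance rule, and all nodes updated with the Gaussian
    neighborhood.  Deterministic given the schedule's seed.
    """
    if not fm.is_normalized:
        raise ValueError("train expects a normalized feature matrix")
    if fm.k != cb.k:
        raise ValueError("feature matrix and codebook dimensions differ")
    if sched is None:
        sched = TrainingSchedule.default(fm.n, cb.rows, cb.cols)
    if sched.neighborhood_kind != "gaussian":
        raise ValueError("only the gaussian neighborhood is implemented")
    X = fm.data
    code = cb.vectors.copy()
    coords = cb.lattice_coords()
    lat_d2 = cdist(coords, coords, "sqeuclidean")
    rng = np.random.default_rng(sched.rng_seed)
    step = 0
    for phase in sched.phases:
        T = phase.t_max
        denom = max(T - 1, 1)
        frac = np.arange(T) / denom
        alphas = phase.alpha0 + (phase.alpha_end - phase.alpha0) * frac
        sigmas = phase.sigma0 + (phase.sigma_end - phase.sigma0) * frac
        draw = rng.integers(0, fm.n, T)
        for t in range(T):
            x = X[draw[t]]
            diff = x - code
            d2 = np.einsum("ij,ij->i", diff, diff)
            c = int(np.argmin(d2))
            two_s2 = 2.0 * sigmas[t] * sigmas[t]
            ld = lat_d2[c]
            near = ld < _H_CUTOFF_LOG * sigmas[t] * sigmas[t]
            h = alphas[t] * np.exp(-ld[near] / two_s2)
            code[near] += h[:, None] * diff[near]
            step += 1
            if step % check_every == 0 and not np.isfinite(code).all():
                raise SOMTrainingError(f"non-finite node vector near step {step}")
    if not np.isfinite(code).all():
        raise SOMTrainingError(f"non-finite node vector at step {step}")
    return SOMCodebook(cb.rows, cb.cols, cb.topology, code, cb.columns)


def quantization_error(cb: SOMCodebook, fm: FeatureMatrix) -> float:
    """Mean distance from each input row to its winning node."""
    if fm.n == 0:
        raise ValueError("empty feature matrix")
    if fm.k != cb.k:
        raise ValueError("dimension mismatch")
    d = cdist(fm.data, cb.vectors)
    return float(d.min(axis=1).mean())


# ---------------------------------------------------------------------------
# U-matrix
# ---------------------------------------------------------------------------


def _neighbor_offsets(topology: str, row: int):
    if topology == "rectangular":
        return ((0, 1), (0, -1), (1, 0), (-1, 0))
    # hexagonal, odd-row offset layout
    if row % 2 == 0:
        return ((0, 1), (0, -1), (1, 0), (-1, 0), (1, -1), (-1, -1))
    return ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, 1))


@dataclass
class UMatrix:
    """Distances between lattice-neighbor prototypes.

    ``edges`` holds (i, j, distance) with i < j; ``node_values`` is the
    mean incident-edge distance per node, shaped like the lattice.
    """

    node_values: np.ndarray
    edges: list[tuple[int, int, float]] = field(default_factory=list)


def compute_umatrix(cb: SOMCodebook) -> UMatrix:
    """U-matrix: Euclidean distance across every lattice edge."""
    edges: list[tuple[int, int, float]] = []
    sums = np.zeros(cb.n_nodes)
    counts = np.zeros(cb.n_nodes)
    for i in range(cb.n_nodes):
        r, c = divmod(i, cb.cols)
        for dr, dc in _neighbor_offsets(cb.topology, r):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < cb.rows and 0 <= cc < cb.cols):
                continue
            j = rr * cb.cols + cc
            if j <= i:
                continue
            d = float(np.linalg.norm(cb.vectors[i] - cb.vectors[j]))
            edges.append((i, j, d))
            sums[i] += d
            sums[j] += d
            counts[i] += 1
            counts[j] += 1
    node_vals = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return UMatrix(node_vals.reshape(cb.rows, cb.cols), edges)
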