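"""Batch-learning self-organising map (BLSOM).

A Kohonen-style SOM variant adapted for genome signatures: the lattice is
initialised on the plane spanned by the first two principal components of the
data (not random values), and weights are updated in batch epochs, which makes
the trained map independent of the order in which data vectors are presented.

Per epoch r of T:

* every data vector is assigned its best-matching unit (BMU), the node whose
  weight vector has minimum Euclidean distance;
* every node pulls its weight toward the mean of the data vectors whose BMU
  lies within Chebyshev distance beta(r) on the lattice:
  w_ij <- w_ij + alpha(r) * (mean - w_ij), nodes with empty neighbourhoods
  being left unchanged;
* the learning coefficient and neighbourhood radius decay linearly,
  alpha(r) = max(alpha_min, alpha0 * (1 - r/T)) and
  beta(r) = max(1, round(beta0 * (1 - r/T))).

There is no random state anywhere; identical inputs give bitwise-identical
maps, and data vectors are put into a canonical order before training so a
permutation of the input cannot change floating-point accumulation order.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrainingConfig",
    "Lattice",
    "pca_initialize",
    "bmu",
    "bmus",
    "train",
    "quantization_error",
    "save_lattice",
    "load_lattice",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Training schedule and lattice-sizing parameters.

    beta0 defaults to max(I, J)/2 when left as None.  nodes_per_vector sets
    the number of lattice nodes per training vector when the lattice width is
    chosen automatically; ~0.35 keeps about three training vectors per node,
    enough occupancy to label node territories while resolving sub-clusters.
    init_span is the half-width of the initial weight plane in standard
    deviations along each principal axis.
    """

    epochs: int = 100
    alpha0: float = 0.6
    alpha_min: float = 0.01
    beta0: Optional[float] = None
    init_span: float = 2.5
    nodes_per_vector: float = 0.35

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.alpha0 <= 1:
            raise ValueError("alpha0 must be in (0, 1]")
        if not 0 < self.alpha_min <= self.alpha0:
            raise ValueError("alpha_min must be in (0, alpha0]")
        if self.beta0 is not None and self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if self.init_span <= 0 or self.nodes_per_vector <= 0:
            raise ValueError("init_span and nodes_per_vector must be positive")


@dataclass
class Lattice:
    """An I x J grid of weight vectors w_ij in composition space."""

    weights: np.ndarray  # shape (I, J, dim), float64
    trained_epochs: int = 0
    config: TrainingConfig = field(default_factory=TrainingConfig)

    @property
    def I(self) -> int:  # noqa: E743 - field-standard lattice axis name
        return self.weights.shape[0]

    @property
    def J(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    @property
    def flat_weights(self) -> np.ndarray:
        return self.weights.reshape(self.I * self.J, self.dim)


class InitializationError(ValueError):
    pass


def _principal_plane(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, first two principal axes (rows) and their standard deviations.

    The sign of each axis is fixed so that its largest-magnitude loading is
    positive, making the decomposition (and everything downstream of it)
    deterministic.
    """
    mean = data.mean(axis=0)
    centered = data - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise InitializationError("data has zero total variance")
    sigma = s / np.sqrt(len(data) - 1)
    axes = vt[:2].copy()
    for a in axes:
        if a[np.argmax(np.abs(a))] < 0:
            a *= -1
    if len(sigma) < 2:
        sigma = np.array([sigma[0], 0.0])
    return mean, axes, sigma[:2]


def auto_lattice_width(data: Sequence[np.ndarray], config: TrainingConfig) -> int:
    """Lattice width I such that I*J ~= nodes_per_vector * n_data.

    With J = round(I * sigma2/sigma1) the node count is ~I^2 * sigma2/sigma1,
    so I = sqrt(target * sigma1/sigma2); degenerate aspect ratios are clipped
    to keep the lattice two-dimensional.
    """
    X = np.asarray(data, dtype=np.float64)
    _, _, sigma = _principal_plane(X)
    ratio = sigma[1] / sigma[0] if sigma[1] > 0 else 0.0
    target = max(4.0, config.nodes_per_vector * len(X))
    ratio = min(max(ratio, 0.05), 1.0)
    return max(2, int(round(np.sqrt(target / ratio))))


def pca_initialize(
    data: Sequence[np.ndarray],
    I: Optional[int] = None,  # noqa: E741
    config: TrainingConfig = TrainingConfig(),
) -> Lattice:
    """Initial lattice on the PC1-PC2 plane of the data.

    J = max(1, round(I * sigma2/sigma1)) so the lattice aspect follows the
    data cloud; node (i, j) starts at
    mean + span*sigma1*(2i/(I-1) - 1)*b1 + span*sigma2*(2j/(J-1) - 1)*b2,
    the linear term along an axis being dropped when that axis has length 1.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2 or len(X) < 3:
        raise InitializationError("need at least 3 data vectors")
    mean, axes, sigma = _principal_plane(X)
    if I is None:
        I = auto_lattice_width(X, config)  # noqa: E741
    if I < 1:
        raise InitializationError("lattice width I must be >= 1")
    J = max(1, int(round(I * sigma[1] / sigma[0])))
    span = config.init_span
    ti = np.linspace(-1.0, 1.0, I) if I > 1 else np.zeros(1)
    tj = np.linspace(-1.0, 1.0, J) if J > 1 else np.zeros(1)
    weights = (
        mean[None, None, :]
        + span * sigma[0] * ti[:, None, None] * axes[0][None, None, :]
        + span * sigma[1] * tj[None, :, None] * axes[1][None, None, :]
    )
    return Lattice(weights=np.ascontiguousarray(weights), trained_epochs=0, config=config)


def bmus(X: np.ndarray, lattice: Lattice) -> np.ndarray:
    """Flat best-matching-unit index (i*J + j) of each row of X.

    Ties in squared distance resolve to the smallest flat index, i.e. the
    smallest i then the smallest j.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != lattice.dim:
        raise ValueError(f"query dim {X.shape[1]} != lattice dim {lattice.dim}")
    W = lattice.flat_weights
    # ||x - w||^2 up to the constant ||x||^2; argmin is unaffected
    d = -2.0 * (X @ W.T) + np.einsum("ij,ij->i", W, W)[None, :]
    return np.argmin(d, axis=1)


def bmu(x: np.ndarray, lattice: Lattice) -> tuple[int, int]:
    """(i, j) of the node with minimum Euclidean distance to x."""
    flat = int(bmus(np.asarray(x, dtype=np.float64)[None, :], lattice)[0])
    return divmod(flat, lattice.J)


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Data matrix sorted lexicographically by row bytes.

    Training accumulates sums over the rows mapped to each node; fixing one
    canonical row order makes those floating-point sums identical for any
    permutation of the input.
    """
    order = np.lexsort(X.T[::-1])
    return np.ascontiguousarray(X[order])


def _box_sum(A: np.ndarray, radius: int) -> np.ndarray:
    """Sum of A over the (2*radius+1)^2 Chebyshev ball around each (i, j)."""
    I, J = A.shape[0], A.shape[1]
    c = np.zeros((I + 1, J + 1) + A.shape[2:], dtype=A.dtype)
    np.cumsum(A, axis=0, out=c[1:, 1:])
    np.cumsum(c[1:, 1:], axis=1, out=c[1:, 1:])
    i0 = np.clip(np.arange(I) - radius, 0, I)
    i1 = np.clip(np.arange(I) + radius + 1, 0, I)
    j0 = np.clip(np.arange(J) - radius, 0, J)
    j1 = np.clip(np.arange(J) + radius + 1, 0, J)
    return (
        c[i1[:, None], j1[None, :]]
        - c[i0[:, None], j1[None, :]]
        - c[i1[:, None], j0[None, :]]
        + c[i0[:, None], j0[None, :]]
    )


def train(
    lattice: Lattice,
    data: Sequence[np.ndarray],
    config: Optional[TrainingConfig] = None,
) -> Lattice:
    """Run the batch training schedule; returns a new trained Lattice."""
    cfg = config if config is not None else lattice.config
    X = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("training data is empty")
    if X.shape[1] != lattice.dim:
        raise ValueError(f"data dim {X.shape[1]} != lattice dim {lattice.dim}")
    X = _canonical_order(X)
    I, J, dim = lattice.I, lattice.J, lattice.dim
    beta0 = cfg.beta0 if cfg.beta0 is not None else max(I, J) / 2.0
    W = lattice.weights.copy()
    work = Lattice(weights=W, trained_epochs=lattice.trained_epochs, config=cfg)
    T = cfg.epochs
    for r in range(1, T + 1):
        alpha = max(cfg.alpha_min, cfg.alpha0 * (1.0 - r / T))
        beta = max(1, int(round(beta0 * (1.0 - r / T))))
        flat = bmus(X, work)
        sums = np.zeros((I * J, dim))
        counts = np.bincount(flat, minlength=I * J).astype(np.float64)
        np.add.at(sums, flat, X)
        nbr_sum = _box_sum(sums.reshape(I, J, dim), beta)
        nbr_count = _box_sum(counts.reshape(I, J), beta)
        occupied = nbr_count > 0
        target = np.where(
            occupied[:, :, None], nbr_sum / np.maximum(nbr_count, 1.0)[:, :, None], W
        )
        W += alpha * (target - W)
    work.trained_epochs = lattice.trained_epochs + T
    return work


def quantization_error(lattice: Lattice, data: Sequence[np.ndarray]) -> float:
    """Mean Euclidean distance from each data vector to its BMU weight."""
    X = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("data is empty")
    W = lattice.flat_weights[bmus(X, lattice)]
    return float(np.mean(np.linalg.norm(X - W, axis=1)))


# ---------------------------------------------------------------------------
# serialization: self-describing structured text, one node per row

_MAGIC = "blsomhgt-lattice v1"


def lattice_to_text(lattice: Lattice) -> str:
    cfg = lattice.config
    buf = _stdio.StringIO()
    buf.write(f"# {_MAGIC}\n")
    buf.write(f"# I={lattice.I} J={lattice.J} dim={lattice.dim}\n")
    buf.write(f"# trained_epochs={lattice.trained_epochs}\n")
    buf.write(
        f"# config epochs={cfg.epochs} alpha0={cfg.alpha0!r} alpha_min={cfg.alpha_min!r}"
        f" beta0={cfg.beta0!r} init_span={cfg.init_span!r}"
        f" nodes_per_vector={cfg.nodes_per_vector!r}\n"
    )
    flat = lattice.flat_weights
    for idx in range(flat.shape[0]):
        i, j = divmod(idx, lattice.J)
        buf.write(f"{i}\t{j}\t" + "\t".join(f"{v:.17g}" for v in flat[idx]) + "\n")
    return buf.getvalue()


def save_lattice(lattice: Lattice, path) -> None:
    with open(path, "w") as fh:
        fh.write(lattice_to_text(lattice))


class LatticeLoadError(ValueError):
    pass


def load_lattice(path) -> Lattice:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != f"# {_MAGIC}":
        raise LatticeLoadError(f"{path}: not a lattice file (bad magic)")
    try:
        dims = dict(kv.split("=") for kv in lines[1].lstrip("# ").split())
        I, J, dim = int(dims["I"]), int(dims["J"]), int(dims["dim"])
        trained = int(lines[2].split("=", 1)[1])
        ckv = dict(kv.split("=", 1) for kv in lines[3].lstrip("# ").split()[1:])
        cfg = TrainingConfig(
            epochs=int(ckv["epochs"]),
            alpha0=float(ckv["alpha0"]),
            alpha_min=float(ckv["alpha_min"]),
            beta0=None if ckv["beta0"] == "None" else float(ckv["beta0"]),
            init_span=float(ckv["init_span"]),
            nodes_per_vector=float(ckv["nodes_per_vector"]),
        )
        body = lines[4:]
        if len(body) != I * J:
            raise ValueError(f"expected {I * J} node rows, found {len(body)}")
        weights = np.empty((I * J, dim))
        for idx, line in enumerate(body):
            parts = line.split("\t")
            if len(parts) != dim + 2 or int(parts[0]) * J + int(parts[1]) != idx:
                raise ValueError(f"corrupt node row {idx}")
            weights[idx] = [float(v) for v in parts[2:]]
    except LatticeLoadError:
        raise
    except Exception as exc:
        raise LatticeLoadError(f"{path}: corrupt lattice file ({exc})") from exc
    return Lattice(weights=weights.reshape(I, J, dim), trained_epochs=trained, config=cfg)
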