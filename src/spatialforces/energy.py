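"""Energy model: local fields, interaction energy, moments, and the loss.

The model is a maximum-entropy (Ising/Potts-style) distribution over
normalized expression states ``S`` on a spatial neighbor graph ``J``:

    p(S | G, G') ∝ exp(H),   H = Σ_i s_i·G'·s_i  +  Σ_ij J_ij s_i·G·s_j

``G`` couples genes across neighboring cells (inter-cellular forces) and
``G'`` couples genes within a cell (intra-cellular forces); both are the
Lagrange multipliers enforcing the empirical same-cell and neighbor-cell
gene-gene moments. The intractable log-partition is replaced by a
per-cell mean-field normalizer (row-wise logsumexp of the local field),
giving the training loss

    L = z_mft(Z) - zmft_scalar * Tr(Z Sᵀ),     Z = (J S) G + S G'.

Stationary points of L in (G, G') satisfy mean-field moment matching:
model softmax moments equal ``zmft_scalar`` times the empirical ones.
All energies and partitions are in natural-log units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "GeneGeneForces",
    "ModelConfig",
    "local_field",
    "interaction_energy",
    "empirical_moments",
    "mean_field_log_partition",
    "loss",
    "force_gradients",
    "expression_gradient",
    "flatten_forces",
]


@dataclass
class GeneGeneForces:
    """The pair of gene-gene interaction matrices.

    ``g_inter`` acts on neighbor-aggregated expression (forces between
    genes in adjacent cells); ``g_intra`` acts on the cell's own
    expression (forces between genes within one cell). Matrices produced
    by fitting or by the symmetric random generator are symmetric: the
    undirected graph is the identifiable object.
    """

    g_inter: np.ndarray
    g_intra: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.g_inter = np.asarray(self.g_inter, dtype=float)
        self.g_intra = np.asarray(self.g_intra, dtype=float)
        self.gene_names = list(self.gene_names)
        g = len(self.gene_names)
        for name, m in (("g_inter", self.g_inter), ("g_intra", self.g_intra)):
            if m.shape != (g, g):
                raise ValueError(
                    f"{name} shape {m.shape} does not match {g} gene names"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def is_symmetric(self, tol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.g_inter, self.g_inter.T, atol=tol)
            and np.allclose(self.g_intra, self.g_intra.T, atol=tol)
        )


@dataclass
class ModelConfig:
    """Hyperparameters shared by fitting and generation.

    ``zmft_scalar`` down-weights the energy term relative to the
    mean-field normalizer; 1 means the mean-field approximation is taken
    as exact, values toward 0 adjust for its violation. ``n_neighbors``
    is the spatial kNN graph degree (default 6: disentangle a cell's own
    regulation from that of its 6 nearest neighbors).
    """

    n_neighbors: int = 6
    zmft_scalar: float = 1.0
    learning_rate: float = 0.1
    epochs: int = 100
    seed: int = 0
    symmetrize: bool = True
    init: str = "zeros"  # "zeros" | "random"
    init_scale: float = 1.0
    optimizer: str = "gd"  # "gd" | "adam"
    line_search: bool = True  # generation only: halve step on loss increase

    def __post_init__(self) -> None:
        if not (0.0 < self.zmft_scalar <= 1.0) and self.zmft_scalar != 0.0:
            raise ValueError("zmft_scalar must be in (0, 1] (0 allowed for diagnostics)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.init not in ("zeros", "random"):
            raise ValueError("init must be 'zeros' or 'random'")
        if self.optimizer not in ("gd", "adam"):
            raise ValueError("optimizer must be 'gd' or 'adam'")

    def to_dict(self) -> dict:
        return {
            "n_neighbors": self.n_neighbors,
            "zmft_scalar": self.zmft_scalar,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "seed": self.seed,
            "symmetrize": self.symmetrize,
            "init": self.init,
            "init_scale": self.init_scale,
            "optimizer": self.optimizer,
            "line_search": self.line_search,
        }


def _check_dims(S: np.ndarray, J: np.ndarray, forces: GeneGeneForces | None) -> None:
    n, g = S.shape
    if J.shape != (n, n):
        raise ValueError(
            f"adjacency J has shape {J.shape}, expected ({n}, {n}) to match S"
        )
    if forces is not None:
        if forces.g_inter.shape != (g, g):
            raise ValueError(
                f"g_inter has shape {forces.g_inter.shape}, expected ({g}, {g}) to match S"
            )
        if forces.g_intra.shape != (g, g):
            raise ValueError(
                f"g_intra has shape {forces.g_intra.shape}, expected ({g}, {g}) to match S"
            )


def local_field(S: np.ndarray, J: np.ndarray, forces: GeneGeneForces) -> np.ndarray:
    """Node embedding Z = (J S) G_inter + S G_intra.

    The neighbor-aggregated term carries the inter-cellular forces; the
    self term carries the intra-cellular forces.
    """
    S = np.asarray(S, dtype=float)
    J = np.asarray(J, dtype=float)
    _check_dims(S, J, forces)
    return (J @ S) @ forces.g_inter + S @ forces.g_intra


def interaction_energy(S: np.ndarray, J: np.ndarray, forces: GeneGeneForces) -> float:
    """H = Tr(Z Sᵀ) = Σ_i s_i·G'·s_i + Σ_ij J_ij s_i·G·s_j."""
    S = np.asarray(S, dtype=float)
    return float(np.sum(local_field(S, J, forces) * S))


def empirical_moments(S: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical neighbor-cell and same-cell gene-gene moments.

    C_inter[α,β] = Σ_ij s_i^α J_ij s_j^β = (Sᵀ J S)[α,β];
    C_intra[α,β] = Σ_i s_i^α s_i^β = (Sᵀ S)[α,β].
    """
    S = np.asarray(S, dtype=float)
    J = np.asarray(J, dtype=float)
    _check_dims(S, J, None)
    return S.T @ J @ S, S.T @ S


def mean_field_log_partition(Z: np.ndarray) -> float:
    """Per-cell mean-field normalizer: Σ_i log Σ_α exp(Z_iα)."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("local field contains non-finite entries")
    return float(logsumexp(Z, axis=1).sum())


def loss(
    S: np.ndarray,
    J: np.ndarray,
    forces: GeneGeneForces,
    zmft_scalar: float = 1.0,
) -> float:
    """Training loss L = z_mft(Z) - zmft_scalar * Tr(Z Sᵀ).

    This is the negative mean-field log-likelihood surrogate of the
    maximum-entropy model; it is convex in (G, G') for fixed S.
    """
    S = np.asarray(S, dtype=float)
    Z = local_field(S, J, forces)
    return mean_field_log_partition(Z) - zmft_scalar * float(np.sum(Z * S))


def force_gradients(
    S: np.ndarray,
    J: np.ndarray,
    forces: GeneGeneForces,
    zmft_scalar: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradients of :func:`loss` with respect to G_inter and G_intra.

    With P = row-softmax(Z) (the per-cell mean-field gene distribution):

      dL/dG_inter[α,β] = Σ_i (J S)_iα P_iβ - zmft_scalar * C_inter[α,β]
      dL/dG_intra[α,β] = Σ_i  s_i^α  P_iβ - zmft_scalar * C_intra[α,β]

    i.e. model softmax moments minus (scaled) empirical moments — the
    moment-matching stationarity condition of the maximum-entropy fit.
    """
    S = np.asarray(S, dtype=float)
    J = np.asarray(J, dtype=float)
    Z = local_field(S, J, forces)
    P = softmax(Z, axis=1)
    JS = J @ S
    grad_inter = JS.T @ P - zmft_scalar * (JS.T @ S)
    grad_intra = S.T @ P - zmft_scalar * (S.T @ S)
    return grad_inter, grad_intra


def expression_gradient(
    S: np.ndarray,
    J: np.ndarray,
    forces: GeneGeneForces,
    zmft_scalar: float = 1.0,
) -> np.ndarray:
    """Exact gradient of :func:`loss` with respect to the state S.

    Valid for arbitrary (not necessarily symmetric) J, G, G'; used by the
    generation module's projected descent.
    """
    S = np.asarray(S, dtype=float)
    J = np.asarray(J, dtype=float)
    G, Gp = forces.g_inter, forces.g_intra
    Z = local_field(S, J, forces)
    P = softmax(Z, axis=1)
    d_lse = J.T @ P @ G.T + P @ Gp.T
    d_energy = J.T @ S @ G.T + J @ S @ G + S @ (Gp.T + Gp)
    return d_lse - zmft_scalar * d_energy


def flatten_forces(forces: GeneGeneForces) -> np.ndarray:
    """Concatenate g_inter and g_intra row-major, diagonals included.

    The canonical vectorization used for all force-matrix correlations.
    """
    return np.concatenate([forces.g_inter.ravel(), forces.g_intra.ravel()])
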