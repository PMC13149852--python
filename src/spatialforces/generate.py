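"""Generation: the most probable expression state under fixed forces.

Given learned force matrices, the generator finds a maximum a
posteriori expression state by projected gradient descent on the same
mean-field loss used for inference — with the forces frozen and the
state free. Knockouts are expressed as clamps: (cell, gene) entries held
at zero through every update, yielding the counterfactual

    p({s_i}  |  s_j^β = 0, G, G').

After each unconstrained step the state is projected back to the model's
domain: clamped entries zeroed, negative entries floored at zero, rows
rescaled to unit L2 norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .energy import GeneGeneForces, ModelConfig, expression_gradient, loss
from .preprocess import SpatialSample

__all__ = ["PerturbationSpec", "GenerationResult", "generate", "knockout", "random_state"]

_MAX_HALVINGS = 40


@dataclass
class PerturbationSpec:
    """Entries clamped to zero during generation: a set of (cell, gene) pairs."""

    clamps: frozenset[tuple[int, int]]

    def __init__(self, clamps) -> None:
        clamps = [(int(c), int(g)) for c, g in clamps]
        if len(clamps) != len(set(clamps)):
            raise ValueError("duplicate clamp entries")
        self.clamps = frozenset(clamps)

    def validate(self, n_cells: int, n_genes: int) -> None:
        per_cell: dict[int, int] = {}
        for c, g in self.clamps:
            if not (0 <= c < n_cells and 0 <= g < n_genes):
                raise IndexError(f"clamp ({c}, {g}) out of range for {n_cells}x{n_genes}")
            per_cell[c] = per_cell.get(c, 0) + 1
        for c, k in per_cell.items():
            if k >= n_genes:
                raise ValueError(
                    f"cell {c} has all {n_genes} genes clamped; no valid state exists"
                )

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.clamps:
            return np.array([], dtype=int), np.array([], dtype=int)
        cells, genes = zip(*sorted(self.clamps))
        return np.asarray(cells), np.asarray(genes)


@dataclass
class GenerationResult:
    states: list[np.ndarray]
    final_state: np.ndarray
    loss_trajectory: np.ndarray
    recorded_epochs: list[int]


def random_state(n_cells: int, n_genes: int, seed: int) -> np.ndarray:
    """Uniform-random non-negative unit-norm rows: the de-novo 'raw input'."""
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, 1.0, (n_cells, n_genes))
    return S / np.linalg.norm(S, axis=1, keepdims=True)


def _project(S: np.ndarray, cells: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Clamp, floor at zero, rescue dead rows, renormalize rows."""
    S = np.maximum(S, 0.0)
    if cells.size:
        S[cells, genes] = 0.0
    norms = np.linalg.norm(S, axis=1)
    dead = norms == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} row(s) became all-zero after projection; "
            "re-seeded to uniform",
            stacklevel=3,
        )
        S[dead] = 1.0
        if cells.size:
            S[cells, genes] = 0.0
        norms = np.linalg.norm(S, axis=1)
    return S / norms[:, None]


def generate(
    forces: GeneGeneForces,
    J: np.ndarray,
    init_S: np.ndarray,
    perturbation: PerturbationSpec | None = None,
    config: ModelConfig | None = None,
    record_stride: int = 1,
) -> GenerationResult:
    """MAP state search by projected gradient descent with frozen forces.

    With ``config.line_search`` (default) the step is halved until the
    projected loss does not increase, so the loss trajectory is
    non-increasing up to numerical tolerance. Every recorded state has
    unit-norm rows and exact zeros at all clamped positions.
    """
    config = config or ModelConfig()
    J = np.asarray(J, dtype=float)
    S = np.asarray(init_S, dtype=float).copy()
    if np.any(S < 0):
        raise ValueError("init_S must be non-negative")
    n, g = S.shape
    perturbation = perturbation or PerturbationSpec([])
    perturbation.validate(n, g)
    cells, genes = perturbation.indices()

    S = _project(S, cells, genes)
    current_loss = loss(S, J, forces, config.zmft_scalar)

    states: list[np.ndarray] = []
    recorded: list[int] = []
    trajectory = np.empty(config.epochs)
    for epoch in range(config.epochs):
        grad = expression_gradient(S, J, forces, config.zmft_scalar)
        step = config.learning_rate
        S_new = _project(S - step * grad, cells, genes)
        new_loss = loss(S_new, J, forces, config.zmft_scalar)
        if config.line_search:
            halvings = 0
            while new_loss > current_loss and halvings < _MAX_HALVINGS:
                step /= 2.0
                halvings += 1
                S_new = _project(S - step * grad, cells, genes)
                new_loss = loss(S_new, J, forces, config.zmft_scalar)
            if new_loss > current_loss:
                # no feasible descent along the projected ray; hold state
                S_new, new_loss = S, current_loss
        S, current_loss = S_new, new_loss
        trajectory[epoch] = current_loss
        if epoch % record_stride == 0 or epoch == config.epochs - 1:
            states.append(S.copy())
            recorded.append(epoch)

    return GenerationResult(
        states=states,
        final_state=S,
        loss_trajectory=trajectory,
        recorded_epochs=recorded,
    )


def knockout(
    sample: SpatialSample,
    gene: str,
    cell: int | str = "random_positive",
    seed: int = 0,
) -> tuple[PerturbationSpec, int]:
    """One-gene, one-cell knockout clamp.

    ``cell="random_positive"`` draws uniformly (seeded) among cells with
    positive expression of the gene — the 'randomly selected previously
    positive cell' protocol. Returns the clamp set and the chosen cell
    index.
    """
    if gene not in sample.gene_names:
        raise KeyError(f"gene {gene!r} not in sample")
    gidx = sample.gene_names.index(gene)
    if cell == "random_positive":
        positive = np.flatnonzero(sample.expression[:, gidx] > 0)
        if positive.size == 0:
            raise ValueError(f"no cell expresses {gene!r}; cannot pick a positive cell")
        rng = np.random.default_rng(seed)
        cidx = int(rng.choice(positive))
    else:
        cidx = int(cell)
        if not 0 <= cidx < sample.n_cells:
            raise IndexError(f"cell index {cidx} out of range")
    return PerturbationSpec([(cidx, gidx)]), cidx
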