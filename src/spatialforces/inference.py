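"""Inference: learn gene-gene force matrices from spatial samples.

Fitting minimizes the summed mean-field loss over one or more samples by
full-batch first-order descent. The loss is convex in the forces for
fixed data, so plain gradient descent with a fixed step is auditable and
adequate; Adam is available as an opt-in. With symmetrization on (the
default) both matrices are projected to their symmetric part after every
update — only the undirected interaction graph is identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .energy import (
    GeneGeneForces,
    ModelConfig,
    flatten_forces,
    force_gradients,
    loss,
)
from .preprocess import SpatialSample

__all__ = [
    "FitResult",
    "ConsistencyReport",
    "fit",
    "cross_model_consistency",
    "interaction_contrast",
]


@dataclass
class FitResult:
    forces: GeneGeneForces
    loss_trajectory: np.ndarray
    config: ModelConfig
    n_samples_trained: int
    final_grad_norm: float


@dataclass
class ConsistencyReport:
    """Spearman agreement between two force sets against a shuffled null."""

    rho: float
    p: float
    shuffled_rhos: np.ndarray
    mw_p: float


def _init_forces(n_genes: int, gene_names: list[str], config: ModelConfig) -> GeneGeneForces:
    if config.init == "zeros":
        gi = np.zeros((n_genes, n_genes))
        gq = np.zeros((n_genes, n_genes))
    else:
        rng = np.random.default_rng(config.seed)
        gi = rng.uniform(-config.init_scale, config.init_scale, (n_genes, n_genes))
        gq = rng.uniform(-config.init_scale, config.init_scale, (n_genes, n_genes))
        if config.symmetrize:
            gi = (gi + gi.T) / 2
            gq = (gq + gq.T) / 2
    return GeneGeneForces(gi, gq, gene_names)


def fit(
    samples: SpatialSample | list[SpatialSample],
    config: ModelConfig | None = None,
) -> FitResult:
    """Learn force matrices minimizing the summed per-sample loss.

    All samples must share ``gene_names``; each brings its own adjacency.
    Runs exactly ``config.epochs`` epochs (no early stopping) and reports
    the final gradient norm. Deterministic given ``config.seed``.
    """
    if isinstance(samples, SpatialSample):
        samples = [samples]
    if not samples:
        raise ValueError("at least one sample is required")
    config = config or ModelConfig()
    gene_names = samples[0].gene_names
    for s in samples[1:]:
        if s.gene_names != gene_names:
            raise ValueError("samples have mismatched gene_names; align genes first")
    g = len(gene_names)
    forces = _init_forces(g, gene_names, config)

    lr = config.learning_rate
    # Adam state (used only with optimizer="adam")
    m_i = np.zeros((g, g)); v_i = np.zeros((g, g))
    m_q = np.zeros((g, g)); v_q = np.zeros((g, g))
    b1, b2, eps = 0.9, 0.999, 1e-8

    trajectory = np.empty(config.epochs)
    grad_i = grad_q = np.zeros((g, g))
    for epoch in range(config.epochs):
        total = 0.0
        grad_i = np.zeros((g, g))
        grad_q = np.zeros((g, g))
        for s in samples:
            total += loss(s.expression, s.adjacency, forces, config.zmft_scalar)
            gi, gq = force_gradients(
                s.expression, s.adjacency, forces, config.zmft_scalar
            )
            grad_i += gi
            grad_q += gq
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; reduce the learning rate"
            )
        trajectory[epoch] = total
        if config.optimizer == "adam":
            t = epoch + 1
            m_i = b1 * m_i + (1 - b1) * grad_i
            v_i = b2 * v_i + (1 - b2) * grad_i**2
            m_q = b1 * m_q + (1 - b1) * grad_q
            v_q = b2 * v_q + (1 - b2) * grad_q**2
            step_i = lr * (m_i / (1 - b1**t)) / (np.sqrt(v_i / (1 - b2**t)) + eps)
            step_q = lr * (m_q / (1 - b1**t)) / (np.sqrt(v_q / (1 - b2**t)) + eps)
        else:
            step_i = lr * grad_i
            step_q = lr * grad_q
        gi_new = forces.g_inter - step_i
        gq_new = forces.g_intra - step_q
        if config.symmetrize:
            gi_new = (gi_new + gi_new.T) / 2
            gq_new = (gq_new + gq_new.T) / 2
        forces = GeneGeneForces(gi_new, gq_new, gene_names)

    final_grad_norm = float(np.sqrt(np.sum(grad_i**2) + np.sum(grad_q**2)))
    return FitResult(
        forces=forces,
        loss_trajectory=trajectory,
        config=config,
        n_samples_trained=len(samples),
        final_grad_norm=final_grad_norm,
    )


def cross_model_consistency(
    forces_a: GeneGeneForces,
    forces_b: GeneGeneForces,
    n_shuffles: int = 200,
    seed: int = 0,
) -> ConsistencyReport:
    """Spearman agreement between two independently learned force sets.

    Both force pairs are flattened (inter then intra, diagonals included)
    and rank-correlated; the null distribution comes from re-correlating
    against ``n_shuffles`` random permutations of the second vector. The
    Mann-Whitney U p compares the observed rho against the shuffled rhos.
    """
    if forces_a.gene_names != forces_b.gene_names:
        raise ValueError("force sets must share the same genes in the same order")
    va = flatten_forces(forces_a)
    vb = flatten_forces(forces_b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant force vector: Spearman correlation is undefined")
    res = stats.spearmanr(va, vb)
    rng = np.random.default_rng(seed)
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled[i] = stats.spearmanr(va, rng.permutation(vb)).statistic
    mw = stats.mannwhitneyu([res.statistic], shuffled, alternative="two-sided")
    return ConsistencyReport(
        rho=float(res.statistic),
        p=float(res.pvalue),
        shuffled_rhos=shuffled,
        mw_p=float(mw.pvalue),
    )


def interaction_contrast(
    forces: GeneGeneForces,
    gene_classes: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Contrast inter- vs intra-cellular force per interaction, by gene class.

    For every ordered off-diagonal gene pair (a, b) the contrast is
    ``g_inter[a,b] - g_intra[a,b]``; the pair contributes one row per
    annotated class among its two genes (e.g. secreted, membrane,
    cytoplasmic localization labels). Genes labeled "unannotated" (or
    absent from the mapping) are excluded.

    Returns (per-interaction table, per-class summary with mean and 95%
    CI, pairwise two-tailed Mann-Whitney U p-values).
    """
    import warnings as _warnings

    names = forces.gene_names
    diff = forces.g_inter - forces.g_intra
    rows = []
    for ia, a in enumerate(names):
        for ib, b in enumerate(names):
            if ia == ib:
                continue
            for cls_gene in (a, b):
                cls = gene_classes.get(cls_gene, "unannotated")
                if cls == "unannotated":
                    continue
                rows.append((a, b, cls, diff[ia, ib]))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "class", "difference"])

    summaries = []
    for cls, grp in table.groupby("class"):
        x = grp["difference"].to_numpy()
        mean = x.mean()
        if x.size > 1 and x.std(ddof=1) > 0:
            lo, hi = stats.t.interval(
                0.95, df=x.size - 1, loc=mean, scale=stats.sem(x)
            )
        else:
            lo = hi = mean
        summaries.append((cls, x.size, mean, lo, hi))
    summary = pd.DataFrame(
        summaries, columns=["class", "n", "mean", "ci_low", "ci_high"]
    )

    classes = summary["class"].tolist()
    announced = set(gene_classes.values()) - {"unannotated"}
    for missing in sorted(announced - set(classes)):
        _warnings.warn(f"class {missing!r} has zero interactions; omitted", stacklevel=2)

    pvals = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            xa = table.loc[table["class"] == ca, "difference"]
            xb = table.loc[table["class"] == cb, "difference"]
            p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            pvals.append((ca, cb, float(p)))
    pairwise = pd.DataFrame(pvals, columns=["class_a", "class_b", "mw_p"])
    return table, summary, pairwise
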