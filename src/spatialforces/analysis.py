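"""Downstream perturbation statistics.

Neighbor tiers around a perturbed cell, signature derivation and
scoring, pre/post differential-change ranking between cell subsets, rank
agreement against observed knockouts with a shuffled-ranking null, and
spot trimming near perturbed clusters. All p-values are two-tailed;
rank ties are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "RankAgreementReport",
    "neighbor_tiers",
    "derive_signature",
    "signature_score",
    "differential_change",
    "rank_agreement",
    "trim_near_perturbed",
    "export_rnk",
]


@dataclass
class RankAgreementReport:
    rho: float
    p: float
    shuffled_rhos: np.ndarray
    mw_p: float


def neighbor_tiers(
    coords: np.ndarray,
    focal_cell: int,
    r1: float = 15.0,
    r2: float = 30.0,
) -> np.ndarray:
    """Label cells by distance from the perturbed cell.

    distance 0 for the focal cell itself -> "perturbed"; 0 < d < r1 ->
    "first"; r1 <= d < r2 -> "second"; otherwise "other". Defaults 15
    and 30 are in the coordinate units (µm for single-cell platforms). A
    non-self cell at distance exactly 0 (duplicate centroid) is labeled
    "first" with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if not (0 <= focal_cell < coords.shape[0]):
        raise IndexError(f"focal_cell {focal_cell} out of range")
    if not r1 < r2:
        raise ValueError("require r1 < r2")
    d = np.linalg.norm(coords - coords[focal_cell], axis=1)
    tiers = np.full(coords.shape[0], "other", dtype=object)
    tiers[d < r2] = "second"
    tiers[d < r1] = "first"
    dup = (d == 0) & (np.arange(coords.shape[0]) != focal_cell)
    if np.any(dup):
        warnings.warn(
            f"{int(dup.sum())} non-self cell(s) share the focal coordinate; "
            "labeled 'first'",
            stacklevel=2,
        )
    tiers[focal_cell] = "perturbed"
    return tiers


def derive_signature(
    S: np.ndarray,
    gene_names: list[str],
    anchor_gene: str,
    top_n: int = 25,
) -> list[str]:
    """Signature of an anchor gene: top differential genes, high vs low cells.

    Cells are split by presence (> 0) vs absence (= 0) of the anchor
    gene's expression; genes are ranked by mean(high) - mean(low) and the
    top ``top_n`` returned, excluding the anchor itself (it would bias
    downstream knockout scoring).
    """
    S = np.asarray(S, dtype=float)
    if anchor_gene not in gene_names:
        raise KeyError(f"anchor gene {anchor_gene!r} not present")
    a = gene_names.index(anchor_gene)
    high = S[:, a] > 0
    if not high.any() or high.all():
        raise ValueError(
            f"cannot split on {anchor_gene!r}: one of the high/low groups is empty"
        )
    diff = S[high].mean(axis=0) - S[~high].mean(axis=0)
    order = np.argsort(-diff, kind="stable")
    ranked = [gene_names[i] for i in order if i != a]
    return ranked[:top_n]


def signature_score(S: np.ndarray, gene_names: list[str], gene_set: list[str]) -> np.ndarray:
    """Per-cell mean expression over the signature genes."""
    if not gene_set:
        raise ValueError("gene_set is empty")
    S = np.asarray(S, dtype=float)
    missing = [g for g in gene_set if g not in gene_names]
    if missing:
        raise KeyError(f"genes not present: {missing}")
    idx = [gene_names.index(g) for g in gene_set]
    return S[:, idx].mean(axis=1)


def differential_change(
    S_pre: np.ndarray,
    S_post: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene contrast of expression change between two cell subsets.

    delta = S_post - S_pre per cell; the statistic per gene is
    mean(delta | group_a) - mean(delta | group_b). Genes are returned
    ranked by the statistic descending, with tied ranks averaged.
    """
    S_pre = np.asarray(S_pre, dtype=float)
    S_post = np.asarray(S_post, dtype=float)
    if S_pre.shape != S_post.shape:
        raise ValueError(f"shape mismatch: pre {S_pre.shape} vs post {S_post.shape}")
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both cell groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("cell groups must be disjoint")
    delta = S_post - S_pre
    stat = delta[group_a].mean(axis=0) - delta[group_b].mean(axis=0)
    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(S_pre.shape[1])]
    df = pd.DataFrame({"gene": gene_names, "statistic": stat})
    df["rank"] = stats.rankdata(-stat, method="average")
    return df.sort_values("rank", kind="stable").reset_index(drop=True)


def rank_agreement(
    predicted: np.ndarray,
    observed: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
) -> RankAgreementReport:
    """Spearman agreement of predicted vs observed gene rankings.

    The null distribution re-correlates against ``n_shuffles`` random
    permutations of the observed vector; the Mann-Whitney U p compares
    the observed rho with the shuffled family. Accepts rankings or any
    scores on the same gene universe.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must cover the same genes")
    if predicted.size < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    res = stats.spearmanr(predicted, observed)
    rng = np.random.default_rng(seed)
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled[i] = stats.spearmanr(predicted, rng.permutation(observed)).statistic
    mw = stats.mannwhitneyu([res.statistic], shuffled, alternative="two-sided")
    return RankAgreementReport(
        rho=float(res.statistic),
        p=float(res.pvalue),
        shuffled_rhos=shuffled,
        mw_p=float(mw.pvalue),
    )


def trim_near_perturbed(
    spot_coords: np.ndarray,
    spot_labels: np.ndarray,
    background_label: str,
    distance_cutoff: float = 100.0,
) -> np.ndarray:
    """Background spots far enough from every perturbation-specific spot.

    Keeps background-labeled spots whose minimum distance to any
    non-background spot is >= ``distance_cutoff`` (a strictly smaller
    distance removes the spot). Returns kept spot indices.
    """
    spot_coords = np.asarray(spot_coords, dtype=float)
    spot_labels = np.asarray(spot_labels, dtype=object)
    if spot_labels.shape[0] != spot_coords.shape[0]:
        raise ValueError("labels must cover all spots")
    bg = np.flatnonzero(spot_labels == background_label)
    if bg.size == 0:
        raise ValueError(f"no spot carries the background label {background_label!r}")
    fg = np.flatnonzero(spot_labels != background_label)
    if fg.size == 0:
        return bg
    dmin = cdist(spot_coords[bg], spot_coords[fg]).min(axis=1)
    kept = bg[dmin >= distance_cutoff]
    if kept.size == 0:
        raise ValueError(
            "all background spots are within the cutoff of a perturbed spot; "
            "use a larger lesion or smaller cutoff"
        )
    return kept


def export_rnk(genes: list[str], scores: np.ndarray, path) -> None:
    """Write a two-column ranked gene list (.rnk, GSEA-compatible)."""
    pd.DataFrame({"gene": genes, "score": np.asarray(scores, dtype=float)}).to_csv(
        path, sep="\t", header=False, index=False
    )
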