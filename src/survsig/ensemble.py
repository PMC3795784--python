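"""Ensemble integration of signature dichotomies.

Orients each dichotomy by survival, measures pairwise disagreement between
the oriented dichotomies, clusters them into a dendrogram, classifies
samples into stable prognosis groups by a consensus threshold, ranks genes
across signatures, and runs the downstream differential-expression /
two-cluster / silhouette analysis of the stable groups.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    Dichotomy,
    EnsembleResult,
    ExpressionMatrix,
    GeneRanking,
    Signature,
    SurvivalData,
)
from .survival import km_estimate

__all__ = [
    "orient_dichotomy",
    "dichotomy_distance",
    "cluster_dichotomies",
    "classify_stability",
    "rank_genes",
    "integrate_signatures",
    "differential_expression",
    "cluster_samples_and_silhouette",
    "linkage_to_newick",
]


def orient_dichotomy(d: Dichotomy, surv: SurvivalData) -> Dichotomy:
    """Label the group with the larger restricted-mean survival "good".

    The restricted mean is the area under each group's Kaplan-Meier curve up
    to the last follow-up time common to both groups. Ties break toward the
    larger group. Invariant to swapping the arbitrary {1,2} codes.
    """
    curves = km_estimate(surv, d.assignment)
    tau = min(
        float(surv.time[d.assignment == 1].max()),
        float(surv.time[d.assignment == 2].max()),
    )
    rms = {g: curves[g].restricted_mean(tau) for g in (1, 2)}
    sizes = {g: int(np.sum(d.assignment == g)) for g in (1, 2)}
    if (rms[1], sizes[1]) >= (rms[2], sizes[2]):
        good = 1
    else:
        good = 2
    orientation = {good: "good", 3 - good: "poor"}
    return replace(d, orientation=orientation)


def dichotomy_distance(a: Dichotomy, b: Dichotomy) -> float:
    """Fraction of samples whose good/poor prognosis label differs."""
    if not (a.is_oriented and b.is_oriented):
        raise ValueError("both dichotomies must be oriented")
    if a.n_samples != b.n_samples:
        raise ValueError("dichotomies cover different sample universes")
    return float(np.mean(a.prognosis_labels() != b.prognosis_labels()))


def cluster_dichotomies(distance_matrix: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration over the dichotomy distance matrix.

    Returns a scipy linkage matrix; leaves correspond to the dichotomy
    (signature) order of the input matrix.
    """
    dm = np.asarray(distance_matrix, dtype=float)
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 dichotomies to build a dendrogram")
    return linkage(squareform(dm, checks=False), method="average")


def classify_stability(dichotomies: list[Dichotomy], threshold: float = 0.8) -> np.ndarray:
    """Consensus classes: stable_good / stable_poor / uncertain per sample.

    A sample is stable_good when its good-label fraction across all oriented
    dichotomies reaches ``threshold``; analogously for stable_poor.
    """
    if not dichotomies:
        raise ValueError("need at least one dichotomy")
    good = np.stack([d.prognosis_labels() == "good" for d in dichotomies])
    frac_good = good.mean(axis=0)
    out = np.full(good.shape[1], "uncertain", dtype=object)
    out[frac_good >= threshold] = "stable_good"
    out[(1.0 - frac_good) >= threshold] = "stable_poor"
    return out


def rank_genes(signatures: list[Signature]) -> GeneRanking:
    """One row per distinct member gene: occurrence count, mean importance.

    Sorted by count descending, then mean importance descending, then probe.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    counts: dict[str, int] = {}
    sums: dict[str, float] = {}
    for sig in signatures:
        for m in sig.members:
            counts[m] = counts.get(m, 0) + 1
            sums[m] = sums.get(m, 0.0) + float(sig.importance.get(m, np.nan))
    rows = sorted(counts, key=lambda g: (-counts[g], -(sums[g] / counts[g]), g))
    return GeneRanking(
        probe_ids=tuple(rows),
        n_signatures=tuple(counts[g] for g in rows),
        mean_importance=tuple(sums[g] / counts[g] for g in rows),
    )


def integrate_signatures(
    signatures: list[Signature],
    surv: SurvivalData,
    threshold: float = 0.8,
) -> EnsembleResult:
    """Orient, measure, cluster and classify the ensemble of signatures."""
    oriented = [orient_dichotomy(s.dichotomy, surv) for s in signatures]
    k = len(oriented)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dm[i, j] = dm[j, i] = dichotomy_distance(oriented[i], oriented[j])
    return EnsembleResult(
        signatures=signatures,
        dichotomies=oriented,
        distance_matrix=dm,
        stability=classify_stability(oriented, threshold=threshold),
        ranking=rank_genes(signatures),
        sample_ids=list(surv.sample_ids),
        linkage=cluster_dichotomies(dm) if k >= 2 else None,
    )


def differential_expression(
    expr: ExpressionMatrix,
    stability: np.ndarray,
    fold_change: float = 1.5,
    alpha: float = 0.05,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Welch t-test per probe between the stable good and poor groups.

    Expression is assumed on the log scale of ``log_base``; fold change is
    the anti-log of the group-mean difference.  Selection requires both
    |fold change| >= ``fold_change`` (linear scale) and BH-adjusted
    p < ``alpha``.  Uncertain samples are excluded.
    """
    stability = np.asarray(stability, dtype=object)
    good = stability == "stable_good"
    poor = stability == "stable_poor"
    if good.sum() < 2 or poor.sum() < 2:
        raise ValueError("each stable group needs at least 2 samples")
    a = expr.values[:, good]
    b = expr.values[:, poor]
    diff = a.mean(axis=1) - b.mean(axis=1)
    stat, p = ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    linear_fc = log_base ** np.abs(diff)
    selected = (linear_fc >= fold_change) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "probe_id": expr.probe_ids,
            "log_fc": diff,
            "p": p,
            "p_adjusted": p_adj,
            "selected": selected,
        }
    )


def cluster_samples_and_silhouette(
    expr: ExpressionMatrix, k: int = 2
) -> tuple[np.ndarray, float]:
    """Two-cluster cut of samples on the given (DEG-restricted) submatrix.

    Distance = 1 - Pearson correlation between sample profiles; average
    linkage; mean silhouette width computed over the same distance.
    """
    if expr.n_probes < 2:
        raise ValueError("need at least 2 probes to cluster samples")
    x = expr.values.T  # samples x probes
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    sizes = np.bincount(labels)[1:]
    if np.any(sizes < 2):
        raise ValueError("a cluster ended up with fewer than 2 samples")
    sil = float(silhouette_score(dist, labels, metric="precomputed"))
    return labels, sil


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
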