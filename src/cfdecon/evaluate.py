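"""Statistics for scoring decompositions and interpreting unknowns."""

from __future__ import annotations

import warnings

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats

__all__ = [
    "pearson_r2",
    "mse",
    "percent_difference",
    "grouped_t_test",
    "assign_unknowns",
    "cluster_methylation",
]


def pearson_r2(est, truth) -> float:
    """Squared Pearson correlation between two vectors.

    Symmetric and invariant to affine rescaling of either argument.
    Returns NaN (with a warning) if either vector is constant.
    """
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if est.size != truth.size or est.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 entries")
    if np.ptp(est) == 0 or np.ptp(truth) == 0:
        warnings.warn("constant input: correlation undefined, returning NaN")
        return float("nan")
    r = scipy.stats.pearsonr(est, truth).statistic
    return float(r * r)


def mse(est, truth) -> float:
    """Mean squared error."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.mean((est - truth) ** 2))


def percent_difference(est, truth) -> float:
    """Mean relative deviation (est - truth) / truth.

    Positive values mean overestimation: +0.32 reads as estimates 32%
    above the truth on average.  Entries with zero truth are excluded.
    """
    est = np.asarray(est, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    keep = truth != 0
    if not keep.any():
        raise ValueError("all truth entries are zero; relative difference undefined")
    return float(np.mean((est[keep] - truth[keep]) / truth[keep]))


def grouped_t_test(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test between independent groups.

    Student's pooled-variance test by default; ``welch=True`` drops the
    equal-variance assumption.  Two identical constant groups return
    (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def assign_unknowns(est_beta: np.ndarray, true_beta: np.ndarray) -> dict[int, int]:
    """Match estimated unknown methylation profiles to candidate cell types.

    Each unknown row of ``est_beta`` is assigned to the row of
    ``true_beta`` with the highest Pearson correlation, greedily without
    replacement in descending order of best available correlation, so
    the mapping is a bijection onto its image and independent of the
    order the unknowns are supplied in.
    """
    est_beta = np.atleast_2d(est_beta)
    true_beta = np.atleast_2d(true_beta)
    n_unknown, n_cand = est_beta.shape[0], true_beta.shape[0]
    if n_unknown == 0:
        raise ValueError("no unknown rows given")
    if n_unknown > n_cand:
        raise ValueError("more unknowns than candidate cell types")
    corr = np.empty((n_unknown, n_cand))
    for i in range(n_unknown):
        for j in range(n_cand):
            corr[i, j] = scipy.stats.pearsonr(est_beta[i], true_beta[j]).statistic
    mapping: dict[int, int] = {}
    free_u = set(range(n_unknown))
    free_c = set(range(n_cand))
    while free_u:
        best = max(
            ((i, j) for i in free_u for j in free_c),
            key=lambda ij: (corr[ij], -ij[0], -ij[1]),
        )
        mapping[best[0]] = best[1]
        free_u.discard(best[0])
        free_c.discard(best[1])
    return mapping


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_methylation(
    beta_rows: np.ndarray,
    labels: list[str],
    metric: str = "correlation",
    linkage: str = "average",
) -> str:
    """Hierarchically cluster methylation profiles; return Newick text.

    Rows are compared with correlation distance (1 - r) and merged with
    average linkage by default; profiles that are alike — for example an
    estimated unknown and the reference cell type it corresponds to —
    join at low height.  Rows containing NaN are dropped with a warning.
    """
    beta_rows = np.atleast_2d(np.asarray(beta_rows, dtype=float))
    if beta_rows.shape[0] != len(labels):
        raise ValueError("one label per row required")
    ok = ~np.isnan(beta_rows).any(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} row(s) containing NaN")
        beta_rows = beta_rows[ok]
        labels = [l for l, k in zip(labels, ok) if k]
    if beta_rows.shape[0] < 2:
        raise ValueError("need at least two complete rows to cluster")
    dist = scipy.spatial.distance.pdist(beta_rows, metric=metric)
    Z = scipy.cluster.hierarchy.linkage(dist, method=linkage)
    tree = scipy.cluster.hierarchy.to_tree(Z)
    return _to_newick(tree, list(labels)) + ";"
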