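"""Phylogenetic clustering tests: MPD/MNTD with permutation nulls.

For a focal group of tips, MPD is the mean cophenetic distance over all
within-group pairs and MNTD the mean distance to the nearest same-group
tip.  The null is built by uniformly permuting the full label vector
across tips; the one-sided p-value (low statistic = clustering) is the
min-rank of the observed value in the pooled {observed} + null set,
p = r / (n_perm + 1) with r = 1 + #{null < observed}, so p is never
zero and a permutation that happens to reproduce the focal group exactly
does not count against it.  Results across a
bootstrap/posterior tree sample are summarized by mean and empirical 95%
interval of the p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import PhyloTree, TipDistances, TreeSample, cophenetic_distances

__all__ = [
    "ClusteringTestResult", "TreeSampleSummary",
    "group_members", "mpd", "mntd",
    "permutation_test", "fdr_correct", "summarize_over_trees",
    "results_table",
]

UNION_SEP = "+"


def group_members(labels: dict[str, str], group) -> list[str]:
    """Cells whose sample label is in ``group``.

    ``group`` is a label, a ``"T1+CTC2"``-style union string, or an
    iterable of labels.
    """
    if isinstance(group, str):
        wanted = set(group.split(UNION_SEP))
    else:
        wanted = set(group)
    return [c for c, s in labels.items() if s in wanted]


def _group_indices(dist: TipDistances, labels, group) -> np.ndarray:
    members = group_members(labels, group)
    if not members:
        raise ValueError(f"group {group!r} has no members among the labels")
    missing = [c for c in members if c not in dist._index]
    if missing:
        raise ValueError(f"group member(s) not on the tree: {missing[:5]}")
    return dist.indices(members)


def mpd(dist: TipDistances, group) -> float:
    """Mean pairwise distance within the group (>= 2 members)."""
    idx = group if isinstance(group, np.ndarray) else dist.indices(list(group))
    if idx.size < 2:
        raise ValueError("MPD needs a group of at least 2 tips")
    sub = dist.matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def mntd(dist: TipDistances, group) -> float:
    """Mean distance to the nearest same-group tip (>= 2 members)."""
    idx = group if isinstance(group, np.ndarray) else dist.indices(list(group))
    if idx.size < 2:
        raise ValueError("MNTD needs a group of at least 2 tips")
    sub = dist.matrix[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


_STATS = {"mpd": mpd, "mntd": mntd}


@dataclass
class ClusteringTestResult:
    group: str
    statistic: str
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    n_members: int
    fdr_significant: bool | None = None


def _null_distribution(dist: TipDistances, member_mask: np.ndarray,
                       statistic: str, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorized null: permute the label vector across all tips."""
    n = member_mask.size
    g = int(member_mask.sum())
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    in_group = member_mask[perms]  # (n_perm, n): membership after permutation
    rows, cols = np.nonzero(in_group)
    idx = cols.reshape(n_perm, g)  # each row has exactly g members
    sub = dist.matrix[idx[:, :, None], idx[:, None, :]]  # (n_perm, g, g)
    if statistic == "mpd":
        iu = np.triu_indices(g, k=1)
        return sub[:, iu[0], iu[1]].mean(axis=1)
    sub[:, np.arange(g), np.arange(g)] = np.inf
    return sub.min(axis=2).mean(axis=1)


def permutation_test(tree: PhyloTree, labels: dict[str, str], group,
                     statistic: str = "mpd", n_perm: int = 999,
                     seed: int | None = None,
                     dist: TipDistances | None = None) -> ClusteringTestResult:
    """One-sided clustering test for a focal group on one tree.

    ``dist`` may pass a precomputed cophenetic matrix for the tree.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if dist is None:
        dist = cophenetic_distances(tree)
    unlabelled = [t for t in dist.labels if t not in labels]
    if unlabelled:
        raise ValueError(f"tips without a label: {unlabelled[:5]}")
    idx = _group_indices(dist, labels, group)
    if idx.size < 2:
        raise ValueError(f"group {group!r} has fewer than 2 members")
    observed = _STATS[statistic](dist, idx)

    member_mask = np.zeros(len(dist.labels), dtype=bool)
    member_mask[idx] = True
    rng = np.random.default_rng(seed)
    null = _null_distribution(dist, member_mask, statistic, n_perm, rng)

    r = 1 + int(np.sum(null < observed))
    p = r / (n_perm + 1)
    name = group if isinstance(group, str) else UNION_SEP.join(sorted(group))
    return ClusteringTestResult(
        group=name, statistic=statistic, observed=float(observed),
        null_values=null, p_value=float(p), n_perm=n_perm, seed=seed,
        n_members=int(idx.size))


def fdr_correct(results: list[ClusteringTestResult],
                alpha: float = 0.05) -> list[ClusteringTestResult]:
    """Benjamini–Hochberg step-up across the supplied family; sets
    ``fdr_significant`` in place and returns the list."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not results:
        return results
    p = np.array([r.p_value for r in results])
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = (np.arange(1, m + 1) / m) * alpha
    passing = p[order] <= thresholds
    k = np.max(np.nonzero(passing)[0]) + 1 if passing.any() else 0
    significant = np.zeros(m, dtype=bool)
    significant[order[:k]] = True
    for r, s in zip(results, significant):
        r.fdr_significant = bool(s)
    return results


@dataclass
class TreeSampleSummary:
    """Mean p and empirical 95% interval per (group, statistic) over a
    tree sample."""

    kind: str
    n_trees: int
    n_perm: int
    rows: list[dict] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def summarize_over_trees(trees: TreeSample, labels: dict[str, str], groups,
                         statistics=("mpd", "mntd"), n_perm: int = 999,
                         seed: int | None = None) -> TreeSampleSummary:
    """Run the permutation test on every tree of the sample and summarize
    p-values with mean and 2.5%/97.5% quantiles.

    Each tree gets an independent permutation stream spawned from the
    master seed.
    """
    if not len(trees):
        raise ValueError("empty tree sample")
    ref = set(trees.trees[0].tip_labels)
    for i, t in enumerate(trees):
        if set(t.tip_labels) != ref:
            raise ValueError(f"tree {i} tip set differs from the first tree")
    child_seeds = np.random.SeedSequence(seed).spawn(len(trees))
    pvals: dict[tuple[str, str], list[float]] = {}
    for t, ss in zip(trees, child_seeds):
        dist = cophenetic_distances(t)
        tree_seed = int(ss.generate_state(1)[0])
        for group in groups:
            for stat in statistics:
                res = permutation_test(t, labels, group, statistic=stat,
                                       n_perm=n_perm, seed=tree_seed, dist=dist)
                pvals.setdefault((res.group, stat), []).append(res.p_value)
    rows = []
    for (group, stat), ps in pvals.items():
        arr = np.array(ps)
        lo, hi = np.quantile(arr, [0.025, 0.975])
        rows.append({
            "group": group, "statistic": stat,
            "mean_p": float(arr.mean()),
            "ci_lower": float(lo), "ci_upper": float(hi),
        })
    return TreeSampleSummary(kind=trees.kind, n_trees=len(trees),
                             n_perm=n_perm, rows=rows)


def results_table(results: list[ClusteringTestResult],
                  data_type: str | None = None) -> pd.DataFrame:
    """Delimited-friendly table: group, n cells, statistic, p, FDR flag."""
    rows = []
    for r in results:
        row = {
            "group": r.group, "n_cells": r.n_members,
            "statistic": r.statistic, "observed": r.observed,
            "p_value": r.p_value, "n_perm": r.n_perm,
            "fdr_significant": r.fdr_significant,
        }
        if data_type is not None:
            row["data_type"] = data_type
        rows.append(row)
    return pd.DataFrame(rows)
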