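"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, path walking, plain
loops) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_hdi(values, mass):
    """Exhaustive minimum-width window over sorted values; ties -> lowest
    lower bound."""
    v = sorted(float(x) for x in values)
    n = len(v)
    k = max(1, math.ceil(mass * n - 1e-9))
    best = None
    for i in range(n - k + 1):
        lo, hi = v[i], v[i + k - 1]
        if best is None or (hi - lo) < best[1] - best[0]:
            best = (lo, hi)
    return best


def brute_cophenetic(tree):
    """All-pairs tip path sums by explicit root-path walking (no LCA
    machinery); takes a dendropy tree with branch lengths."""
    leaves = tree.leaf_nodes()
    paths = {}
    for lf in leaves:
        chain = []
        node, total = lf, 0.0
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            chain.append((node.parent_node, total))
            node = node.parent_node
        paths[lf.taxon.label] = chain
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = {id(a): dist for a, dist in paths[labels[i]]}
            for a, dist_j in paths[labels[j]]:
                if id(a) in anc_i:
                    d[i, j] = d[j, i] = anc_i[id(a)] + dist_j
                    break
    return labels, d


def brute_mpd(d, idx):
    """Mean over all unordered within-group pairs, plain loops."""
    total, count = 0.0, 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            total += d[idx[a], idx[b]]
            count += 1
    return total / count


def brute_mntd(d, idx):
    """Mean of each member's minimum distance to another member."""
    acc = []
    for a in idx:
        acc.append(min(d[a, b] for b in idx if b != a))
    return float(np.mean(acc))


def brute_consensus(counts):
    """Argmax with tie/zero -> None over a 4-tuple of counts."""
    bases = "ACGT"
    mx = max(counts)
    if mx == 0:
        return None
    winners = [b for b, c in zip(bases, counts) if c == mx]
    return winners[0] if len(winners) == 1 else None


def bh_reject(pvalues, alpha):
    """Benjamini-Hochberg step-up via statsmodels (independent route)."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return list(reject)


def random_newick(n_tips, rng, prefix="t"):
    """Random binary topology with exponential branch lengths, as text."""
    nodes = [f"{prefix}{i}:{rng.exponential(1.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(1.0):.6f}")
    return f"{nodes[0][:nodes[0].rindex(':')]};"


def reflecting_walk_stationary():
    """Stationary distribution of the +/-1 jump chain on states 1..5 with
    forced moves at the ends, from the transition matrix eigenvector."""
    P = np.zeros((5, 5))
    P[0, 1] = P[4, 3] = 1.0
    for i in (1, 2, 3):
        P[i, i - 1] = P[i, i + 1] = 0.5
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return pi / pi.sum()
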