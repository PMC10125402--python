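"""Synthetic tree-structured single-cell datasets.

Generates a multi-sample cell phylogeny (monophyletic per-sample clades
on a backbone, with optionally polyphyletic groups grafted as early
seeded singleton lineages), evolves ordinal expression characters
(reflecting +/-1 jump chain on {1..5}) and nucleotide characters
(Jukes-Cantor) along it, and degrades the complete matrices with per-cell
dropout and read-level base counts, so the whole pipeline is testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, OrdinalMatrix, SNVCharacterMatrix, UNKNOWN_BASE
from .snv import BASES
from .trees import PhyloTree, parse_newick

__all__ = [
    "SimulationConfig", "GroundTruth", "SimulatedDataset",
    "simulate_tree", "evolve_ordinal", "evolve_snv",
    "apply_dropout", "generate_base_counts", "expression_from_ordinal",
    "simulate_dataset",
]

#: five-sample design: three tumor clades and two circulating groups,
#: the second circulating group polyphyletic
DEFAULT_SAMPLES = {"T1": 20, "T2": 6, "T3": 20, "CTC1": 6, "CTC2": 6}


@dataclass(frozen=True)
class SimulationConfig:
    samples: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    monophyly: dict[str, bool] | None = None  # default: all but CTC2
    n_genes: int = 300
    n_sites: int = 200
    ordinal_rate: float = 1.0
    nucleotide_rate: float = 1.0
    dropout: tuple | float = ("beta", 0.4, 4.0)
    depth_mean: float = 3.0
    error_rate: float = 0.01
    backbone_depth: float = 1.0
    within_depth: float = 0.1
    seed: int | None = None

    def resolved_monophyly(self) -> dict[str, bool]:
        if self.monophyly is not None:
            mono = dict(self.monophyly)
            for s in self.samples:
                mono.setdefault(s, True)
            return mono
        return {s: (s != "CTC2") for s in self.samples}

    def validate(self) -> None:
        if not self.samples or any(n <= 0 for n in self.samples.values()):
            raise ValueError("sample cell counts must be positive")
        if self.ordinal_rate < 0 or self.nucleotide_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not any(self.resolved_monophyly().values()):
            raise ValueError("at least one monophyletic sample is required")


@dataclass
class GroundTruth:
    tree: PhyloTree
    labels: dict[str, str]
    ordinal: OrdinalMatrix | None = None
    snv: SNVCharacterMatrix | None = None


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children: list[_Node] = []
        self.length = length
        self.label = label

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10g}"


_MIN_EDGE = 1e-6


def _random_coalescent(labels: list[str], depth: float,
                       rng: np.random.Generator) -> _Node:
    """Random ultrametric binary tree: merge heights uniform on (0, depth],
    root forced to ``depth``."""
    if len(labels) == 1:
        return _Node(label=labels[0])
    heights = np.sort(rng.uniform(0.0, depth, len(labels) - 1))
    heights[-1] = depth
    lineages = [(_Node(label=l), 0.0) for l in labels]
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (b, hb) = lineages.pop(j)
        (a, ha) = lineages.pop(i)
        a.length = max(h - ha, _MIN_EDGE)
        b.length = max(h - hb, _MIN_EDGE)
        parent = _Node()
        parent.children = [a, b]
        lineages.append((parent, h))
    return lineages[0][0]


def simulate_tree(config: SimulationConfig,
                  seed: int | None = None) -> tuple[PhyloTree, dict[str, str]]:
    """Backbone tree over monophyletic samples, per-sample clades hanging
    below it, polyphyletic cells grafted at uniform backbone points."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mono = config.resolved_monophyly()
    cell_ids = {s: [f"{s}_{i + 1:03d}" for i in range(n)]
                for s, n in config.samples.items()}
    labels = {c: s for s, cs in cell_ids.items() for c in cs}

    mono_samples = [s for s in config.samples if mono[s]]
    poly_samples = [s for s in config.samples if not mono[s]]

    root = _random_coalescent(mono_samples, config.backbone_depth, rng)
    if not root.children:  # a single monophyletic sample
        wrap = _Node()
        root.length = config.backbone_depth
        wrap.children = [root]
        root = wrap

    # backbone edges available for grafting, weighted by length
    edges: list[tuple[_Node, _Node]] = []

    def collect(parent):
        for ch in parent.children:
            edges.append((parent, ch))
            collect(ch)

    collect(root)

    for s in poly_samples:
        for cell in cell_ids[s]:
            lengths = np.array([c.length for _, c in edges])
            e = int(rng.choice(len(edges), p=lengths / lengths.sum()))
            parent, child = edges[e]
            u = rng.uniform(0.0, child.length)
            mid = _Node(length=max(child.length - u, _MIN_EDGE))
            child.length = max(u, _MIN_EDGE)
            parent.children[parent.children.index(child)] = mid
            mid.children = [child]
            pendant = _Node(label=cell,
                            length=config.within_depth * rng.uniform(0.5, 1.5))
            mid.children.append(pendant)
            edges[e] = (parent, mid)
            edges.append((mid, child))

    # hang per-sample clades below the backbone tips
    def attach(node):
        for i, ch in enumerate(node.children):
            if ch.children:
                attach(ch)
            elif ch.label in mono:
                sub = _random_coalescent(cell_ids[ch.label], config.within_depth, rng)
                sub.length = ch.length
                if not sub.children:  # one-cell sample
                    sub.label = cell_ids[ch.label][0]
                node.children[i] = sub

    attach(root)
    tree = parse_newick(root.newick() + ";")
    return tree, labels


# ---------------------------------------------------------------------------
# Character evolution
# ---------------------------------------------------------------------------

# jump chain on the path graph 1-2-3-4-5 (uniform neighbor choice);
# stationary distribution is proportional to node degree: (1,2,2,2,1)/8
_JUMP = np.zeros((5, 5))
_JUMP[0, 1] = _JUMP[4, 3] = 1.0
for _i in (1, 2, 3):
    _JUMP[_i, _i - 1] = _JUMP[_i, _i + 1] = 0.5

def _jump_transition(expected_jumps: float) -> np.ndarray:
    """Marginal transition matrix after Poisson(expected_jumps) jumps of
    the chain: sum_k Pois(k) P^k = expm(lambda (P - I))."""
    from scipy.linalg import expm

    return expm(expected_jumps * (_JUMP - np.eye(5)))


def _step_categorical(states: np.ndarray, probs_by_state: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    p = probs_by_state[states]
    u = rng.random(states.size)
    return (u[:, None] > p.cumsum(axis=1)).sum(axis=1).astype(np.int64)


def _traverse(tree: PhyloTree, root_states: np.ndarray, step,
              ) -> dict[str, np.ndarray]:
    """Generic preorder simulation; ``step(parent_states, length)`` returns
    child states."""
    t = tree.tree
    states: dict[int, np.ndarray] = {id(t.seed_node): root_states}
    out: dict[str, np.ndarray] = {}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            s = root_states
        else:
            length = node.edge.length or 0.0
            s = step(states[id(node.parent_node)], float(length))
        states[id(node)] = s
        if node.is_leaf():
            out[node.taxon.label] = s
    return out


def evolve_ordinal(tree: PhyloTree, n_genes: int, rate: float,
                   seed: int | None = None) -> OrdinalMatrix:
    """Ordinal characters on {1..5}: root category 3, Poisson(rate x length)
    +/-1 jumps reflecting at the bounds, independent genes.  Branch
    transitions use the exact compound-Poisson marginal."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    cache: dict[float, np.ndarray] = {}

    def step(parent: np.ndarray, length: float) -> np.ndarray:
        lam = rate * length
        if lam == 0:
            return parent.copy()
        if lam not in cache:
            cache[lam] = _jump_transition(lam)
        return _step_categorical(parent, cache[lam], rng)

    tips = _traverse(tree, np.full(n_genes, 2, dtype=np.int64), step)
    cells = sorted(tips)
    values = np.array([tips[c] for c in cells], dtype=float) + 1.0
    genes = [f"g{j + 1:06d}" for j in range(n_genes)]
    return OrdinalMatrix(values=values, cell_ids=cells, feature_ids=genes)


def evolve_snv(tree: PhyloTree, n_sites: int, rate: float,
               seed: int | None = None) -> SNVCharacterMatrix:
    """Jukes-Cantor nucleotide characters from uniform root states.

    ``rate`` is the expected number of substitutions per unit branch
    length, so two tips at path distance d mismatch with probability
    (3/4)(1 - exp(-4 x rate x d / 3))."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, n_sites)

    def step(parent: np.ndarray, length: float) -> np.ndarray:
        p_change = 0.75 * (1.0 - np.exp(-4.0 * rate * length / 3.0))
        child = parent.copy()
        mask = rng.random(n_sites) < p_change
        if mask.any():
            shift = rng.integers(1, 4, size=int(mask.sum()))
            child[mask] = (child[mask] + shift) % 4
        return child
    tips = _traverse(tree, root, step)
    cells = sorted(tips)
    base = np.array(BASES, dtype="<U1")
    values = base[np.array([tips[c] for c in cells])]
    sites = [f"chr1:{100 * (j + 1)}" for j in range(n_sites)]
    return SNVCharacterMatrix(values=values, cell_ids=cells, feature_ids=sites)


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------

def _keep_rates(spec, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, (int, float)):
        spec = ("fixed", float(spec))
    kind = spec[0]
    if kind == "fixed":
        rates = np.full(n_cells, float(spec[1]))
    elif kind == "beta":
        rates = rng.beta(spec[1], spec[2], size=n_cells)
    else:
        raise ValueError(f"unknown keep-rate distribution {spec!r}")
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("keep rates must be in [0, 1]")
    return rates


def apply_dropout(matrix, keep_rate, seed: int | None = None):
    """Per cell, draw a keep rate and retain each entry independently with
    that probability; the rest become unknown.

    Returns (degraded matrix, per-cell keep rates)."""
    rng = np.random.default_rng(seed)
    rates = _keep_rates(keep_rate, matrix.n_cells, rng)
    keep = rng.random(matrix.shape) < rates[:, None]
    if isinstance(matrix, SNVCharacterMatrix):
        values = np.where(keep, matrix.values, UNKNOWN_BASE)
    else:
        values = np.where(keep, matrix.values, np.nan)
    degraded = matrix._replace(values=values)
    return degraded, rates


def _zero_truncated_poisson(mean: float, size: int,
                            rng: np.random.Generator) -> np.ndarray:
    depth = rng.poisson(mean, size)
    zero = depth == 0
    while zero.any():
        depth[zero] = rng.poisson(mean, int(zero.sum()))
        zero = depth == 0
    return depth


def generate_base_counts(snv: SNVCharacterMatrix, depth_mean: float = 3.0,
                         error_rate: float = 0.0,
                         seed: int | None = None) -> pd.DataFrame:
    """Read-level base counts for every known cell x site entry.

    Depth is zero-truncated Poisson; each read reports the true base with
    probability 1 - error_rate, otherwise a uniform other base."""
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    known = snv.known_mask()
    ri, ci = np.nonzero(known)
    m = ri.size
    base_idx = {b: k for k, b in enumerate(BASES)}
    true_idx = np.array([base_idx[b] for b in snv.values[ri, ci]])

    depth = _zero_truncated_poisson(depth_mean, m, rng)
    correct = rng.binomial(depth, 1.0 - error_rate)
    errors = depth - correct
    counts = np.zeros((m, 4), dtype=np.int64)
    counts[np.arange(m), true_idx] = correct
    if errors.any():
        spread = rng.multinomial(errors, [1 / 3] * 3)
        others = np.array([[k for k in range(4) if k != t] for t in true_idx])
        for j in range(3):
            np.add.at(counts, (np.arange(m), others[:, j]), spread[:, j])
    return pd.DataFrame({
        "cell": [snv.cell_ids[i] for i in ri],
        "site": [snv.site_ids[j] for j in ci],
        "A": counts[:, 0], "C": counts[:, 1],
        "G": counts[:, 2], "T": counts[:, 3],
    })


def expression_from_ordinal(ordinal: OrdinalMatrix, seed: int | None = None,
                            noise_sd: float = 0.2,
                            gene_loc_range: tuple[float, float] = (5.0, 10.0),
                            gene_scale_range: tuple[float, float] = (0.5, 2.0),
                            ) -> ExpressionMatrix:
    """Continuous positive expression values whose per-gene standardized
    form reflects the ordinal truth: value = loc_g + scale_g x (category
    + Gaussian noise).  Unknown entries stay unknown."""
    rng = np.random.default_rng(seed)
    loc = rng.uniform(*gene_loc_range, ordinal.n_features)
    scale = rng.uniform(*gene_scale_range, ordinal.n_features)
    noise = rng.normal(0.0, noise_sd, ordinal.shape)
    values = loc + scale * (ordinal.values + noise)
    values[np.isnan(ordinal.values)] = np.nan
    return ExpressionMatrix(values=values, cell_ids=list(ordinal.cell_ids),
                            feature_ids=list(ordinal.feature_ids),
                            sample_of=ordinal.sample_of)


# ---------------------------------------------------------------------------
# One-shot dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: GroundTruth
    expression: ExpressionMatrix       # continuous, dropout as NaN
    ordinal_observed: OrdinalMatrix
    snv_observed: SNVCharacterMatrix
    base_counts: pd.DataFrame
    sites: pd.DataFrame
    keep_rates: np.ndarray


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate tree, characters, dropout and base counts in one pass.

    All randomness derives from ``config.seed`` via spawned child streams,
    so a fixed seed gives bit-identical output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]

    tree, labels = simulate_tree(config, seed=seeds[0])
    ordinal = evolve_ordinal(tree, config.n_genes, config.ordinal_rate, seeds[1])
    ordinal = ordinal._replace(sample_of=labels)
    snv = evolve_snv(tree, config.n_sites, config.nucleotide_rate, seeds[2])
    snv = snv._replace(sample_of=labels)

    ordinal_obs, rates = apply_dropout(ordinal, config.dropout, seeds[3])
    snv_obs, _ = apply_dropout(snv, config.dropout, seeds[4])
    expression = expression_from_ordinal(ordinal_obs, seed=seeds[5])
    base_counts = generate_base_counts(
        snv_obs, config.depth_mean, config.error_rate, seeds[5])

    rng = np.random.default_rng(seeds[5])
    ref_alt = []
    for s in snv.site_ids:
        i = rng.integers(0, 4)
        j = (i + rng.integers(1, 4)) % 4
        ref_alt.append((BASES[i], BASES[j]))
    sites = pd.DataFrame({
        "chrom": [s.split(":")[0] for s in snv.site_ids],
        "pos": [int(s.split(":")[1]) for s in snv.site_ids],
        "ref": [r for r, _ in ref_alt],
        "alt": [a for _, a in ref_alt],
        "site": list(snv.site_ids),
    })
    return SimulatedDataset(
        config=config,
        truth=GroundTruth(tree=tree, labels=labels, ordinal=ordinal, snv=snv),
        expression=expression,
        ordinal_observed=ordinal_obs,
        snv_observed=snv_obs,
        base_counts=base_counts,
        sites=sites,
        keep_rates=rates,
    )
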