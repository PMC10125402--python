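"""Tree I/O, cophenetic distances, and an internal neighbor-joining
builder.

Maximum-likelihood / Bayesian inference is delegated to external engines:
this module writes their inputs (alignment plus a run manifest) and reads
their newick outputs.  The NJ builder is plumbing so the pipeline can be
exercised end-to-end without external software.
"""

from __future__ import annotations

import io as _io
import json
import os
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .matrix import OrdinalMatrix, SNVCharacterMatrix

__all__ = [
    "PhyloTree", "TreeSample", "TipDistances",
    "parse_newick", "write_newick",
    "read_newick_file", "write_newick_file",
    "cophenetic_distances", "nj_tree", "nj_from_distances",
    "write_engine_inputs",
]


@dataclass
class PhyloTree:
    """Thin wrapper around a dendropy tree with unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def branch_lengths(self) -> list[float | None]:
        root = self.tree.seed_node
        return [e.length for e in self.tree.preorder_edge_iter()
                if e.head_node is not root]


@dataclass
class TreeSample:
    """Ordered collection of trees over an identical tip set."""

    trees: list[PhyloTree]
    kind: str = "bootstrap"  # or "posterior"

    def __post_init__(self) -> None:
        if self.kind not in ("bootstrap", "posterior"):
            raise ValueError(f"invalid tree-sample kind {self.kind!r}")
        if self.trees:
            ref = set(self.trees[0].tip_labels)
            for i, t in enumerate(self.trees):
                if set(t.tip_labels) != ref:
                    raise ValueError(f"tree {i} has a different tip set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree; underscores in labels are preserved."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as e:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {e}") from None
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    return tree.tree.as_string(
        schema="newick", unquoted_underscores=True,
        suppress_rooting=True).strip()


def read_newick_file(path, kind: str = "bootstrap") -> TreeSample:
    """Read one or many newick trees (one per line / record)."""
    trees = dendropy.TreeList.get(
        path=os.fspath(path), schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True)
    if not trees:
        raise ValueError(f"no trees in {path}")
    return TreeSample(trees=[PhyloTree(t) for t in trees], kind=kind)


def write_newick_file(trees: TreeSample | list[PhyloTree], path) -> None:
    seq = trees.trees if isinstance(trees, TreeSample) else trees
    with open(path, "w") as fh:
        for t in seq:
            fh.write(write_newick(t) + "\n")


@dataclass
class TipDistances:
    """Cophenetic distance matrix with its tip-label order."""

    labels: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self._index = {l: i for i, l in enumerate(self.labels)}

    def indices(self, cells) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in cells], dtype=int)
        except KeyError as e:
            raise KeyError(f"tip {e.args[0]!r} not on the tree") from None

    def between(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])


def cophenetic_distances(tree: PhyloTree, unit_branches: bool = False) -> TipDistances:
    """Tip-to-tip path-length matrix (symmetric, zero diagonal).

    Missing branch lengths raise unless ``unit_branches`` substitutes 1.
    """
    t = tree.tree
    root = t.seed_node
    for e in t.preorder_edge_iter():
        if e.head_node is root:
            continue
        if e.length is None:
            if unit_branches:
                e.length = 1.0
            else:
                raise ValueError("tree has edges without branch lengths")
    pdm = t.phylogenetic_distance_matrix()
    leaves = t.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            m[i, j] = m[j, i] = d
    return TipDistances(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# Pairwise distances & neighbor joining (internal plumbing)
# ---------------------------------------------------------------------------

def _pairwise_distances(alignment, kind: str) -> tuple[list[str], np.ndarray]:
    if kind == "ordinal":
        if not isinstance(alignment, OrdinalMatrix):
            raise TypeError("ordinal distances need an OrdinalMatrix")
        x = alignment.values
        known = ~np.isnan(x)
        span = 5.0 if alignment.zero_mode == "biological" else 4.0
        diff = lambda a, b: np.abs(a - b) / span
    elif kind == "nucleotide":
        if not isinstance(alignment, SNVCharacterMatrix):
            raise TypeError("nucleotide distances need an SNVCharacterMatrix")
        x = alignment.values
        known = alignment.known_mask()
        diff = lambda a, b: (a != b).astype(float)
    else:
        raise ValueError(f"unknown alignment kind {kind!r}")

    n = x.shape[0]
    d = np.zeros((n, n))
    no_overlap = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = known[i] & known[j]
            if not shared.any():
                d[i, j] = d[j, i] = 1.0
                no_overlap.append((alignment.cell_ids[i], alignment.cell_ids[j]))
                continue
            d[i, j] = d[j, i] = float(np.mean(diff(x[i, shared], x[j, shared])))
    if no_overlap:
        warnings.warn(
            f"{len(no_overlap)} cell pair(s) share no known sites; "
            "their distance was set to 1", stacklevel=3)
    return list(alignment.cell_ids), d


def nj_from_distances(ids: list[str], d: np.ndarray) -> PhyloTree:
    """Neighbor joining on a precomputed distance matrix; negative branch
    lengths are clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    tn = nj(DistanceMatrix(d, ids))
    buf = _io.StringIO()
    tn.write(buf, format="newick")
    tree = parse_newick(buf.getvalue())
    for e in tree.tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            e.length = 0.0
    return tree


def nj_tree(alignment, kind: str) -> PhyloTree:
    """Neighbor-joining tree from pairwise character distances.

    Ordinal distance: mean |a-b| / category span over shared known sites.
    Nucleotide distance: mismatch fraction over shared known sites.
    """
    ids, d = _pairwise_distances(alignment, kind)
    return nj_from_distances(ids, d)


# ---------------------------------------------------------------------------
# External engine interface
# ---------------------------------------------------------------------------

_ML_SETTINGS = {
    "ordinal": {"model": "ORDINAL+ASC", "bootstrap": "-b 100"},
    "nucleotide": {"model": "TEST", "bootstrap": "-b 100"},
}
_BAYES_SETTINGS = {
    "ordinal": {"substitution_model": "ordinal (Morph-Models)",
                "ambiguous_states": "not ignored"},
    "nucleotide": {"substitution_model": "GTR",
                   "ambiguous_states": "not ignored"},
}
# both priors are documented: published settings and the authors'
# correction disagree, so the choice is left to the operator
_TREE_PRIOR_OPTIONS = ["birth-death", "coalescent (exponential growth)"]


def write_engine_inputs(alignment, outdir, engine: str = "ml") -> dict:
    """Write the alignment FASTA plus a JSON run manifest for an external
    inference engine (``ml`` or ``bayesian``)."""
    from . import io as sio

    if engine not in ("ml", "bayesian"):
        raise ValueError(f"unknown engine {engine!r}")
    if alignment.n_cells == 0 or alignment.n_features == 0:
        raise ValueError("empty alignment")
    if isinstance(alignment, OrdinalMatrix):
        kind = "ordinal"
        writer = sio.write_ordinal_fasta
    elif isinstance(alignment, SNVCharacterMatrix):
        kind = "nucleotide"
        writer = sio.write_snv_fasta
    else:
        raise TypeError("alignment must be OrdinalMatrix or SNVCharacterMatrix")

    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "alignment.fasta")
    writer(alignment, fasta)
    manifest = {
        "engine": engine,
        "alignment": os.path.basename(fasta),
        "data_kind": kind,
        "n_sequences": alignment.n_cells,
        "n_characters": alignment.n_features,
    }
    if engine == "ml":
        manifest.update(_ML_SETTINGS[kind])
    else:
        manifest.update(_BAYES_SETTINGS[kind])
        manifest["tree_prior_options"] = _TREE_PRIOR_OPTIONS
        manifest["posterior_sample_size"] = 1000
    path = os.path.join(outdir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
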