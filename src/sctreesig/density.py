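"""Data density reporting and matrix reduction.

Two reduction strategies are provided: a greedy stepwise algorithm that
repeatedly removes the single worst-covered row or column until a target
density (or a local maximum) is reached, and a per-sample selection
strategy that keeps a fixed quota of the best-covered cells from each
sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import LabelledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DensityReport",
    "StepwiseResult",
    "data_density",
    "stepwise_filter",
    "select_cells",
    "qc_filter",
    "drop_uninformative_features",
]


@dataclass(frozen=True)
class DensityReport:
    """Fraction of known entries plus per-cell/per-feature known counts."""

    density: float
    n_cells: int
    n_features: int
    per_cell_known: dict[str, int]
    per_feature_known: dict[str, int]


def data_density(matrix: LabelledMatrix) -> DensityReport:
    """Known entries / (cells x features); 1.0 means no unknowns."""
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise ValueError("cannot compute density of a zero-dimension matrix")
    known = matrix.known_mask()
    per_cell = known.sum(axis=1)
    per_feature = known.sum(axis=0)
    return DensityReport(
        density=float(known.sum()) / known.size,
        n_cells=matrix.n_cells,
        n_features=matrix.n_features,
        per_cell_known={c: int(k) for c, k in zip(matrix.cell_ids, per_cell)},
        per_feature_known={f: int(k) for f, k in zip(matrix.feature_ids, per_feature)},
    )


@dataclass
class StepwiseResult:
    matrix: LabelledMatrix
    trace: list[dict] = field(default_factory=list)
    reached_target: bool = False
    warning: str | None = None

    @property
    def densities(self) -> list[float]:
        return [step["density"] for step in self.trace]


def stepwise_filter(matrix: LabelledMatrix, target_density: float) -> StepwiseResult:
    """Greedy density filtering.

    Each iteration removes the row or column with the lowest fraction of
    known entries (rows win ties, then lexicographic id) provided that
    removal strictly increases overall density; stops at the target
    density, at a local maximum (no single removal increases density), or
    when a dimension would become empty.  The per-step density trace is
    returned for auditing.
    """
    if not (0.0 < target_density <= 1.0):
        raise ValueError("target_density must be in (0, 1]")
    known = matrix.known_mask().astype(np.int64)
    row_alive = np.ones(matrix.n_cells, dtype=bool)
    col_alive = np.ones(matrix.n_features, dtype=bool)
    row_known = known.sum(axis=1)
    col_known = known.sum(axis=0)
    total = int(known.sum())
    trace: list[dict] = []

    # tie-break keys: ids sorted lexicographically within rows / columns
    row_order = np.argsort(np.array(matrix.cell_ids, dtype=object))
    col_order = np.argsort(np.array(matrix.feature_ids, dtype=object))

    def best(order, alive, counts):
        """Index with min known count among alive, first lexicographic id."""
        cand, cbest = -1, None
        for i in order:
            if alive[i] and (cbest is None or counts[i] < cbest):
                cand, cbest = i, counts[i]
        return cand, cbest

    while True:
        R = int(row_alive.sum())
        C = int(col_alive.sum())
        density = total / (R * C)
        if density >= target_density:
            return StepwiseResult(
                matrix=_subset_alive(matrix, row_alive, col_alive),
                trace=trace, reached_target=True)

        ri, rcnt = best(row_order, row_alive, row_known)
        ci, ccnt = best(col_order, col_alive, col_known)
        # compare fractions rcnt/C vs ccnt/R exactly; rows win ties
        take_row = rcnt * R <= ccnt * C

        if take_row:
            # removal increases density iff rcnt/C < density, i.e. rcnt*R < total
            if rcnt * R >= total:
                return _local_max_result(matrix, row_alive, col_alive, trace,
                                         target_density, density)
            if R == 1:
                return _empty_stop(matrix, row_alive, col_alive, trace, density)
            row_alive[ri] = False
            total -= int(rcnt)
            col_known -= known[ri, :]
            removed = ("cell", matrix.cell_ids[ri])
        else:
            if ccnt * C >= total:
                return _local_max_result(matrix, row_alive, col_alive, trace,
                                         target_density, density)
            if C == 1:
                return _empty_stop(matrix, row_alive, col_alive, trace, density)
            col_alive[ci] = False
            total -= int(ccnt)
            row_known -= known[:, ci]
            removed = ("feature", matrix.feature_ids[ci])

        R = int(row_alive.sum())
        C = int(col_alive.sum())
        trace.append({
            "step": len(trace) + 1,
            "removed_kind": removed[0],
            "removed_id": removed[1],
            "density": total / (R * C),
        })


def _subset_alive(matrix, row_alive, col_alive):
    cells = [c for c, a in zip(matrix.cell_ids, row_alive) if a]
    feats = [f for f, a in zip(matrix.feature_ids, col_alive) if a]
    return matrix.subset(cells=cells, features=feats)


def _local_max_result(matrix, row_alive, col_alive, trace, target, density):
    warning = None
    if density < target:
        warning = (f"target density {target} unreachable: stopped at local "
                   f"maximum {density:.4f}")
        logger.warning(warning)
    return StepwiseResult(
        matrix=_subset_alive(matrix, row_alive, col_alive),
        trace=trace, reached_target=density >= target, warning=warning)


def _empty_stop(matrix, row_alive, col_alive, trace, density):
    warning = ("stopped: next removal would empty a dimension "
               f"(density {density:.4f})")
    logger.warning(warning)
    return StepwiseResult(
        matrix=_subset_alive(matrix, row_alive, col_alive),
        trace=trace, reached_target=False, warning=warning)


def select_cells(matrix: LabelledMatrix, quotas: dict[str, int],
                 min_cells_per_feature: int = 2,
                 cells: list[str] | None = None) -> LabelledMatrix:
    """Keep, per sample, the quota cells with the highest known-entry
    counts (ties broken by lexicographically smaller cell id), then drop
    features left uninformative.

    ``cells`` forces an explicit cell set instead of ranking — the
    shared-cell mode used to keep expression and SNV subsets on identical
    cells.  ``min_cells_per_feature=0`` skips the feature-drop step.
    """
    def _finish(reduced):
        if min_cells_per_feature <= 0:
            return reduced
        return drop_uninformative_features(reduced,
                                           min_cells=min_cells_per_feature)[0]

    if cells is not None:
        return _finish(matrix.subset(cells=sorted(cells)))
    if matrix.sample_of is None:
        raise ValueError("select_cells requires sample labels")
    if not any(q > 0 for q in quotas.values()):
        raise ValueError("all quotas are zero")
    by_sample = matrix.samples()
    known = matrix.known_mask().sum(axis=1)
    count_of = dict(zip(matrix.cell_ids, known))
    chosen: list[str] = []
    for sample, quota in quotas.items():
        if sample not in by_sample:
            raise ValueError(f"sample {sample!r} not present in matrix")
        avail = by_sample[sample]
        if quota > len(avail):
            raise ValueError(
                f"quota {quota} exceeds {len(avail)} available cells "
                f"for sample {sample!r}")
        ranked = sorted(avail, key=lambda c: (-count_of[c], c))
        chosen.extend(ranked[:quota])
    return _finish(matrix.subset(cells=sorted(chosen)))


def drop_uninformative_features(matrix: LabelledMatrix,
                                min_cells: int = 2) -> tuple[LabelledMatrix, int]:
    """Drop features known in fewer than ``min_cells`` cells or with fewer
    than two distinct known values.  Generic over matrix kinds."""
    known = matrix.known_mask()
    n_cells_known = known.sum(axis=0)
    keep = n_cells_known >= min_cells
    for j in np.nonzero(keep)[0]:
        col = matrix.values[known[:, j], j]
        if np.unique(col).size < 2:
            keep[j] = False
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all features uninformative: empty matrix")
    kept = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return matrix.subset(features=kept), n_dropped


def qc_filter(matrix: LabelledMatrix, min_features: int = 250,
              min_total: int = 500) -> tuple[LabelledMatrix, dict[str, int]]:
    """Drop cells with fewer than ``min_features`` represented (nonzero,
    known) features or total counts below ``min_total``.

    Operates on raw counts.  Returns the reduced matrix and per-sample
    pass counts; an empty result only warns.
    """
    vals = np.asarray(matrix.values, dtype=float)
    represented = ((vals > 0) & ~np.isnan(vals)).sum(axis=1)
    totals = np.nansum(np.where(np.isnan(vals), 0.0, vals), axis=1)
    keep = (represented >= min_features) & (totals >= min_total)
    kept_cells = [c for c, k in zip(matrix.cell_ids, keep) if k]
    per_sample: dict[str, int] = {}
    if matrix.sample_of is not None:
        for c in matrix.cell_ids:
            per_sample.setdefault(matrix.sample_of[c], 0)
        for c in kept_cells:
            per_sample[matrix.sample_of[c]] += 1
    if not kept_cells:
        warnings.warn("qc_filter removed every cell", stacklevel=2)
        out = matrix.subset(cells=[])
        return out, per_sample
    return matrix.subset(cells=kept_cells), per_sample
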