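"""Expression discretization: standardize per gene, bin by highest-density
intervals into a five-level ordinal scale, and drop uninformative genes.

Raw zeros are either converted to unknown before standardization
(``zero_mode="unknown"``, the default: dropout makes zeros untrustworthy)
or kept as an explicit extra category 0 (``zero_mode="biological"``), in
which case standardization and the HDIs are computed over non-zero values
only so that the zero mass cannot dominate the interval estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix, OrdinalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HdiInterval",
    "center_scale",
    "compute_hdi",
    "discretize",
    "remove_uninformative_genes",
    "discretize_expression",
]


@dataclass(frozen=True)
class HdiInterval:
    """Shortest interval containing at least ``ceil(mass * n)`` of n values."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mass <= 1.0):
            raise ValueError("mass must be in (0, 1]")
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    def contains(self, v) -> np.ndarray:
        return (np.asarray(v) >= self.lower) & (np.asarray(v) <= self.upper)


def compute_hdi(values, mass: float) -> HdiInterval:
    """Highest-density interval of a sample.

    Among all contiguous windows of ``k = ceil(mass * n)`` sorted values,
    returns the narrowest; ties are broken by the lowest lower bound.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("cannot compute HDI of an empty sample")
    if np.isnan(v).any():
        raise ValueError("HDI input contains NaN; exclude unknowns first")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must be in (0, 1]")
    n = v.size
    k = max(1, math.ceil(mass * n - 1e-9))
    widths = v[k - 1:] - v[: n - k + 1]
    i = int(np.argmin(widths))  # first minimum = lowest lower bound
    return HdiInterval(lower=float(v[i]), upper=float(v[i + k - 1]), mass=mass)


def center_scale(matrix: ExpressionMatrix, zero_mode: str = "unknown") -> ExpressionMatrix:
    """Standardize each gene to mean 0, sample variance 1 over known values.

    ``zero_mode="unknown"``: entries equal to 0 become unknown *before*
    the mean/variance are computed.  ``zero_mode="biological"``: zeros are
    flagged in ``zero_mask`` and bypass standardization (they will be
    category 0 downstream).  Genes with fewer than two standardizable
    values or zero variance are dropped and the count is logged.
    """
    if zero_mode not in ("unknown", "biological"):
        raise ValueError(f"invalid zero_mode {zero_mode!r}")
    vals = matrix.values.astype(float, copy=True)
    raw_zero = vals == 0
    if zero_mode == "unknown":
        vals[raw_zero] = np.nan
        zero_mask = None
    else:
        zero_mask = raw_zero & ~np.isnan(vals)
        vals[zero_mask] = np.nan  # excluded from standardization

    known = ~np.isnan(vals)
    n_known = known.sum(axis=0)
    filled = np.where(known, vals, 0.0)
    mean = filled.sum(axis=0) / np.maximum(n_known, 1)
    ss = (np.where(known, vals - mean, 0.0) ** 2).sum(axis=0)
    ok = n_known >= 2
    sd = np.full(vals.shape[1], np.nan)
    sd[ok] = np.sqrt(ss[ok] / (n_known[ok] - 1))

    keep = ok & (sd > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "center_scale: dropped %d gene(s) with <2 known values or zero variance",
            n_dropped,
        )
    if not keep.any():
        raise ValueError("no genes left after dropping unscalable genes")

    scaled = (vals[:, keep] - mean[keep]) / sd[keep]
    zm = zero_mask[:, keep] if zero_mask is not None else None
    return ExpressionMatrix(
        values=scaled,
        cell_ids=list(matrix.cell_ids),
        feature_ids=[g for g, k in zip(matrix.feature_ids, keep) if k],
        sample_of=matrix.sample_of,
        zero_mask=zm,
    )


def discretize(matrix: ExpressionMatrix, hdi60: HdiInterval, hdi90: HdiInterval,
               zero_mode: str = "unknown") -> OrdinalMatrix:
    """Map standardized values to ordinal categories using nested HDIs.

    v < hdi90.lower -> 1; below hdi60 -> 2; inside hdi60 (closed) -> 3;
    above hdi60 -> 4; v > hdi90.upper -> 5.  Unknowns propagate.  In
    biological mode raw-zero entries are category 0 and skip the map.
    """
    if hdi60.lower < hdi90.lower or hdi60.upper > hdi90.upper:
        raise ValueError("inner HDI must be nested within the outer HDI")
    v = matrix.values
    cats = np.select(
        [
            v < hdi90.lower,
            v < hdi60.lower,
            v <= hdi60.upper,
            v <= hdi90.upper,
            v > hdi90.upper,
        ],
        [1.0, 2.0, 3.0, 4.0, 5.0],
        default=np.nan,
    )
    cats[np.isnan(v)] = np.nan
    if zero_mode == "biological":
        if matrix.zero_mask is None:
            raise ValueError(
                "biological zero_mode requires a matrix with zero_mask "
                "(run center_scale with zero_mode='biological')"
            )
        cats[matrix.zero_mask] = 0.0
    return OrdinalMatrix(
        values=cats,
        cell_ids=list(matrix.cell_ids),
        feature_ids=list(matrix.feature_ids),
        sample_of=matrix.sample_of,
        zero_mode=zero_mode,
    )


def remove_uninformative_genes(matrix: OrdinalMatrix,
                               min_cells: int = 2) -> tuple[OrdinalMatrix, int]:
    """Drop genes with fewer than two distinct known categories, or with
    known values in fewer than ``min_cells`` cells.

    Returns (filtered matrix, number of genes dropped).
    """
    known = matrix.known_mask()
    n_cells_known = known.sum(axis=0)
    distinct = np.zeros(matrix.n_features, dtype=int)
    for j in range(matrix.n_features):
        col = matrix.values[known[:, j], j]
        distinct[j] = np.unique(col).size
    keep = (n_cells_known >= min_cells) & (distinct >= 2)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all genes uninformative: empty alignment")
    kept = [g for g, k in zip(matrix.feature_ids, keep) if k]
    return matrix.subset(features=kept), n_dropped


def discretize_expression(matrix: ExpressionMatrix, zero_mode: str = "unknown",
                          masses: tuple[float, float] = (0.6, 0.9),
                          per_gene: bool = False,
                          min_cells: int = 2) -> OrdinalMatrix:
    """Full pipeline: center_scale -> HDIs -> discretize -> drop
    uninformative genes.

    HDIs are computed from the pooled known standardized values by default
    (values are per-gene standardized first, so pooling is scale
    consistent); ``per_gene=True`` computes the two intervals separately
    for every gene.
    """
    inner_mass, outer_mass = sorted(masses)
    scaled = center_scale(matrix, zero_mode=zero_mode)
    if not per_gene:
        pooled = scaled.values[~np.isnan(scaled.values)]
        hdi_inner = compute_hdi(pooled, inner_mass)
        hdi_outer = compute_hdi(pooled, outer_mass)
        if hdi_inner.lower < hdi_outer.lower or hdi_inner.upper > hdi_outer.upper:
            hdi_outer = HdiInterval(min(hdi_inner.lower, hdi_outer.lower),
                                    max(hdi_inner.upper, hdi_outer.upper),
                                    hdi_outer.mass)
        ordinal = discretize(scaled, hdi_inner, hdi_outer, zero_mode=zero_mode)
    else:
        cols = []
        for j in range(scaled.n_features):
            col = scaled.values[:, j]
            known = col[~np.isnan(col)]
            gm = scaled.subset(features=[scaled.feature_ids[j]])
            inner = compute_hdi(known, inner_mass)
            outer = compute_hdi(known, outer_mass)
            # empirical HDIs need not nest; widen the outer interval (its
            # mass can only grow) so the category map stays monotone
            if inner.lower < outer.lower or inner.upper > outer.upper:
                outer = HdiInterval(min(inner.lower, outer.lower),
                                    max(inner.upper, outer.upper), outer.mass)
            cols.append(
                discretize(gm, inner, outer, zero_mode=zero_mode).values[:, 0]
            )
        ordinal = OrdinalMatrix(
            values=np.column_stack(cols),
            cell_ids=list(scaled.cell_ids),
            feature_ids=list(scaled.feature_ids),
            sample_of=scaled.sample_of,
            zero_mode=zero_mode,
        )
    filtered, _ = remove_uninformative_genes(ordinal, min_cells=min_cells)
    return filtered
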