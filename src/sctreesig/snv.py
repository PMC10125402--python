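"""Per-cell SNV character matrices from base counts at pre-called sites.

Variant calling itself happens upstream; this module consumes a
(cell, site) base-count table and a candidate site list and reduces each
cell/site to its strictly most common base.  Ties and zero coverage map
to unknown — no reference bias is introduced.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .matrix import SNVCharacterMatrix, UNKNOWN_BASE

logger = logging.getLogger(__name__)

__all__ = ["BASES", "consensus_base", "build_snv_matrix"]

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["cell", "site", "A", "C", "G", "T"]


def consensus_base(count_a: int, count_c: int, count_g: int, count_t: int) -> str | None:
    """Strictly most common base, or None when coverage is zero or tied."""
    counts = (count_a, count_c, count_g, count_t)
    if any(c < 0 for c in counts):
        raise ValueError("base counts must be non-negative")
    mx = max(counts)
    if mx == 0 or counts.count(mx) > 1:
        return None
    return BASES[counts.index(mx)]


def _consensus_array(counts: np.ndarray) -> np.ndarray:
    """Vectorized consensus over a (..., 4) count array -> '<U1' bases."""
    if (counts < 0).any():
        raise ValueError("base counts must be non-negative")
    mx = counts.max(axis=-1)
    n_at_max = (counts == mx[..., None]).sum(axis=-1)
    best = counts.argmax(axis=-1)
    out = np.array(BASES, dtype="<U1")[best]
    out[(mx == 0) | (n_at_max > 1)] = UNKNOWN_BASE
    return out


def build_snv_matrix(table: pd.DataFrame, sites: list[str],
                     min_cells_per_site: int = 2,
                     drop_empty_cells: bool = False,
                     ) -> tuple[SNVCharacterMatrix, dict]:
    """Consensus matrix over all cells x requested sites.

    Sites known in fewer than ``min_cells_per_site`` cells are dropped.
    Cells with zero known sites are reported in the info dict (and removed
    when ``drop_empty_cells``).  Returns (matrix, info) where info has
    keys ``dropped_sites``, ``empty_cells``.
    """
    if not sites:
        raise ValueError("site list is empty")
    sites = [str(s) for s in sites]
    for col in COUNT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"base-count table lacks column {col!r}")

    cells = sorted(table["cell"].astype(str).unique())
    if not cells:
        warnings.warn("empty base-count table: all sites dropped", stacklevel=2)
        return (
            SNVCharacterMatrix(
                values=np.empty((0, 0), dtype="<U1"), cell_ids=[], feature_ids=[]),
            {"dropped_sites": list(sites), "empty_cells": []},
        )

    cell_pos = {c: i for i, c in enumerate(cells)}
    site_pos = {s: j for j, s in enumerate(sites)}
    counts = np.zeros((len(cells), len(sites), 4), dtype=np.int64)
    tbl = table[table["site"].astype(str).isin(site_pos)]
    ri = tbl["cell"].astype(str).map(cell_pos).to_numpy()
    ci = tbl["site"].astype(str).map(site_pos).to_numpy()
    dup = pd.Series(list(zip(ri, ci))).duplicated()
    if dup.any():
        raise ValueError("duplicate (cell, site) rows in base-count table")
    counts[ri, ci, :] = tbl[list(BASES)].to_numpy(dtype=np.int64)

    values = _consensus_array(counts)
    known = values != UNKNOWN_BASE

    keep_sites = known.sum(axis=0) >= min_cells_per_site
    dropped_sites = [s for s, k in zip(sites, keep_sites) if not k]
    if dropped_sites:
        logger.info("build_snv_matrix: dropped %d low-presence site(s)",
                    len(dropped_sites))
    values = values[:, keep_sites]
    kept_sites = [s for s, k in zip(sites, keep_sites) if k]

    empty = (values != UNKNOWN_BASE).sum(axis=1) == 0 if kept_sites else \
        np.ones(len(cells), dtype=bool)
    empty_cells = [c for c, e in zip(cells, empty) if e]
    if empty_cells:
        logger.info("build_snv_matrix: %d cell(s) without any known site",
                    len(empty_cells))
    if drop_empty_cells and empty_cells:
        keep = ~empty
        values = values[keep]
        cells = [c for c, k in zip(cells, keep) if k]
    if not kept_sites:
        warnings.warn("all sites dropped by the presence filter", stacklevel=2)

    matrix = SNVCharacterMatrix(
        values=values.reshape(len(cells), len(kept_sites)),
        cell_ids=cells, feature_ids=kept_sites)
    return matrix, {"dropped_sites": dropped_sites, "empty_cells": empty_cells}
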