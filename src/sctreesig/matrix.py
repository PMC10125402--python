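"""Labelled cell-by-feature matrices with an explicit unknown state.

All downstream stages (discretization, density filtering, SNV consensus,
tree building) operate on these containers.  Unknown entries are NaN for
numeric matrices and ``'N'`` for nucleotide matrices, and are always
distinguishable from observed zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LabelledMatrix",
    "ExpressionMatrix",
    "OrdinalMatrix",
    "SNVCharacterMatrix",
    "UNKNOWN_BASE",
]

UNKNOWN_BASE = "N"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class LabelledMatrix:
    """Base container: 2-D values with row (cell) and column (feature) ids."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    sample_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features"
            )
        if self.sample_of is not None:
            missing = [c for c in self.cell_ids if c not in self.sample_of]
            if missing:
                raise ValueError(f"cells without a sample label: {missing[:5]}")
            self.sample_of = {c: self.sample_of[c] for c in self.cell_ids}

    # -- unknown handling -------------------------------------------------
    def known_mask(self) -> np.ndarray:
        """Boolean mask of observed (non-unknown) entries."""
        raise NotImplementedError

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- subsetting -------------------------------------------------------
    def _replace(self, **kw) -> "LabelledMatrix":
        args = dict(
            values=self.values,
            cell_ids=self.cell_ids,
            feature_ids=self.feature_ids,
            sample_of=self.sample_of,
        )
        args.update(self._extra_fields())
        args.update(kw)
        return type(self)(**args)

    def _extra_fields(self) -> dict:
        return {}

    def subset(self, cells: Sequence[str] | None = None,
               features: Sequence[str] | None = None) -> "LabelledMatrix":
        """Return a copy restricted to the given cell/feature ids (in the
        given order)."""
        ridx = np.arange(self.n_cells)
        cidx = np.arange(self.n_features)
        cell_ids, feature_ids = self.cell_ids, self.feature_ids
        if cells is not None:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            try:
                ridx = np.array([pos[c] for c in cells], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown cell id {e.args[0]!r}") from None
            cell_ids = [str(c) for c in cells]
        if features is not None:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            try:
                cidx = np.array([pos[f] for f in features], dtype=int)
            except KeyError as e:
                raise KeyError(f"unknown feature id {e.args[0]!r}") from None
            feature_ids = [str(f) for f in features]
        sample_of = None
        if self.sample_of is not None:
            sample_of = {c: self.sample_of[c] for c in cell_ids}
        return self._replace(
            values=self.values[np.ix_(ridx, cidx)].copy(),
            cell_ids=cell_ids,
            feature_ids=feature_ids,
            sample_of=sample_of,
        )

    def samples(self) -> dict[str, list[str]]:
        """Map sample label -> cell ids, preserving matrix cell order."""
        if self.sample_of is None:
            raise ValueError("matrix has no sample labels")
        out: dict[str, list[str]] = {}
        for c in self.cell_ids:
            out.setdefault(self.sample_of[c], []).append(c)
        return out


@dataclass
class ExpressionMatrix(LabelledMatrix):
    """Cells x genes real values; NaN marks unknown.

    ``zero_mask`` (set by ``center_scale`` in biological-zero mode) flags
    entries that were raw zeros: they are observed data (category 0
    downstream) but are excluded from standardization.
    """

    zero_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()
        if self.zero_mask is not None:
            self.zero_mask = np.asarray(self.zero_mask, dtype=bool)
            if self.zero_mask.shape != self.values.shape:
                raise ValueError("zero_mask shape mismatch")

    def _extra_fields(self) -> dict:
        return {"zero_mask": self.zero_mask}

    def subset(self, cells=None, features=None):
        out = super().subset(cells, features)
        if self.zero_mask is not None:
            # subset() copied values only; redo the index math for the mask
            ridx = [self.cell_ids.index(c) for c in out.cell_ids]
            cidx = [self.feature_ids.index(f) for f in out.feature_ids]
            out.zero_mask = self.zero_mask[np.ix_(ridx, cidx)].copy()
        return out

    def known_mask(self) -> np.ndarray:
        known = ~np.isnan(self.values)
        if self.zero_mask is not None:
            known |= self.zero_mask
        return known

    @property
    def gene_ids(self) -> list[str]:
        return self.feature_ids


@dataclass
class OrdinalMatrix(LabelledMatrix):
    """Cells x genes ordinal categories; NaN marks unknown.

    Categories are {1..5} when ``zero_mode == "unknown"`` and {0..5} when
    ``zero_mode == "biological"`` (raw zeros become category 0).
    """

    zero_mode: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        super().__post_init__()
        if self.zero_mode not in ("unknown", "biological"):
            raise ValueError(f"invalid zero_mode {self.zero_mode!r}")
        known = self.values[~np.isnan(self.values)]
        lo = 0 if self.zero_mode == "biological" else 1
        if known.size and (
            (known < lo).any() or (known > 5).any()
            or (known != np.round(known)).any()
        ):
            raise ValueError(
                f"ordinal categories must be integers in [{lo}, 5]"
            )

    def _extra_fields(self) -> dict:
        return {"zero_mode": self.zero_mode}

    def known_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def gene_ids(self) -> list[str]:
        return self.feature_ids

    @property
    def categories(self) -> tuple[int, ...]:
        lo = 0 if self.zero_mode == "biological" else 1
        return tuple(range(lo, 6))


@dataclass
class SNVCharacterMatrix(LabelledMatrix):
    """Cells x sites single-nucleotide characters; 'N' marks unknown."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype="<U1")
        super().__post_init__()
        bad = ~np.isin(self.values, list("ACGT" + UNKNOWN_BASE))
        if bad.any():
            raise ValueError(
                f"invalid base characters: {sorted(set(self.values[bad]))}"
            )

    def known_mask(self) -> np.ndarray:
        return self.values != UNKNOWN_BASE

    @property
    def site_ids(self) -> list[str]:
        return self.feature_ids
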