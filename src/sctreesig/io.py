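"""Readers and writers for the formats the pipeline exchanges.

Alignments travel as FASTA (ordinal categories as digit characters with
'-' for unknown; nucleotides as A/C/G/T with 'N' for unknown), matrices
as MTX triplets or delimited tables, base counts and labels as TSV, and
candidate sites as plain VCF.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix, OrdinalMatrix, SNVCharacterMatrix, UNKNOWN_BASE
from .snv import COUNT_COLUMNS

__all__ = [
    "write_ordinal_fasta", "read_ordinal_fasta",
    "write_snv_fasta", "read_snv_fasta",
    "read_expression_mtx", "write_expression_mtx",
    "read_expression_table", "write_expression_table",
    "read_labels", "write_labels",
    "read_base_counts", "write_base_counts",
    "read_vcf_sites", "write_vcf_sites",
]

ORDINAL_GAP = "-"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _write_fasta(ids, seqs, path) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids in FASTA output")
    records = [SeqRecord(Seq(s), id=str(i), description="") for i, s in zip(ids, seqs)]
    SeqIO.write(records, os.fspath(path), "fasta")


def write_ordinal_fasta(matrix: OrdinalMatrix, path) -> None:
    """One record per cell; categories as digits, unknown as '-'."""
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise ValueError("refusing to write an empty alignment")
    vals = matrix.values
    seqs = []
    for row in vals:
        seqs.append("".join(
            ORDINAL_GAP if np.isnan(v) else str(int(v)) for v in row))
    _write_fasta(matrix.cell_ids, seqs, path)


def read_ordinal_fasta(path, zero_mode: str = "unknown",
                       gene_ids: list[str] | None = None) -> OrdinalMatrix:
    """Inverse of :func:`write_ordinal_fasta`.

    FASTA carries no column names; pass ``gene_ids`` to restore them,
    otherwise synthetic ids g000001.. are assigned.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        ids.append(rec.id)
        s = str(rec.seq)
        rows.append([np.nan if ch == ORDINAL_GAP else float(ch) for ch in s])
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    values = np.asarray(rows, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{j + 1:06d}" for j in range(values.shape[1])]
    return OrdinalMatrix(values=values, cell_ids=ids, feature_ids=gene_ids,
                         zero_mode=zero_mode)


def write_snv_fasta(matrix: SNVCharacterMatrix, path) -> None:
    """One record per cell; A/C/G/T with unknown as 'N'."""
    if matrix.n_cells == 0 or matrix.n_features == 0:
        raise ValueError("refusing to write an empty alignment")
    seqs = ["".join(row) for row in matrix.values]
    _write_fasta(matrix.cell_ids, seqs, path)


def read_snv_fasta(path, site_ids: list[str] | None = None) -> SNVCharacterMatrix:
    ids, rows = [], []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        ids.append(rec.id)
        rows.append(list(str(rec.seq).upper()))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    values = np.asarray(rows, dtype="<U1")
    if site_ids is None:
        site_ids = [f"s{j + 1:06d}" for j in range(values.shape[1])]
    return SNVCharacterMatrix(values=values, cell_ids=ids, feature_ids=site_ids)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_mtx(matrix_path, barcodes_path, features_path,
                        sample_of: dict[str, str] | None = None,
                        zeros_as_missing: bool = True) -> ExpressionMatrix:
    """Read an MTX triplet (features x cells, Cellranger orientation).

    Implicit (absent) entries of the sparse matrix are dropout: they
    become unknown when ``zeros_as_missing`` (the default), or numeric 0
    otherwise.
    """
    m = spio.mmread(os.fspath(matrix_path))
    barcodes = [ln.split("\t")[0].strip() for ln in
                Path(barcodes_path).read_text().splitlines() if ln.strip()]
    features = [ln.split("\t")[0].strip() for ln in
                Path(features_path).read_text().splitlines() if ln.strip()]
    dense = np.asarray(sparse.coo_matrix(m).todense(), dtype=float).T  # cells x genes
    if dense.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"MTX shape {dense.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features")
    if zeros_as_missing:
        dense[dense == 0] = np.nan
    return ExpressionMatrix(values=dense, cell_ids=barcodes, feature_ids=features,
                            sample_of=sample_of)


def write_expression_mtx(matrix: ExpressionMatrix, matrix_path, barcodes_path,
                         features_path) -> None:
    """Write the MTX triplet; unknown entries are left implicit (absent)."""
    vals = np.where(np.isnan(matrix.values), 0.0, matrix.values)
    spio.mmwrite(os.fspath(matrix_path), sparse.coo_matrix(vals.T))
    Path(barcodes_path).write_text("".join(c + "\n" for c in matrix.cell_ids))
    Path(features_path).write_text("".join(f + "\n" for f in matrix.feature_ids))


def read_expression_table(path, sep: str = "\t",
                          sample_of: dict[str, str] | None = None,
                          zeros_as_missing: bool = False) -> ExpressionMatrix:
    """Delimited cells-by-genes table, first column cell id."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy(dtype=float)
    if zeros_as_missing:
        vals[vals == 0] = np.nan
    return ExpressionMatrix(
        values=vals,
        cell_ids=[str(c) for c in df.index],
        feature_ids=[str(g) for g in df.columns],
        sample_of=sample_of,
    )


def write_expression_table(matrix: ExpressionMatrix, path, sep: str = "\t",
                           missing_as_zero: bool = True) -> None:
    vals = matrix.values
    if missing_as_zero:
        vals = np.where(np.isnan(vals), 0.0, vals)
    pd.DataFrame(vals, index=matrix.cell_ids, columns=matrix.feature_ids) \
        .to_csv(path, sep=sep, index_label="cell")


# ---------------------------------------------------------------------------
# Labels, base counts, VCF sites
# ---------------------------------------------------------------------------

def read_labels(path, sep: str = "\t") -> dict[str, str]:
    """Two-column table cell_id -> sample label (header optional)."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label table needs two columns: cell, sample")
    first = df.iloc[0]
    if str(first.iloc[0]).lower() in ("cell", "cell_id", "barcode"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(sample_of: dict[str, str], path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"cell{sep}sample\n")
        for cell, sample in sample_of.items():
            fh.write(f"{cell}{sep}{sample}\n")


def read_base_counts(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"cell": str, "site": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"base-count table lacks columns {missing}")
    return df


def write_base_counts(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_vcf_sites(path) -> pd.DataFrame:
    """CHROM/POS/REF/ALT of every record in a (plain-text) VCF.

    Returns a data frame with a ``site`` id column ``chrom:pos`` in file
    order; only the site list is consumed, genotypes are ignored.
    """
    import pysam

    rows = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            alt = rec.alts[0] if rec.alts else "."
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref or ".", "alt": alt,
                "site": f"{rec.chrom}:{rec.pos}",
            })
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return pd.DataFrame(rows)


def write_vcf_sites(sites: pd.DataFrame, path) -> None:
    """Minimal uncompressed VCF carrying just the candidate site list."""
    chroms = list(dict.fromkeys(sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in chroms:
            length = int(sites.loc[sites["chrom"] == ch, "pos"].max()) + 1000
            fh.write(f"##contig=<ID={ch},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in sites.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t"
                     f"{r['alt']}\t.\tPASS\t.\n")
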