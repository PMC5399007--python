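"""Readers and writers for the external tabular formats.

Everything downstream consumes only in-memory domain types; these functions
are the sole place where file layout knowledge lives. All tables are
tab-delimited text. Interval exports follow 0-based half-open BED
semantics, expressed in gene-order ordinals (flagged in the track header).
"""

from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    GeneOrderTable,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "read_alignment_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_order",
    "write_gene_order",
    "read_gene_lengths",
    "read_aligned_totals",
    "read_groups",
    "write_groups",
    "write_he_blocks_bed",
    "write_he_blocks_tsv",
]

BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_alignment_table(path, dialect: str = "blast6") -> pd.DataFrame:
    """Parse a tabular alignment file into (query, subject, evalue, bitscore).

    ``dialect='blast6'`` is the standard 12-column outfmt-6 layout;
    ``dialect='minimal'`` accepts 4 columns (query, subject, evalue,
    bitscore). Malformed rows raise :class:`FormatError` naming the row.
    All hits are returned; best-hit selection is left to the pairing stage.
    """
    if dialect == "blast6":
        ncol, ev_idx, bs_idx = 12, 10, 11
    elif dialect == "minimal":
        ncol, ev_idx, bs_idx = 4, 2, 3
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")

    queries, subjects, evalues, bitscores = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-delimited toy files
                fields = line.split()
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}: row {lineno}: expected {ncol} columns, "
                    f"got {len(fields)}"
                )
            try:
                ev = float(fields[ev_idx])
                bs = float(fields[bs_idx])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: row {lineno}: non-numeric E-value/bitscore"
                ) from exc
            queries.append(fields[0])
            subjects.append(fields[1])
            evalues.append(ev)
            bitscores.append(bs)
    return pd.DataFrame(
        {"query": queries, "subject": subjects,
         "evalue": evalues, "bitscore": bitscores}
    )


def read_expression_matrix(path, na_policy: str = "error") -> pd.DataFrame:
    """Read a genes x samples TSV matrix (first column gene_id, header row).

    ``na_policy='error'`` (default) rejects missing values; ``'zero'``
    imputes 0. Negative values and duplicate gene rows are always rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric value in matrix") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated gene row {dup!r}")
    if df.isna().any().any():
        if na_policy == "zero":
            df = df.fillna(0.0)
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            col = df.columns[df.isna().any(axis=0)][0]
            raise ValidationError(
                f"{path}: missing value at gene {gene!r}, sample {col!r} "
                "(use na_policy='zero' to impute)"
            )
    arr = df.to_numpy()
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "accession_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_gene_order(path) -> GeneOrderTable:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"gene_id": str, "genome": str, "chromosome": str},
    )
    return GeneOrderTable(df)


def write_gene_order(table: GeneOrderTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    """TSV (gene_id, length) -> Series of positive int lengths in bp."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or "length" not in df.columns:
        raise FormatError(f"{path}: expected columns gene_id, length")
    lengths = pd.Series(df["length"].astype(int).values, index=df["gene_id"])
    if (lengths < 1).any():
        bad = lengths.index[lengths < 1][0]
        raise ValidationError(f"{path}: non-positive length for gene {bad!r}")
    return lengths


def read_aligned_totals(path) -> pd.Series:
    """TSV (sample_id, aligned_reads) -> Series of positive int totals."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "aligned_reads" not in df.columns:
        raise FormatError(f"{path}: expected columns sample_id, aligned_reads")
    totals = pd.Series(df["aligned_reads"].astype(float).values, index=df["sample_id"])
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"{path}: non-positive aligned total for {bad!r}")
    return totals


def write_groups(groups, path) -> None:
    """Homoeologue groups TSV: group_id, one <genome> column per genome,
    ordering_genome, chromosome, ordinal."""
    rows = []
    for g in groups:
        row = {"group_id": g.group_id}
        for genome in g.genomes:
            row[genome] = g.members[genome]
        row.update(
            ordering_genome=g.ordering_genome,
            chromosome=g.chromosome,
            ordinal=g.ordinal,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_groups(path):
    from .types import HomoeologGroup

    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = {"group_id", "ordering_genome", "chromosome", "ordinal"}
    genome_cols = [c for c in df.columns if c not in fixed]
    groups = []
    for _, row in df.iterrows():
        members = {g: row[g] for g in genome_cols if pd.notna(row[g])}
        groups.append(
            HomoeologGroup(
                group_id=row["group_id"],
                members=members,
                ordering_genome=row["ordering_genome"],
                chromosome=row["chromosome"],
                ordinal=int(row["ordinal"]),
            )
        )
    return groups


def _block_sort_key(b):
    return (b.chromosome, b.start_ordinal, b.end_ordinal, b.accession_id)


def write_he_blocks_bed(blocks, path) -> None:
    """Export HE blocks as BED (0-based half-open), sorted by position.

    Coordinates are gene-order ordinals, not base pairs; the track header
    flags this. The name field encodes ``accession|direction``.
    """
    for b in blocks:
        if b.start_ordinal is None or b.end_ordinal is None:
            raise ValidationError(
                f"block for accession {b.accession_id!r} lacks coordinates"
            )
    with open(path, "w") as fh:
        fh.write(
            'track name=he_blocks description="homoeologous exchange blocks" '
            "coordinates=gene_ordinal\n"
        )
        for b in sorted(blocks, key=_block_sort_key):
            name = f"{b.accession_id}|{b.direction.replace(' ', '_')}"
            fh.write(
                f"{b.chromosome}\t{b.start_ordinal}\t{b.end_ordinal}\t"
                f"{name}\t{int(round(1000 * b.support))}\t.\n"
            )


def write_he_blocks_tsv(blocks, path) -> None:
    rows = [
        {
            "accession_id": b.accession_id,
            "chromosome": b.chromosome,
            "start_ordinal": b.start_ordinal,
            "end_ordinal": b.end_ordinal,
            "direction": b.direction,
            "n_genes": b.n_genes,
            "support": b.support,
        }
        for b in sorted(blocks, key=_block_sort_key)
    ]
    cols = ["accession_id", "chromosome", "start_ordinal", "end_ordinal",
            "direction", "n_genes", "support"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
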