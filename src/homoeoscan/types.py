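"""Core domain types shared across the pipeline.

The pipeline works in *gene-order space*: every gene is placed on a
chromosome of its subgenome at a 0-based ordinal rank, and all downstream
coordinates (tile-plot columns, exchange blocks, BED exports) are expressed
in those ordinals. Base-pair coordinates are optional pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HomoeoscanError",
    "FormatError",
    "ValidationError",
    "SampleSheet",
    "GeneOrderTable",
    "HomoeologGroup",
    "ExpressionPanel",
]


class HomoeoscanError(Exception):
    """Base class for all package errors."""


class FormatError(HomoeoscanError):
    """A file could not be parsed; the message names the offending row."""


class ValidationError(HomoeoscanError):
    """Parsed data violate a domain invariant."""


SAMPLE_SHEET_COLUMNS = ["sample_id", "accession_id", "replicate", "assay"]
VALID_ASSAYS = {"mrnaseq", "dnaseq"}


class SampleSheet:
    """Mapping of samples to accessions and replicates.

    Wraps a DataFrame with columns ``sample_id``, ``accession_id``,
    ``replicate`` (positive integer), ``assay`` (``mrnaseq``/``dnaseq``)
    and an optional boolean ``is_control`` column marking in-silico /
    parental control pseudo-samples, which are excluded from panel means
    and low-expression filtering.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if "is_control" not in frame.columns:
            frame["is_control"] = False
        frame["is_control"] = frame["is_control"].astype(bool)
        frame["replicate"] = frame["replicate"].astype(int)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
        if (frame["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        bad = set(frame["assay"]) - VALID_ASSAYS
        if bad:
            raise ValidationError(f"unknown assay values: {sorted(bad)}")
        for acc, sub in frame.groupby("accession_id"):
            if sub["replicate"].duplicated().any():
                raise ValidationError(
                    f"accession {acc!r} has duplicate replicate indices"
                )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def accessions(self) -> list[str]:
        """Non-control accessions, in first-appearance order."""
        sub = self.frame.loc[~self.frame["is_control"]]
        return list(dict.fromkeys(sub["accession_id"]))

    def samples_of(self, accession_id: str) -> list[str]:
        sub = self.frame[self.frame["accession_id"] == accession_id]
        return list(sub["sample_id"])

    @property
    def non_control_samples(self) -> list[str]:
        return list(self.frame.loc[~self.frame["is_control"], "sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        sub = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleSheet(sub)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.frame.equals(other.frame)


class GeneOrderTable:
    """Placement of genes on chromosomes at ordinal positions.

    After loading, ordinals within each (genome, chromosome) are re-ranked
    to a gap-free ``0..n-1`` sequence, preserving the input order.
    """

    COLUMNS = ["gene_id", "genome", "chromosome", "ordinal"]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"gene order table missing columns: {missing}")
        frame["ordinal"] = frame["ordinal"].astype(int)
        if (frame["ordinal"] < 0).any():
            raise ValidationError("ordinals must be non-negative")
        if frame["gene_id"].duplicated().any():
            dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene_id {dup!r} in gene order table")
        key = frame[["genome", "chromosome", "ordinal"]]
        if key.duplicated().any():
            raise ValidationError("(genome, chromosome, ordinal) must be unique")
        # re-rank to gap-free 0..n-1 within each chromosome
        frame = frame.sort_values(["genome", "chromosome", "ordinal"], kind="stable")
        frame["ordinal"] = frame.groupby(["genome", "chromosome"]).cumcount()
        self.frame = frame.reset_index(drop=True)
        self._pos = {
            g: (c, o)
            for g, c, o in zip(frame["gene_id"], frame["chromosome"], frame["ordinal"])
        }

    def position(self, gene_id: str) -> tuple[str, int] | None:
        """(chromosome, ordinal) of a gene, or None if unplaced."""
        return self._pos.get(gene_id)

    def chromosome_length(self, genome: str, chromosome: str) -> int:
        sub = self.frame[
            (self.frame["genome"] == genome) & (self.frame["chromosome"] == chromosome)
        ]
        return len(sub)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._pos

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class HomoeologGroup:
    """A homoeologous pair or triplet: one gene per subgenome.

    ``chromosome``/``ordinal`` locate the member from ``ordering_genome``,
    the genome whose gene order indexes tile-plot columns and blocks.
    """

    group_id: str
    members: dict  # genome -> gene_id (2 or 3 entries)
    ordering_genome: str
    chromosome: str
    ordinal: int

    def __post_init__(self):
        if len(self.members) not in (2, 3):
            raise ValidationError(
                f"group {self.group_id}: needs 2 or 3 members, got {len(self.members)}"
            )
        if self.ordering_genome not in self.members:
            raise ValidationError(
                f"group {self.group_id}: ordering genome {self.ordering_genome!r} "
                "not among members"
            )
        if self.ordinal < 0:
            raise ValidationError(f"group {self.group_id}: negative ordinal")

    @property
    def genomes(self) -> list[str]:
        return sorted(self.members)


def check_no_shared_genes(groups: list[HomoeologGroup]) -> None:
    """Assert the no-gene-in-two-groups invariant over a group list."""
    seen: dict[str, str] = {}
    for g in groups:
        for gene in g.members.values():
            if gene in seen:
                raise ValidationError(
                    f"gene {gene!r} occurs in groups {seen[gene]!r} and {g.group_id!r}"
                )
            seen[gene] = g.group_id


@dataclass
class ExpressionPanel:
    """Genes x samples abundance matrix (RPKM) plus its sample sheet.

    The same container carries transcript abundance (``assay='mrnaseq'``)
    and low-pass genome-coverage redundancy (``assay='dnaseq'``); all
    downstream code is agnostic to the assay except for default filter
    thresholds.
    """

    values: pd.DataFrame  # index gene_id, columns sample_id
    sample_sheet: SampleSheet
    assay: str = "mrnaseq"

    def __post_init__(self):
        if self.assay not in VALID_ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        if list(self.values.columns) != self.sample_sheet.sample_ids:
            raise ValidationError(
                "panel columns do not match the sample sheet sample_ids"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("panel values must be numeric")
        if np.isnan(arr).any():
            raise ValidationError("panel contains missing values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene_ids in panel")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def panel_values(self) -> pd.DataFrame:
        """Values restricted to non-control samples."""
        return self.values[self.sample_sheet.non_control_samples]

    def accession_values(self, accession_id: str) -> pd.DataFrame:
        return self.values[self.sample_sheet.samples_of(accession_id)]
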