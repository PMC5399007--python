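"""HE block segmentation, panel-wide frequency and aneuploidy screening.

Per-accession dosage calls are segmented into contiguous homoeologous-
exchange blocks by run-length smoothing: a block is a maximal run of at
least ``min_run`` genes sharing the same exchange direction, tolerating up
to ``max_gap`` non-concordant genes between consecutive concordant ones.
Blocks never span chromosomes. The panel-wide frequency table counts, per
gene-order position and direction, how many accessions carry a covering
block — the analysis behind the observation that HEs concentrate in
regions whose homoeologous collinearity extends to telomeres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

__all__ = [
    "HEBlock",
    "call_blocks",
    "he_frequency",
    "aneuploidy_screen",
    "direction_bias",
]


@dataclass(frozen=True)
class HEBlock:
    """A maximal run of consecutive groups with a consistent exchange call.

    ``start_ordinal``/``end_ordinal`` span the block 0-based half-open on
    the ordering genome; ``support`` is the fraction of groups in the span
    carrying the block's call.
    """

    accession_id: str
    chromosome: str
    start_ordinal: int
    end_ordinal: int
    direction: str  # e.g. "Exchange A → C"
    n_genes: int
    support: float

    def __post_init__(self):
        if self.end_ordinal <= self.start_ordinal:
            raise ValidationError("block end must exceed start")
        span = self.end_ordinal - self.start_ordinal
        if self.n_genes > span:
            raise ValidationError("n_genes exceeds span length")
        if not (0.0 < self.support <= 1.0):
            raise ValidationError("support must lie in (0, 1]")

    def covers(self, ordinal: int) -> bool:
        return self.start_ordinal <= ordinal < self.end_ordinal


def _is_exchange(category: str) -> bool:
    return category.startswith("Exchange")


def call_blocks(
    calls: pd.DataFrame,
    min_run: int = 10,
    max_gap: int = 2,
) -> list[HEBlock]:
    """Segment per-accession exchange calls into maximal blocks.

    ``calls`` is the classify_panel output; rows must be ordered by
    (chromosome, ordinal) within each accession (unordered input raises).
    Only single-direction exchange categories seed blocks; support counts
    concordant genes over the ordinal span.
    """
    if calls.empty:
        return []
    blocks: list[HEBlock] = []
    for (acc, chrom), sub in calls.groupby(
        ["accession_id", "chromosome"], sort=True
    ):
        ordinals = sub["ordinal"].to_numpy()
        if np.any(np.diff(ordinals) < 0):
            raise ValidationError(
                f"calls for accession {acc!r} chromosome {chrom!r} are not "
                "ordered by ordinal"
            )
        cats = sub["category"].to_numpy()
        for direction in sorted({c for c in cats if _is_exchange(c) and ";" not in c}):
            hits = ordinals[cats == direction]
            if len(hits) == 0:
                continue
            # split concordant positions where more than max_gap
            # non-concordant genes intervene
            run_start = 0
            for i in range(1, len(hits) + 1):
                if i == len(hits) or hits[i] - hits[i - 1] - 1 > max_gap:
                    run = hits[run_start:i]
                    if len(run) >= min_run:
                        start, end = int(run[0]), int(run[-1]) + 1
                        blocks.append(
                            HEBlock(
                                accession_id=acc,
                                chromosome=chrom,
                                start_ordinal=start,
                                end_ordinal=end,
                                direction=direction,
                                n_genes=int(len(run)),
                                support=len(run) / (end - start),
                            )
                        )
                    run_start = i
    return blocks


def he_frequency(
    blocks: list[HEBlock],
    groups,
    panel_accessions: list[str],
) -> pd.DataFrame:
    """Per-position HE frequency across the panel, split by direction.

    One row per (chromosome, ordinal, direction) with the count and
    fraction of accessions whose blocks cover that position, plus a
    ``telomeric`` flag set when a covering block touches either end of its
    chromosome (ordinal extremes proxy for chromosome ends in gene-order
    space).
    """
    n_acc = len(panel_accessions)
    positions = sorted({(g.chromosome, g.ordinal) for g in groups})
    chrom_last = {}
    for chrom, o in positions:
        chrom_last[chrom] = max(chrom_last.get(chrom, 0), o)
    directions = sorted({b.direction for b in blocks})
    counts: dict[tuple, set] = {}
    telo: dict[tuple, bool] = {}
    for b in blocks:
        touches_end = b.start_ordinal == 0 or b.end_ordinal - 1 >= chrom_last.get(
            b.chromosome, np.inf
        )
        for o in range(b.start_ordinal, b.end_ordinal):
            key = (b.chromosome, o, b.direction)
            counts.setdefault(key, set()).add(b.accession_id)
            telo[key] = telo.get(key, False) or touches_end
    rows = []
    for chrom, o in positions:
        for d in directions:
            key = (chrom, o, d)
            n = len(counts.get(key, ()))
            rows.append(
                {
                    "chromosome": chrom,
                    "ordinal": o,
                    "direction": d,
                    "count": n,
                    "fraction": n / n_acc if n_acc else 0.0,
                    "telomeric": telo.get(key, False),
                }
            )
    cols = ["chromosome", "ordinal", "direction", "count", "fraction", "telomeric"]
    return pd.DataFrame(rows, columns=cols)


def direction_bias(blocks: list[HEBlock]) -> pd.Series:
    """Total block-gene counts per exchange direction (e.g. to quantify a
    genome-replacement bias across the panel)."""
    acc: dict[str, int] = {}
    for b in blocks:
        acc[b.direction] = acc.get(b.direction, 0) + b.n_genes
    return pd.Series(acc, dtype=int).sort_index()


def aneuploidy_screen(
    calls: pd.DataFrame,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Flag whole-chromosome gains/losses per (accession, chromosome).

    A chromosome is flagged when at least ``threshold`` of its groups carry
    the same single-genome duplication (gain) or deletion (loss) category.
    """
    rows = []
    if calls.empty:
        return pd.DataFrame(
            columns=["accession_id", "chromosome", "genome", "event", "fraction"]
        )
    genomes = sorted(
        c[: -len("_direction")] for c in calls.columns if c.endswith("_direction")
    )
    for (acc, chrom), sub in calls.groupby(["accession_id", "chromosome"], sort=True):
        n = len(sub)
        for genome in genomes:
            for event, label in (
                ("gain", f"Duplication {genome}"),
                ("loss", f"Deletion {genome}"),
            ):
                frac = float((sub["category"] == label).mean())
                if n > 0 and frac >= threshold:
                    rows.append(
                        {
                            "accession_id": acc,
                            "chromosome": chrom,
                            "genome": genome,
                            "event": event,
                            "fraction": frac,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["accession_id", "chromosome", "genome", "event", "fraction"]
    )
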