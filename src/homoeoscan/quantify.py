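"""RPKM computation, low-abundance filtering and in-silico parental controls.

RPKM (reads per kilobase of gene model per million aligned reads) is the
abundance unit for both transcript quantification and the low-pass DNA
coverage mode:

    rpkm[g, s] = counts[g, s] / (length[g] / 1000) / (aligned_total[s] / 1e6)

Aligned totals are supplied by the caller (they come from the mapper, not
from the count matrix); a sum-of-counts fallback exists behind a flag for
data where the totals were lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionPanel, SampleSheet, ValidationError

__all__ = [
    "compute_rpkm",
    "filter_low_expression",
    "in_silico_combination",
    "default_min_mean_rpkm",
    "FilterReport",
]

#: Default low-abundance thresholds per assay: groups whose member genes
#: fall below the panel-wide mean are removed before classification.
DEFAULT_MIN_MEAN_RPKM = {"mrnaseq": 0.4, "dnaseq": 0.01}


def default_min_mean_rpkm(assay: str) -> float:
    return DEFAULT_MIN_MEAN_RPKM[assay]


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    aligned_totals: pd.Series | None,
    sample_sheet: SampleSheet | None = None,
    assay: str = "mrnaseq",
    totals_from_counts: bool = False,
) -> ExpressionPanel:
    """Normalize a count matrix to RPKM.

    ``aligned_totals`` maps sample_id -> aligned reads; pass
    ``totals_from_counts=True`` to fall back to column sums instead (not
    the definition used here, which is per million *aligned* reads).
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(
            f"genes without length: {list(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    if totals_from_counts:
        aligned_totals = counts.sum(axis=0)
    if aligned_totals is None:
        raise ValidationError("aligned_totals required (or totals_from_counts=True)")
    missing_s = counts.columns.difference(aligned_totals.index)
    if len(missing_s):
        raise ValidationError(f"samples without aligned totals: {list(missing_s)}")
    totals = aligned_totals.reindex(counts.columns).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"zero/negative aligned total for sample {bad!r}")
    kb = lengths.reindex(counts.index).astype(float) / 1000.0
    rpkm = counts.astype(float).div(kb, axis=0).div(totals / 1e6, axis=1)
    if sample_sheet is None:
        sample_sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": counts.columns,
                    "accession_id": counts.columns,
                    "replicate": 1,
                    "assay": assay,
                }
            )
        )
    return ExpressionPanel(values=rpkm, sample_sheet=sample_sheet, assay=assay)


class FilterReport(dict):
    """Counts recorded by filter_low_expression (groups in/out/removed)."""


def filter_low_expression(
    panel: ExpressionPanel,
    groups,
    min_mean_rpkm: float | None = None,
) -> tuple[list, list, FilterReport]:
    """Drop homoeologue groups with low panel-wide abundance.

    The mean RPKM of each member gene is taken across all non-control
    samples of the panel (replicates included); a group is removed if *any*
    member falls below the threshold, so that one-sided pairs cannot fake
    exchanges downstream. Default threshold: 0.4 RPKM for mRNA-seq panels,
    0.01 for DNA-coverage panels.
    """
    if min_mean_rpkm is None:
        min_mean_rpkm = default_min_mean_rpkm(panel.assay)
    means = panel.panel_values().mean(axis=1)
    retained, removed = [], []
    for g in groups:
        member_means = []
        for gene in g.members.values():
            if gene not in means.index:
                member_means.append(0.0)
            else:
                member_means.append(float(means[gene]))
        if all(m >= min_mean_rpkm for m in member_means):
            retained.append(g)
        else:
            removed.append(g)
    report = FilterReport(
        groups_in=len(groups),
        groups_retained=len(retained),
        groups_removed=len(removed),
        min_mean_rpkm=min_mean_rpkm,
    )
    return retained, removed, report


def in_silico_combination(
    parent_panels: list[ExpressionPanel],
    weights=None,
    label: str = "in_silico_combination",
) -> pd.Series:
    """Weighted per-gene mean of parental panels: the synthetic 'perfect
    allopolyploid' control row of the tile plots.

    Each parent contributes its per-gene mean across its own samples;
    weights default to equal. Parents must share the gene universe (after
    homoeologue mapping); mismatches raise an error listing missing genes.
    """
    if not parent_panels:
        raise ValidationError("no parent panels given")
    if weights is None:
        weights = [1.0] * len(parent_panels)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(parent_panels):
        raise ValidationError("weights length != number of parents")
    if (weights < 0).any() or weights.sum() == 0:
        raise ValidationError("weights must be non-negative with positive sum")
    genes = parent_panels[0].gene_ids
    for p in parent_panels[1:]:
        diff = genes.symmetric_difference(p.gene_ids)
        if len(diff):
            raise ValidationError(
                f"parents disagree on gene universe; e.g. {list(diff[:5])}"
            )
    stacked = np.stack(
        [p.values.mean(axis=1).reindex(genes).to_numpy() for p in parent_panels]
    )
    combined = (weights[:, None] * stacked).sum(axis=0) / weights.sum()
    return pd.Series(combined, index=genes, name=label)


def append_control_samples(
    panel: ExpressionPanel, controls: dict[str, pd.Series]
) -> ExpressionPanel:
    """Append labelled control columns (parents, in-silico combination) to a
    panel; controls are flagged in the sample sheet and excluded from panel
    means and filtering."""
    values = panel.values.copy()
    rows = []
    for name, col in controls.items():
        values[name] = col.reindex(values.index)
        rows.append(
            {
                "sample_id": name,
                "accession_id": name,
                "replicate": 1,
                "assay": panel.assay,
                "is_control": True,
            }
        )
    sheet = SampleSheet(pd.concat([panel.sample_sheet.frame, pd.DataFrame(rows)]))
    return ExpressionPanel(values=values, sample_sheet=sheet, assay=panel.assay)
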