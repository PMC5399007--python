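"""Nine-category genome-dosage classification of homoeologue groups.

For every (group, accession, genome) the accession's replicate RPKM values
are compared with the panel mean of that gene by a two-sided one-sample
t-test. The per-genome outcomes (high / null / low at significance alpha,
default 0.01) place each group in one of nine dosage categories:

    A high, C high -> Duplication A and C      A high, C null -> Duplication A
    A null, C high -> Duplication C            A high, C low  -> Exchange C -> A
    A low,  C high -> Exchange A -> C          A low,  C null -> Deletion A
    A low,  C low  -> Deletion A and C         A null, C low  -> Deletion C
    A null, C null -> No difference

"Exchange X -> Y" reads: the X-genome copy was lost and replaced by a
duplicate of the Y-genome copy (X low, Y high). Genome letters generalize
to any pair or triplet of subgenome names.

Zero-variance replicate sets (common when a deleted copy yields all-zero
RPKM) are never dropped: p is 1 when the replicate mean equals the panel
mean exactly, otherwise the case is flagged degenerate with p recorded as 0
and the direction taken from the sign of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionPanel, ValidationError

__all__ = [
    "DirectionCall",
    "direction_test",
    "classify_directions",
    "classify_group",
    "classify_triplet",
    "classify_panel",
    "split_call_tables",
    "EXCHANGE_ARROW",
]

EXCHANGE_ARROW = " → "  # the arrow used in category labels


@dataclass(frozen=True)
class DirectionCall:
    """Outcome of one accession-vs-panel test for one genome copy."""

    genome: str
    direction: str  # "high" | "null" | "low"
    p_value: float
    accession_mean: float
    panel_mean: float
    degenerate: bool = False

    def __post_init__(self):
        if self.direction not in ("high", "null", "low"):
            raise ValidationError(f"bad direction {self.direction!r}")


def direction_test(
    replicate_values,
    panel_mean: float,
    alpha: float = 0.01,
    genome: str = "",
    log_transform: bool = False,
) -> DirectionCall:
    """Two-sided one-sample t-test of replicates against the panel mean.

    Returns high/low when p < alpha by the sign of (replicate mean - panel
    mean), else null. Degenerate cases (n < 2 or zero variance with a
    non-zero mean difference) are flagged, never silently passed.
    """
    x = np.asarray(replicate_values, dtype=float)
    mu = float(panel_mean)
    if log_transform:
        x = np.log2(x + 1.0)
        mu = float(np.log2(panel_mean + 1.0))
    n = x.size
    xbar = float(x.mean()) if n else float("nan")
    # means computed along different reduction paths can differ by float
    # rounding; treat them as tied within relative 1e-9
    same = n > 0 and bool(np.isclose(xbar, mu, rtol=1e-9, atol=1e-12))
    degenerate = False
    if n < 2:
        degenerate = True
        p = 1.0 if (n == 1 and same) else 0.0
    elif float(x.std(ddof=1)) == 0.0:
        if same:
            p = 1.0
        else:
            degenerate = True
            p = 0.0
    else:
        _, p = stats.ttest_1samp(x, mu)
        p = float(p)
    if p < alpha and not same:
        direction = "high" if xbar > mu else "low"
    else:
        direction = "null"
    return DirectionCall(
        genome=genome,
        direction=direction,
        p_value=p,
        accession_mean=float(np.asarray(replicate_values, dtype=float).mean())
        if n
        else float("nan"),
        panel_mean=float(panel_mean),
        degenerate=degenerate,
    )


def classify_directions(directions: dict[str, str]) -> str:
    """Map per-genome directions to a dosage-category label.

    Pure function of the direction vector; for two genomes this is exactly
    the nine-way grid above, and the same rule extends to triplets:
    mixtures of high and low become one exchange label per (loser, gainer)
    pair, pure highs a duplication, pure lows a deletion, all-null
    "No difference".
    """
    for g, d in directions.items():
        if d not in ("high", "null", "low"):
            raise ValidationError(f"bad direction {d!r} for genome {g!r}")
    genomes = sorted(directions)
    highs = [g for g in genomes if directions[g] == "high"]
    lows = [g for g in genomes if directions[g] == "low"]
    if not highs and not lows:
        return "No difference"
    if highs and lows:
        labels = [
            f"Exchange {lo}{EXCHANGE_ARROW}{hi}" for lo in lows for hi in highs
        ]
        return "; ".join(labels)
    if highs:
        return "Duplication " + " and ".join(highs)
    return "Deletion " + " and ".join(lows)


def classify_group(directions) -> str:
    """Dosage category for a two-genome group.

    ``directions``: dict genome -> direction string, or a list of
    :class:`DirectionCall`. Exactly two genomes.
    """
    dirs = _as_direction_dict(directions)
    if len(dirs) != 2:
        raise ValidationError(f"classify_group needs 2 genomes, got {len(dirs)}")
    return classify_directions(dirs)


def classify_triplet(directions) -> str:
    """Extended category for a three-genome group (same convention)."""
    dirs = _as_direction_dict(directions)
    if len(dirs) != 3:
        raise ValidationError(f"classify_triplet needs 3 genomes, got {len(dirs)}")
    return classify_directions(dirs)


def _as_direction_dict(directions) -> dict[str, str]:
    if isinstance(directions, dict):
        return {g: (d.direction if isinstance(d, DirectionCall) else d)
                for g, d in directions.items()}
    return {d.genome: d.direction for d in directions}


def classify_panel(
    panel: ExpressionPanel,
    groups,
    alpha: float = 0.01,
    exclude_self: bool = False,
    log_transform: bool = False,
) -> pd.DataFrame:
    """One dosage call per (group, accession) over the whole panel.

    The panel mean is taken over all non-control samples; by default it
    includes the tested accession's own replicates ("mean of all samples"),
    with ``exclude_self=True`` as the leave-one-accession-out variant. No
    multiple-testing correction is applied (raw p < alpha).

    Returns a tidy frame with one row per (group, accession): group id,
    position, per-genome mean / panel mean / p / direction columns, a
    ``degenerate`` flag, and the category label.
    """
    genomes = groups[0].genomes if groups else []
    for g in groups:
        if g.genomes != genomes:
            raise ValidationError("all groups must share the same genome set")
    sheet = panel.sample_sheet
    accessions = sheet.accessions
    values = panel.values
    # member matrix per genome: n_groups x n_samples
    gene_by_genome = {
        gn: [grp.members[gn] for grp in groups] for gn in genomes
    }
    missing = {
        gene
        for genes in gene_by_genome.values()
        for gene in genes
        if gene not in values.index
    }
    if missing:
        raise ValidationError(
            f"panel lacks member genes, e.g. {sorted(missing)[:5]}"
        )
    panel_cols = sheet.non_control_samples
    n_groups = len(groups)
    records: dict[str, np.ndarray] = {}
    cat_rows = []
    out_frames = []
    for gn in genomes:
        records[gn] = values.loc[gene_by_genome[gn]].to_numpy(dtype=float)
    col_index = {s: i for i, s in enumerate(values.columns)}
    panel_idx = np.array([col_index[s] for s in panel_cols])

    for acc in accessions:
        acc_samples = sheet.samples_of(acc)
        acc_idx = np.array([col_index[s] for s in acc_samples])
        n = len(acc_idx)
        frame = {
            "group_id": [g.group_id for g in groups],
            "accession_id": acc,
            "chromosome": [g.chromosome for g in groups],
            "ordinal": [g.ordinal for g in groups],
        }
        dir_codes = {}
        degen_any = np.zeros(n_groups, dtype=bool)
        for gn in genomes:
            mat = records[gn]
            if log_transform:
                full = np.log2(mat + 1.0)
            else:
                full = mat
            if exclude_self:
                mask = np.ones(full.shape[1], dtype=bool)
                mask[:] = False
                mask[panel_idx] = True
                mask[acc_idx] = False
                pm = full[:, mask].mean(axis=1)
            else:
                pm = full[:, panel_idx].mean(axis=1)
            x = full[:, acc_idx]
            xbar = x.mean(axis=1)
            if n >= 2:
                s = x.std(axis=1, ddof=1)
            else:
                s = np.zeros(n_groups)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (xbar - pm) / (s / np.sqrt(max(n, 1)))
            p = 2.0 * stats.t.sf(np.abs(t), max(n - 1, 1))
            zero_var = (s == 0.0) | (n < 2)
            equal = np.isclose(xbar, pm, rtol=1e-9, atol=1e-12)
            p = np.where(zero_var, np.where(equal, 1.0, 0.0), p)
            degen = zero_var & ~equal
            degen_any |= degen
            sig = (p < alpha) & ~equal
            direction = np.where(sig, np.where(xbar > pm, "high", "low"), "null")
            dir_codes[gn] = direction
            frame[f"{gn}_mean"] = xbar
            frame[f"{gn}_panel_mean"] = pm
            frame[f"{gn}_p"] = p
            frame[f"{gn}_direction"] = direction
        cats = [
            classify_directions({gn: dir_codes[gn][i] for gn in genomes})
            for i in range(n_groups)
        ]
        frame["category"] = cats
        frame["degenerate"] = degen_any
        out_frames.append(pd.DataFrame(frame))
        cat_rows.append(cats)
    if not out_frames:
        return pd.DataFrame()
    calls = pd.concat(out_frames, ignore_index=True)
    return calls


def split_call_tables(calls: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Genome-ordered sub-tables of the calls: over-expressed groups (any
    genome high), under-expressed (any genome low) and exchange calls (one
    genome high with another low)."""
    if calls.empty:
        empty = calls.copy()
        return {"over": empty, "under": empty, "exchange": empty}
    dir_cols = [c for c in calls.columns if c.endswith("_direction")]
    any_high = (calls[dir_cols] == "high").any(axis=1)
    any_low = (calls[dir_cols] == "low").any(axis=1)
    order = ["chromosome", "ordinal", "accession_id"]
    return {
        "over": calls[any_high].sort_values(order, kind="stable"),
        "under": calls[any_low].sort_values(order, kind="stable"),
        "exchange": calls[any_high & any_low].sort_values(order, kind="stable"),
    }
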