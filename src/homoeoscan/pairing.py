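"""Reciprocal-best-hit homoeologue pairing.

Homoeologous pairs are built from two-way alignment tables by the classic
reciprocal-best-hit (RBH) rule: gene ``a`` and gene ``b`` are paired iff
``b`` is ``a``'s best surviving hit in the A->B table and ``a`` is ``b``'s
best surviving hit in the B->A table, after discarding hits weaker than an
E-value threshold (default 1e-30). "Best" means highest bitscore, with ties
broken by lower E-value and then lexicographically smallest subject id, so
the pair set is fully deterministic. Triplets for three-subgenome species
require a consistent triangle across the three pairwise RBH lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import GeneOrderTable, HomoeologGroup, ValidationError, check_no_shared_genes

__all__ = [
    "reciprocal_best_pairs",
    "build_triplets",
    "attach_order",
    "TripletReport",
]

DEFAULT_MAX_EVALUE = 1e-30


def _coerce_hits(hits) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    return pd.DataFrame(hits, columns=["query", "subject", "evalue", "bitscore"])


def best_hits(hits, max_evalue: float = DEFAULT_MAX_EVALUE) -> dict:
    """Map each query to its single best subject under the RBH ranking.

    Multiple HSPs for the same (query, subject) are collapsed to the single
    strongest one (highest bitscore, then lowest E-value) before ranking,
    since RBH is defined on gene pairs, not HSPs.
    """
    df = _coerce_hits(hits)
    if len(df) == 0:
        return {}
    df = df[df["evalue"] <= max_evalue]
    if len(df) == 0:
        return {}
    # collapse HSPs: strongest per (query, subject)
    df = df.sort_values(
        ["query", "subject", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="stable",
    ).drop_duplicates(["query", "subject"], keep="first")
    # rank per query: bitscore desc, evalue asc, subject lexicographic
    df = df.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="stable",
    ).drop_duplicates("query", keep="first")
    return dict(zip(df["query"], df["subject"]))


def reciprocal_best_pairs(
    hits_ab, hits_ba, max_evalue: float = DEFAULT_MAX_EVALUE
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two subgenomes.

    Returns sorted (geneA, geneB) tuples; each gene appears in at most one
    pair (guaranteed by the best-hit maps being single-valued).
    """
    best_ab = best_hits(hits_ab, max_evalue)
    best_ba = best_hits(hits_ba, max_evalue)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)


@dataclass
class TripletReport:
    """Bookkeeping from triplet construction."""

    n_triplets: int
    n_genes_dropped: int
    dropped_genes: list


def build_triplets(
    pairs_ab, pairs_ad, pairs_bd, genomes: tuple[str, str, str] = ("A", "B", "D")
) -> tuple[list[HomoeologGroup], TripletReport]:
    """Assemble three-member groups from three pairwise RBH lists.

    A triplet (a, b, d) is emitted iff (a,b), (a,d) and (b,d) are all
    present — a consistent triangle. Genes participating in inconsistent
    triangles (two edges but not the third) are dropped and reported.
    """
    ga, gb, gd = genomes
    ab = dict(pairs_ab)
    ad = dict(pairs_ad)
    bd = set(map(tuple, pairs_bd))
    triplets: list[HomoeologGroup] = []
    for a in sorted(set(ab) & set(ad)):
        b, d = ab[a], ad[a]
        if (b, d) in bd:
            gid = f"t{len(triplets):05d}"
            triplets.append(
                HomoeologGroup(
                    group_id=gid,
                    members={ga: a, gb: b, gd: d},
                    ordering_genome=ga,
                    chromosome="?",
                    ordinal=0,
                )
            )
    # every gene seen on some edge that did not end up in a triplet
    seen: set[str] = set()
    for a, b in ab.items():
        seen.update((a, b))
    for a, d in ad.items():
        seen.update((a, d))
    for b, d in bd:
        seen.update((b, d))
    kept = {gene for t in triplets for gene in t.members.values()}
    dropped = seen - kept
    report = TripletReport(
        n_triplets=len(triplets),
        n_genes_dropped=len(dropped),
        dropped_genes=sorted(dropped),
    )
    check_no_shared_genes(triplets)
    return triplets, report


def pairs_to_groups(
    pairs: list[tuple[str, str]],
    genomes: tuple[str, str],
    ordering_genome: str,
) -> list[HomoeologGroup]:
    """Wrap RBH pairs as two-member groups (positions attached later)."""
    g1, g2 = genomes
    groups = []
    for i, (a, b) in enumerate(sorted(pairs)):
        groups.append(
            HomoeologGroup(
                group_id=f"p{i:05d}",
                members={g1: a, g2: b},
                ordering_genome=ordering_genome,
                chromosome="?",
                ordinal=0,
            )
        )
    return groups


def attach_order(
    groups: list[HomoeologGroup],
    order_table: GeneOrderTable,
    ordering_genome: str,
) -> tuple[list[HomoeologGroup], list[HomoeologGroup]]:
    """Place groups in genome order by their ordering-genome member.

    Returns ``(ordered, excluded)``: groups whose ordering-genome member is
    absent from the order table are excluded (and should be reported by the
    caller). Ordered groups are sorted by (chromosome, ordinal) and get
    fresh sequential group ids per chromosome run.
    """
    placed, excluded = [], []
    for g in groups:
        if ordering_genome not in g.members:
            raise ValidationError(
                f"group {g.group_id}: ordering genome {ordering_genome!r} "
                "not among member genomes"
            )
        pos = order_table.position(g.members[ordering_genome])
        if pos is None:
            excluded.append(g)
            continue
        chrom, ordinal = pos
        placed.append(
            HomoeologGroup(
                group_id=g.group_id,
                members=dict(g.members),
                ordering_genome=ordering_genome,
                chromosome=chrom,
                ordinal=ordinal,
            )
        )
    placed.sort(key=lambda g: (g.chromosome, g.ordinal))
    check_no_shared_genes(placed)
    return placed, excluded
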