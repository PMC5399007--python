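"""Reciprocal-best-hit pairing against exhaustive-search oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from homoeoscan.pairing import (
    attach_order,
    build_triplets,
    pairs_to_groups,
    reciprocal_best_pairs,
)
from homoeoscan.types import GeneOrderTable, HomoeologGroup, ValidationError


def hits_df(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])


def oracle_best(hits, max_evalue):
    """Independent best-hit map: collapse HSPs, then rank each query's hits
    by (bitscore desc, evalue asc, subject asc), all in pure python."""
    per_pair = {}
    for q, s, ev, bs in hits.itertuples(index=False):
        if ev > max_evalue:
            continue
        key = (q, s)
        if key not in per_pair or (-bs, ev) < (-per_pair[key][0], per_pair[key][1]):
            per_pair[key] = (bs, ev)
    best = {}
    for (q, s), (bs, ev) in per_pair.items():
        cand = (-bs, ev, s)
        if q not in best or cand < best[q][0]:
            best[q] = (cand, s)
    return {q: s for q, (_, s) in best.items()}


def oracle_rbh(hits_ab, hits_ba, max_evalue=1e-30):
    fwd = oracle_best(hits_ab, max_evalue)
    rev = oracle_best(hits_ba, max_evalue)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


class TestReciprocalBestPairs:
    def test_single_mutual_best(self):
        ab = hits_df([("gA1", "gC1", 1e-100, 900)])
        ba = hits_df([("gC1", "gA1", 1e-100, 900)])
        assert reciprocal_best_pairs(ab, ba) == [("gA1", "gC1")]

    def test_reciprocity_violation_gives_nothing(self):
        ab = hits_df([("gA1", "gC1", 1e-100, 900)])
        ba = hits_df(
            [("gC1", "gA2", 1e-120, 950), ("gC1", "gA1", 1e-100, 900)]
        )
        assert reciprocal_best_pairs(ab, ba) == []

    def test_evalue_threshold_discards_hits(self):
        ab = hits_df([("gA1", "gC1", 1e-10, 900)])
        ba = hits_df([("gC1", "gA1", 1e-10, 900)])
        assert reciprocal_best_pairs(ab, ba) == []
        assert reciprocal_best_pairs(ab, ba, max_evalue=1e-5) == [("gA1", "gC1")]

    def test_bitscore_tie_broken_by_evalue_then_subject(self):
        ab = hits_df(
            [
                ("gA1", "gC2", 1e-80, 500),
                ("gA1", "gC1", 1e-90, 500),  # same bitscore, lower E-value
            ]
        )
        ba = hits_df([("gC1", "gA1", 1e-90, 500), ("gC2", "gA1", 1e-80, 500)])
        assert reciprocal_best_pairs(ab, ba) == [("gA1", "gC1")]
        # full tie -> lexicographically smallest subject
        ab2 = hits_df([("gA1", "gC2", 1e-80, 500), ("gA1", "gC1", 1e-80, 500)])
        ba2 = hits_df([("gC1", "gA1", 1e-80, 500), ("gC2", "gA1", 1e-80, 500)])
        assert reciprocal_best_pairs(ab2, ba2) == [("gA1", "gC1")]

    def test_multiple_hsps_collapsed_before_ranking(self):
        # weaker HSP of the true partner must not demote it
        ab = hits_df(
            [
                ("gA1", "gC1", 1e-200, 900),
                ("gA1", "gC1", 1e-5, 50),  # second HSP, weak
                ("gA1", "gC2", 1e-100, 600),
            ]
        )
        ba = hits_df([("gC1", "gA1", 1e-200, 900), ("gC2", "gA1", 1e-100, 600)])
        assert reciprocal_best_pairs(ab, ba) == [("gA1", "gC1")]

    @pytest.mark.parametrize("seed", range(8))
    def test_random_tables_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes_a = [f"a{i}" for i in range(5)]
        genes_c = [f"c{i}" for i in range(5)]
        # random tables with deliberate score ties
        scores = [400.0, 500.0, 500.0, 600.0]
        evs = [1e-40, 1e-60, 1e-60, 1e-80]

        def random_hits(queries, subjects):
            rows = []
            for q in queries:
                for s in subjects:
                    if rng.random() < 0.6:
                        rows.append(
                            (q, s, evs[rng.integers(4)], scores[rng.integers(4)])
                        )
            return hits_df(rows)

        ab = random_hits(genes_a, genes_c)
        ba = random_hits(genes_c, genes_a)
        assert reciprocal_best_pairs(ab, ba) == oracle_rbh(ab, ba)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_of_pair_sets(self, seed):
        rng = np.random.default_rng(100 + seed)
        rows_ab, rows_ba = [], []
        for i in range(6):
            for j in range(6):
                if rng.random() < 0.5:
                    rows_ab.append(
                        (f"a{i}", f"c{j}", 10.0 ** -rng.integers(31, 90),
                         float(rng.integers(100, 999)))
                    )
                if rng.random() < 0.5:
                    rows_ba.append(
                        (f"c{j}", f"a{i}", 10.0 ** -rng.integers(31, 90),
                         float(rng.integers(100, 999)))
                    )
        ab, ba = hits_df(rows_ab), hits_df(rows_ba)
        fwd = set(reciprocal_best_pairs(ab, ba))
        rev = {(b, a) for a, b in reciprocal_best_pairs(ba, ab)}
        assert fwd == rev

    def test_each_gene_in_at_most_one_pair(self):
        rng = np.random.default_rng(42)
        rows_ab, rows_ba = [], []
        for i in range(10):
            for j in range(10):
                if rng.random() < 0.7:
                    ev = 10.0 ** -rng.integers(31, 200)
                    bs = float(rng.integers(100, 2000))
                    rows_ab.append((f"a{i}", f"c{j}", ev, bs))
                    rows_ba.append((f"c{j}", f"a{i}", ev, bs))
        pairs = reciprocal_best_pairs(hits_df(rows_ab), hits_df(rows_ba))
        flat = [g for p in pairs for g in p]
        assert len(flat) == len(set(flat))


def oracle_triangles(pairs_ab, pairs_ad, pairs_bd):
    """Brute-force triangle enumeration over all gene combinations."""
    sab, sad, sbd = set(pairs_ab), set(pairs_ad), set(pairs_bd)
    tris = set()
    for a, b in sab:
        for a2, d in sad:
            if a2 != a:
                continue
            if (b, d) in sbd:
                tris.add((a, b, d))
    return sorted(tris)


class TestTriplets:
    def test_consistent_triangle(self):
        tris, rep = build_triplets([("a1", "b1")], [("a1", "d1")], [("b1", "d1")])
        assert len(tris) == 1
        assert tris[0].members == {"A": "a1", "B": "b1", "D": "d1"}
        assert rep.n_genes_dropped == 0

    def test_incomplete_triangle_drops_genes(self):
        tris, rep = build_triplets([("a1", "b1")], [("a1", "d1")], [])
        assert tris == []
        assert rep.n_genes_dropped == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graph_matches_triangle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        # random partial matchings between the three genomes
        def matching(p1, p2):
            perm = rng.permutation(n)
            return [
                (f"{p1}{i}", f"{p2}{perm[i]}") for i in range(n)
                if rng.random() < 0.7
            ]

        ab, ad, bd = matching("a", "b"), matching("a", "d"), matching("b", "d")
        tris, _ = build_triplets(ab, ad, bd)
        got = sorted((t.members["A"], t.members["B"], t.members["D"]) for t in tris)
        assert got == oracle_triangles(ab, ad, bd)


def order_table(genes_with_pos):
    return GeneOrderTable(
        pd.DataFrame(
            [
                {"gene_id": g, "genome": "C", "chromosome": chrom, "ordinal": o}
                for g, chrom, o in genes_with_pos
            ]
        )
    )


class TestAttachOrder:
    def test_groups_sorted_by_position(self):
        table = order_table([("c1", "C1", 5), ("c2", "C1", 1), ("c3", "C1", 3)])
        groups = pairs_to_groups(
            [("a1", "c1"), ("a2", "c2"), ("a3", "c3")], ("A", "C"), "C"
        )
        ordered, excluded = attach_order(groups, table, "C")
        assert [g.ordinal for g in ordered] == [0, 1, 2]
        assert [g.members["C"] for g in ordered] == ["c2", "c3", "c1"]
        assert excluded == []

    def test_unplaced_member_excluded_and_reported(self):
        table = order_table([("c1", "C1", 0)])
        groups = pairs_to_groups([("a1", "c1"), ("a2", "cX")], ("A", "C"), "C")
        ordered, excluded = attach_order(groups, table, "C")
        assert len(ordered) == 1 and len(excluded) == 1

    def test_missing_ordering_genome_raises(self):
        table = order_table([("c1", "C1", 0)])
        groups = pairs_to_groups([("a1", "c1")], ("A", "C"), "C")
        with pytest.raises(ValidationError, match="ordering genome"):
            attach_order(groups, table, "Z")

    def test_shuffled_fixture_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        entries = [
            (f"c{i}", f"C{1 + i % 3}", i // 3) for i in range(60)
        ]
        table = order_table(entries)
        pairs = [(f"a{i}", f"c{i}") for i in rng.permutation(60)]
        groups = pairs_to_groups(pairs, ("A", "C"), "C")
        ordered, _ = attach_order(groups, table, "C")
        keys = [(g.chromosome, g.ordinal) for g in ordered]
        assert keys == sorted(keys)
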