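"""HE block segmentation against a brute-force scan oracle, frequency and
aneuploidy screening."""

import numpy as np
import pandas as pd
import pytest

from homoeoscan.blocks import (
    HEBlock,
    aneuploidy_screen,
    call_blocks,
    direction_bias,
    he_frequency,
)
from homoeoscan.types import HomoeologGroup, ValidationError

EX_AC = "Exchange A → C"
EX_CA = "Exchange C → A"
NODIFF = "No difference"


def calls_frame(categories, acc="acc1", chrom="C1"):
    return pd.DataFrame(
        {
            "group_id": [f"g{i}" for i in range(len(categories))],
            "accession_id": acc,
            "chromosome": chrom,
            "ordinal": range(len(categories)),
            "category": categories,
        }
    )


def oracle_blocks(categories, min_run, max_gap):
    """Brute-force scan implementing the run definition directly."""
    out = []
    for direction in sorted({c for c in categories if c.startswith("Exchange")}):
        hits = [i for i, c in enumerate(categories) if c == direction]
        runs, current = [], []
        for i in hits:
            if current and i - current[-1] - 1 > max_gap:
                runs.append(current)
                current = []
            current.append(i)
        if current:
            runs.append(current)
        for run in runs:
            if len(run) >= min_run:
                out.append(
                    (direction, run[0], run[-1] + 1, len(run))
                )
    return sorted(out)


class TestCallBlocks:
    def test_pure_run_single_block(self):
        calls = calls_frame([EX_AC] * 15)
        blocks = call_blocks(calls, min_run=10, max_gap=2)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start_ordinal, b.end_ordinal, b.n_genes) == (0, 15, 15)
        assert b.support == 1.0

    def test_single_gap_tolerated_with_support(self):
        cats = [EX_AC] * 8 + [NODIFF] + [EX_AC] * 7
        blocks = call_blocks(calls_frame(cats), min_run=10, max_gap=2)
        assert len(blocks) == 1
        assert blocks[0].n_genes == 15
        assert blocks[0].support == pytest.approx(15 / 16)

    def test_gap_beyond_tolerance_splits(self):
        cats = [EX_AC] * 12 + [NODIFF] * 3 + [EX_AC] * 12
        blocks = call_blocks(calls_frame(cats), min_run=10, max_gap=2)
        assert len(blocks) == 2

    def test_short_runs_dropped(self):
        cats = [EX_AC] * 5 + [NODIFF] * 5 + [EX_CA] * 4
        assert call_blocks(calls_frame(cats), min_run=10, max_gap=2) == []

    def test_blocks_never_span_chromosomes(self):
        part1 = calls_frame([EX_AC] * 8, chrom="C1")
        part2 = calls_frame([EX_AC] * 8, chrom="C2")
        calls = pd.concat([part1, part2], ignore_index=True)
        assert call_blocks(calls, min_run=10, max_gap=2) == []
        assert len(call_blocks(calls, min_run=8, max_gap=2)) == 2

    def test_unordered_input_rejected(self):
        calls = calls_frame([EX_AC] * 12)
        calls["ordinal"] = list(calls["ordinal"])[::-1]
        with pytest.raises(ValidationError, match="ordered"):
            call_blocks(calls)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sequences_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cats = list(
            rng.choice([EX_AC, EX_CA, NODIFF, "Duplication A"], size=120,
                       p=[0.35, 0.15, 0.4, 0.1])
        )
        min_run = int(rng.integers(3, 12))
        max_gap = int(rng.integers(0, 4))
        blocks = call_blocks(calls_frame(cats), min_run=min_run,
                             max_gap=max_gap)
        got = sorted(
            (b.direction, b.start_ordinal, b.end_ordinal, b.n_genes)
            for b in blocks
        )
        assert got == oracle_blocks(cats, min_run, max_gap)

    @pytest.mark.parametrize("seed", range(5))
    def test_blocks_are_maximal(self, seed):
        rng = np.random.default_rng(100 + seed)
        cats = list(rng.choice([EX_AC, NODIFF], size=100, p=[0.5, 0.5]))
        max_gap = 2
        blocks = call_blocks(calls_frame(cats), min_run=3, max_gap=max_gap)
        same = sorted(
            [b for b in blocks if b.direction == EX_AC],
            key=lambda b: b.start_ordinal,
        )
        for b1, b2 in zip(same, same[1:]):
            gap = b2.start_ordinal - b1.end_ordinal
            assert gap > max_gap


def mk_groups(n, chrom="C1"):
    return [
        HomoeologGroup(
            group_id=f"g{i}", members={"A": f"a{i}", "C": f"c{i}"},
            ordering_genome="C", chromosome=chrom, ordinal=i,
        )
        for i in range(n)
    ]


def mk_block(acc, start, end, chrom="C1", direction=EX_AC):
    return HEBlock(
        accession_id=acc, chromosome=chrom, start_ordinal=start,
        end_ordinal=end, direction=direction, n_genes=end - start,
        support=1.0,
    )


class TestHeFrequency:
    def test_single_carrier_fraction(self):
        groups = mk_groups(30)
        accs = [f"acc{i}" for i in range(10)]
        freq = he_frequency([mk_block("acc0", 5, 15)], groups, accs)
        at_p = freq[(freq["ordinal"] == 10) & (freq["direction"] == EX_AC)]
        assert at_p["fraction"].iloc[0] == pytest.approx(0.1)
        outside = freq[(freq["ordinal"] == 20)]
        assert (outside["count"] == 0).all()

    def test_no_blocks_all_zero(self):
        freq = he_frequency([], mk_groups(10), ["a", "b"])
        assert freq.empty or (freq["count"] == 0).all()

    def test_coverage_conservation(self):
        groups = mk_groups(50)
        blocks = [
            mk_block("acc0", 0, 20),
            mk_block("acc1", 10, 30),
            mk_block("acc2", 25, 50, direction=EX_CA),
        ]
        freq = he_frequency(blocks, groups, [f"acc{i}" for i in range(5)])
        assert freq["count"].sum() == sum(b.end_ordinal - b.start_ordinal
                                          for b in blocks)

    def test_terminal_block_flagged_telomeric(self):
        groups = mk_groups(40)
        accs = [f"acc{i}" for i in range(10)]
        blocks = [mk_block(f"acc{i}", 30, 40) for i in range(3)]  # touches end
        freq = he_frequency(blocks, groups, accs)
        covered = freq[(freq["ordinal"] == 35) & (freq["direction"] == EX_AC)]
        assert covered["fraction"].iloc[0] == pytest.approx(0.3)
        assert covered["telomeric"].iloc[0]
        internal = he_frequency([mk_block("acc0", 10, 20)], groups, accs)
        row = internal[(internal["ordinal"] == 15)
                       & (internal["direction"] == EX_AC)]
        assert not row["telomeric"].iloc[0]

    def test_direction_bias_counts_block_genes(self):
        blocks = [mk_block("a", 0, 20), mk_block("b", 0, 10, direction=EX_CA)]
        bias = direction_bias(blocks)
        assert bias[EX_AC] == 20 and bias[EX_CA] == 10


class TestAneuploidyScreen:
    def _calls(self, frac_dup, n=50, label="Duplication A", acc="acc1"):
        n_dup = int(round(frac_dup * n))
        cats = [label] * n_dup + [NODIFF] * (n - n_dup)
        df = calls_frame(cats, acc=acc)
        df["A_direction"] = "null"
        df["C_direction"] = "null"
        return df

    def test_chromosome_wide_duplication_flagged(self):
        flags = aneuploidy_screen(self._calls(0.9))
        assert len(flags) == 1
        row = flags.iloc[0]
        assert (row["genome"], row["event"]) == ("A", "gain")

    def test_scattered_calls_not_flagged(self):
        assert aneuploidy_screen(self._calls(0.1)).empty

    def test_monosomic_chromosome_recovery(self):
        # simulated whole-chromosome loss: recovery across many replicate
        # panels must be essentially certain
        from homoeoscan.dosage import classify_panel
        from homoeoscan.quantify import compute_rpkm
        from homoeoscan.simulate import (
            PlantedEvent, SimulationConfig, simulate_panel,
        )

        hits = 0
        n_sims = 10
        for seed in range(n_sims):
            cfg = SimulationConfig(
                n_chromosomes=1, genes_per_chromosome=40, n_accessions=6,
                replicates=4, seed=200 + seed,
                events=[
                    PlantedEvent("acc03", "C1", (0, 40),
                                 "whole_chromosome_loss", "A"),
                ],
            )
            sim = simulate_panel(cfg)
            panel = compute_rpkm(sim.counts, sim.lengths, sim.aligned_totals,
                                 sample_sheet=sim.sample_sheet)
            calls = classify_panel(panel, sim.groups)
            flags = aneuploidy_screen(calls)
            sub = flags[(flags["accession_id"] == "acc03")
                        & (flags["genome"] == "A")
                        & (flags["event"] == "loss")]
            hits += int(len(sub) == 1)
        assert hits >= int(0.95 * n_sims)
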