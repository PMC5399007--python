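"""Synthetic allopolyploid expression panels with planted genome exchanges.

The generator emulates the data this pipeline consumes: a panel of
accessions of an allopolyploid (two or three subgenomes), each sequenced in
replicate, where every homoeologue group shares one baseline expression
level across its members (balanced 1:1 dosage) and planted events alter
copy number in carrier accessions:

    exchange     loser genome 0x, gainer genome 2x (reciprocal substitution)
    duplication  one genome 2x
    deletion     one genome 0x
    whole-chromosome gain/loss  2x / 0x across an entire chromosome

Read counts are Poisson around ``copy_number x baseline RPKM x gene length
(kb) x library size (millions)`` with multiplicative lognormal replicate
noise; ``count_noise='none'`` produces noiseless expected counts for exact
concordance checks. Defaults model a well-replicated variety panel: 27
accessions x 4 replicates, lognormal baselines (median 30 RPKM, sigma_log
0.7 — well-quantified transcripts of the kind that survive the 0.4-RPKM
filter), 1.5-kb median gene models and 20 M aligned reads per library.

Every output is a plain in-memory domain object or DataFrame in the exact
shape the io module reads/writes, plus a truth table for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dosage import classify_directions
from .types import (
    ExpressionPanel,
    GeneOrderTable,
    HomoeologGroup,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "PlantedEvent",
    "SimulationConfig",
    "SimulatedPanel",
    "simulate_panel",
    "simulate_alignment_tables",
    "make_parental_controls",
    "preset",
    "PRESETS",
]

GENOME_NAMES = {2: ("A", "C"), 3: ("A", "B", "D")}
EVENT_KINDS = {
    "exchange",
    "duplication",
    "deletion",
    "whole_chromosome_gain",
    "whole_chromosome_loss",
}


@dataclass(frozen=True)
class PlantedEvent:
    """A copy-number event carried by one accession.

    ``span`` is a 0-based half-open ordinal interval on the ordering
    genome (ignored for whole-chromosome events). For exchanges ``genome``
    is the losing genome and ``gainer`` the gaining one; for the other
    kinds ``genome`` is the affected genome.
    """

    accession: str
    chromosome: str
    span: tuple[int, int]
    kind: str
    genome: str
    gainer: str | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "exchange" and not self.gainer:
            raise ValidationError("exchange events need a gainer genome")
        if self.span[1] <= self.span[0]:
            raise ValidationError("event span must be non-empty")


@dataclass
class SimulationConfig:
    """Panel-level study conditions; the defaults are the conditions all
    recovery and calibration checks run under."""

    n_genomes: int = 2
    genome_names: tuple = None
    ordering_genome: str = None
    n_chromosomes: int = 2
    genes_per_chromosome: int = 100
    n_accessions: int = 27
    replicates: int = 4
    baseline_log_mean: float = math.log(30.0)  # median 30 RPKM
    baseline_log_sigma: float = 0.7
    noise_cv: float = 0.10
    count_noise: str = "poisson"  # "poisson" | "none"
    library_size: float = 2e7
    gene_length_log_mean: float = math.log(1500.0)  # median 1.5 kb
    gene_length_log_sigma: float = 0.4
    assay: str = "mrnaseq"
    events: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes not in (2, 3):
            raise ValidationError("n_genomes must be 2 or 3")
        if self.genome_names is None:
            self.genome_names = GENOME_NAMES[self.n_genomes]
        self.genome_names = tuple(self.genome_names)
        if len(self.genome_names) != self.n_genomes:
            raise ValidationError("genome_names length != n_genomes")
        if self.ordering_genome is None:
            # B. napus panels are plotted in C-genome order; otherwise the
            # first genome orders the plot.
            self.ordering_genome = (
                "C" if "C" in self.genome_names else self.genome_names[0]
            )
        if self.count_noise not in ("poisson", "none"):
            raise ValidationError("count_noise must be 'poisson' or 'none'")
        if self.replicates < 1 or self.n_accessions < 1:
            raise ValidationError("need at least one accession and replicate")

    @property
    def chromosomes(self) -> list[str]:
        g = self.ordering_genome
        return [f"{g}{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimulatedPanel:
    """Bundle of everything simulate_panel emits."""

    config: SimulationConfig
    groups: list
    order_table: GeneOrderTable
    counts: pd.DataFrame
    lengths: pd.Series
    aligned_totals: pd.Series
    sample_sheet: SampleSheet
    truth: pd.DataFrame
    baselines: pd.Series  # per-group baseline RPKM


def _copy_matrices(config: SimulationConfig, groups) -> dict:
    """genome -> (n_groups x n_accessions) copy-number matrix."""
    n_groups = len(groups)
    accs = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
    acc_idx = {a: i for i, a in enumerate(accs)}
    pos_idx = {}
    for k, g in enumerate(groups):
        pos_idx[(g.chromosome, g.ordinal)] = k
    copies = {
        gn: np.ones((n_groups, config.n_accessions)) for gn in config.genome_names
    }
    touched: dict[tuple, str] = {}
    for ev in config.events:
        if ev.accession not in acc_idx:
            raise ValidationError(f"event accession {ev.accession!r} not in panel")
        ai = acc_idx[ev.accession]
        if ev.kind.startswith("whole_chromosome"):
            span = (0, config.genes_per_chromosome)
        else:
            span = ev.span
        if span[1] > config.genes_per_chromosome:
            raise ValidationError(
                f"event span {span} exceeds chromosome length "
                f"{config.genes_per_chromosome}"
            )
        for o in range(*span):
            key = (ev.accession, ev.chromosome, o)
            if key in touched:
                raise ValidationError(
                    f"overlapping events on {ev.chromosome}:{o} for "
                    f"{ev.accession!r}"
                )
            touched[key] = ev.kind
            k = pos_idx.get((ev.chromosome, o))
            if k is None:
                raise ValidationError(f"no group at {ev.chromosome}:{o}")
            if ev.kind == "exchange":
                copies[ev.genome][k, ai] = 0.0
                copies[ev.gainer][k, ai] = 2.0
            elif ev.kind in ("duplication", "whole_chromosome_gain"):
                copies[ev.genome][k, ai] = 2.0
            elif ev.kind in ("deletion", "whole_chromosome_loss"):
                copies[ev.genome][k, ai] = 0.0
    return dict(copies), accs


def _truth_category(copy_vector: dict[str, float]) -> str:
    directions = {
        gn: ("high" if c > 1 else "low" if c < 1 else "null")
        for gn, c in copy_vector.items()
    }
    return classify_directions(directions)


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate groups, gene order, counts, sample sheet and truth table."""
    rng = np.random.default_rng(config.seed)
    genomes = config.genome_names
    ordering = config.ordering_genome

    # collinear gene order: group k sits at the same ordinal on the
    # homoeologous chromosome of every genome
    groups, order_rows = [], []
    for ci in range(config.n_chromosomes):
        for o in range(config.genes_per_chromosome):
            chrom_order = f"{ordering}{ci + 1}"
            members = {}
            for gn in genomes:
                gene = f"{gn}{ci + 1}g{o:04d}"
                members[gn] = gene
                order_rows.append(
                    {
                        "gene_id": gene,
                        "genome": gn,
                        "chromosome": f"{gn}{ci + 1}",
                        "ordinal": o,
                    }
                )
            groups.append(
                HomoeologGroup(
                    group_id=f"g{ci + 1}_{o:04d}",
                    members=members,
                    ordering_genome=ordering,
                    chromosome=chrom_order,
                    ordinal=o,
                )
            )
    order_table = GeneOrderTable(pd.DataFrame(order_rows))

    n_groups = len(groups)
    baselines = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sigma, n_groups
    )
    gene_ids = [g.members[gn] for g in groups for gn in genomes]
    lengths = np.clip(
        rng.lognormal(
            config.gene_length_log_mean, config.gene_length_log_sigma,
            len(gene_ids),
        ),
        300, 5000,
    ).round().astype(int)
    lengths = pd.Series(lengths, index=gene_ids)

    copies, accs = _copy_matrices(config, groups)
    samples, sheet_rows = [], []
    for acc in accs:
        for r in range(1, config.replicates + 1):
            sid = f"{acc}_r{r}"
            samples.append(sid)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "accession_id": acc,
                    "replicate": r,
                    "assay": config.assay,
                }
            )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    lib = float(config.library_size)
    totals = pd.Series(lib, index=samples)

    sl = math.sqrt(math.log(1.0 + config.noise_cv**2))
    mu_noise = -0.5 * sl * sl
    count_blocks = []
    for gi, gn in enumerate(genomes):
        member_genes = [g.members[gn] for g in groups]
        kb = lengths[member_genes].to_numpy() / 1000.0
        # expected counts per (group, accession): copy x baseline x kb x libM
        lam_acc = copies[gn] * (baselines * kb)[:, None] * (lib / 1e6)
        lam = np.repeat(lam_acc, config.replicates, axis=1)
        if config.noise_cv > 0 and config.count_noise == "poisson":
            lam = lam * rng.lognormal(mu_noise, sl, lam.shape)
        if config.count_noise == "poisson":
            counts = rng.poisson(lam).astype(float)
        else:
            counts = lam  # noiseless expected counts
        count_blocks.append(
            pd.DataFrame(counts, index=member_genes, columns=samples)
        )
    counts = pd.concat(count_blocks)

    truth_rows = []
    for k, g in enumerate(groups):
        for ai, acc in enumerate(accs):
            cv = {gn: float(copies[gn][k, ai]) for gn in genomes}
            row = {
                "group_id": g.group_id,
                "accession_id": acc,
                "chromosome": g.chromosome,
                "ordinal": g.ordinal,
            }
            row.update({f"copy_{gn}": cv[gn] for gn in genomes})
            row["category"] = _truth_category(cv)
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    return SimulatedPanel(
        config=config,
        groups=groups,
        order_table=order_table,
        counts=counts,
        lengths=lengths,
        aligned_totals=totals,
        sample_sheet=sheet,
        truth=truth,
        baselines=pd.Series(baselines, index=[g.group_id for g in groups]),
    )


def simulate_alignment_tables(
    groups,
    decoy_fraction: float = 0.0,
    broken_genes: list[str] | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Reciprocal hit tables whose RBH solution is the true pairing.

    Returns ``(tables, truth)``. ``tables`` maps an ordered genome pair
    (g1, g2) to a minimal-dialect hit DataFrame of g1-queries against
    g2-subjects; both directions are present for every genome pair in the
    groups. True partners get strong hits (E-value <= 1e-40); a
    ``decoy_fraction`` of genes also receive weaker off-target cross-hits;
    genes listed in ``broken_genes`` get their reciprocity broken (their
    return hit points elsewhere), so the corresponding pairs must be absent
    from any correct RBH recovery. ``truth`` maps genome pairs to the
    planted pair sets minus broken ones.
    """
    if not 0.0 <= decoy_fraction < 1.0:
        raise ValidationError("decoy_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    broken = set(broken_genes or [])
    genomes = sorted({gn for g in groups for gn in g.members})
    tables: dict = {}
    truth: dict = {}
    for i, g1 in enumerate(genomes):
        for g2 in genomes[i + 1:]:
            rows_fwd, rows_rev = [], []
            expected = set()
            members = [(g.members[g1], g.members[g2]) for g in groups]
            other_targets = [m[1] for m in members]
            other_queries = [m[0] for m in members]
            for idx, (a, b) in enumerate(members):
                strong_ev = 10.0 ** -float(rng.integers(60, 200))
                strong_bs = float(rng.integers(500, 2000))
                rows_fwd.append((a, b, strong_ev, strong_bs))
                if b in broken and len(members) > 1:
                    # reciprocity break: b's best hit points to a different
                    # A-genome gene with an even stronger score
                    j = (idx + 1) % len(members)
                    rows_rev.append((b, other_queries[j], 1e-220, strong_bs + 500))
                    rows_rev.append((b, a, strong_ev, strong_bs))
                else:
                    rows_rev.append((b, a, strong_ev, strong_bs))
                    expected.add((a, b))
                if rng.random() < decoy_fraction and len(members) > 1:
                    j = int(rng.integers(0, len(members)))
                    if j != idx:
                        # decoys score strictly below every true hit (true
                        # bitscores are >= 500) so they lose any ranking
                        decoy_bs = float(rng.uniform(100.0, 400.0))
                        rows_fwd.append(
                            (a, other_targets[j], 1e-35, decoy_bs)
                        )
                        rows_rev.append(
                            (other_targets[j], a, 1e-35, decoy_bs)
                        )
            cols = ["query", "subject", "evalue", "bitscore"]
            tables[(g1, g2)] = pd.DataFrame(rows_fwd, columns=cols)
            tables[(g2, g1)] = pd.DataFrame(rows_rev, columns=cols)
            truth[(g1, g2)] = expected
    return tables, truth


def make_parental_controls(
    groups, baselines: pd.Series, genomes=None
) -> dict[str, pd.Series]:
    """Parent-species pseudo-samples: each parent expresses only its own
    genome's members (other members 0), at the group baseline RPKM.

    Returns label -> per-gene RPKM Series over all member genes, suitable
    for :func:`homoeoscan.quantify.append_control_samples`.
    """
    if genomes is None:
        genomes = sorted({gn for g in groups for gn in g.members})
    all_genes = [g.members[gn] for g in groups for gn in sorted(g.members)]
    controls = {}
    for parent in genomes:
        vals = pd.Series(0.0, index=pd.Index(all_genes))
        for g in groups:
            vals[g.members[parent]] = float(baselines[g.group_id])
        controls[f"parent_{parent}"] = vals
    return controls


def _napus_panel() -> SimulationConfig:
    """27-accession A/C panel with telomeric exchange blocks, a duplication,
    a deletion and one aneuploid accession."""
    return SimulationConfig(
        n_genomes=2,
        n_chromosomes=2,
        genes_per_chromosome=100,
        n_accessions=27,
        events=[
            PlantedEvent("acc03", "C1", (70, 100), "exchange", "C", gainer="A"),
            PlantedEvent("acc07", "C1", (0, 25), "exchange", "A", gainer="C"),
            PlantedEvent("acc07", "C2", (60, 90), "exchange", "C", gainer="A"),
            PlantedEvent("acc12", "C2", (40, 55), "duplication", "A"),
            PlantedEvent("acc18", "C1", (30, 45), "deletion", "C"),
            PlantedEvent("acc22", "C2", (0, 100), "whole_chromosome_loss", "A"),
        ],
    )


def _juncea_panel() -> SimulationConfig:
    """A/B panel with fewer, smaller, chromosome-internal exchanges."""
    return SimulationConfig(
        n_genomes=2,
        genome_names=("A", "B"),
        ordering_genome="A",
        n_chromosomes=2,
        genes_per_chromosome=100,
        n_accessions=20,
        events=[
            PlantedEvent("acc05", "A1", (40, 55), "exchange", "B", gainer="A"),
            PlantedEvent("acc11", "A2", (30, 42), "exchange", "A", gainer="B"),
        ],
    )


def _wheat_triplet() -> SimulationConfig:
    """Three-genome (A/B/D) panel in the wheat layout."""
    return SimulationConfig(
        n_genomes=3,
        n_chromosomes=1,
        genes_per_chromosome=120,
        n_accessions=12,
        events=[
            PlantedEvent("acc02", "A1", (80, 110), "exchange", "B", gainer="A"),
            PlantedEvent("acc05", "A1", (0, 100), "whole_chromosome_gain", "B"),
        ],
    )


def _dh_population() -> SimulationConfig:
    """Doubled-haploid-style panel with an elevated HE load."""
    events = []
    spans = [(0, 20), (25, 45), (55, 80), (80, 100)]
    for i in range(1, 11):
        lo, hi = spans[i % len(spans)]
        loser = "C" if i % 2 else "A"
        gainer = "A" if loser == "C" else "C"
        events.append(
            PlantedEvent(
                f"acc{i:02d}", f"C{1 + i % 2}", (lo, hi), "exchange",
                loser, gainer=gainer,
            )
        )
    return SimulationConfig(
        n_genomes=2,
        n_chromosomes=2,
        genes_per_chromosome=100,
        n_accessions=16,
        events=events,
    )


PRESETS = {
    "napus_panel": _napus_panel,
    "juncea_panel": _juncea_panel,
    "wheat_triplet": _wheat_triplet,
    "dh_population": _dh_population,
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A named study-condition preset, optionally reseeded/overridden."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[name]()
    return replace(cfg, seed=seed, **overrides)
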