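import numpy as np
import pandas as pd
import pytest

from homoeoscan.simulate import (
    PlantedEvent,
    SimulationConfig,
    simulate_panel,
)
from homoeoscan.quantify import compute_rpkm


@pytest.fixture(scope="session")
def small_balanced_sim():
    """Tiny balanced panel: no planted events, quick to classify."""
    cfg = SimulationConfig(
        n_chromosomes=1,
        genes_per_chromosome=60,
        n_accessions=8,
        replicates=4,
        seed=11,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def planted_sim():
    """Panel with one exchange block, one duplication and one deletion."""
    cfg = SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=80,
        n_accessions=12,
        replicates=4,
        seed=5,
        events=[
            PlantedEvent("acc02", "C1", (10, 40), "exchange", "A", gainer="C"),
            PlantedEvent("acc05", "C2", (20, 35), "duplication", "C"),
            PlantedEvent("acc09", "C1", (50, 66), "deletion", "A"),
        ],
    )
    return simulate_panel(cfg)


@pytest.fixture()
def panel_of(request):
    def build(sim):
        return compute_rpkm(
            sim.counts, sim.lengths, sim.aligned_totals,
            sample_sheet=sim.sample_sheet, assay=sim.config.assay,
        )

    return build


@pytest.fixture(scope="session")
def planted_panel(planted_sim):
    return compute_rpkm(
        planted_sim.counts,
        planted_sim.lengths,
        planted_sim.aligned_totals,
        sample_sheet=planted_sim.sample_sheet,
    )
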