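"""Classify homoeologue groups into the nine genome-dosage categories.

Simulates a 12-accession panel with one planted A-to-C exchange (30
genes), one duplication and one deletion, then t-tests every accession's
replicates against the panel mean (alpha 0.01) and tabulates categories.
"""

from homoeoscan import classify_panel, compute_rpkm, simulate_panel
from homoeoscan.simulate import PlantedEvent, SimulationConfig

cfg = SimulationConfig(
    n_chromosomes=2, genes_per_chromosome=80, n_accessions=12,
    replicates=4, seed=5,
    events=[
        PlantedEvent("acc02", "C1", (10, 40), "exchange", "A", gainer="C"),
        PlantedEvent("acc05", "C2", (20, 35), "duplication", "C"),
        PlantedEvent("acc09", "C1", (50, 66), "deletion", "A"),
    ],
)
sim = simulate_panel(cfg)
panel = compute_rpkm(sim.counts, sim.lengths, sim.aligned_totals,
                     sample_sheet=sim.sample_sheet)
calls = classify_panel(panel, sim.groups, alpha=0.01)

print("category counts over all (group, accession) calls:")
print(calls["category"].value_counts().to_string())

carrier = calls[(calls["accession_id"] == "acc02")
                & (calls["chromosome"] == "C1")
                & calls["ordinal"].between(10, 39)]
print(f"\nplanted exchange span in acc02: "
      f"{(carrier['category'] == 'Exchange A → C').sum()}/30 genes called "
      "'Exchange A → C'")
# 'Exchange A → C' means the A copy was lost and replaced by a duplicate
# C copy: A replicates test low, C replicates test high vs the panel mean.
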