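"""Pair homoeologues across subgenomes by reciprocal best hits.

Builds synthetic two-way alignment tables for 120 true homoeologue pairs
(with 30% decoy cross-hits and two deliberately broken genes), then runs
the RBH procedure at the standard E-value threshold of 1e-30.
"""

from homoeoscan import reciprocal_best_pairs, simulate_panel
from homoeoscan.simulate import SimulationConfig, simulate_alignment_tables

sim = simulate_panel(
    SimulationConfig(n_chromosomes=2, genes_per_chromosome=60,
                     n_accessions=2, replicates=2, seed=0)
)
broken = [sim.groups[5].members["C"], sim.groups[40].members["C"]]
tables, truth = simulate_alignment_tables(
    sim.groups, decoy_fraction=0.3, broken_genes=broken, seed=1
)

pairs = reciprocal_best_pairs(tables[("A", "C")], tables[("C", "A")],
                              max_evalue=1e-30)
expected = truth[("A", "C")]

print(f"true pairs planted:    {len(sim.groups)}")
print(f"reciprocity broken:    {len(broken)}")
print(f"pairs recovered:       {len(pairs)}")
print(f"exactly the truth set: {set(pairs) == expected}")
# Every recoverable pair (118 of 120) is found despite decoys; the two
# broken genes cannot form reciprocal best hits and are correctly absent.
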