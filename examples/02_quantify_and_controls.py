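"""RPKM normalization, the low-abundance filter and in-silico controls.

Normalizes a simulated count matrix to reads per kilobase per million
aligned reads, applies the 0.4-RPKM panel-mean filter, and builds the
parental-combination control column used on tile plots.
"""

import pandas as pd

from homoeoscan import (
    ExpressionPanel,
    compute_rpkm,
    filter_low_expression,
    in_silico_combination,
)
from homoeoscan.simulate import SimulationConfig, make_parental_controls, simulate_panel
from homoeoscan.types import SampleSheet

sim = simulate_panel(
    SimulationConfig(n_chromosomes=1, genes_per_chromosome=80,
                     n_accessions=6, replicates=4, seed=2,
                     baseline_log_mean=0.0, baseline_log_sigma=1.5)
)
panel = compute_rpkm(sim.counts, sim.lengths, sim.aligned_totals,
                     sample_sheet=sim.sample_sheet)
kept, removed, report = filter_low_expression(panel, sim.groups)
print(f"groups in: {report['groups_in']}  kept: {report['groups_retained']}  "
      f"removed below {report['min_mean_rpkm']} RPKM: "
      f"{report['groups_removed']}")

# parent pseudo-samples and their in-silico combination
controls = make_parental_controls(sim.groups, sim.baselines)


def as_panel(name, series):
    sheet = SampleSheet(pd.DataFrame(
        {"sample_id": [name], "accession_id": [name],
         "replicate": [1], "assay": ["mrnaseq"]}
    ))
    return ExpressionPanel(values=series.to_frame(name), sample_sheet=sheet)


combo = in_silico_combination(
    [as_panel("parent_A", controls["parent_A"]),
     as_panel("parent_C", controls["parent_C"])]
)
g = sim.groups[0]
print(f"group {g.group_id}: parent_A expresses A copy at "
      f"{controls['parent_A'][g.members['A']]:.2f} RPKM, C copy at "
      f"{controls['parent_A'][g.members['C']]:.2f}")
print(f"in-silico combination: A {combo[g.members['A']]:.2f}, "
      f"C {combo[g.members['C']]:.2f}")
# The combination halves each parental value: a perfectly balanced
# synthetic allopolyploid that renders blue on the tile plot.
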