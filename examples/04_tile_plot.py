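"""Render a Transcriptome Display Tile Plot (TDTP).

Simulates the 27-accession panel preset (telomeric exchanges, a
duplication, a deletion, one aneuploid accession), adds parental and
in-silico-combination control rows, and renders the CMYK-encoded tile plot
to PNG and SVG.
"""

from pathlib import Path

from homoeoscan import (
    append_control_samples,
    cmyk_to_rgb,
    compute_rpkm,
    encode_cmyk,
    normalize_abundance,
    render_tdtp,
    simulate_panel,
)
from homoeoscan.simulate import make_parental_controls, preset

sim = simulate_panel(preset("napus_panel", seed=0))
panel = compute_rpkm(sim.counts, sim.lengths, sim.aligned_totals,
                     sample_sheet=sim.sample_sheet)
controls = make_parental_controls(sim.groups, sim.baselines)
controls["combination"] = (controls["parent_A"] + controls["parent_C"]) / 2
panel = append_control_samples(panel, controls)

norm = normalize_abundance(panel, sim.groups)
spec = encode_cmyk(norm, sim.groups, row_order=panel.sample_sheet.sample_ids)

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)
render_tdtp(spec, out / "tdtp.png", tile_size=(3, 3))
render_tdtp(spec, out / "tdtp.svg", tile_size=(3, 3))
print(f"wrote {out / 'tdtp.png'} and .svg "
      f"({len(spec.row_labels)} rows x {len(spec.groups)} columns)")

row = spec.row_labels.index("acc03_r1")
col = next(j for j, g in enumerate(spec.groups)
           if g.chromosome == "C1" and g.ordinal == 85)
r, g, b = cmyk_to_rgb(*spec.cmyk(row, col))
print(f"tile acc03 x C1:85 (inside planted C->A exchange): "
      f"RGB ({r:.2f}, {g:.2f}, {b:.2f})")
# Cyan (low red only) marks A-genome-only signal: the C copy is gone and
# the A copy doubled. Balanced regions render blue; parent rows render
# pure cyan / magenta; the combination row renders blue.
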