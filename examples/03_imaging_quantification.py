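"""Quantify a segmented-cell imaging table into proportions and cell sizes.

Simulates a 30,000-cell tissue section as an image-analysis export (one row
per segmented cell with phenotype, nuclear area, and total-RNA puncta
count), removes oversized segmentation artefacts (nuclear radius > 5 um),
and computes per-section cell-type proportions and the three per-type size
metrics.  Proportions should track the known composition; neurons should
show larger areas and more puncta than glia.
"""

import deconvbench as db

composition = {"Excit": 0.23, "Inhib": 0.11, "Astro": 0.09,
               "EndoMural": 0.04, "Micro": 0.03, "OligoOPC": 0.12,
               "other": 0.38}
cells = db.simulate_cells_table(composition, n_cells=30000, seed=4,
                                oversize_fraction=0.01)
cells, n_removed = db.radius_filter(cells, max_radius=5.0)
print(f"removed {n_removed} oversized cells "
      f"({n_removed / 30000:.1%} of segmented cells)")

props = db.section_proportions(cells)
print("\nsection proportions (true value in parentheses):")
for ct, p in composition.items():
    print(f"  {ct:10s} {props.values.loc['S1', ct]:.3f}  ({p:.2f})")

sizes = db.cell_size_metrics(cells)
print("\nper-type size metrics (median area um^2, puncta, area x puncta):")
for ct in sorted(sizes["area"]):
    print(f"  {ct:10s} {sizes['area'][ct]:6.1f}  {sizes['puncta'][ct]:5.1f}  "
          f"{sizes['area_x_puncta'][ct]:7.1f}")
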