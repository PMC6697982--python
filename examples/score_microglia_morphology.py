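"""Simulate a DAB-stained section and score microglial activation.

Renders an Iba-1-style bright-field image containing ramified (resting)
and amoeboid (activated) cells, segments it, and prints each cell's
area:perimeter ratio (hydraulic radius).  High values mean compact,
activated morphology; low values mean branched, resting morphology.
"""

from synspread import morphometry as mm
from synspread import synthetic_data as sd

cfg = sd.SectionSimConfig(seed=1, n_ramified=3, n_amoeboid=3)
section, truth = sd.make_section_image(cfg)

# area cutoffs scaled to this synthetic field of view (the 2000-px default
# matches full-resolution 60x acquisition)
cells = mm.measure_section_cells(section, body_area_min_px=300,
                                 process_area_min_px=30)

print("per-cell hydraulic radius (um):")
for _, row in cells.iterrows():
    print(f"  cell {int(row.cell_id)}: area {row.area_um2:7.1f} um^2, "
          f"index {row.hydraulic_radius_um:5.2f}")
print("\ntrue shape classes for comparison:")
print(truth.cells[["cell_id", "shape_class", "true_area"]].to_string(index=False))
print("\nCells scoring above ~2.5 um here are the compact amoeboid ones; the"
      "\nbranched ramified cells score lower because their perimeter is long.")
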