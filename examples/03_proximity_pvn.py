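"""Tumor-cell / vessel proximity mapping and perivascular-niche binning.

Circular tumor cells are planted at 5, 15, …, 55 µm from a vessel; the
exact Euclidean distance transform recovers each cell's distance, bins it
into the canonical 10-µm bins, and computes the fraction of cells
residing within 50 µm of the vasculature (the perivascular niche, PVN).
Marker-positive and -negative subpopulations get paired histograms.
"""

from nichequant.proximity import (
    bin_distances,
    cell_distances,
    distance_map,
    split_by_marker,
)
from nichequant.synth import make_proximity_scene

specs = [{"distance_um": d, "sox2": d < 30} for d in (5, 15, 25, 35, 45, 55)]
vessel, cells, markers, truth = make_proximity_scene(specs, seed=0)

dmap = distance_map(vessel)
records = cell_distances(cells, dmap, aggregation="mean", markers=markers)
print(records[["label", "distance_um", "bin", "sox2"]].to_string(index=False))

hist = bin_distances(records)
print(f"\nbin fractions: {hist.fractions.round(3).tolist()}")
print(f"PVN fraction (< 50 µm): {hist.pvn_fraction:.3f}")

neg, pos = split_by_marker(records, "sox2")
print(f"SOX2+ PVN fraction: {pos.pvn_fraction:.2f}  "
      f"(planted SOX2+ cells all sit < 30 µm)")
print(f"SOX2- PVN fraction: {neg.pvn_fraction:.2f}")
print()
print("5 of 6 cells lie within 50 µm, so the overall PVN fraction is "
      "0.833; the marker split shows stem-like (SOX2+) cells enriched "
      "near vessels, the comparison the distance binning exists for.")
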