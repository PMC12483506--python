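"""Connectivity-pattern geometry of one input map.

Builds a map with two input clusters and prints the collapsed-profile
metrics: cluster count and widths, the cortical-column count (one barrel
~ two 75 um grid columns, so a run of n connected columns spans
ceiling(n/2) columns), input-field width, connectivity-gap fraction, and
the dominant-cluster EPSC ratio.
"""
import numpy as np

from lspsmap import GridSpec, InputMap
from lspsmap.map_metrics import (
    collapse_and_clusters,
    column_count,
    dominant_cluster_ratio,
    field_metrics,
    layer_summary,
)

grid = GridSpec()
amps = np.zeros(grid.shape)
amps[9, 7] = 62.0    # L5a, columns 8-9: the strong cluster
amps[9, 8] = 38.0
amps[6, 8] = 25.0    # L4 site in the same columns
amps[11, 16] = 30.0  # L5b, column 17: a weaker, distant cluster
imap = InputMap(grid, amps)

profile, clusters = collapse_and_clusters(imap.connectivity())
f = field_metrics(clusters, grid)
print(f"clusters: {[(c.start_col, c.end_col) for c in clusters]}")
print(f"cluster widths (um): {[c.width_um for c in clusters]}")
print(f"cortical columns: {column_count(clusters)}")
print(f"input field width: {f.width_um:.0f} um "
      f"(columns {f.first_col}-{f.last_col})")
print(f"gap fraction: {f.gap_fraction_pct:.1f}% of the field has no input")
print(f"cluster spacing: {f.cluster_spacings_um} um")
print(f"dominant cluster ratio: "
      f"{dominant_cluster_ratio(imap, clusters):.2f}x "
      "(strongest cluster EPSC sum over the mean of the others)")
print("\nper-layer EPSC totals (pA):")
print(layer_summary(imap)[["n_sites", "epsc_total_pA"]])
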