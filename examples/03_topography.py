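"""Cohort topography: centers of mass versus SPN position.

Generates a 150-cell synthetic cohort with the default loosely topographic
pattern, computes each cell's connectivity and synaptic-input centers of
mass from the planted maps, and prints the Pearson/Spearman correlations
with SPN position plus the mean CM shift.  R near 0.6 reproduces a loose
topography: organised at the population level, imprecise cell by cell.
"""
import numpy as np

from lspsmap import GridSpec
from lspsmap.synthetic_data import PatternParams, generate_cohort_truth, truth_maps
from lspsmap.topography import cm_result, topography_summary

grid = GridSpec()
cohort = generate_cohort_truth(150, grid, PatternParams(), seed=11)

pos, conn_cms, syn_cms, shifts = [], [], [], []
for cell, truth in cohort:
    imap, cmap = truth_maps(truth, grid)
    res = cm_result(imap, cmap)
    pos.append(cell.lateral_pos_um)
    conn_cms.append(res.connectivity_cm_um)
    syn_cms.append(res.synaptic_cm_um)
    shifts.append(res.shift_um)

summ = topography_summary(np.array(pos), np.array(conn_cms))
summ_syn = topography_summary(np.array(pos), np.array(syn_cms))
print(f"cells: {len(pos)}")
print(f"connectivity CM vs position: Pearson R = {summ.pearson_r:.2f}, "
      f"Spearman R = {summ.spearman_r:.2f}")
print(f"synaptic-input CM vs position: Pearson R = {summ_syn.pearson_r:.2f}")
print(f"regression slope {summ.slope:.2f} (1 = ideal point-to-point map)")
print(f"mean |CM shift| between definitions: {np.mean(shifts):.0f} um")
print("amplitude weighting barely moves the CM: connectivity pattern, not "
      "synaptic strength, carries the topography.")
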