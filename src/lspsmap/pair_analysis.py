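"""Pairwise heterogeneity of connectivity maps for cells of one slice.

For a pair of SPNs recorded in the same slice the module reports how much
of their cortical innervation is shared: the overlap of their input-field
column intervals (um), the fraction of connected sites that are vertically
aligned (same column holds a connected site in the other map), and the
fraction that coincide exactly (same row and column).  Both fractions pool
the two maps' connected sites in the denominator; per-map fractions are
also emitted for transparency.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import CellRecord, ConnectivityMap

__all__ = ["PairMetrics", "pair_metrics", "same_slice_pairs", "cohort_pair_summary"]


@dataclass
class PairMetrics:
    id_a: str
    id_b: str
    spn_distance_um: float
    field_overlap_um: float  # 0 if the column intervals are disjoint
    aligned_pct: float
    overlap_pct: float
    aligned_pct_a: float
    aligned_pct_b: float
    n_sites_a: int
    n_sites_b: int


def _field_interval(cmap: ConnectivityMap) -> tuple[int, int]:
    cols = np.nonzero(cmap.connected.any(axis=0))[0]
    return int(cols[0]) + 1, int(cols[-1]) + 1


def pair_metrics(
    cmap_a: ConnectivityMap,
    cmap_b: ConnectivityMap,
    cell_a: CellRecord,
    cell_b: CellRecord,
) -> PairMetrics:
    """Shared-innervation statistics for two same-slice cells.

    Both cells must have at least one connected site.  ``field_overlap_um``
    is the inclusive intersection length of the two [first, last] column
    intervals; an aligned site is a connected site whose column contains at
    least one connected site in the other map; overlap requires exact
    (row, col) coincidence.
    """
    if cell_a.slice_id != cell_b.slice_id:
        raise ValueError(
            f"cells {cell_a.cell_id} and {cell_b.cell_id} are from different slices"
        )
    if cmap_a.n_connected == 0 or cmap_b.n_connected == 0:
        raise ValueError("pair_metrics requires both maps to be non-empty")
    grid = cmap_a.grid
    fa, fb = _field_interval(cmap_a), _field_interval(cmap_b)
    inter_lo, inter_hi = max(fa[0], fb[0]), min(fa[1], fb[1])
    overlap_cols = max(0, inter_hi - inter_lo + 1)
    field_overlap_um = overlap_cols * grid.spacing_um

    sites_a = set(cmap_a.sites())
    sites_b = set(cmap_b.sites())
    cols_a = {c for _, c in sites_a}
    cols_b = {c for _, c in sites_b}
    aligned_a = sum(1 for _, c in sites_a if c in cols_b)
    aligned_b = sum(1 for _, c in sites_b if c in cols_a)
    shared = len(sites_a & sites_b)
    na, nb = len(sites_a), len(sites_b)
    return PairMetrics(
        id_a=cell_a.cell_id,
        id_b=cell_b.cell_id,
        spn_distance_um=abs(cell_a.lateral_pos_um - cell_b.lateral_pos_um),
        field_overlap_um=field_overlap_um,
        aligned_pct=100.0 * (aligned_a + aligned_b) / (na + nb),
        overlap_pct=100.0 * 2 * shared / (na + nb),
        aligned_pct_a=100.0 * aligned_a / na,
        aligned_pct_b=100.0 * aligned_b / nb,
        n_sites_a=na,
        n_sites_b=nb,
    )


def same_slice_pairs(
    cells: list[CellRecord],
    cmaps: dict[str, ConnectivityMap],
) -> list[PairMetrics]:
    """All within-slice pairs with non-empty maps on both sides."""
    by_slice: dict[str, list[CellRecord]] = {}
    for cell in cells:
        cmap = cmaps.get(cell.cell_id)
        if cmap is not None and cmap.n_connected > 0:
            by_slice.setdefault(cell.slice_id, []).append(cell)
    out = []
    for members in by_slice.values():
        for a, b in itertools.combinations(members, 2):
            out.append(pair_metrics(cmaps[a.cell_id], cmaps[b.cell_id], a, b))
    return out


def cohort_pair_summary(
    pairs: list[PairMetrics], bin_um: float = 100.0
) -> pd.DataFrame:
    """Pair statistics binned by inter-SPN distance (half-open bins).

    Bins run from 0 up to the largest observed distance; bins with no pairs
    carry NaN (the lack of data, not a zero).
    """
    if not pairs:
        raise ValueError("cohort_pair_summary requires at least one pair")
    dist = np.array([p.spn_distance_um for p in pairs])
    n_bins = int(dist.max() // bin_um) + 1
    rows = []
    for k in range(n_bins):
        mask = (dist >= k * bin_um) & (dist < (k + 1) * bin_um)
        sel = [p for p, m in zip(pairs, mask) if m]
        if sel:
            rows.append(
                {
                    "bin_left_um": k * bin_um,
                    "n_pairs": len(sel),
                    "frac_field_overlap": float(
                        np.mean([p.field_overlap_um > 0 for p in sel])
                    ),
                    "mean_overlap_width_um": float(
                        np.mean([p.field_overlap_um for p in sel])
                    ),
                    "mean_aligned_pct": float(np.mean([p.aligned_pct for p in sel])),
                    "mean_overlap_pct": float(np.mean([p.overlap_pct for p in sel])),
                }
            )
        else:
            rows.append(
                {
                    "bin_left_um": k * bin_um,
                    "n_pairs": 0,
                    "frac_field_overlap": np.nan,
                    "mean_overlap_width_um": np.nan,
                    "mean_aligned_pct": np.nan,
                    "mean_overlap_pct": np.nan,
                }
            )
    return pd.DataFrame(rows)
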