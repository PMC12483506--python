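"""Per-cell connectivity-pattern geometry.

A connectivity map is collapsed along the vertical (laminar) axis to a
boolean profile over grid columns.  A *cluster* is a maximal run of
consecutive connected columns; its length in sites (ConsSites) is converted
to a cortical-column count as ceiling(ConsSites / 2), one barrel being
about two grid columns (150 um) wide in this preparation.  The *input
field* spans from the first to the last connected column inclusive;
unconnected interior columns are connectivity gaps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import CellRecord, ConnectivityMap, GridSpec, InputMap, assign_layer

__all__ = [
    "Cluster",
    "InputField",
    "collapse_profile",
    "collapse_and_clusters",
    "find_clusters",
    "column_count",
    "field_metrics",
    "layer_summary",
    "dominant_cluster_ratio",
    "cell_pattern_metrics",
    "cohort_metrics",
]


@dataclass(frozen=True)
class Cluster:
    """Maximal run of connected columns in the collapsed profile."""

    start_col: int
    end_col: int
    spacing_um: float = 75.0

    def __post_init__(self) -> None:
        if self.start_col > self.end_col:
            raise ValueError("cluster start_col must be <= end_col")

    @property
    def n_sites(self) -> int:
        """ConsSites: number of consecutive connected sites."""
        return self.end_col - self.start_col + 1

    @property
    def width_um(self) -> float:
        return self.n_sites * self.spacing_um

    @property
    def column_count(self) -> int:
        """Cortical columns spanned: ceiling(ConsSites / 2)."""
        return (self.n_sites + 1) // 2


@dataclass
class InputField:
    """Horizontal extent and gap structure of one cell's connectivity."""

    first_col: int
    last_col: int
    width_um: float
    n_clusters: int
    total_columns: int
    gap_fraction_pct: float
    cluster_spacings_um: list[float] = field(default_factory=list)


def collapse_profile(cmap: ConnectivityMap) -> np.ndarray:
    """Column-wise OR over rows: connected iff any row in the column is."""
    return cmap.connected.any(axis=0)


def find_clusters(profile: np.ndarray, spacing_um: float = 75.0) -> list[Cluster]:
    """Maximal runs of connected columns in a collapsed boolean profile.

    Returns an empty list for an all-empty profile (the caller decides how
    to treat cells with no connectivity).
    """
    profile = np.asarray(profile, dtype=bool)
    padded = np.concatenate(([False], profile, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1  # 1-based columns
    ends = np.nonzero(diff == -1)[0]
    return [Cluster(int(s), int(e), spacing_um) for s, e in zip(starts, ends)]


def collapse_and_clusters(
    cmap: ConnectivityMap,
) -> tuple[np.ndarray, list[Cluster]]:
    profile = collapse_profile(cmap)
    return profile, find_clusters(profile, cmap.grid.spacing_um)


def column_count(clusters: list[Cluster]) -> int:
    """Number of cortical columns: sum over clusters of ceiling(ConsSites/2)."""
    return sum(c.column_count for c in clusters)


def field_metrics(clusters: list[Cluster], grid: GridSpec) -> InputField:
    """Input-field width, inter-cluster spacings, and gap fraction.

    Width counts the inclusive site extent, (last - first + 1) x spacing, so
    a single connected site yields one site's width rather than zero.
    """
    if not clusters:
        raise ValueError("field_metrics requires at least one cluster")
    first = clusters[0].start_col
    last = clusters[-1].end_col
    span = last - first + 1
    connected = sum(c.n_sites for c in clusters)
    spacings = [
        (b.start_col - a.end_col - 1) * grid.spacing_um
        for a, b in zip(clusters, clusters[1:])
    ]
    return InputField(
        first_col=first,
        last_col=last,
        width_um=span * grid.spacing_um,
        n_clusters=len(clusters),
        total_columns=column_count(clusters),
        gap_fraction_pct=100.0 * (span - connected) / span,
        cluster_spacings_um=spacings,
    )


def layer_summary(imap: InputMap) -> pd.DataFrame:
    """Per-layer connectivity and summed EPSC amplitude (EPSC^T).

    One row per layer of the grid's scheme: whether the layer holds any
    connected site, how many, the layer's total EPSC (pA) and the mean
    amplitude over its connected sites.
    """
    grid = imap.grid
    rows = []
    for label, (lo, hi) in grid.layer_scheme.items():
        block = imap.amplitudes[lo - 1 : hi, :]
        mask = block > 0
        n = int(mask.sum())
        total = float(block.sum())
        rows.append(
            {
                "layer": label,
                "connected": n > 0,
                "n_sites": n,
                "epsc_total_pA": total,
                "mean_site_amp_pA": total / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("layer")


def _cluster_epsc_sums(imap: InputMap, clusters: list[Cluster]) -> np.ndarray:
    return np.array(
        [imap.amplitudes[:, c.start_col - 1 : c.end_col].sum() for c in clusters]
    )


def dominant_cluster_ratio(
    imap: InputMap, clusters: list[Cluster], others: str = "mean"
) -> float:
    """Strongest cluster's EPSC sum relative to the other clusters'.

    ``others="mean"`` (default) divides by the mean of the remaining
    clusters' sums; ``others="total"`` divides by their total.  Defined only
    for cells with at least two clusters.
    """
    if len(clusters) < 2:
        raise ValueError("dominant_cluster_ratio requires >= 2 clusters")
    if others not in ("mean", "total"):
        raise ValueError("others must be 'mean' or 'total'")
    sums = _cluster_epsc_sums(imap, clusters)
    top = int(np.argmax(sums))
    rest = np.delete(sums, top)
    denom = rest.mean() if others == "mean" else rest.sum()
    if denom == 0:
        raise ValueError("other clusters carry zero EPSC")
    return float(sums[top] / denom)


def cell_pattern_metrics(
    imap: InputMap,
    cell: CellRecord | None = None,
    dominant_others: str = "mean",
) -> dict:
    """Flat per-cell metric row (one CSV line) from an input map."""
    grid = imap.grid
    cmap = imap.connectivity()
    profile, clusters = collapse_and_clusters(cmap)
    if not clusters:
        raise ValueError("cell has an empty connectivity map")
    fieldm = field_metrics(clusters, grid)
    lsum = layer_summary(imap)
    row: dict = {}
    if cell is not None:
        row.update(
            cell_id=cell.cell_id,
            slice_id=cell.slice_id,
            subtype=cell.subtype,
            lateral_pos_um=cell.lateral_pos_um,
        )
    row.update(
        n_connected_sites=cmap.n_connected,
        n_clusters=fieldm.n_clusters,
        total_columns=fieldm.total_columns,
        field_width_um=fieldm.width_um,
        gap_pct=fieldm.gap_fraction_pct,
        mean_cluster_width_um=float(np.mean([c.width_um for c in clusters])),
        epsc_sum_pA=float(imap.amplitudes.sum()),
    )
    for label in grid.layer_scheme:
        key = "epsc_" + label.replace("/", "") + "_pA"
        row[key] = float(lsum.loc[label, "epsc_total_pA"])
    row["dominant_ratio"] = (
        dominant_cluster_ratio(imap, clusters, dominant_others)
        if len(clusters) >= 2
        else np.nan
    )
    return row


def cohort_metrics(
    cells: list[CellRecord],
    input_maps: dict[str, InputMap],
    dominant_others: str = "mean",
) -> tuple[pd.DataFrame, list[str]]:
    """Metric table for a cohort; cells with empty maps are excluded.

    Returns the table (one row per cell with >= 1 connected site) and the
    ids of excluded empty-map cells, reported separately per convention.
    """
    rows, empty = [], []
    for cell in cells:
        imap = input_maps[cell.cell_id]
        if not np.any(imap.amplitudes > 0):
            empty.append(cell.cell_id)
            continue
        rows.append(cell_pattern_metrics(imap, cell, dominant_others))
    return pd.DataFrame(rows), empty
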