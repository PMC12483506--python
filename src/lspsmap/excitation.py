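"""Excitation-profile analysis: AP counts, firing sites, grid conversion.

Excitation profiles are current-clamp AP-count maps of cortical neurons
under focal uncaging, acquired on a dense 50 um grid.  They calibrate the
spatial resolution of the mapping: the number of firing sites (sAP) bounds
how far a "connected site" can lie from the presynaptic soma.  Firing-site
counts measured on one grid spacing are converted to another with the
area-preserving ratio (spacing_from / spacing_to)^2 — a coarser grid tiles
the same excitable area with fewer sites.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import GridSpec

__all__ = [
    "ExcitationProfile",
    "ap_metrics",
    "count_spikes",
    "convert_site_count",
    "excitation_radius",
]


@dataclass
class ExcitationProfile:
    """Per-site AP counts of one cortical neuron."""

    grid: GridSpec
    ap_counts: np.ndarray
    soma_site: tuple[int, int]
    cell_type: str = "unknown"

    def __post_init__(self) -> None:
        self.ap_counts = np.asarray(self.ap_counts)
        if self.ap_counts.shape != self.grid.shape:
            raise ValueError("ap_counts shape must match the grid")
        if np.any(self.ap_counts < 0) or not np.issubdtype(
            self.ap_counts.dtype, np.integer
        ):
            raise ValueError("ap_counts must be non-negative integers")

    @property
    def total_spikes(self) -> int:
        return int(self.ap_counts.sum())

    @property
    def sap(self) -> int:
        """Number of firing sites at the profile's own grid spacing."""
        return int((self.ap_counts >= 1).sum())

    @property
    def spikes_per_firing_site(self) -> float:
        if self.sap == 0:
            raise ValueError("spikes_per_firing_site undefined: no firing site")
        return self.total_spikes / self.sap

    def sap_at_spacing(self, spacing_to_um: float) -> float:
        """Firing-site count converted to another grid spacing."""
        return convert_site_count(self.sap, self.grid.spacing_um, spacing_to_um)


def count_spikes(trace_mv: np.ndarray, threshold_mv: float = 0.0) -> int:
    """Number of upward threshold crossings in a membrane-potential trace."""
    v = np.asarray(trace_mv, dtype=float)
    above = v > threshold_mv
    return int(np.count_nonzero(~above[:-1] & above[1:]) + int(above[0]))


def ap_metrics(
    counts: np.ndarray | None = None,
    traces: np.ndarray | None = None,
    grid: GridSpec | None = None,
    soma_site: tuple[int, int] = (4, 4),
    cell_type: str = "unknown",
    spike_threshold_mv: float = 0.0,
) -> ExcitationProfile:
    """Build an excitation profile from per-site AP counts or raw traces.

    ``traces`` has shape (n_rows, n_cols, n_samples); spikes are counted as
    upward crossings of ``spike_threshold_mv`` (default 0 mV).
    """
    if (counts is None) == (traces is None):
        raise ValueError("provide exactly one of counts or traces")
    if traces is not None:
        traces = np.asarray(traces, dtype=float)
        counts = np.apply_along_axis(count_spikes, -1, traces, spike_threshold_mv)
    counts = np.asarray(counts, dtype=int)
    if grid is None:
        from .synthetic_data import excitation_grid

        grid = excitation_grid(n_rows=counts.shape[0], n_cols=counts.shape[1])
    return ExcitationProfile(grid, counts, soma_site, cell_type)


def convert_site_count(
    sap: float, spacing_from_um: float, spacing_to_um: float
) -> float:
    """Area-preserving firing-site count conversion between grid spacings."""
    if spacing_from_um <= 0 or spacing_to_um <= 0:
        raise ValueError("grid spacings must be positive")
    return sap * (spacing_from_um / spacing_to_um) ** 2


def excitation_radius(profile: ExcitationProfile) -> float:
    """Max Euclidean distance (um) from the soma to any firing site.

    Returns 0 when only the somatic site fires; raises if no site fires.
    """
    firing = np.nonzero(profile.ap_counts >= 1)
    if firing[0].size == 0:
        raise ValueError("excitation_radius undefined: no firing site")
    rows = firing[0] + 1
    cols = firing[1] + 1
    d = np.hypot(rows - profile.soma_site[0], cols - profile.soma_site[1])
    return float(d.max() * profile.grid.spacing_um)
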