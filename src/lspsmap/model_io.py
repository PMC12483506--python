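"""Domain types, grid geometry, layer conventions, and on-disk formats.

The mapping experiment stimulates a rectangular grid of cortical sites
(default 29 columns x 16 rows, 75 um spacing) while one striatal projection
neuron (SPN) is recorded in voltage clamp.  Rows run from the pia (row 1)
down through the cortical layers; columns run laterally.  All lateral
positions are expressed in micrometres relative to a horizontal anatomical
reference (Ref_hor, the striatum/GPe/internal-capsule junction), carried by
each slice as a signed offset of grid column 1.

Currents are stored signed, inward negative (voltage-clamp convention at
-80 mV); reported EPSC amplitudes are positive magnitudes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import h5py
import numpy as np

__all__ = [
    "DEFAULT_LAYER_SCHEME",
    "GridSpec",
    "Sweep",
    "CellRecord",
    "InputMap",
    "ConnectivityMap",
    "Experiment",
    "FormatError",
    "assign_layer",
    "site_lateral_um",
    "column_lateral_um",
    "write_bundle",
    "read_bundle",
]

#: Row-to-layer convention for the default 16-row grid: rows 1-6 are L2/3,
#: 7-9 L4, 10 L5a, 11-13 L5b, 14-16 L6.
DEFAULT_LAYER_SCHEME: Mapping[str, tuple[int, int]] = {
    "L2/3": (1, 6),
    "L4": (7, 9),
    "L5a": (10, 10),
    "L5b": (11, 13),
    "L6": (14, 16),
}


class FormatError(ValueError):
    """A bundle file is malformed (missing group, field or attribute)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and layer labelling of one stimulation grid.

    ``refhor_col_offset_um`` is the signed lateral position of grid column 1
    relative to Ref_hor; alignment of slices is metadata-only (a coordinate
    shift), maps are never resampled.
    """

    n_cols: int = 29
    n_rows: int = 16
    spacing_um: float = 75.0
    refhor_col_offset_um: float = 0.0
    l5a_row: int = 10
    layer_scheme: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_SCHEME)
    )

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        covered = np.zeros(self.n_rows, dtype=int)
        for label, (lo, hi) in self.layer_scheme.items():
            if lo > hi:
                raise ValueError(f"layer {label!r} has start row > end row")
            if lo < 1 or hi > self.n_rows:
                raise ValueError(f"layer {label!r} rows outside the grid")
            covered[lo - 1 : hi] += 1
        if not np.all(covered == 1):
            raise ValueError("layer_scheme must cover every row exactly once")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    def sites(self) -> Iterator[tuple[int, int]]:
        """All (row, col) sites, 1-based, row-major."""
        for row in range(1, self.n_rows + 1):
            for col in range(1, self.n_cols + 1):
                yield (row, col)

    def with_offset(self, refhor_col_offset_um: float) -> "GridSpec":
        return replace(self, refhor_col_offset_um=refhor_col_offset_um)


def assign_layer(row: int, grid: GridSpec) -> str:
    """Layer label of a grid row under the grid's layer scheme."""
    if not 1 <= row <= grid.n_rows:
        raise IndexError(f"row {row} outside grid rows 1..{grid.n_rows}")
    for label, (lo, hi) in grid.layer_scheme.items():
        if lo <= row <= hi:
            return label
    raise IndexError(f"row {row} not covered by layer scheme")  # pragma: no cover


def site_lateral_um(col: int, grid: GridSpec) -> float:
    """Lateral position of a grid column relative to Ref_hor, in um."""
    if not 1 <= col <= grid.n_cols:
        raise IndexError(f"col {col} outside grid columns 1..{grid.n_cols}")
    return grid.refhor_col_offset_um + (col - 1) * grid.spacing_um


def column_lateral_um(grid: GridSpec) -> np.ndarray:
    """Lateral positions of all columns (vectorised :func:`site_lateral_um`)."""
    return grid.refhor_col_offset_um + np.arange(grid.n_cols) * grid.spacing_um


@dataclass
class Sweep:
    """One current trace for one grid site and one repetition.

    ``samples`` are in pA, inward negative.  The trace must cover at least
    the 100 ms baseline plus a 50 ms post-stimulus response window.
    """

    site: tuple[int, int]
    repetition: int
    samples: np.ndarray
    sampling_rate_hz: float
    stim_onset_ms: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")
        needed = (self.stim_onset_ms + 50.0) / 1000.0 * self.sampling_rate_hz
        if self.samples.size < int(round(needed)):
            raise ValueError(
                "trace must cover stim_onset_ms + 50 ms "
                f"({self.samples.size} samples < {needed:.0f})"
            )

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sampling_rate_hz * 1000.0


@dataclass
class CellRecord:
    """Metadata of one recorded SPN."""

    cell_id: str
    slice_id: str
    lateral_pos_um: float
    depth_um: float = 80.0
    subtype: str = "unknown"  # "D1" | "D2" | "unknown"

    def __post_init__(self) -> None:
        if self.depth_um < 0:
            raise ValueError("depth_um must be >= 0")
        if self.subtype not in ("D1", "D2", "unknown"):
            raise ValueError(f"unknown subtype {self.subtype!r}")


@dataclass
class InputMap:
    """Grid of mean evoked-EPSC amplitudes (pA, >= 0; 0 = not connected)."""

    grid: GridSpec
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.shape != self.grid.shape:
            raise ValueError(
                f"amplitudes shape {self.amplitudes.shape} != grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")

    def connectivity(self) -> "ConnectivityMap":
        """Binary support of the map: connected iff amplitude > 0."""
        return ConnectivityMap(self.grid, self.amplitudes > 0)


@dataclass
class ConnectivityMap:
    """Binary grid marking connected stimulation sites."""

    grid: GridSpec
    connected: np.ndarray

    def __post_init__(self) -> None:
        self.connected = np.asarray(self.connected, dtype=bool)
        if self.connected.shape != self.grid.shape:
            raise ValueError(
                f"connected shape {self.connected.shape} != grid {self.grid.shape}"
            )

    @property
    def n_connected(self) -> int:
        return int(self.connected.sum())

    def sites(self) -> list[tuple[int, int]]:
        """Connected (row, col) sites, 1-based."""
        rows, cols = np.nonzero(self.connected)
        return [(int(r) + 1, int(c) + 1) for r, c in zip(rows, cols)]


@dataclass
class Experiment:
    """In-memory experiment bundle: cohort + sweeps + maps + ground truth."""

    grid: GridSpec
    cells: list[CellRecord] = field(default_factory=list)
    sweeps: dict[str, list[Sweep]] = field(default_factory=dict)
    input_maps: dict[str, InputMap] = field(default_factory=dict)
    connectivity_maps: dict[str, ConnectivityMap] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)  # cell_id -> GroundTruth

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


# ---------------------------------------------------------------------------
# HDF5 bundle format
#
#   /grid            attributes of the GridSpec
#   /cells/<id>/meta               cell metadata attributes
#   /cells/<id>/sweeps/<r>_<c>/<rep>   one trace dataset per repetition
#   /maps/<id>/input, /maps/<id>/connectivity
#   /truth/<id>      planted ground truth (optional)
# ---------------------------------------------------------------------------

def _write_grid(f: h5py.File, grid: GridSpec) -> None:
    g = f.create_group("grid")
    g.attrs["n_cols"] = grid.n_cols
    g.attrs["n_rows"] = grid.n_rows
    g.attrs["spacing_um"] = grid.spacing_um
    g.attrs["refhor_col_offset_um"] = grid.refhor_col_offset_um
    g.attrs["l5a_row"] = grid.l5a_row
    g.attrs["layer_scheme"] = json.dumps(
        {k: list(v) for k, v in grid.layer_scheme.items()}
    )


def _read_grid(f: h5py.File) -> GridSpec:
    if "grid" not in f:
        raise FormatError("missing group /grid")
    g = f["grid"]
    for key in ("n_cols", "n_rows", "spacing_um", "refhor_col_offset_um",
                "l5a_row", "layer_scheme"):
        if key not in g.attrs:
            raise FormatError(f"missing attribute /grid@{key}")
    scheme = {k: tuple(v) for k, v in json.loads(g.attrs["layer_scheme"]).items()}
    return GridSpec(
        n_cols=int(g.attrs["n_cols"]),
        n_rows=int(g.attrs["n_rows"]),
        spacing_um=float(g.attrs["spacing_um"]),
        refhor_col_offset_um=float(g.attrs["refhor_col_offset_um"]),
        l5a_row=int(g.attrs["l5a_row"]),
        layer_scheme=scheme,
    )


def write_bundle(path, exp: Experiment) -> None:
    """Write an experiment bundle to HDF5 (lossless round trip)."""
    with h5py.File(path, "w") as f:
        _write_grid(f, exp.grid)
        cells = f.create_group("cells")
        for cell in exp.cells:
            cg = cells.create_group(cell.cell_id)
            meta = cg.create_group("meta")
            meta.attrs["cell_id"] = cell.cell_id
            meta.attrs["slice_id"] = cell.slice_id
            meta.attrs["lateral_pos_um"] = cell.lateral_pos_um
            meta.attrs["depth_um"] = cell.depth_um
            meta.attrs["subtype"] = cell.subtype
            if cell.cell_id in exp.sweeps:
                sg = cg.create_group("sweeps")
                for sw in exp.sweeps[cell.cell_id]:
                    site_key = f"{sw.site[0]}_{sw.site[1]}"
                    grp = sg.require_group(site_key)
                    ds = grp.create_dataset(str(sw.repetition), data=sw.samples)
                    ds.attrs["sampling_rate_hz"] = sw.sampling_rate_hz
                    ds.attrs["stim_onset_ms"] = sw.stim_onset_ms
        maps = f.create_group("maps")
        for cid, imap in exp.input_maps.items():
            mg = maps.create_group(cid)
            mg.create_dataset("input", data=imap.amplitudes)
            cmap = exp.connectivity_maps.get(cid, imap.connectivity())
            mg.create_dataset("connectivity", data=cmap.connected.astype(np.uint8))
        if exp.truth:
            tg = f.create_group("truth")
            for cid, truth in exp.truth.items():
                _write_truth(tg.create_group(cid), truth)


def _write_truth(group: h5py.Group, truth) -> None:
    src = np.array(
        [(s.row, s.col, s.n_presyn, s.mean_amp_pA) for s in truth.sources],
        dtype=[("row", "i4"), ("col", "i4"), ("n_presyn", "i4"),
               ("mean_amp_pA", "f8")],
    )
    group.create_dataset("sources", data=src)
    plan = np.array(truth.cluster_plan, dtype=np.int64).reshape(-1, 2)
    group.create_dataset("cluster_plan", data=plan)
    group.attrs["cell_id"] = truth.cell_id
    group.attrs["clipped"] = bool(truth.clipped)


def _read_truth(group: h5py.Group):
    from .synthetic_data import GroundTruth, SourceSite

    for key in ("sources", "cluster_plan"):
        if key not in group:
            raise FormatError(f"missing dataset {group.name}/{key}")
    src = group["sources"][()]
    sources = [
        SourceSite(int(r["row"]), int(r["col"]), int(r["n_presyn"]),
                   float(r["mean_amp_pA"]))
        for r in src
    ]
    plan = [(int(a), int(b)) for a, b in group["cluster_plan"][()]]
    return GroundTruth(
        cell_id=str(group.attrs["cell_id"]),
        sources=sources,
        cluster_plan=plan,
        clipped=bool(group.attrs.get("clipped", False)),
    )


def read_bundle(path) -> Experiment:
    """Read an experiment bundle written by :func:`write_bundle`."""
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        exp = Experiment(grid=grid)
        if "cells" not in f:
            raise FormatError("missing group /cells")
        for cid in sorted(f["cells"]):
            cg = f["cells"][cid]
            if "meta" not in cg:
                raise FormatError(f"missing group /cells/{cid}/meta")
            meta = cg["meta"].attrs
            exp.cells.append(
                CellRecord(
                    cell_id=str(meta["cell_id"]),
                    slice_id=str(meta["slice_id"]),
                    lateral_pos_um=float(meta["lateral_pos_um"]),
                    depth_um=float(meta["depth_um"]),
                    subtype=str(meta["subtype"]),
                )
            )
            if "sweeps" in cg:
                sweeps: list[Sweep] = []
                for site_key in sorted(cg["sweeps"]):
                    row, col = (int(x) for x in site_key.split("_"))
                    for rep in sorted(cg["sweeps"][site_key], key=int):
                        ds = cg["sweeps"][site_key][rep]
                        sweeps.append(
                            Sweep(
                                site=(row, col),
                                repetition=int(rep),
                                samples=ds[()],
                                sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
                                stim_onset_ms=float(ds.attrs["stim_onset_ms"]),
                            )
                        )
                exp.sweeps[cid] = sweeps
        if "maps" in f:
            for cid in sorted(f["maps"]):
                mg = f["maps"][cid]
                if "input" not in mg or "connectivity" not in mg:
                    raise FormatError(f"missing dataset under /maps/{cid}")
                exp.input_maps[cid] = InputMap(grid, mg["input"][()])
                exp.connectivity_maps[cid] = ConnectivityMap(
                    grid, mg["connectivity"][()].astype(bool)
                )
        if "truth" in f:
            for cid in sorted(f["truth"]):
                exp.truth[cid] = _read_truth(f["truth"][cid])
    return exp
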