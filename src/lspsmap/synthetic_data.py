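"""Synthetic cohorts with known ground truth, and realistic sweep synthesis.

The generator emulates the mapping experiment end to end so that every
downstream stage is testable without recordings:

* cohorts of SPNs whose planted connectivity is clustered along the
  column axis and loosely topographic (cluster counts averaging ~1.9,
  cluster widths of mostly 1-2 columns, inter-cluster gaps averaging
  ~3.5 columns, layer weights dominated by L5a);
* per-site, per-repetition current sweeps: 100 ms baseline + 450 ms
  post-stimulus window, baseline noise with a 3-SD level near 9.2 pA,
  Poisson spontaneous EPSCs of 10-20 pA, and evoked EPSCs (difference of
  exponentials, ~40 pA mean, short latency) at the planted sites;
* current-clamp excitation profiles with firing confined to a configurable
  radius around the soma.

Topography is generated constructively: a cell's planted map is placed
around a random cortical anchor, and its striatal position is defined so
that ``CM = slope * position + intercept + e`` holds exactly, with
``e ~ N(0, jitter_sd_um)``.  With ``jitter_sd_um = 0`` the cohort therefore
has a perfectly linear CM-position relation, and the jitter needed for any
target correlation follows from ``jitter_sd = sd(CM) * sqrt(1/R^2 - 1)``.

Noise model: Gaussian samples smoothed with a double boxcar (~1 ms) and
passed through a soft saturation (tanh at 2.5 SD) before rescaling to the
target SD.  The core of the distribution is Gaussian; the extreme tails are
bounded, so a pointwise 3-SD peak detector sees practically no false
crossings from noise alone.  Real broadband recordings have heavier
excursions and would be pre-filtered before such a detector; see
docs/methods.md.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .model_io import CellRecord, ConnectivityMap, GridSpec, InputMap, Sweep
from .topography import connectivity_cm

__all__ = [
    "SourceSite",
    "GroundTruth",
    "NoiseModel",
    "PatternParams",
    "default_row_probs",
    "jitter_for_target_r",
    "generate_cohort_truth",
    "truth_maps",
    "simulate_sweepset",
    "excitation_grid",
    "simulate_excitation_profile",
    "high_snr_pattern",
    "high_snr_noise",
]


@dataclass(frozen=True)
class SourceSite:
    """One planted connected site: a few presynaptic cells at one grid site."""

    row: int
    col: int
    n_presyn: int
    mean_amp_pA: float

    def __post_init__(self) -> None:
        if self.n_presyn < 1:
            raise ValueError("n_presyn must be >= 1")
        if self.mean_amp_pA <= 0:
            raise ValueError("mean_amp_pA must be positive")


@dataclass
class GroundTruth:
    """Planted connectivity of one synthetic cell."""

    cell_id: str
    sources: list[SourceSite]
    cluster_plan: list[tuple[int, int]]  # collapsed clusters (start, end col)
    clipped: bool = False  # a planned cluster hit the grid edge


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition and noise parameters for sweep synthesis.

    ``baseline_sd_pA`` defaults to 3.07 so the detector's 3-SD threshold
    lands at ~9.2 pA.  ``n_reps`` is the number of map repetitions (2-4).
    """

    baseline_sd_pA: float = 3.07
    spont_rate_hz: float = 2.0
    spont_amp_range_pA: tuple[float, float] = (10.0, 20.0)
    evoked_latency_mean_ms: float = 7.0
    evoked_latency_sd_ms: float = 2.0
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 10.0
    n_reps: int = 3
    sampling_rate_hz: float = 5000.0
    baseline_ms: float = 100.0
    duration_ms: float = 550.0
    noise_smooth_ms: float = 1.0
    noise_clip_sd: float = 2.0
    rep_amp_cv: float = 0.2  # per-repetition variability of evoked amplitude

    def __post_init__(self) -> None:
        if not 2 <= self.n_reps <= 4:
            raise ValueError("n_reps must be in 2..4")
        for name in ("baseline_sd_pA", "rise_tau_ms", "decay_tau_ms",
                     "sampling_rate_hz", "baseline_ms", "duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spont_rate_hz < 0:
            raise ValueError("spont_rate_hz must be >= 0")
        if self.duration_ms < self.baseline_ms + 50.0:
            raise ValueError("duration must cover baseline + 50 ms window")


def default_row_probs(grid: GridSpec) -> np.ndarray:
    """Per-row probability of hosting a presynaptic source.

    Layer weights put L5a first (the dominant origin of corticostriatal
    input), then L4 and L5b, with smaller contributions from L2/3 and L6;
    a layer's weight is spread uniformly over its rows.
    """
    weights = {"L2/3": 0.12, "L4": 0.25, "L5a": 0.40, "L5b": 0.18, "L6": 0.05}
    p = np.zeros(grid.n_rows)
    for label, (lo, hi) in grid.layer_scheme.items():
        w = weights.get(label, 0.1)
        p[lo - 1 : hi] = w / (hi - lo + 1)
    return p / p.sum()


@dataclass(frozen=True)
class PatternParams:
    """Cohort-level connectivity-pattern distributions.

    Defaults target the field's typical pattern statistics: mean cluster
    count ~1.9 (probabilities over 1-6 clusters), cluster widths of mostly
    1-2 columns, geometric inter-cluster gaps with mean ~3.5 columns
    (~265 um), log-normal site amplitudes with mean 40 pA, and a loosely
    topographic CM-position relation calibrated for R ~ 0.6.
    """

    n_cluster_probs: tuple[float, ...] = (0.50, 0.27, 0.12, 0.06, 0.03, 0.02)
    cluster_width_probs: tuple[float, ...] = (0.30, 0.40, 0.20, 0.10)  # 1..4 sites
    gap_mean_sites: float = 3.5
    rows_per_col_probs: tuple[float, ...] = (0.55, 0.35, 0.10)  # 1..3 rows
    row_probs: tuple[float, ...] | None = None  # default: default_row_probs
    amp_mean_pA: float = 40.0
    amp_cv: float = 0.5
    n_presyn_probs: tuple[float, ...] = (0.50, 0.25, 0.15, 0.07, 0.03)  # 1..5
    slope: float = 1.0
    intercept_um: float = 0.0
    jitter_sd_um: float | None = None  # None -> calibrated for target_r
    target_r: float = 0.6
    anchor_range_um: tuple[float, float] = (225.0, 1875.0)
    cells_per_slice: tuple[int, int] = (1, 4)
    depth_um: float = 80.0

    def __post_init__(self) -> None:
        for name in ("n_cluster_probs", "cluster_width_probs",
                     "rows_per_col_probs", "n_presyn_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be a probability vector")
        if self.amp_mean_pA <= 0 or self.amp_cv < 0:
            raise ValueError("amplitude parameters must be positive")
        if self.slope == 0:
            raise ValueError("topographic slope must be nonzero")

    @property
    def mean_cluster_count(self) -> float:
        k = np.arange(1, len(self.n_cluster_probs) + 1)
        return float(np.dot(k, self.n_cluster_probs))

    @property
    def cluster_count_sd(self) -> float:
        k = np.arange(1, len(self.n_cluster_probs) + 1)
        m = self.mean_cluster_count
        return float(np.sqrt(np.dot(k**2, self.n_cluster_probs) - m**2))


def high_snr_pattern(**overrides) -> PatternParams:
    """Pattern preset with tight amplitudes for exact-recovery experiments."""
    defaults = dict(amp_cv=0.15)
    defaults.update(overrides)
    return PatternParams(**defaults)


def high_snr_noise(**overrides) -> NoiseModel:
    """Noise preset without spontaneous events, for exact-recovery runs."""
    defaults = dict(spont_rate_hz=0.0, rep_amp_cv=0.05)
    defaults.update(overrides)
    return NoiseModel(**defaults)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Cohort ground truth
# ---------------------------------------------------------------------------

def jitter_for_target_r(
    pattern: PatternParams,
    grid: GridSpec | None = None,
    target_r: float | None = None,
    n_probe: int = 400,
    probe_seed: int = 719,
) -> float:
    """Topographic jitter SD (um) that yields a target CM-position R.

    Uses ``jitter_sd = sd(CM) * sqrt(1/R^2 - 1)``, estimating sd(CM) from a
    fixed-seed probe cohort generated without jitter, so the result is a
    deterministic function of the pattern parameters.
    """
    grid = grid or GridSpec()
    r = pattern.target_r if target_r is None else target_r
    if not 0 < r <= 1:
        raise ValueError("target_r must be in (0, 1]")
    probe = replace(pattern, jitter_sd_um=0.0)
    cohort = generate_cohort_truth(n_probe, grid, probe, seed=probe_seed)
    cms = np.array(
        [connectivity_cm(truth_maps(t, grid)[1]) for _, t in cohort]
    )
    return float(cms.std() * math.sqrt(1.0 / r**2 - 1.0))


def _place_clusters(
    rng: np.random.Generator,
    grid: GridSpec,
    pattern: PatternParams,
    anchor_col: int,
) -> tuple[np.ndarray, bool]:
    """Plant cluster columns around an anchor; returns (profile, clipped).

    The primary cluster is centred on the anchor; further clusters step
    outward left/right separated by geometric gaps (>= 1 empty column, so
    planned clusters never merge).  A cluster running past the grid edge is
    truncated there and flagged.
    """
    n_clusters = int(rng.choice(len(pattern.n_cluster_probs),
                                p=pattern.n_cluster_probs)) + 1
    widths = rng.choice(len(pattern.cluster_width_probs),
                        size=n_clusters, p=pattern.cluster_width_probs) + 1
    p_gap = 1.0 / pattern.gap_mean_sites
    profile = np.zeros(grid.n_cols, dtype=bool)
    clipped = False

    def paint(start: int, end: int) -> bool:
        nonlocal clipped
        s, e = max(1, start), min(grid.n_cols, end)
        if s > e:
            clipped = True
            return False
        if (s, e) != (start, end):
            clipped = True
        profile[s - 1 : e] = True
        return True

    w0 = int(widths[0])
    start0 = anchor_col - (w0 - 1) // 2
    paint(start0, start0 + w0 - 1)
    left_edge, right_edge = start0, start0 + w0 - 1
    side = rng.integers(0, 2)  # which side the first secondary cluster takes
    for i in range(1, n_clusters):
        w = int(widths[i])
        gap = int(rng.geometric(p_gap))
        go_right = (side + i) % 2 == 0
        # prefer the chosen side; shorten the gap if the grid edge is near,
        # and fall back to the other side when there is no room at all
        room_right = grid.n_cols - right_edge  # columns available past the edge
        room_left = left_edge - 1
        placed = False
        for attempt_right in (go_right, not go_right):
            room = room_right if attempt_right else room_left
            if room < w + 1:
                continue
            g_eff = min(gap, room - w)
            if g_eff < gap:
                clipped = True
            if attempt_right:
                start = right_edge + g_eff + 1
                paint(start, start + w - 1)
                right_edge = start + w - 1
            else:
                end = left_edge - g_eff - 1
                paint(end - w + 1, end)
                left_edge = end - w + 1
            placed = True
            break
        if not placed:
            clipped = True  # no room on either side: cluster dropped
    return profile, clipped


def _profile_runs(profile: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], profile, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0] + 1
    ends = np.nonzero(diff == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def generate_cohort_truth(
    n_cells: int,
    grid: GridSpec | None = None,
    pattern: PatternParams | None = None,
    seed=0,
) -> list[tuple[CellRecord, GroundTruth]]:
    """Generate a cohort of cells with planted, loosely topographic truth."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    grid = grid or GridSpec()
    pattern = pattern or PatternParams()
    rng = _rng(seed)
    jitter = (
        pattern.jitter_sd_um
        if pattern.jitter_sd_um is not None
        else jitter_for_target_r(pattern, grid)
    )
    row_probs = (
        np.asarray(pattern.row_probs, dtype=float)
        if pattern.row_probs is not None
        else default_row_probs(grid)
    )
    row_probs = row_probs / row_probs.sum()
    sigma_ln = math.sqrt(math.log(1.0 + pattern.amp_cv**2))
    mu_ln = math.log(pattern.amp_mean_pA) - sigma_ln**2 / 2.0

    # slice membership decided up front so enabling later stages never
    # perturbs per-cell draws
    slice_ids: list[str] = []
    s_idx = 0
    while len(slice_ids) < n_cells:
        size = int(rng.integers(pattern.cells_per_slice[0],
                                pattern.cells_per_slice[1] + 1))
        slice_ids.extend([f"slice{s_idx:03d}"] * size)
        s_idx += 1
    slice_ids = slice_ids[:n_cells]

    cohort: list[tuple[CellRecord, GroundTruth]] = []
    lo, hi = pattern.anchor_range_um
    for i in range(n_cells):
        anchor_um = rng.uniform(lo, hi)
        anchor_col = int(round((anchor_um - grid.refhor_col_offset_um)
                               / grid.spacing_um)) + 1
        anchor_col = int(np.clip(anchor_col, 1, grid.n_cols))
        profile, clipped = _place_clusters(rng, grid, pattern, anchor_col)
        plan = _profile_runs(profile)
        sources: list[SourceSite] = []
        for col in np.nonzero(profile)[0] + 1:
            m = int(rng.choice(len(pattern.rows_per_col_probs),
                               p=pattern.rows_per_col_probs)) + 1
            rows = rng.choice(grid.n_rows, size=m, replace=False, p=row_probs) + 1
            for row in sorted(int(r) for r in rows):
                amp = float(rng.lognormal(mu_ln, sigma_ln))
                n_presyn = int(rng.choice(len(pattern.n_presyn_probs),
                                          p=pattern.n_presyn_probs)) + 1
                sources.append(SourceSite(row, int(col), n_presyn, amp))
        truth = GroundTruth(f"cell{i:04d}", sources, plan, clipped)
        cm = connectivity_cm(truth_maps(truth, grid)[1])
        eps = rng.normal(0.0, jitter) if jitter > 0 else 0.0
        lateral_pos = (cm - pattern.intercept_um - eps) / pattern.slope
        subtype = "D1" if rng.random() < 0.5 else "D2"
        cell = CellRecord(
            cell_id=truth.cell_id,
            slice_id=slice_ids[i],
            lateral_pos_um=float(lateral_pos),
            depth_um=pattern.depth_um,
            subtype=subtype,
        )
        cohort.append((cell, truth))
    return cohort


def truth_maps(truth: GroundTruth, grid: GridSpec) -> tuple[InputMap, ConnectivityMap]:
    """Noise-free maps implied by the planted truth (the recovery oracle)."""
    amps = np.zeros(grid.shape)
    for s in truth.sources:
        amps[s.row - 1, s.col - 1] = s.mean_amp_pA
    imap = InputMap(grid, amps)
    return imap, imap.connectivity()


# ---------------------------------------------------------------------------
# Sweep synthesis
# ---------------------------------------------------------------------------

def _epsc_kernel(noise: NoiseModel) -> np.ndarray:
    """Difference-of-exponentials EPSC kernel, unit peak, positive."""
    fs = noise.sampling_rate_hz
    n = int(round(8.0 * noise.decay_tau_ms / 1000.0 * fs))
    t = np.arange(n) / fs * 1000.0  # ms
    k = np.exp(-t / noise.decay_tau_ms) - np.exp(-t / noise.rise_tau_ms)
    peak = k.max()
    if peak <= 0:
        raise ValueError("rise_tau_ms must be smaller than decay_tau_ms")
    return k / peak


def _tanh_shrink(clip_sd: float) -> float:
    """SD of c*tanh(X/c) for X ~ N(0,1), by quadrature."""
    x = np.linspace(-8.0, 8.0, 4001)
    pdf = np.exp(-0.5 * x**2) / math.sqrt(2.0 * math.pi)
    y = clip_sd * np.tanh(x / clip_sd)
    return float(np.sqrt(np.trapezoid(y**2 * pdf, x)))


def _baseline_noise(
    rng: np.random.Generator, shape: tuple[int, int], noise: NoiseModel
) -> np.ndarray:
    """Smoothed, soft-saturated Gaussian noise scaled to the target SD."""
    x = rng.standard_normal(shape)
    w = max(1, int(round(noise.noise_smooth_ms / 1000.0 * noise.sampling_rate_hz)))
    if w > 1:
        x = uniform_filter1d(x, size=w, axis=-1, mode="wrap")
        x = uniform_filter1d(x, size=w, axis=-1, mode="wrap")
        box = np.ones(w) / w
        kern = np.convolve(box, box)
        x /= math.sqrt(float((kern**2).sum()))
    c = noise.noise_clip_sd
    if c > 0:
        x = c * np.tanh(x / c)
        x /= _tanh_shrink(c)
    return x * noise.baseline_sd_pA


def _add_event(trace: np.ndarray, kernel: np.ndarray, start: int, amp: float) -> None:
    n = min(kernel.size, trace.size - start)
    if n > 0:
        trace[start : start + n] -= amp * kernel[:n]


def simulate_sweepset(
    truth: GroundTruth,
    noise: NoiseModel | None = None,
    grid: GridSpec | None = None,
    seed=0,
) -> list[Sweep]:
    """Synthesise all sweeps (every site x repetition) for one cell.

    Each trace holds baseline noise plus Poisson spontaneous EPSCs; at the
    planted sites an evoked EPSC is added per repetition, with amplitude
    drawn per presynaptic contact (sum of ``n_presyn`` draws whose means
    split ``mean_amp_pA``) and latency ~N(mean, sd) clipped into the
    detection window.  Deterministic for a fixed seed.
    """
    noise = noise or NoiseModel()
    grid = grid or GridSpec()
    rng = _rng(seed)
    fs = noise.sampling_rate_hz
    n_samples = int(round(noise.duration_ms / 1000.0 * fs))
    onset_idx = int(round(noise.baseline_ms / 1000.0 * fs))
    sites = list(grid.sites())
    n_traces = len(sites) * noise.n_reps
    traces = _baseline_noise(rng, (n_traces, n_samples), noise)
    kernel = _epsc_kernel(noise)

    # spontaneous events, uniform over the whole trace
    if noise.spont_rate_hz > 0:
        counts = rng.poisson(noise.spont_rate_hz * noise.duration_ms / 1000.0,
                             size=n_traces)
        total = int(counts.sum())
        if total:
            owners = np.repeat(np.arange(n_traces), counts)
            starts = rng.integers(0, n_samples, size=total)
            amps = rng.uniform(*noise.spont_amp_range_pA, size=total)
            for tr, st, am in zip(owners, starts, amps):
                _add_event(traces[tr], kernel, int(st), float(am))

    # evoked events at planted sites
    site_index = {s: i for i, s in enumerate(sites)}
    lat_lo, lat_hi = 1.0, 45.0  # ms, keeps the peak inside the window
    for src in truth.sources:
        base = site_index[(src.row, src.col)] * noise.n_reps
        per_syn_mean = src.mean_amp_pA / src.n_presyn
        for rep in range(noise.n_reps):
            draws = rng.normal(per_syn_mean, per_syn_mean * noise.rep_amp_cv,
                               size=src.n_presyn)
            amp = float(np.clip(draws, 0.0, None).sum())
            lat = float(np.clip(rng.normal(noise.evoked_latency_mean_ms,
                                           noise.evoked_latency_sd_ms),
                                lat_lo, lat_hi))
            start = onset_idx + int(round(lat / 1000.0 * fs))
            _add_event(traces[base + rep], kernel, start, amp)

    sweeps = []
    for i, site in enumerate(sites):
        for rep in range(noise.n_reps):
            sweeps.append(
                Sweep(
                    site=site,
                    repetition=rep + 1,
                    samples=traces[i * noise.n_reps + rep],
                    sampling_rate_hz=fs,
                    stim_onset_ms=noise.baseline_ms,
                )
            )
    return sweeps


# ---------------------------------------------------------------------------
# Excitation profiles
# ---------------------------------------------------------------------------

def excitation_grid(n_rows: int = 8, n_cols: int = 8,
                    spacing_um: float = 50.0) -> GridSpec:
    """Small dense grid used for current-clamp excitation profiling."""
    return GridSpec(
        n_cols=n_cols,
        n_rows=n_rows,
        spacing_um=spacing_um,
        l5a_row=1,
        layer_scheme={"n/a": (1, n_rows)},
    )


#: Probability that a suprathreshold site fires two APs rather than one,
#: per cell type; tuned so the mean spikes-per-firing-site is ~1.03-1.04.
DOUBLE_SPIKE_PROB = {"L2/3": 0.04, "L5a_RS": 0.03, "L5b_nonRS": 0.04}


def simulate_excitation_profile(
    cell_type: str = "L5a_RS",
    grid: GridSpec | None = None,
    excitation_radius_um: float = 75.0,
    seed=0,
    soma_site: tuple[int, int] | None = None,
):
    """AP-count map of a cortical neuron under focal uncaging.

    Sites within ``excitation_radius_um`` of the soma fire 1-2 APs; all
    others stay silent.  The soma site itself always fires.  Returns an
    :class:`~lspsmap.excitation.ExcitationProfile`.
    """
    from .excitation import ExcitationProfile

    if excitation_radius_um < 0:
        raise ValueError("excitation_radius_um must be >= 0")
    grid = grid or excitation_grid()
    rng = _rng(seed)
    if soma_site is None:
        soma_site = ((grid.n_rows + 1) // 2, (grid.n_cols + 1) // 2)
    rr, cc = np.meshgrid(np.arange(1, grid.n_rows + 1),
                         np.arange(1, grid.n_cols + 1), indexing="ij")
    dist = grid.spacing_um * np.hypot(rr - soma_site[0], cc - soma_site[1])
    firing = dist <= excitation_radius_um
    p2 = DOUBLE_SPIKE_PROB.get(cell_type, 0.035)
    counts = np.where(firing, 1 + (rng.random(grid.shape) < p2).astype(int), 0)
    return ExcitationProfile(
        grid=grid,
        ap_counts=counts.astype(int),
        soma_site=soma_site,
        cell_type=cell_type,
    )
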