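"""EPSC detection: per-site sweep sets -> synaptic input / connectivity maps.

Detection rule, applied independently per repetition: the baseline mean and
standard deviation are taken over the 100 ms pre-stimulus segment; the
response amplitude is the magnitude of the most-negative baseline-subtracted
current within a 50 ms window starting at stimulus onset, kept only if it
exceeds ``threshold_sd`` (default 3) baseline standard deviations.  A site
counts as connected only when at least two repetitions carry a detection —
responses occurring once across map repetitions are treated as spontaneous
and set to zero.  The map value is the mean over the repetitions *with* a
detection (the zero-inclusive mean is available via ``mean_mode="all"``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .model_io import ConnectivityMap, GridSpec, InputMap, Sweep

__all__ = ["SiteDetection", "detect_site_response", "detect_arrays", "build_maps"]

#: Guard against degenerate flat baselines (pA).
SD_FLOOR_PA = 1e-6


@dataclass
class SiteDetection:
    """Detection outcome for one grid site."""

    site: tuple[int, int]
    per_rep_peak_pA: list[float]  # 0 where below threshold
    n_detected: int
    mean_amp_pA: float


def detect_arrays(
    traces: np.ndarray,
    sampling_rate_hz: float,
    stim_onset_ms: float = 100.0,
    threshold_sd: float = 3.0,
    window_ms: float = 50.0,
    baseline_ms: float = 100.0,
    mean_mode: str = "detected",
    boxcar_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised core: per-repetition peaks and detection flags.

    ``traces`` has shape (..., n_reps, n_samples); returns ``(peaks, det)``
    of shape (..., n_reps) where ``peaks`` holds baseline-subtracted peak
    magnitudes (pA, 0 where below threshold) and ``det`` the detection mask.
    """
    traces = np.asarray(traces, dtype=np.float64)
    if not np.all(np.isfinite(traces)):
        raise ValueError("sweep samples contain non-finite values")
    if mean_mode not in ("detected", "all"):
        raise ValueError("mean_mode must be 'detected' or 'all'")
    fs = sampling_rate_hz
    onset = int(round(stim_onset_ms / 1000.0 * fs))
    b0 = max(0, onset - int(round(baseline_ms / 1000.0 * fs)))
    w = int(round(window_ms / 1000.0 * fs))
    if onset + w > traces.shape[-1]:
        raise ValueError("trace too short for the response window")
    if boxcar_ms:
        size = max(1, int(round(boxcar_ms / 1000.0 * fs)))
        traces = uniform_filter1d(traces, size=size, axis=-1, mode="nearest")
    baseline = traces[..., b0:onset]
    bmean = baseline.mean(axis=-1)
    bsd = np.maximum(baseline.std(axis=-1), SD_FLOOR_PA)
    window = traces[..., onset : onset + w]
    peak = bmean - window.min(axis=-1)  # positive magnitude of inward peak
    det = peak > threshold_sd * bsd
    return np.where(det, peak, 0.0), det


def detect_site_response(
    sweeps: list[Sweep],
    threshold_sd: float = 3.0,
    window_ms: float = 50.0,
    mean_mode: str = "detected",
    boxcar_ms: float | None = None,
) -> SiteDetection:
    """Apply the detection and repetition-consistency rules to one site."""
    if len(sweeps) < 2:
        raise ValueError("detection requires at least 2 repetitions per site")
    site = sweeps[0].site
    if any(sw.site != site for sw in sweeps):
        raise ValueError("all sweeps must come from the same site")
    peaks = []
    for sw in sweeps:
        p, _ = detect_arrays(
            sw.samples[np.newaxis, :],
            sw.sampling_rate_hz,
            sw.stim_onset_ms,
            threshold_sd,
            window_ms,
            baseline_ms=min(100.0, sw.stim_onset_ms),
            mean_mode=mean_mode,
            boxcar_ms=boxcar_ms,
        )
        peaks.append(float(p[0]))
    peaks_arr = np.asarray(peaks)
    n_det = int((peaks_arr > 0).sum())
    if n_det < 2:
        mean_amp = 0.0
    elif mean_mode == "detected":
        mean_amp = float(peaks_arr[peaks_arr > 0].mean())
    else:
        mean_amp = float(peaks_arr.mean())
    return SiteDetection(site, peaks, n_det, mean_amp)


def build_maps(
    sweeps: list[Sweep],
    grid: GridSpec,
    threshold_sd: float = 3.0,
    window_ms: float = 50.0,
    mean_mode: str = "detected",
    boxcar_ms: float | None = None,
) -> tuple[InputMap, ConnectivityMap]:
    """Assemble one cell's input and connectivity maps from all its sweeps.

    Requires identical coverage: every grid site with the same number of
    repetitions (>= 2) at a common sampling rate and stimulus onset.
    """
    by_site: dict[tuple[int, int], list[Sweep]] = {}
    for sw in sweeps:
        by_site.setdefault(sw.site, []).append(sw)
    missing = [s for s in grid.sites() if s not in by_site]
    if missing:
        shown = ", ".join(map(str, missing[:5]))
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        raise ValueError(f"missing sweeps for sites: {shown}{more}")
    n_reps = {len(v) for v in by_site.values()}
    if len(n_reps) != 1:
        raise ValueError("all sites must carry the same number of repetitions")
    if n_reps.pop() < 2:
        raise ValueError("detection requires at least 2 repetitions per site")

    # Fast path: homogeneous acquisition lets us stack everything.
    rates = {sw.sampling_rate_hz for sw in sweeps}
    onsets = {sw.stim_onset_ms for sw in sweeps}
    lengths = {sw.samples.size for sw in sweeps}
    amplitudes = np.zeros(grid.shape)
    if len(rates) == 1 and len(onsets) == 1 and len(lengths) == 1:
        sites = list(grid.sites())
        reps = sorted(by_site[sites[0]], key=lambda s: s.repetition)
        stack = np.empty((len(sites), len(reps), reps[0].samples.size))
        for i, s in enumerate(sites):
            for j, sw in enumerate(sorted(by_site[s], key=lambda x: x.repetition)):
                stack[i, j] = sw.samples
        peaks, det = detect_arrays(
            stack, rates.pop(), onsets.pop(), threshold_sd, window_ms,
            baseline_ms=min(100.0, sweeps[0].stim_onset_ms),
            mean_mode=mean_mode, boxcar_ms=boxcar_ms,
        )
        n_det = det.sum(axis=-1)
        connected = n_det >= 2
        if mean_mode == "detected":
            with np.errstate(invalid="ignore"):
                means = peaks.sum(axis=-1) / np.maximum(n_det, 1)
        else:
            means = peaks.mean(axis=-1)
        vals = np.where(connected, means, 0.0)
        for (row, col), v in zip(sites, vals):
            amplitudes[row - 1, col - 1] = v
    else:
        for (row, col), site_sweeps in by_site.items():
            d = detect_site_response(
                site_sweeps, threshold_sd, window_ms, mean_mode, boxcar_ms
            )
            amplitudes[row - 1, col - 1] = d.mean_amp_pA
    imap = InputMap(grid, amplitudes)
    return imap, imap.connectivity()
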