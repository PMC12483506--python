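from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from lspsmap.detection import build_maps, detect_arrays
from lspsmap.model_io import GridSpec
from lspsmap.synthetic_data import (
    GroundTruth,
    NoiseModel,
    PatternParams,
    SourceSite,
    generate_cohort_truth,
    jitter_for_target_r,
    simulate_excitation_profile,
    simulate_sweepset,
    truth_maps,
)
from lspsmap.topography import connectivity_cm
from lspsmap.excitation import excitation_radius


class TestCohortTruth:
    def test_forced_single_site_cluster(self, grid):
        pattern = PatternParams(n_cluster_probs=(1.0,),
                                cluster_width_probs=(1.0,),
                                rows_per_col_probs=(1.0,))
        [(cell, truth)] = generate_cohort_truth(1, grid, pattern, seed=0)
        assert len(truth.sources) == 1
        assert len(truth.cluster_plan) == 1
        start, end = truth.cluster_plan[0]
        assert start == end == truth.sources[0].col

    def test_noiseless_topography_is_exact(self, grid):
        pattern = PatternParams(slope=1.0, intercept_um=0.0, jitter_sd_um=0.0)
        cohort = generate_cohort_truth(30, grid, pattern, seed=4)
        for cell, truth in cohort:
            cm = connectivity_cm(truth_maps(truth, grid)[1])
            assert cm == pytest.approx(cell.lateral_pos_um, abs=1e-9)

    def test_mean_cluster_count_within_three_se(self, grid):
        pattern = PatternParams()
        cohort = generate_cohort_truth(200, grid, pattern, seed=9)
        counts = [len(truth.cluster_plan) for _, truth in cohort]
        se = pattern.cluster_count_sd / np.sqrt(len(counts))
        assert abs(np.mean(counts) - pattern.mean_cluster_count) < 3 * se

    def test_amplitude_sample_mean_within_five_percent(self, grid):
        pattern = PatternParams()
        cohort = generate_cohort_truth(300, grid, pattern, seed=13)
        amps = [s.mean_amp_pA for _, t in cohort for s in t.sources]
        assert len(amps) >= 500
        assert abs(np.mean(amps) - pattern.amp_mean_pA) < 0.05 * pattern.amp_mean_pA

    def test_sources_lie_on_grid_and_plan_matches_sources(self, grid):
        cohort = generate_cohort_truth(50, grid, PatternParams(), seed=2)
        for _, truth in cohort:
            cols = set()
            for s in truth.sources:
                assert 1 <= s.row <= grid.n_rows
                assert 1 <= s.col <= grid.n_cols
                assert 1 <= s.n_presyn <= 5
                cols.add(s.col)
            plan_cols = {
                c for start, end in truth.cluster_plan
                for c in range(start, end + 1)
            }
            assert cols == plan_cols

    def test_same_seed_same_cohort(self, grid):
        a = generate_cohort_truth(10, grid, PatternParams(), seed=77)
        b = generate_cohort_truth(10, grid, PatternParams(), seed=77)
        for (ca, ta), (cb, tb) in zip(a, b):
            assert ca == cb
            assert ta.sources == tb.sources
            assert ta.cluster_plan == tb.cluster_plan

    def test_jitter_calibration_formula(self, grid):
        pattern = PatternParams()
        jitter = jitter_for_target_r(pattern, grid, target_r=0.6)
        # sd(CM) for the default anchor range is a few hundred um; the
        # calibrated jitter must scale it by sqrt(1/0.36 - 1) ~ 1.333
        probe = replace(pattern, jitter_sd_um=0.0)
        cohort = generate_cohort_truth(400, grid, probe, seed=719)
        sd_cm = np.std([
            connectivity_cm(truth_maps(t, grid)[1]) for _, t in cohort
        ])
        assert jitter == pytest.approx(sd_cm * np.sqrt(1 / 0.36 - 1), rel=0.05)


class TestSweepSynthesis:
    def test_fixed_seed_byte_identical(self, small_grid):
        truth = GroundTruth("c", [SourceSite(2, 3, 2, 40.0)], [(3, 3)])
        noise = NoiseModel(duration_ms=200.0)
        a = simulate_sweepset(truth, noise, small_grid, seed=5)
        b = simulate_sweepset(truth, noise, small_grid, seed=5)
        for sa, sb in zip(a, b):
            assert sa.site == sb.site and sa.repetition == sb.repetition
            assert sa.samples.tobytes() == sb.samples.tobytes()

    def test_sweep_geometry(self, small_grid):
        noise = NoiseModel()
        sweeps = simulate_sweepset(GroundTruth("c", [], []), noise,
                                   small_grid, seed=0)
        assert len(sweeps) == small_grid.n_sites * noise.n_reps
        sw = sweeps[0]
        assert sw.stim_onset_ms == 100.0
        assert sw.duration_ms == pytest.approx(550.0)
        assert sw.sampling_rate_hz == noise.sampling_rate_hz

    def test_noise_only_windows_stay_below_threshold(self, grid):
        # source-free, spontaneous-free sweeps: the 3-SD detector should
        # cross on far fewer than 1% of response windows
        noise = NoiseModel(spont_rate_hz=0.0)
        truth = GroundTruth("c", [], [])
        crossings = total = 0
        for seed in range(3):
            sweeps = simulate_sweepset(truth, noise, grid, seed=seed)
            arr = np.stack([sw.samples for sw in sweeps])
            _, det = detect_arrays(arr, noise.sampling_rate_hz, noise.baseline_ms)
            crossings += int(det.sum())
            total += det.size
        assert crossings / total < 0.01

    def test_baseline_sd_matches_configuration(self, small_grid):
        noise = NoiseModel(spont_rate_hz=0.0)
        sweeps = simulate_sweepset(GroundTruth("c", [], []), noise,
                                   small_grid, seed=3)
        arr = np.stack([sw.samples for sw in sweeps])
        sds = arr[:, :500].std(axis=1)
        assert np.mean(sds) == pytest.approx(noise.baseline_sd_pA, rel=0.05)

    def test_single_source_recovered_across_seeds(self, small_grid):
        # 40 pA source against default noise (spontaneous events included):
        # the site must be recovered as connected in >= 95% of runs
        truth = GroundTruth("c", [SourceSite(2, 3, 1, 40.0)], [(3, 3)])
        noise = NoiseModel()
        hits = 0
        for seed in range(100):
            sweeps = simulate_sweepset(truth, noise, small_grid, seed=seed)
            _, cmap = build_maps(sweeps, small_grid)
            hits += bool(cmap.connected[1, 2])
        assert hits >= 95

    def test_evoked_peak_lands_in_detection_window(self, small_grid):
        truth = GroundTruth("c", [SourceSite(1, 1, 1, 60.0)], [(1, 1)])
        noise = NoiseModel(spont_rate_hz=0.0, baseline_sd_pA=0.01,
                           rep_amp_cv=0.02, duration_ms=200.0)
        sweeps = simulate_sweepset(truth, noise, small_grid, seed=8)
        fs = noise.sampling_rate_hz
        onset = int(100e-3 * fs)
        for sw in sweeps:
            if sw.site == (1, 1):
                peak_idx = int(np.argmin(sw.samples))
                assert onset < peak_idx < onset + int(50e-3 * fs)
                assert -sw.samples[peak_idx] == pytest.approx(60.0, rel=0.1)


class TestPipelineIdentityOracle:
    def test_noiseless_pipeline_recovers_planned_clusters(self, grid):
        # jitter 0, no spontaneous activity, tiny noise: simulate -> detect
        # -> cluster metrics must reproduce the plan exactly
        from lspsmap.map_metrics import collapse_and_clusters

        pattern = PatternParams(jitter_sd_um=0.0)
        noise = NoiseModel(spont_rate_hz=0.0, baseline_sd_pA=0.01)
        cohort = generate_cohort_truth(5, grid, pattern, seed=31)
        rng = np.random.default_rng(31)
        for cell, truth in cohort:
            sweeps = simulate_sweepset(truth, noise, grid, seed=rng)
            _, cmap = build_maps(sweeps, grid)
            _, clusters = collapse_and_clusters(cmap)
            assert [(c.start_col, c.end_col) for c in clusters] == \
                truth.cluster_plan


class TestExcitationProfiles:
    def test_zero_radius_fires_soma_only(self):
        prof = simulate_excitation_profile(excitation_radius_um=0.0, seed=0)
        assert prof.sap == 1
        assert prof.ap_counts[prof.soma_site[0] - 1, prof.soma_site[1] - 1] >= 1
        assert excitation_radius(prof) == 0.0

    def test_radius_75_keeps_firing_within_75_um(self):
        for seed in range(5):
            prof = simulate_excitation_profile(excitation_radius_um=75.0,
                                               seed=seed)
            assert excitation_radius(prof) <= 75.0

    def test_radius_60_is_plus_shaped_on_50um_grid(self):
        # 50 um neighbours are in range; 70.7 um diagonals are not
        prof = simulate_excitation_profile(excitation_radius_um=60.0, seed=1)
        r0, c0 = prof.soma_site
        firing = {(r + 1, c + 1) for r, c in zip(*np.nonzero(prof.ap_counts))}
        assert firing == {(r0, c0), (r0 - 1, c0), (r0 + 1, c0),
                          (r0, c0 - 1), (r0, c0 + 1)}

    def test_spikes_per_site_between_one_and_two(self):
        prof = simulate_excitation_profile("L5b_nonRS",
                                           excitation_radius_um=100.0, seed=3)
        assert 1.0 <= prof.spikes_per_firing_site <= 2.0
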