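import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lspsmap.map_metrics import (
    Cluster,
    cell_pattern_metrics,
    cohort_metrics,
    collapse_and_clusters,
    column_count,
    dominant_cluster_ratio,
    field_metrics,
    find_clusters,
    layer_summary,
)
from lspsmap.model_io import CellRecord, ConnectivityMap, GridSpec, InputMap

from conftest import random_connectivity


def brute_force_runs(profile):
    """Independent oracle: scan the profile column by column."""
    runs, start = [], None
    for i, v in enumerate(list(profile) + [False]):
        if v and start is None:
            start = i + 1
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    return runs


def cmap_from_profile(profile, grid):
    connected = np.zeros(grid.shape, dtype=bool)
    connected[0, :] = profile
    return ConnectivityMap(grid, connected)


class TestClusters:
    def test_example_profile(self, grid):
        profile = np.zeros(grid.n_cols, dtype=bool)
        profile[[1, 2, 5]] = True  # columns 2, 3, 6
        clusters = find_clusters(profile)
        assert [(c.start_col, c.end_col) for c in clusters] == [(2, 3), (6, 6)]

    def test_fully_connected_profile(self, grid):
        clusters = find_clusters(np.ones(grid.n_cols, dtype=bool))
        assert len(clusters) == 1
        assert clusters[0].n_sites == 29

    def test_empty_profile_gives_empty_list(self, grid):
        assert find_clusters(np.zeros(grid.n_cols, dtype=bool)) == []

    def test_collapse_marks_column_with_any_connected_row(self, grid):
        connected = np.zeros(grid.shape, dtype=bool)
        connected[9, 4] = True   # deep row
        connected[0, 4] = True   # superficial row, same column
        connected[15, 20] = True
        profile, clusters = collapse_and_clusters(ConnectivityMap(grid, connected))
        assert profile.sum() == 2
        assert [(c.start_col, c.end_col) for c in clusters] == [(5, 5), (21, 21)]

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.booleans(), min_size=1, max_size=29))
    def test_matches_brute_force_oracle(self, profile):
        clusters = find_clusters(np.array(profile, dtype=bool))
        assert [(c.start_col, c.end_col) for c in clusters] == \
            brute_force_runs(profile)

    def test_random_maps_match_oracle(self, grid, rng):
        for _ in range(200):
            cmap = ConnectivityMap(
                grid, random_connectivity(rng, grid, rng.uniform(0.0, 0.3)))
            profile, clusters = collapse_and_clusters(cmap)
            assert [(c.start_col, c.end_col) for c in clusters] == \
                brute_force_runs(profile)


class TestColumnCount:
    @pytest.mark.parametrize("sizes,expected", [
        ([1], 1),        # ceiling(1/2)
        ([3], 2),        # ceiling(3/2)
        ([2, 2, 5], 5),  # 1 + 1 + 3
        ([2], 1),
        ([6], 3),
    ])
    def test_ceiling_formula(self, sizes, expected):
        col = 1
        clusters = []
        for s in sizes:
            clusters.append(Cluster(col, col + s - 1))
            col += s + 1
        assert column_count(clusters) == expected

    def test_monotone_under_added_columns(self, grid, rng):
        for _ in range(50):
            profile = rng.random(grid.n_cols) < 0.2
            off = np.nonzero(~profile)[0]
            if off.size == 0:
                continue
            grown = profile.copy()
            grown[rng.choice(off)] = True
            assert column_count(find_clusters(grown)) >= \
                column_count(find_clusters(profile))


class TestInputField:
    def test_single_site_field(self, grid):
        f = field_metrics([Cluster(4, 4)], grid)
        assert f.width_um == 75.0
        assert f.gap_fraction_pct == 0.0
        assert f.cluster_spacings_um == []
        assert f.total_columns == 1

    def test_two_cluster_example(self, grid):
        f = field_metrics([Cluster(2, 3), Cluster(6, 6)], grid)
        assert f.cluster_spacings_um == [150.0]  # 2 gap sites x 75
        assert f.width_um == 5 * 75.0            # columns 2..6
        assert f.gap_fraction_pct == pytest.approx(40.0)  # 2 of 5 columns

    def test_widely_spaced_single_site_clusters(self, grid):
        f = field_metrics([Cluster(1, 1), Cluster(13, 13)], grid)
        assert f.cluster_spacings_um == [825.0]
        assert 75.0 <= f.cluster_spacings_um[0] <= 900.0

    def test_requires_a_cluster(self, grid):
        with pytest.raises(ValueError):
            field_metrics([], grid)

    def test_width_bookkeeping_conserved(self, grid, rng):
        # sum of cluster widths + sum of gap widths == field width
        for _ in range(100):
            profile = rng.random(grid.n_cols) < rng.uniform(0.05, 0.4)
            clusters = find_clusters(profile)
            if not clusters:
                continue
            f = field_metrics(clusters, grid)
            total = sum(c.width_um for c in clusters) + sum(f.cluster_spacings_um)
            assert total == pytest.approx(f.width_um)

    def test_gap_zero_iff_single_cluster(self, grid, rng):
        for _ in range(100):
            profile = rng.random(grid.n_cols) < rng.uniform(0.05, 0.4)
            clusters = find_clusters(profile)
            if not clusters:
                continue
            f = field_metrics(clusters, grid)
            assert (f.gap_fraction_pct == 0.0) == (len(clusters) == 1)


class TestLayerSummary:
    def test_empty_map(self, grid):
        summary = layer_summary(InputMap(grid, np.zeros(grid.shape)))
        assert (summary["epsc_total_pA"] == 0).all()
        assert not summary["connected"].any()

    def test_single_l5a_site(self, grid):
        amps = np.zeros(grid.shape)
        amps[9, 4] = 40.0  # row 10 = L5a
        summary = layer_summary(InputMap(grid, amps))
        assert summary.loc["L5a", "epsc_total_pA"] == 40.0
        assert summary.loc["L5a", "n_sites"] == 1
        others = summary.drop("L5a")
        assert (others["epsc_total_pA"] == 0).all()

    def test_layer_totals_conserve_whole_map_sum(self, grid, rng):
        amps = np.where(rng.random(grid.shape) < 0.2,
                        rng.uniform(10, 80, grid.shape), 0.0)
        summary = layer_summary(InputMap(grid, amps))
        assert summary["epsc_total_pA"].sum() == pytest.approx(amps.sum())


class TestDominantClusterRatio:
    def _map_with_cluster_sums(self, grid, sums):
        amps = np.zeros(grid.shape)
        clusters = []
        col = 1
        for s in sums:
            amps[0, col - 1] = s
            clusters.append(Cluster(col, col))
            col += 2
        return InputMap(grid, amps), clusters

    @pytest.mark.parametrize("sums,expected", [
        ([40.0, 40.0], 1.0),
        ([100.0, 50.0], 2.0),
        ([60.0, 30.0, 10.0], 3.0),  # 60 / mean(30, 10)
    ])
    def test_mean_of_others(self, grid, sums, expected):
        imap, clusters = self._map_with_cluster_sums(grid, sums)
        assert dominant_cluster_ratio(imap, clusters) == pytest.approx(expected)

    def test_total_of_others_variant(self, grid):
        imap, clusters = self._map_with_cluster_sums(grid, [60.0, 30.0, 10.0])
        assert dominant_cluster_ratio(imap, clusters, others="total") == \
            pytest.approx(1.5)

    def test_requires_two_clusters(self, grid):
        imap, clusters = self._map_with_cluster_sums(grid, [40.0])
        with pytest.raises(ValueError):
            dominant_cluster_ratio(imap, clusters)


class TestCohortTable:
    def test_empty_map_cells_excluded_and_reported(self, grid, rng):
        amps = np.zeros(grid.shape)
        amps[9, 3] = 40.0
        cells = [CellRecord("a", "s0", 100.0), CellRecord("b", "s0", 200.0)]
        maps = {"a": InputMap(grid, amps), "b": InputMap(grid, np.zeros(grid.shape))}
        table, empty = cohort_metrics(cells, maps)
        assert list(table["cell_id"]) == ["a"]
        assert empty == ["b"]
        row = table.iloc[0]
        assert row["n_clusters"] == 1
        assert row["field_width_um"] == 75.0
        assert row["epsc_L5a_pA"] == 40.0
        assert np.isnan(row["dominant_ratio"])
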