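"""Unit tests for spatial partitions, pooling, temporal filtering and
reference-map scoring."""

import numpy as np
import pytest

from spikesym import (
    Arena,
    GridSpec,
    PerturbationSpec,
    Region,
    Partitioning,
    ScoreSeries,
    Shell,
    SpikeMap,
    ValidationError,
    block_average,
    covariate_correlation,
    generate_grid_map,
    global_scores,
    grid_partitioning,
    partition_means,
    pool_cells,
    reference_scores,
    score_spike_map,
    strip_partitioning,
    temporal_filter,
    temporal_transition,
)
from spikesym.classify import psi_pipeline

ARENA = Arena(0, 1, 0, 1)
SHELL = Shell.hexagonal(0.5)


class TestPartitionMeans:
    def test_single_region_equals_global(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        parts = grid_partitioning(perfect_map.arena, 1, 1)
        summary = partition_means(scores, perfect_map, parts)
        g = global_scores(scores)
        assert summary.mean_psi[0] == pytest.approx(g.psi, abs=1e-12)
        assert summary.theta_deg[0] == pytest.approx(g.theta_deg, abs=1e-9)
        assert summary.n_spikes[0] == perfect_map.n_spikes

    def test_east_jitter_degrades_east_strips(self):
        # noise on field locations applied only in the eastern half:
        # scores decay along the west-east axis. Per cell the west strip
        # beats the east strip; the full three-strip gradient emerges in
        # the mean over cells (single-cell middle/east ordering is noisy
        # once scores approach the floor).
        wins = 0
        all_means = []
        for s in range(10):
            sm = generate_grid_map(
                GridSpec(seed=100 + s),
                PerturbationSpec(jitter_sigma=0.1, region=(0.5, 1.0, 0.0, 1.0)),
            )
            result = psi_pipeline(sm, shell_mode="cutoff")
            parts = strip_partitioning(sm.arena, 3, axis="x")
            means = partition_means(result.scores, sm, parts).mean_psi
            all_means.append(means)
            if means[0] > means[2]:
                wins += 1
        assert wins >= 8
        avg = np.mean(all_means, axis=0)
        assert avg[0] > avg[1] > avg[2]

    def test_empty_region_flagged_undefined(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        parts = Partitioning(
            regions=(Region("outside", rect=(2.0, 3.0, 2.0, 3.0)),)
        )
        summary = partition_means(scores, perfect_map, parts)
        assert summary.n_spikes[0] == 0
        assert np.isnan(summary.mean_psi[0])

    def test_tiling_partition_conserves_score_sum(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        parts = grid_partitioning(perfect_map.arena, 4, 3)
        summary = partition_means(scores, perfect_map, parts)
        assert summary.n_spikes.sum() == perfect_map.n_spikes
        total = np.nansum(summary.mean_psi * summary.n_spikes)
        assert total == pytest.approx(scores.psi_hat.sum(), rel=1e-9)

    def test_boundary_spike_assigned_to_exactly_one_strip(self):
        sm = SpikeMap(np.array([[0.5, 0.5], [1.0, 1.0], [0.0, 0.0]]), ARENA)
        parts = strip_partitioning(ARENA, 2, axis="x")
        idx = parts.assign(sm.positions, ARENA)
        assert idx.tolist() == [1, 1, 0]  # 0.5 goes east (half-open), 1.0 stays in


class TestPoolCells:
    def test_pooling_one_cell_is_identity(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        parts = grid_partitioning(perfect_map.arena, 2, 2)
        s1 = partition_means(scores, perfect_map, parts)
        pooled = pool_cells([s1])
        np.testing.assert_allclose(pooled.mean_psi, s1.mean_psi)
        np.testing.assert_allclose(pooled.theta_deg, s1.theta_deg)

    def test_pooling_identical_cells_is_identity(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        parts = grid_partitioning(perfect_map.arena, 2, 2)
        s1 = partition_means(scores, perfect_map, parts)
        pooled = pool_cells([s1, s1, s1])
        np.testing.assert_allclose(pooled.mean_psi, s1.mean_psi)
        np.testing.assert_allclose(pooled.theta_deg, s1.theta_deg)
        assert pooled.n_spikes.tolist() == (3 * s1.n_spikes).tolist()

    def test_pooled_east_jitter_trend(self):
        # an ensemble with random phases shows the west-east decay
        summaries = []
        rng = np.random.default_rng(0)
        for s in range(10):
            phase = tuple(rng.uniform(-0.25, 0.25, 2))
            sm = generate_grid_map(
                GridSpec(seed=300 + s, phase=phase),
                PerturbationSpec(jitter_sigma=0.1, region=(0.5, 1.0, 0.0, 1.0)),
            )
            result = psi_pipeline(sm, shell_mode="cutoff")
            parts = strip_partitioning(sm.arena, 3, axis="x")
            summaries.append(partition_means(result.scores, sm, parts))
        pooled = pool_cells(summaries)
        assert pooled.mean_psi[0] > pooled.mean_psi[1] > pooled.mean_psi[2]

    def test_mismatched_partitionings_rejected(self, perfect_map):
        scores = score_spike_map(perfect_map, SHELL)
        a = partition_means(scores, perfect_map, grid_partitioning(ARENA, 2, 1))
        b = partition_means(scores, perfect_map, grid_partitioning(ARENA, 3, 1))
        with pytest.raises(ValidationError):
            pool_cells([a, b])


class TestTemporalFilter:
    def test_constant_scores_stay_constant(self):
        series = ScoreSeries(times=np.arange(100.0), values=np.full(100, 0.4))
        out = temporal_filter(series, window=20.0)
        np.testing.assert_allclose(out.smoothed, 0.4)

    def test_zero_window_is_identity_for_distinct_times(self):
        rng = np.random.default_rng(0)
        series = ScoreSeries(times=np.arange(50.0), values=rng.uniform(0, 1, 50))
        out = temporal_filter(series, window=0.0)
        np.testing.assert_allclose(out.smoothed, series.values, rtol=1e-12)

    def test_commutes_with_time_translation(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 100, 80))
        v = rng.uniform(0, 1, 80)
        a = temporal_filter(ScoreSeries(times=t, values=v), window=10.0)
        b = temporal_filter(ScoreSeries(times=t + 1234.5, values=v), window=10.0)
        np.testing.assert_allclose(a.smoothed, b.smoothed)

    def test_uniform_to_grid_switch_rises_within_window(self):
        sm = temporal_transition(GridSpec(seed=8), n_uniform=1000, n_grid=1000)
        result = psi_pipeline(sm, shell_mode="cutoff")
        series = temporal_filter(
            ScoreSeries(times=sm.times, values=result.scores.psi_hat), window=100.0
        )
        before = series.smoothed[(sm.times > 700) & (sm.times < 900)].mean()
        after = series.smoothed[(sm.times > 1100) & (sm.times < 1300)].mean()
        assert after > before + 0.1

    def test_missing_times_rejected(self):
        with pytest.raises(ValidationError):
            ScoreSeries(times=np.array([2.0, 1.0]), values=np.array([0.0, 0.0]))


class TestReferenceScores:
    def test_self_scoring_reproduces_pipeline_exactly(self, perfect_map):
        own = score_spike_map(perfect_map, SHELL)
        ref = reference_scores(perfect_map, perfect_map, SHELL)
        np.testing.assert_array_equal(ref.psi_hat, own.psi_hat)
        np.testing.assert_array_equal(
            np.nan_to_num(ref.theta_deg), np.nan_to_num(own.theta_deg)
        )
        np.testing.assert_array_equal(ref.n_neighbors, own.n_neighbors)

    def test_query_far_from_reference_scores_zero(self, perfect_map):
        query = SpikeMap(np.array([[0.5, 0.5]]), Arena(-10, 10, -10, 10))
        far_ref = SpikeMap(perfect_map.positions + 8.0, Arena(-10, 10, -10, 10))
        scores = reference_scores(query, far_ref, SHELL)
        assert scores.n_neighbors[0] == 0
        assert scores.psi_hat[0] == 0.0

    def test_query_at_field_center_scores_like_reference(self):
        sm = generate_grid_map(GridSpec(seed=21))
        own = global_scores(score_spike_map(sm, SHELL)).psi
        probe = SpikeMap(np.array([[0.5, 0.5]]), sm.arena)
        scored = reference_scores(probe, sm, SHELL)
        # a probe inside the pattern should look like a typical good spike
        assert 0.0 <= scored.psi_hat[0] <= 1.0


class TestBlockAverage:
    def _scores(self, psi):
        from spikesym.types import SpikeScores

        n = len(psi)
        return SpikeScores(
            psi_hat=np.asarray(psi, dtype=float),
            theta_deg=np.full(n, np.nan),
            n_neighbors=np.ones(n, dtype=int),
            psi_mag={},
        )

    def test_twelve_blocks_per_label(self):
        times = np.arange(0.0, 480.0)  # four 2-minute trials
        labels = np.where((times // 120) % 2 == 0, "light", "dark")
        out = block_average(
            self._scores(np.ones_like(times)), times, trial_len=120, block_len=10,
            trial_labels=labels,
        )
        assert (out.groupby("label")["block"].nunique() == 12).all()

    def test_constant_scores_give_equal_blocks(self):
        times = np.arange(0.0, 240.0)
        labels = np.full(times.shape, "light")
        out = block_average(self._scores(np.full(times.shape, 0.3)), times, 120, 10, labels)
        filled = out.dropna(subset=["mean_psi"])
        np.testing.assert_allclose(filled["mean_psi"], 0.3)

    def test_grid_trials_beat_uniform_trials_in_every_block(self):
        # "light" spikes come from the grid, "dark" spikes are uniform;
        # scored against the light-only reference map
        spec = GridSpec(seed=31, n_spikes=1440)
        grid = generate_grid_map(spec)
        rng = np.random.default_rng(31)
        uni = rng.uniform(0, 1, (1440, 2))
        pos = np.empty((2880, 2))
        times = np.arange(2880.0)
        trial = (times // 120).astype(int)
        light = trial % 2 == 0
        pos[light] = grid.positions
        pos[~light] = uni
        sm = SpikeMap(pos, ARENA, times=times)
        ref = SpikeMap(pos[light], ARENA)
        scores = reference_scores(sm, ref, SHELL)
        labels = np.where(light, "light", "dark")
        out = block_average(scores, times, 120, 10, labels)
        pivot = out.pivot(index="block", columns="label", values="mean_psi")
        assert (pivot["light"] > pivot["dark"]).all()

    def test_indivisible_block_length_rejected(self):
        with pytest.raises(ValidationError):
            block_average(self._scores([1.0]), np.array([0.0]), 120, 13, ["a"])


class TestCovariateCorrelation:
    def test_identical_series_gives_one(self):
        t = np.arange(50.0)
        v = np.sin(t / 10) ** 2
        series = ScoreSeries(times=t, values=v)
        assert covariate_correlation(series, v.copy()) == pytest.approx(1.0)

    def test_independent_covariate_near_zero(self, rng):
        rs = []
        for _ in range(20):
            t = np.arange(200.0)
            series = ScoreSeries(times=t, values=rng.uniform(0, 1, 200))
            rs.append(covariate_correlation(series, rng.uniform(0, 1, 200)))
        assert abs(np.mean(rs)) < 0.1

    def test_zero_variance_flagged(self):
        series = ScoreSeries(times=np.arange(5.0), values=np.ones(5))
        assert np.isnan(covariate_correlation(series, np.arange(5.0)))

    def test_light_dark_degradation_detected(self):
        # grid firing in "light", uniform in "dark": the smoothed score
        # correlates positively with the lighting condition
        rs = []
        for s in range(5):
            sm = temporal_transition(GridSpec(seed=400 + s), n_uniform=800, n_grid=800)
            result = psi_pipeline(sm, shell_mode="cutoff")
            series = temporal_filter(
                ScoreSeries(times=sm.times, values=result.scores.psi_hat), window=60.0
            )
            covariate = (sm.times > 800).astype(float)  # 0 = uniform, 1 = grid
            rs.append(covariate_correlation(series, covariate))
        assert all(r > 0 for r in rs)
        assert np.mean(rs) > 0.3
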