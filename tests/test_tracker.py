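"""Association, track building and velocity extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bactrack import (FeatureWeights, OpticalConfig, associate, build_tracks,
                      cost_matrix, normalize_features, track_velocities)
from bactrack.particles import FEATURE_COLUMNS
from bactrack.tracker import CostMatrix, Track, TrackSet


def make_table(rows):
    """Particle table from dicts; unspecified characteristics default to
    plausible rod values."""
    defaults = {"perimeter": 40.0, "area": 80.0, "orientation": 0.0,
                "length": 20.0, "width": 7.0}
    out = []
    for r in rows:
        d = {"frame": 0, **defaults, **r}
        out.append(d)
    return pd.DataFrame(out, columns=["frame"] + FEATURE_COLUMNS)


def brute_force_min_cost(cost):
    """Exhaustive minimum over all complete one-to-one assignments."""
    n, m = cost.shape
    if n > m:
        return brute_force_min_cost(cost.T)
    return min(sum(cost[i, j] for i, j in enumerate(cols))
               for cols in itertools.permutations(range(m), n))


class TestNormalize:
    def test_constant_characteristic_scales_to_one(self):
        table = make_table([{"cm_x": 10, "cm_y": 5, "area": 25},
                            {"cm_x": 30, "cm_y": 5, "area": 25}])
        norm, scales = normalize_features(table)
        assert np.all(norm["area"] == 1.0)
        assert scales["area"] == 25

    def test_median_scaling_by_hand(self):
        table = make_table([{"cm_x": 1, "cm_y": 1, "area": 10},
                            {"cm_x": 2, "cm_y": 2, "area": 30}])
        norm, _ = normalize_features(table)
        assert sorted(norm["area"]) == [0.5, 1.5]

    def test_idempotent(self):
        table = make_table([{"cm_x": 100, "cm_y": 40, "area": 60},
                            {"cm_x": 220, "cm_y": 90, "area": 85}])
        once, _ = normalize_features(table)
        twice, _ = normalize_features(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            normalize_features(make_table([]).iloc[0:0])


class TestCostMatrix:
    def test_identical_particle_costs_zero(self):
        t = make_table([{"cm_x": 10, "cm_y": 10}])
        e = cost_matrix(t, t.copy())
        assert e.entries[0, 0] == 0.0
        assert e.admissible[0, 0]

    def test_unit_weight_l1_sum_by_hand(self):
        a = make_table([{"cm_x": 10, "cm_y": 10, "area": 25}])
        b = make_table([{"cm_x": 13, "cm_y": 14, "area": 25}])
        w = FeatureWeights(cm_x=1, cm_y=1, perimeter=1, area=1,
                           orientation=1, length=1, width=1)
        e = cost_matrix(a, b, weights=w)
        assert e.entries[0, 0] == pytest.approx(7.0)  # |3| + |4|

    def test_displacement_beyond_gate_is_inadmissible(self):
        a = make_table([{"cm_x": 0, "cm_y": 0}])
        b = make_table([{"cm_x": 50, "cm_y": 0}])
        e = cost_matrix(a, b, gate_px=30)
        assert not e.admissible[0, 0]

    def test_empty_frame_gives_empty_matrix(self):
        a = make_table([{"cm_x": 0, "cm_y": 0}])
        e = cost_matrix(a, a.iloc[0:0])
        assert e.entries.shape == (1, 0)


class TestAssociate:
    @staticmethod
    def cm(entries):
        entries = np.asarray(entries, float)
        return CostMatrix(entries=entries,
                          admissible=np.ones(entries.shape, bool),
                          gate_px=np.inf)

    def test_single_pair(self):
        matches, dis, app = associate(self.cm([[3.0]]))
        assert matches == [(0, 0)] and dis == [] and app == []

    def test_crossing_prefers_swapped_matching(self):
        matches, _, _ = associate(self.cm([[5.0, 2.0], [2.0, 5.0]]))
        assert sorted(matches) == [(0, 1), (1, 0)]

    def test_rectangular_matrix_reports_disappearance(self):
        matches, dis, app = associate(self.cm([[1.0], [2.0]]))
        assert len(matches) == 1 and len(dis) == 1 and app == []

    def test_inadmissible_entries_become_unmatched(self):
        e = self.cm([[1.0, 9.0], [9.0, 1.0]])
        e.admissible[:] = [[False, False], [False, True]]
        matches, dis, app = associate(e)
        assert matches == [(1, 1)]
        assert dis == [0] and app == [0]

    def test_no_double_assignment_and_optimal_on_random_matrices(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 7))
            cost = rng.random((n, m)) * 10
            matches, dis, app = associate(self.cm(cost))
            assert len({i for i, _ in matches}) == len(matches)
            assert len({j for _, j in matches}) == len(matches)
            total = sum(cost[i, j] for i, j in matches)
            assert total == pytest.approx(brute_force_min_cost(cost))


def straight_line_table(n_frames=30, step=10.0, drop_frames=(), y=50.0):
    rows = [{"frame": f, "cm_x": 20.0 + step * f, "cm_y": y}
            for f in range(n_frames) if f not in drop_frames]
    return make_table(rows)


class TestBuildTracks:
    def test_full_length_track(self):
        table = straight_line_table()
        norm, scales = normalize_features(table)
        ts = build_tracks(norm, 30, scales=scales)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 30
        assert ts.tracks[0].n_gaps == 0

    def test_single_missing_frame_is_gap_closed(self):
        table = straight_line_table(drop_frames={14})
        norm, scales = normalize_features(table)
        ts = build_tracks(norm, 30, max_gap=1, scales=scales)
        assert len(ts) == 1
        t = ts.tracks[0]
        assert len(t) == 29
        assert t.n_gaps == 1
        assert 14 not in t.frames

    def test_gap_longer_than_max_gap_splits_track(self):
        table = straight_line_table(drop_frames={10, 11, 12})
        norm, scales = normalize_features(table)
        ts = build_tracks(norm, 30, max_gap=1, min_track_len=5,
                          scales=scales)
        assert len(ts) == 2

    def test_spurious_single_detection_removed(self):
        table = pd.concat([straight_line_table(),
                           make_table([{"frame": 12, "cm_x": 300.0,
                                        "cm_y": 200.0}])],
                          ignore_index=True)
        norm, scales = normalize_features(table)
        ts = build_tracks(norm, 30, min_track_len=5, scales=scales)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 30


class TestVelocities:
    optics = OpticalConfig()

    def test_stationary_track_zero_speed(self):
        t = Track(id=0, frames=list(range(10)), xs=[5.0] * 10, ys=[7.0] * 10)
        res = track_velocities(TrackSet([t]), self.optics,
                               particles_per_frame=[1] * 10)
        assert res.mean_velocity == 0.0
        assert res.n_vectors == 9

    def test_ten_pixels_per_frame_is_28_26_um_s(self):
        t = Track(id=0, frames=[0, 1, 2], xs=[0.0, 10.0, 20.0],
                  ys=[0.0, 0.0, 0.0])
        res = track_velocities(TrackSet([t]), self.optics)
        assert res.mean_velocity == pytest.approx(28.26)

    def test_3_4_5_displacement(self):
        t = Track(id=0, frames=[0, 1], xs=[0.0, 3.0], ys=[0.0, 4.0])
        res = track_velocities(TrackSet([t]), self.optics)
        assert res.mean_velocity == pytest.approx(14.13)

    def test_gap_step_uses_elapsed_time(self):
        # 20 px over 2 frame intervals -> same speed as 10 px over 1
        t = Track(id=0, frames=[0, 2], xs=[0.0, 20.0], ys=[0.0, 0.0])
        res = track_velocities(TrackSet([t]), self.optics)
        assert res.mean_velocity == pytest.approx(28.26)

    def test_empty_trackset(self):
        res = track_velocities(TrackSet([]), self.optics)
        assert res.n_vectors == 0
        assert np.isnan(res.mean_velocity)
        assert res.qc_flag == "ok"

    def test_crowding_flag(self):
        t = Track(id=0, frames=[0, 1], xs=[0.0, 1.0], ys=[0.0, 0.0])
        res = track_velocities(TrackSet([t]), self.optics,
                               particles_per_frame=[16, 17])
        assert res.qc_flag == "too_crowded"
        res = track_velocities(TrackSet([t]), self.optics,
                               particles_per_frame=[15, 15])
        assert res.qc_flag == "ok"
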