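import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamellikine import synthetic_data as sd
from lamellikine import track_metrics as tm


def make_track(positions, frame_interval=5.0, cell_id="t"):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(len(positions)) * frame_interval
    return tm.Track(cell_id, times, positions)


# ---------------------------------------------------------------------------
# Track validation
# ---------------------------------------------------------------------------

class TestTrack:
    def test_rejects_single_point(self):
        with pytest.raises(tm.TrackMetricsError):
            tm.Track("x", np.array([0.0]), np.zeros((1, 2)))

    def test_rejects_nonuniform_spacing(self):
        with pytest.raises(tm.TrackMetricsError):
            tm.Track("x", np.array([0.0, 5.0, 11.0]), np.zeros((3, 2)))

    def test_rejects_nonfinite(self):
        with pytest.raises(tm.TrackMetricsError):
            make_track([[0, 0], [np.nan, 1]])

    def test_frame_interval(self, straight_track):
        assert straight_track.frame_interval == 5.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadTracks:
    def test_unit_conversion(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_px,y_px\n1,0,10,4\n1,1,12,8\n")
        tracks = tm.read_tracks(p, frame_interval=5.0, pixel_size=0.5)
        np.testing.assert_allclose(tracks[0].positions, [[5, 2], [6, 4]])

    def test_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_px,y_px\n1,0,0,0\n1,0,1,1\n1,1,2,2\n")
        with pytest.raises(tm.TrackMetricsError, match="duplicate"):
            tm.read_tracks(p, 5.0, 1.0)

    def test_missing_frame_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_px,y_px\n7,0,0,0\n7,2,1,1\n")
        with pytest.raises(tm.TrackMetricsError, match="7"):
            tm.read_tracks(p, 5.0, 1.0)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_px,y_px\n1,0,0,0\n1,1,abc,1\n")
        with pytest.raises(tm.TrackMetricsError, match="row 3"):
            tm.read_tracks(p, 5.0, 1.0)

    def test_write_read_roundtrip(self, tmp_path):
        params = sd.CRWParams(n_frames=25, frame_interval=5.0, seed=3)
        track, _ = sd.simulate_crw(params)
        p = tmp_path / "rt.csv"
        tm.write_tracks([track], p, pixel_size=0.65)
        back = tm.read_tracks(p, frame_interval=5.0, pixel_size=0.65)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].positions, track.positions)
        np.testing.assert_allclose(back[0].times, track.times)

    def test_fiji_shim_normalises_one_based_slices(self, tmp_path):
        p = tmp_path / "fiji.csv"
        p.write_text(" ,Track n°,Slice n°,X,Y\n0,1,1,10,20\n1,1,2,11,21\n")
        tracks = tm.read_fiji_manual_tracking(p, 5.0, 1.0)
        assert tracks[0].times[0] == 0.0
        np.testing.assert_allclose(tracks[0].positions[0], [10, 20])


# ---------------------------------------------------------------------------
# Displacements and speed
# ---------------------------------------------------------------------------

class TestIntervalDisplacements:
    def test_constant_velocity(self, straight_track):
        d = tm.interval_displacements(straight_track, 15.0)
        np.testing.assert_allclose(d, 15.0)

    def test_remainder_frames_discarded(self):
        track = make_track(np.column_stack([np.arange(10), np.zeros(10)]),
                           frame_interval=1.0)
        d = tm.interval_displacements(track, 3.0)
        assert len(d) == 3  # frames 0-3-6-9: frame 9 is used; 10th frame absent

    def test_ten_frames_k3_gives_three(self):
        track = make_track(np.column_stack([np.arange(11), np.zeros(11)]),
                           frame_interval=1.0)
        # 11 points = 10 steps -> 0,3,6,9 usable; remainder (9->10) discarded
        assert len(tm.interval_displacements(track, 3.0)) == 3

    def test_closed_loops_give_zero(self):
        cycle = np.array([[0, 0], [1, 0], [0, 1]] * 3 + [[0, 0]], dtype=float)
        track = make_track(cycle, frame_interval=1.0)
        d = tm.interval_displacements(track, 3.0)
        np.testing.assert_allclose(d, 0.0)

    def test_non_multiple_rejected(self, straight_track):
        with pytest.raises(tm.TrackMetricsError):
            tm.interval_displacements(straight_track, 7.0)


class TestMeanTrackSpeed:
    def test_straight_unit_speed(self, straight_track):
        for dt in (5.0, 15.0, 25.0):
            assert tm.mean_track_speed(straight_track, dt) == pytest.approx(1.0)

    def test_stationary(self, stationary_track):
        assert tm.mean_track_speed(stationary_track, 5.0) == 0.0

    def test_recovers_generating_speed(self):
        # simulation oracle at delta_t = frame interval, noise free
        params = sd.CRWParams(n_frames=60, frame_interval=5.0, speed_mean=0.6,
                              speed_sd=0.2, kappa=2.0, noise_sd=0.0, seed=0)
        tracks = sd.simulate_crw_population(params, 200)
        speeds = [tm.mean_track_speed(t, 5.0) for t in tracks]
        assert np.mean(speeds) == pytest.approx(0.6, rel=0.05)

    def test_too_short_track_rejected(self):
        track = make_track([[0, 0], [1, 0]], frame_interval=5.0)
        with pytest.raises(tm.TrackMetricsError):
            tm.mean_track_speed(track, 15.0)


# ---------------------------------------------------------------------------
# Directionality ratio and MTP
# ---------------------------------------------------------------------------

class TestDirectionalityRatio:
    def test_straight_window(self):
        pts = np.column_stack([np.arange(5), np.zeros(5)])
        assert tm.directionality_ratio(pts) == pytest.approx(1.0)

    def test_out_and_back(self):
        pts = np.array([[0, 0], [3, 0], [0, 0]], dtype=float)
        assert tm.directionality_ratio(pts) == 0.0

    def test_right_angle_two_intervals(self):
        # hand geometry: net = sqrt(2) d, path = 2 d
        pts = np.array([[0, 0], [1, 0], [1, 1]], dtype=float)
        assert tm.directionality_ratio(pts) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_path_convention(self):
        pts = np.zeros((4, 2))
        assert tm.directionality_ratio(pts) == 1.0


class TestMeanTrackPersistence:
    def test_straight_track_is_one_in_both_modes(self, straight_track):
        raw = tm.PersistenceParams(delta_t=15.0, TR=4, alpha_mode="raw")
        aff = tm.PersistenceParams(delta_t=15.0, TR=4, alpha_mode="affine_rw",
                                   mc_reps=50, seed=0)
        assert tm.mean_track_persistence(straight_track, raw) == pytest.approx(1.0)
        assert tm.mean_track_persistence(straight_track, aff) == pytest.approx(1.0)

    def test_out_and_back_raw_zero(self):
        # each window returns to its start
        seg = np.array([[0, 0], [1, 0], [2, 0], [1, 0], [0, 0]], dtype=float)
        pts = np.vstack([seg, seg[1:], seg[1:]])
        track = make_track(pts, frame_interval=1.0)
        params = tm.PersistenceParams(delta_t=1.0, TR=4)
        assert tm.mean_track_persistence(track, params) == 0.0

    def test_mtp_monotone_in_kappa(self):
        # simulation-ordering oracle
        mtps = {}
        for kappa in (0.0, 1.0, 8.0):
            params = sd.CRWParams(n_frames=60, frame_interval=5.0,
                                  speed_mean=0.6, speed_sd=0.2, kappa=kappa,
                                  noise_sd=0.0, seed=17)
            tracks = sd.simulate_crw_population(params, 200)
            pp = tm.PersistenceParams(delta_t=15.0, TR=4)
            mtps[kappa] = np.mean([tm.mean_track_persistence(t, pp)
                                   for t in tracks])
        assert mtps[8.0] > mtps[1.0] > mtps[0.0]

    def test_incomplete_window_rejected(self):
        track = make_track(np.column_stack([np.arange(5), np.zeros(5)]),
                           frame_interval=5.0)
        with pytest.raises(tm.TrackMetricsError):
            tm.mean_track_persistence(
                track, tm.PersistenceParams(delta_t=15.0, TR=4))

    def test_affine_mode_shrinks_random_walk_score(self):
        params = sd.CRWParams(n_frames=81, frame_interval=5.0, speed_mean=0.6,
                              speed_sd=0.0, kappa=0.0, noise_sd=0.0, seed=8)
        track, _ = sd.simulate_crw(params)
        raw = tm.mean_track_persistence(
            track, tm.PersistenceParams(delta_t=5.0, TR=4))
        aff = tm.mean_track_persistence(
            track, tm.PersistenceParams(delta_t=5.0, TR=4,
                                        alpha_mode="affine_rw",
                                        mc_reps=200, seed=0))
        assert abs(aff) < raw


class TestWindowLength:
    def test_fibronectin_settings_window_is_60_min(self):
        params = tm.PersistenceParams(delta_t=15.0, TR=4)
        assert params.window_length == 60.0

    def test_laminin_settings_window_is_50_min(self):
        params = tm.PersistenceParams(delta_t=25.0, TR=2)
        assert params.window_length == 50.0


# ---------------------------------------------------------------------------
# Usable time interval
# ---------------------------------------------------------------------------

class TestUsableTimeInterval:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth_track():
        params = sd.CRWParams(n_frames=200, frame_interval=5.0, speed_mean=0.4,
                              speed_sd=0.1, kappa=4.0, noise_sd=0.0, seed=11)
        track, _ = sd.simulate_crw(params)
        return track

    def test_noiseless_replicates_give_k1(self, truth_track):
        reps = sd.replicate_observations(truth_track, 0.0, 3, seed=0)
        dt, table = tm.usable_time_interval(reps)
        assert dt == truth_track.frame_interval
        assert table.loc[0, "ratio"] < 1e-12

    def test_ratio_non_increasing_for_directed_track(self):
        # monotonicity oracle: straight true path, fixed noise
        times = np.arange(120) * 5.0
        pos = np.column_stack([times * 0.5, np.zeros(120)])
        truth = tm.Track("dir", times, pos)
        reps = sd.replicate_observations(truth, 1.0, 10, seed=3)
        _, table = tm.usable_time_interval(reps, threshold=0.5)
        ratios = table["ratio"].to_numpy()
        assert np.all(np.diff(ratios) <= 1e-9)

    def test_noisy_track_needs_larger_interval(self, truth_track):
        reps = sd.replicate_observations(truth_track, 1.2, 10, seed=12)
        dt, _ = tm.usable_time_interval(reps)
        assert dt > truth_track.frame_interval

    def test_impossible_threshold_raises_with_table(self, truth_track):
        reps = sd.replicate_observations(truth_track, 50.0, 5, seed=1)
        with pytest.raises(tm.TrackMetricsError, match="ratio"):
            tm.usable_time_interval(reps)

    def test_mismatched_timestamps_rejected(self, truth_track):
        other = tm.Track("o", truth_track.times[:50] + 1.0,
                         truth_track.positions[:50])
        with pytest.raises(tm.TrackMetricsError):
            tm.usable_time_interval([truth_track, other])


# ---------------------------------------------------------------------------
# Population curves
# ---------------------------------------------------------------------------

class TestPersistenceProfile:
    def test_straight_population_flat_at_one(self, straight_track):
        profile = tm.persistence_profile([straight_track] * 3, TR=4,
                                         delta_t_grid=[5.0, 10.0])
        np.testing.assert_allclose(profile["mean_mtp"], 1.0)

    def test_random_walk_stays_below_one(self):
        params = sd.CRWParams(n_frames=101, frame_interval=5.0, speed_mean=0.5,
                              speed_sd=0.0, kappa=0.0, noise_sd=0.0, seed=2)
        tracks = sd.simulate_crw_population(params, 30)
        profile = tm.persistence_profile(tracks, TR=4,
                                         delta_t_grid=[5.0, 10.0, 15.0])
        assert np.all(profile["mean_mtp"] < 1.0)

    def test_noise_shifts_profile_peak_right(self):
        # quoted behaviour: low at small intervals, peak, fall-off; peak
        # moves right as positional noise grows
        grid = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]

        def peak_location(noise_sd, seed):
            base = sd.CRWParams(n_frames=150, frame_interval=5.0,
                                speed_mean=0.5, speed_sd=0.1, kappa=6.0,
                                noise_sd=noise_sd, seed=seed)
            tracks = sd.simulate_crw_population(base, 60)
            prof = tm.persistence_profile(tracks, TR=2, delta_t_grid=grid)
            return prof.loc[prof["mean_mtp"].idxmax(), "delta_t"]

        assert peak_location(2.0, 21) > peak_location(0.05, 20)

    def test_empty_grid_rejected(self, straight_track):
        with pytest.raises(tm.TrackMetricsError):
            tm.persistence_profile([straight_track], TR=4, delta_t_grid=[])


class TestMSD:
    def test_ballistic_track(self, straight_track):
        pop, _, slope = tm.mean_square_displacement([straight_track], 10)
        expected = (np.arange(1, 11) * 5.0) ** 2  # (v * lag * dt)^2, v = 1
        np.testing.assert_allclose(pop["msd"], expected)
        assert slope == pytest.approx(2.0)

    def test_stationary_track(self, stationary_track):
        pop, _, _ = tm.mean_square_displacement([stationary_track], 5)
        np.testing.assert_allclose(pop["msd"], 0.0)

    def test_max_lag_bound(self, stationary_track):
        with pytest.raises(tm.TrackMetricsError):
            tm.mean_square_displacement([stationary_track], 20)


class TestDirectionalityRatioOverTime:
    def test_straight_tracks(self, straight_track):
        curve = tm.directionality_ratio_over_time([straight_track] * 2)
        np.testing.assert_allclose(curve["mean_ratio"], 1.0)

    def test_bounded_and_decreasing_for_random_walks(self):
        params = sd.CRWParams(n_frames=200, frame_interval=5.0, speed_mean=0.5,
                              speed_sd=0.0, kappa=0.0, noise_sd=0.0, seed=3)
        tracks = sd.simulate_crw_population(params, 100)
        curve = tm.directionality_ratio_over_time(tracks)
        ratios = curve["mean_ratio"].to_numpy()
        assert np.all(ratios <= 1.0)
        # population mean decays; allow Monte-Carlo wiggle on the tail
        smoothed = pd.Series(ratios).rolling(10, min_periods=1).mean()
        assert np.all(np.diff(smoothed) < 0.01)
        assert ratios[-1] < ratios[0]

    def test_two_frame_track(self):
        track = make_track([[0, 0], [1, 1]], frame_interval=5.0)
        curve = tm.directionality_ratio_over_time([track])
        assert curve["mean_ratio"].iloc[0] == 1.0


class TestDirectionAutocorrelation:
    def test_straight_track(self, straight_track):
        ac = tm.direction_autocorrelation([straight_track], 5.0, max_lag=5)
        np.testing.assert_allclose(ac["autocorr"], 1.0)

    def test_random_walk_decorrelates(self):
        params = sd.CRWParams(n_frames=10_001, frame_interval=1.0,
                              speed_mean=1.0, speed_sd=0.0, kappa=0.0,
                              noise_sd=0.0, seed=4)
        track, _ = sd.simulate_crw(params)
        ac = tm.direction_autocorrelation([track], 1.0, max_lag=3)
        assert np.all(np.abs(ac["autocorr"]) < 0.05)

    def test_zigzag_alternates(self):
        # +90 deg / -90 deg alternating: AC(1) = 0, AC(2) = 1, ...
        steps = []
        for i in range(20):
            steps.append([1, 0] if i % 2 == 0 else [0, 1])
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)]).astype(float)
        track = make_track(pts, frame_interval=1.0)
        ac = tm.direction_autocorrelation([track], 1.0, max_lag=4)
        np.testing.assert_allclose(ac["autocorr"], [0, 1, 0, 1], atol=1e-12)

    def test_all_zero_displacements_rejected(self, stationary_track):
        with pytest.raises(tm.TrackMetricsError):
            tm.direction_autocorrelation([stationary_track], 5.0)


# ---------------------------------------------------------------------------
# Invariance properties
# ---------------------------------------------------------------------------

@st.composite
def random_tracks(draw):
    n = draw(st.integers(min_value=9, max_value=30))
    coords = draw(st.lists(
        st.tuples(st.floats(-50, 50, allow_nan=False),
                  st.floats(-50, 50, allow_nan=False)),
        min_size=n, max_size=n))
    return make_track(np.array(coords), frame_interval=5.0)


@given(random_tracks(), st.floats(0.1, 20.0),
       st.floats(0, 2 * np.pi), st.tuples(st.floats(-100, 100),
                                          st.floats(-100, 100)))
@settings(max_examples=25, deadline=None)
def test_raw_mtp_invariant_under_similarity(track, scale, angle, offset):
    params = tm.PersistenceParams(delta_t=5.0, TR=2)
    moved = track.transformed(scale=scale, rotation=angle, offset=offset)
    try:
        base = tm.mean_track_persistence(track, params)
    except tm.TrackMetricsError:
        return
    assert tm.mean_track_persistence(moved, params) == pytest.approx(
        base, abs=1e-9)


@given(random_tracks(), st.floats(0, 2 * np.pi),
       st.tuples(st.floats(-100, 100), st.floats(-100, 100)))
@settings(max_examples=25, deadline=None)
def test_mts_invariant_under_rigid_motion(track, angle, offset):
    moved = track.transformed(rotation=angle, offset=offset)
    assert tm.mean_track_speed(moved, 5.0) == pytest.approx(
        tm.mean_track_speed(track, 5.0), abs=1e-9)


@given(random_tracks())
@settings(max_examples=25, deadline=None)
def test_mts_decreases_under_subsampling(track):
    # path shortening: MTS at k * frame_interval <= MTS at frame_interval
    fine = tm.mean_track_speed(track, 5.0)
    for k in (2, 4):
        try:
            coarse = tm.mean_track_speed(track, k * 5.0)
        except tm.TrackMetricsError:
            continue
        assert coarse <= fine + 1e-9


def test_mtp_at_usable_interval_defeats_noise():
    # the chosen delta_t brings noisy MTP closer to the noise-free value
    params = sd.CRWParams(n_frames=200, frame_interval=5.0, speed_mean=0.4,
                          speed_sd=0.1, kappa=4.0, noise_sd=0.0, seed=11)
    truth, _ = sd.simulate_crw(params)
    reps = sd.replicate_observations(truth, 1.2, 10, seed=12)
    dt, _ = tm.usable_time_interval(reps)
    assert dt > 5.0
    pp_chosen = tm.PersistenceParams(delta_t=dt, TR=4)
    pp_base = tm.PersistenceParams(delta_t=5.0, TR=4)
    err_chosen = abs(tm.mean_track_persistence(reps[0], pp_chosen)
                     - tm.mean_track_persistence(truth, pp_chosen))
    err_base = abs(tm.mean_track_persistence(reps[0], pp_base)
                   - tm.mean_track_persistence(truth, pp_base))
    assert err_chosen < err_base
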