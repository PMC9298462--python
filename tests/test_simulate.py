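import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from reeftrack.simulate import (
    MODE_NAMES,
    MovementModeParams,
    ReceiverArraySpec,
    SimulationConfig,
    build_triangular_array,
    default_modes,
    simulate_detections,
    simulate_trajectory,
)


def identity_matrix():
    return np.eye(4)


class TestTrajectory:
    def test_absorbing_mode_stays_dwelling(self):
        cfg = SimulationConfig(
            n_days=1, mode_transition_matrix=identity_matrix(), initial_mode="dwelling", rng_seed=3
        )
        traj = simulate_trajectory(cfg)
        day = traj.is_day
        assert set(traj.mode_labels[day]) == {"dwelling"}
        xy = traj.positions[day, :2]
        assert np.linalg.norm(xy[-1] - xy[0]) < 5.0

    def test_zero_speed_dwelling_is_motionless_by_day(self):
        modes = [m for m in default_modes() if m.mode_name != "dwelling"]
        modes.append(MovementModeParams("dwelling", 0.0, 0.0, 0.0, 2.0))
        cfg = SimulationConfig(
            n_days=1, mode_transition_matrix=identity_matrix(), initial_mode="dwelling", rng_seed=3
        )
        traj = simulate_trajectory(cfg, modes)
        xy = traj.positions[traj.is_day, :2]
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        assert steps.max() == pytest.approx(0.0, abs=1e-12)
        # nighttime jitter is bounded by the 5 m clip
        night = traj.positions[~traj.is_day, :2]
        assert np.linalg.norm(night - np.asarray(cfg.sleep_site), axis=1).max() <= 5.0 + 1e-9

    def test_night_positions_at_sleep_site(self):
        cfg = SimulationConfig(n_days=3, rng_seed=5)
        traj = simulate_trajectory(cfg)
        night = traj.positions[~traj.is_day, :2]
        dist = np.linalg.norm(night - np.asarray(cfg.sleep_site), axis=1)
        assert (dist <= 10.0).all()

    def test_reproducible_for_equal_seeds(self):
        a = simulate_trajectory(SimulationConfig(n_days=2, rng_seed=9))
        b = simulate_trajectory(SimulationConfig(n_days=2, rng_seed=9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.mode_labels, b.mode_labels)

    def test_rejects_bad_config(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError):
            SimulationConfig(mode_transition_matrix=bad).validate()
        with pytest.raises(ValueError):
            SimulationConfig(home_extent=(0.0, 50.0)).validate()
        with pytest.raises(ValueError):
            SimulationConfig(transmission_interval=0.0).validate()

    def test_dwell_times_match_markov_chain_oracle(self):
        """Empirical daytime bout lengths agree with a direct chain simulation."""
        cfg = SimulationConfig(n_days=14, rng_seed=21)
        traj = simulate_trajectory(cfg)
        sr, ss = cfg.day_window

        def day_bouts(labels_per_day):
            bouts = {m: [] for m in MODE_NAMES}
            for labels in labels_per_day:
                run_mode, run_len = labels[0], 1
                for lab in labels[1:]:
                    if lab == run_mode:
                        run_len += 1
                    else:
                        bouts[run_mode].append(run_len)
                        run_mode, run_len = lab, 1
                bouts[run_mode].append(run_len)
            return bouts

        observed = day_bouts(
            [traj.mode_labels[d * 1440 + sr : d * 1440 + ss] for d in range(cfg.n_days)]
        )

        # independent oracle: the bare Markov chain over the same day blocks
        rng = np.random.default_rng(987)
        p = cfg.mode_transition_matrix
        idx = {m: i for i, m in enumerate(MODE_NAMES)}
        oracle_days = []
        state = idx[cfg.initial_mode]
        for _ in range(40 * cfg.n_days):
            labels = []
            for _ in range(ss - sr):
                labels.append(MODE_NAMES[state])
                state = rng.choice(4, p=p[state])
            oracle_days.append(labels)
        expected = day_bouts(oracle_days)

        for mode in MODE_NAMES:
            if len(observed[mode]) < 5:
                continue
            obs = np.asarray(observed[mode], dtype=float)
            exp = np.asarray(expected[mode], dtype=float)
            se = np.sqrt(obs.var(ddof=1) / len(obs) + exp.var(ddof=1) / len(exp))
            assert abs(obs.mean() - exp.mean()) <= 3.0 * se, mode


class TestTriangularArray:
    def test_interior_neighbors_at_spacing(self):
        arr = build_triangular_array((0, 0, 300, 300), spacing=50.0)
        pts = arr.stations[["x_m", "y_m"]].to_numpy()
        # pick an interior station and check its 6 nearest neighbors
        center = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
        d = np.sort(np.linalg.norm(pts - center, axis=1))
        assert np.allclose(d[1:7], 50.0, atol=1e-9)

    def test_stations_inside_inflated_bounds(self):
        arr = build_triangular_array((0, 0, 200, 50), spacing=60.0)
        pts = arr.stations[["x_m", "y_m"]].to_numpy()
        assert (pts[:, 0] >= -60 - 1e-9).all() and (pts[:, 0] <= 260 + 1e-9).all()
        assert (pts[:, 1] >= -60 - 1e-9).all() and (pts[:, 1] <= 110 + 1e-9).all()

    def test_station_count_matches_enumeration_oracle(self):
        bounds, spacing = (0.0, 0.0, 200.0, 50.0), 60.0
        arr = build_triangular_array(bounds, spacing)
        # brute-force row enumeration oracle
        xmin, ymin, xmax, ymax = bounds
        dy = spacing * np.sqrt(3) / 2
        count, j = 0, 0
        y = ymin - spacing
        while y <= ymax + spacing:
            x = xmin - spacing + (spacing / 2 if j % 2 else 0.0)
            while x <= xmax + spacing + 1e-9:
                count += 1
                x += spacing
            y += dy
            j += 1
        assert len(arr.stations) == count

    def test_interior_points_have_three_stations_within_spacing(self):
        arr = build_triangular_array((0, 0, 200, 100), spacing=60.0)
        pts = arr.stations[["x_m", "y_m"]].to_numpy()
        rng = np.random.default_rng(0)
        probes = rng.uniform((0, 0), (200, 100), size=(200, 2))
        d = np.linalg.norm(probes[:, None] - pts[None], axis=-1)
        assert ((d <= 60.0 + 1e-9).sum(axis=1) >= 3).all()

    def test_degenerate_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_triangular_array((0, 0, 40, 40), spacing=100.0)

    def test_every_station_hears_a_connected_beacon_network(self):
        arr = build_triangular_array((0, 0, 200, 50), spacing=60.0)
        st = arr.stations[["x_m", "y_m"]].to_numpy()
        bc = arr.sync_beacons[["x_m", "y_m"]].to_numpy()
        d = np.linalg.norm(st[:, None] - bc[None], axis=-1)
        assert (d.min(axis=1) <= arr.detection_range).all()


def _stationary_traj(pos, n_min=10, day_window=(0, 1440)):
    n = n_min
    positions = np.tile(np.asarray(pos, dtype=float), (n, 1))
    from reeftrack.simulate import TrueTrajectory

    return TrueTrajectory(
        np.arange(n, dtype=float), positions, np.full(n, "dwelling", dtype=object), day_window
    )


class TestDetections:
    def test_zero_range_arrival_equals_emission(self):
        st = pd.DataFrame({"id": ["R0", "R1"], "x_m": [10.0, 200.0], "y_m": [5.0, 200.0], "z_m": [3.0, 3.0]})
        arr = ReceiverArraySpec(stations=st, sync_beacons=st.copy(), timing_noise_sd=0.0)
        traj = _stationary_traj((10.0, 5.0, 3.0))
        log = simulate_detections(traj, arr, seed=0, night_dropout=0.0)
        r0 = log.detections[log.detections.receiver_id == "R0"]
        emits = log.emissions.set_index("emission_index") if "emission_index" in log.emissions else log.emissions
        t_emit = log.emissions["emission_time_s"].to_numpy()
        np.testing.assert_allclose(
            r0["arrival_time_s"].to_numpy(), t_emit[r0["emission_index"].to_numpy()], atol=1e-12
        )

    def test_beyond_range_never_detected(self):
        st = pd.DataFrame({"id": ["R0"], "x_m": [75.0], "y_m": [0.0], "z_m": [0.0]})
        arr = ReceiverArraySpec(stations=st, sync_beacons=st.copy())
        traj = _stationary_traj((0.0, 0.0, 0.0))
        log = simulate_detections(traj, arr, seed=0)
        assert log.detections.empty

    def test_equilateral_centroid_symmetric_arrivals(self):
        r = 30.0  # inside the certain-detection half of the range
        ang = np.deg2rad([90, 210, 330])
        st = pd.DataFrame(
            {"id": [f"R{i}" for i in range(3)], "x_m": r * np.cos(ang), "y_m": r * np.sin(ang), "z_m": 0.0}
        )
        arr = ReceiverArraySpec(stations=st, sync_beacons=st.copy(), timing_noise_sd=0.0)
        traj = _stationary_traj((0.0, 0.0, 0.0))
        log = simulate_detections(traj, arr, seed=0, night_dropout=0.0)
        by_emit = log.detections.groupby("emission_index")["arrival_time_s"]
        assert (by_emit.count() == 3).all()
        assert (by_emit.max() - by_emit.min()).max() < 1e-12

    def test_range_gate_invariant(self):
        cfg = SimulationConfig(n_days=1, rng_seed=2)
        traj = simulate_trajectory(cfg)
        arr = build_triangular_array((-110, -35, 110, 35), spacing=60.0)
        log = simulate_detections(traj, arr, seed=4)
        st = arr.stations.set_index("id")
        ex = log.emissions
        for sid, sub in log.detections.groupby("receiver_id"):
            sxyz = st.loc[sid, ["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
            e = ex.iloc[sub["emission_index"].to_numpy()]
            d = np.linalg.norm(e[["x_m", "y_m", "z_m"]].to_numpy() - sxyz, axis=1)
            assert (d <= arr.detection_range + 1e-9).all()

    def test_reproducible_and_noise_dropout_monotonicity(self):
        from dataclasses import replace

        cfg = SimulationConfig(n_days=1, rng_seed=2)
        traj = simulate_trajectory(cfg)
        arr = build_triangular_array((-110, -35, 110, 35), spacing=60.0, timing_noise_sd=0.001)
        a = simulate_detections(traj, arr, seed=7)
        b = simulate_detections(traj, arr, seed=7)
        assert_frame_equal(a.detections, b.detections)
        # raising timing noise leaves the detection count unchanged
        noisy = simulate_detections(traj, replace(arr, timing_noise_sd=0.05), seed=7)
        assert len(noisy.detections) == len(a.detections)
        # raising the night dropout strictly reduces detections (paired seed)
        sparse = simulate_detections(traj, arr, seed=7, night_dropout=0.9)
        assert len(sparse.detections) < len(a.detections)
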