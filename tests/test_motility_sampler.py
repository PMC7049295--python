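"""In-sequence replay fidelity, group partitioning and bias calibration."""

import warnings

import numpy as np
import pytest

from swarmqs.motility_sampler import (
    BiasCalibration,
    SamplerPopulation,
    SamplerState,
    TrackBank,
    calibrate_bias,
    migration_bias_ladder,
    partition_library,
    simulate_cpc,
    step_agent,
)
from swarmqs.synthetic_tracks import TrackGenSpec, generate_library, preset
from swarmqs.trajectory_stats import (
    Track,
    TrajectoryLibrary,
    extract_kinematics,
    persistence_curve,
)


def single_track_library(points, dt=1.0):
    t = extract_kinematics(Track("src", dt, np.asarray(points, dtype=float)))
    return TrajectoryLibrary(tracks=[t])


def initial_heading(track):
    v0 = track.positions[1] - track.positions[0]
    return float(np.degrees(np.arctan2(v0[1], v0[0])))


class TestReplayFidelity:
    def test_straight_track_replayed_exactly(self, rng):
        lib = single_track_library([(0, 0), (1, 0), (2, 0)])
        bank = TrackBank(lib)
        pop = SamplerPopulation(bank, 1, rng, positions=[[0.0, 0.0]], headings=[0.0])
        pop.step()
        assert np.allclose(pop.positions, [[1, 0]])
        pop.step()
        assert np.allclose(pop.positions, [[2, 0]])

    def test_replay_reproduces_source_persistence_curve(self, rng):
        # a simulated agent handed one tracked sequence must trace the same
        # path -- the in-sequence-vs-random contrast rests on this
        g = np.random.default_rng(5)
        pts = np.vstack([[0, 0], np.cumsum(g.normal(0, 3, (40, 2)), axis=0)])
        lib = single_track_library(pts, dt=0.07)
        bank = TrackBank(lib)
        pop = SamplerPopulation(
            bank, 1, rng,
            positions=[pts[0]], headings=[initial_heading(lib.tracks[0])],
        )
        sim = [pop.positions[0].copy()]
        for _ in range(40):
            pop.step()
            sim.append(pop.positions[0].copy())
        sim_track = Track("sim", 0.07, np.asarray(sim))
        assert np.allclose(np.asarray(sim), pts, atol=1e-8)
        assert np.allclose(
            persistence_curve(sim_track), persistence_curve(lib.tracks[0])
        )

    def test_scalar_step_agent_matches_vectorized(self, small_heterogeneous_library):
        bank = TrackBank(small_heterogeneous_library)
        rng_a = np.random.default_rng(77)
        rng_b = np.random.default_rng(77)
        pop = SamplerPopulation(
            bank, 1, rng_a, positions=[[100.0, 100.0]], headings=[30.0]
        )
        state = SamplerState(
            agent_id=0, current_track=0, cursor=np.iinfo(np.intp).max,
            heading=30.0, position=np.array([100.0, 100.0]),
        )
        for _ in range(200):
            pop.step()
            step_agent(state, bank, bank.dt, rng=rng_b)
        assert np.allclose(state.position, pop.positions[0])
        assert state.heading == pytest.approx(pop.headings[0])

    def test_displacement_bounded_by_max_speed(self, small_heterogeneous_library, rng):
        bank = TrackBank(small_heterogeneous_library)
        pop = SamplerPopulation(bank, 50, rng, domain=(0, 1000, 0, 1000))
        for _ in range(300):
            before = pop.positions.copy()
            pop.step()
            step = np.hypot(*(pop.positions - before).T)
            assert np.all(step <= bank.max_speed * bank.dt + 1e-9)

    def test_wall_pause_keeps_agents_inside(self, small_heterogeneous_library, rng):
        bank = TrackBank(small_heterogeneous_library)
        pop = SamplerPopulation(bank, 30, rng, domain=(0, 50, 0, 50))
        for _ in range(500):
            pop.step()
        x, y = pop.positions.T
        assert np.all((x >= 0) & (x <= 50) & (y >= 0) & (y <= 50))


class TestRandomSamplingContrast:
    def test_random_mode_loses_persistence(self, rng):
        # persistent tracks are anchored wobblers: their large turn rates
        # cancel in sequence.  Random resampling of the same values turns
        # them into heavy-angle random walks, erasing the persistent
        # subpopulation while in-sequence replay keeps it.
        spec = TrackGenSpec(
            agent_kind="nanobeads", n_tracks=8, duration=6, frame_interval=0.07,
            speed_mean=23.4, speed_sd=10.0, turn_sd=606.0,
            persistence_mixture=[(0.5, 0.7, 0.7), (0.5, 1.1)], seed=13,
        )
        lib = generate_library(spec)
        for t in lib.tracks:
            extract_kinematics(t)
        bank = TrackBank(lib)
        finals = {}
        for mode in (True, False):
            pop = SamplerPopulation(
                bank, 120, np.random.default_rng(2), in_sequence=mode
            )
            start = pop.positions.copy()
            traj = [start.copy()]
            for _ in range(int(6.0 / 0.07)):
                pop.step()
                traj.append(pop.positions.copy())
            traj = np.asarray(traj)
            vals = []
            for a in range(pop.n):
                vals.append(persistence_curve(Track("a", 0.07, traj[:, a]))[-1])
            finals[mode] = np.asarray(vals)
        assert finals[True].mean() > finals[False].mean()
        # the persistent subpopulation only survives in-sequence replay
        assert (finals[True] > 0.8).any()
        assert not (finals[False] > 0.8).any()


class TestPartitionLibrary:
    @pytest.mark.parametrize("n,expected", [(26, (13, 13)), (154, (77, 77)), (3, (2, 1))])
    def test_equal_split(self, n, expected, rng):
        tracks = [
            extract_kinematics(Track(str(i), 1.0, [(0, 0), (1, 0), (2, 0)]))
            for i in range(n)
        ]
        lib = partition_library(TrajectoryLibrary(tracks=tracks), rng)
        assert (len(lib.group_pos), len(lib.group_neg)) == expected
        assert set(lib.group_pos) | set(lib.group_neg) == set(range(n))
        assert not set(lib.group_pos) & set(lib.group_neg)

    def test_too_few_tracks_rejected(self, rng):
        t = extract_kinematics(Track("0", 1.0, [(0, 0), (1, 0), (2, 0)]))
        with pytest.raises(ValueError):
            partition_library(TrajectoryLibrary(tracks=[t]), rng)


class TestIsotropicSymmetry:
    def test_cpc_near_zero_without_bias(self, zero_drift_isotropic_library):
        curve = simulate_cpc(
            zero_drift_isotropic_library,
            n_agents=500,
            times=[60.0],
            rng=np.random.default_rng(0),
            gradient_direction=None,
        )
        assert abs(curve[0]) < 4.0 / np.sqrt(500)


class TestCalibration:
    def test_zero_drift_zero_target_low_error(self, zero_drift_isotropic_library):
        cal = BiasCalibration(n_pools=4, n_agents=120)
        out = calibrate_bias(
            zero_drift_isotropic_library, [(30.0, 0.0), (60.0, 0.0)], cal, seed=1
        )
        assert out.best_error < 0.05
        assert out.best_partition is not None

    def test_single_pool_returns_that_partition(self, zero_drift_isotropic_library):
        cal = BiasCalibration(n_pools=1, n_agents=60)
        out = calibrate_bias(zero_drift_isotropic_library, [(30.0, 0.5)], cal, seed=3)
        assert np.isfinite(out.best_error)
        assert out.best_partition is not None

    def test_warns_when_error_exceeds_tolerance(self, zero_drift_isotropic_library):
        cal = BiasCalibration(n_pools=1, n_agents=60)
        with pytest.warns(UserWarning, match="tolerance"):
            calibrate_bias(
                zero_drift_isotropic_library, [(30.0, 0.9)], cal, seed=3,
                error_tolerance=1e-6,
            )

    def test_calibration_recovers_separable_drift(self):
        # half the tracks near-ballistic, half diffusive: the best split can
        # ratchet agents up-gradient.  The oracle target is the CPC produced
        # by the known persistent/diffusive split itself.
        spec = TrackGenSpec(
            agent_kind="nanobeads", n_tracks=16, duration=6, frame_interval=0.07,
            speed_mean=23.4, speed_sd=5.0, turn_sd=606.0,
            persistence_mixture=[(1.0, 0.03)], seed=31,
        )
        persistent = generate_library(spec).tracks
        spec2 = TrackGenSpec(
            agent_kind="nanobeads", n_tracks=16, duration=6, frame_interval=0.07,
            speed_mean=23.4, speed_sd=5.0, turn_sd=606.0,
            persistence_mixture=[(1.0, 1.2)], seed=32,
        )
        diffusive = generate_library(spec2).tracks
        tracks = persistent + diffusive
        for t in tracks:
            extract_kinematics(t)
        oracle_lib = TrajectoryLibrary(
            tracks=tracks,
            group_pos=np.arange(16),
            group_neg=np.arange(16, 32),
        )
        t_eval = [120.0]
        oracle = simulate_cpc(
            oracle_lib, 400, t_eval, np.random.default_rng(9)
        )[0]
        assert oracle > 0.3  # the known split really is strongly biased
        cal = BiasCalibration(n_pools=25, n_agents=150)
        out = calibrate_bias(
            TrajectoryLibrary(tracks=tracks), [(t_eval[0], oracle)], cal, seed=4
        )
        assert out.best_curve[0] == pytest.approx(oracle, abs=0.15)


class TestMigrationBiasLadder:
    def test_ladder_monotone_and_anchored(self, small_heterogeneous_library):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder = migration_bias_ladder(
                small_heterogeneous_library,
                n_levels=4, seed=2, n_pools=10, n_agents=100,
                duration=180.0, steady_window=60.0,
            )
        cpcs = [e["steady_cpc"] for e in ladder]
        assert all(b >= a for a, b in zip(cpcs, cpcs[1:]))
        assert all(0 <= e["migration_bias"] <= 1.2 for e in ladder)

    def test_warns_when_target_range_unreachable(self, zero_drift_isotropic_library):
        with pytest.warns(UserWarning, match="achievable"):
            migration_bias_ladder(
                zero_drift_isotropic_library,
                n_levels=3, seed=2, n_pools=4, n_agents=60,
                duration=90.0, steady_window=30.0,
            )
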