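import numpy as np
import pytest

from socnet.association import dyad_counts, simple_ratio_index
from socnet.compare import mantel_test
from socnet.grouping import bin_detections, collapse_to_periods
from socnet.io_telemetry import ReceiverSpec, ValidationError
from socnet.simulate import (
    PingSeries,
    SimulationConfig,
    TrajectorySet,
    blocked_preferences,
    generate_pings,
    jervis2012_preset,
    open_array_preset,
    simulate_detections,
    simulate_trajectories,
    true_association_matrix,
    true_contacts,
    true_groups,
    write_truth_contacts,
)

SITES = ((0.0, 0.0), (100.0, 0.0), (0.0, 100.0))


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_individuals=3,
        duration=6 * 3600.0,
        site_positions=SITES,
        rest_duration_mean=1800.0,
        seed=5,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def fixed_trajectory(positions_by_individual, n_steps=100, step=60.0) -> TrajectorySet:
    """Stationary trajectories at given positions (one (x, y) per individual)."""
    pos = np.array(
        [[p] * n_steps for p in positions_by_individual], dtype=float
    )
    n = len(positions_by_individual)
    return TrajectorySet(
        ids=tuple(f"S{i + 1:02d}" for i in range(n)),
        t0=0.0,
        step=step,
        positions=pos,
        states=np.zeros((n, n_steps), dtype=np.uint8),
    )


class TestConfigValidation:
    def test_no_sites_rejected(self):
        with pytest.raises(ValidationError, match="site"):
            small_config(site_positions=())

    def test_asymmetric_preferences_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            small_config(preference_matrix=((0, 1, 0), (0, 0, 0), (0, 0, 0)))

    def test_nonzero_preference_diagonal_rejected(self):
        with pytest.raises(ValidationError, match="diagonal"):
            small_config(preference_matrix=((1, 0, 0), (0, 0, 0), (0, 0, 0)))

    def test_bad_jitter_rejected(self):
        with pytest.raises(ValidationError, match="jitter"):
            small_config(delay_jitter=1.0)


class TestTrajectories:
    def test_seed_determinism_bitwise(self):
        config = small_config()
        t1 = simulate_trajectories(config)
        t2 = simulate_trajectories(config)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.states, t2.states)

    def test_zero_duration_empty(self):
        traj = simulate_trajectories(small_config(duration=0.0))
        assert traj.n_steps == 0

    def test_displacement_bounded(self):
        config = small_config(duration=12 * 3600.0)
        traj = simulate_trajectories(config)
        steps = np.diff(traj.positions, axis=1)
        displacement = np.hypot(steps[..., 0], steps[..., 1])
        assert displacement.max() <= config.travel_speed * config.step + 1e-9

    def test_social_pairs_closer_than_control(self):
        # independent pairwise-distance oracle over the run
        def contact_fraction(p_social: float) -> float:
            pref = ((0.0, 1.0), (1.0, 0.0))
            config = SimulationConfig(
                n_individuals=2,
                duration=86_400.0,
                site_positions=((0.0, 0.0), (80.0, 0.0), (0.0, 80.0), (80.0, 80.0)),
                preference_matrix=pref,
                p_social=p_social,
                rest_duration_mean=1800.0,
                seed=99,
            )
            traj = simulate_trajectories(config)
            d = np.hypot(
                *(traj.positions[0] - traj.positions[1]).T
            )
            return float(np.mean(d <= config.contact_radius))

        assert contact_fraction(1.0) > contact_fraction(0.0)


class TestPings:
    def test_six_or_seven_pings_in_ten_minutes(self):
        config = small_config(duration=600.0, nominal_delay=90.0)
        traj = simulate_trajectories(config)
        pings = generate_pings(traj, config)
        for iid in traj.ids:
            count = int(np.sum(pings.individual_index == traj.ids.index(iid)))
            assert count in (6, 7)

    def test_delay_equal_duration_at_most_one(self):
        config = small_config(duration=90.0, nominal_delay=90.0)
        pings = generate_pings(simulate_trajectories(config), config)
        counts = np.bincount(pings.individual_index, minlength=3)
        assert np.all(counts <= 1)

    def test_jitter_mean_interval(self):
        # intervals uniform on [60, 120] -> mean 90 within +/- 2 s
        config = small_config(
            n_individuals=1,
            duration=1_000_000.0,
            delay_jitter=1.0 / 3.0,
            site_positions=((0.0, 0.0),),
        )
        traj = simulate_trajectories(config)
        pings = generate_pings(traj, config)
        intervals = pings.intervals("S01")
        assert len(intervals) >= 10_000
        assert abs(float(np.mean(intervals[:10_000])) - 90.0) <= 2.0

    def test_intervals_within_bounds(self):
        config = small_config(delay_jitter=0.2)
        pings = generate_pings(simulate_trajectories(config), config)
        for iid in config.individual_ids:
            intervals = pings.intervals(iid)
            assert np.all(intervals >= 90.0 * 0.8 - 1e-9)
            assert np.all(intervals <= 90.0 * 1.2 + 1e-9)

    def test_sorted_by_time(self):
        config = small_config()
        pings = generate_pings(simulate_trajectories(config), config)
        assert np.all(np.diff(pings.times) >= 0)


class TestDetections:
    def test_out_of_range_never_detected(self):
        traj = fixed_trajectory([(500.0, 0.0)])
        config = small_config(n_individuals=1, site_positions=((0.0, 0.0),))
        pings = generate_pings(traj, config)
        receiver = ReceiverSpec("V", "fixed", 400.0, x=0.0, y=0.0)
        assert simulate_detections(pings, traj, [receiver], config) == []

    def test_in_range_always_detected_step_model(self):
        traj = fixed_trajectory([(1.0, 0.0)])
        config = small_config(n_individuals=1, site_positions=((0.0, 0.0),))
        pings = generate_pings(traj, config)
        receiver = ReceiverSpec("S", "fixed", 10.0, x=0.0, y=0.0)
        records = simulate_detections(pings, traj, [receiver], config)
        assert len(records) == len(pings)

    def test_logistic_midpoint_probability(self):
        # at d = midpoint_fraction * radius the detection probability is
        # exactly p_det_inside / 2; Monte-Carlo check against the binomial
        radius, midpoint = 10.0, 0.7
        traj = fixed_trajectory([(radius * midpoint, 0.0)], n_steps=20_000, step=60.0)
        config = small_config(
            n_individuals=1,
            site_positions=((0.0, 0.0),),
            duration=20_000 * 60.0,
            detection_model="logistic",
            logistic_midpoint_fraction=midpoint,
            logistic_steepness=8.0,
        )
        pings = generate_pings(traj, config)
        assert len(pings) >= 10_000
        receiver = ReceiverSpec("S", "fixed", radius, x=0.0, y=0.0)
        records = simulate_detections(pings, traj, [receiver], config)
        assert abs(len(records) / len(pings) - 0.5) <= 0.02

    def test_mobile_receiver_excludes_host(self):
        traj = fixed_trajectory([(0.0, 0.0), (1.0, 0.0)])
        config = small_config(n_individuals=2, site_positions=((0.0, 0.0),))
        pings = generate_pings(traj, config)
        receiver = ReceiverSpec("P", "mobile", 4.0, host_individual="S01")
        records = simulate_detections(pings, traj, [receiver], config)
        assert records and all(r.individual_id == "S02" for r in records)

    def test_mobile_host_without_trajectory_errors(self):
        traj = fixed_trajectory([(0.0, 0.0)])
        config = small_config(n_individuals=1, site_positions=((0.0, 0.0),))
        pings = generate_pings(traj, config)
        receiver = ReceiverSpec("P", "mobile", 4.0, host_individual="GHOST")
        with pytest.raises(ValidationError, match="GHOST"):
            simulate_detections(pings, traj, [receiver], config)


class TestTruth:
    def test_always_together_sri_one(self):
        traj = fixed_trajectory([(0.0, 0.0), (1.0, 0.0)])
        ledger = true_contacts(traj, contact_radius=4.0)
        matrix = true_association_matrix(ledger)
        assert matrix.edge("S01", "S02") == 1.0

    def test_never_close_sri_zero(self):
        traj = fixed_trajectory([(0.0, 0.0), (100.0, 0.0)])
        ledger = true_contacts(traj, contact_radius=4.0)
        matrix = true_association_matrix(ledger)
        assert matrix.edge("S01", "S02") == 0.0

    def test_transitive_chain_single_group(self):
        traj = fixed_trajectory([(0.0, 0.0), (3.0, 0.0), (6.0, 0.0)], n_steps=1)
        ledger = true_contacts(traj, contact_radius=4.0)
        groups = true_groups(ledger)
        assert len(groups) == 1 and groups[0].members == {"S01", "S02", "S03"}

    def test_pairwise_mode_splits_chain(self):
        traj = fixed_trajectory([(0.0, 0.0), (3.0, 0.0), (6.0, 0.0)], n_steps=1)
        ledger = true_contacts(traj, contact_radius=4.0)
        groups = true_groups(ledger, transitive=False)
        members = sorted(tuple(sorted(g.members)) for g in groups)
        assert members == [("S01", "S02"), ("S02", "S03")]

    def test_truth_contacts_csv(self, tmp_path):
        traj = fixed_trajectory([(0.0, 0.0), (1.0, 0.0)], n_steps=2)
        ledger = true_contacts(traj, contact_radius=4.0)
        write_truth_contacts(ledger, tmp_path / "truth.csv")
        lines = (tmp_path / "truth.csv").read_text().strip().splitlines()
        assert lines[0] == "time,individual_a,individual_b"
        assert len(lines) == 3  # one dyad per step


class TestPresets:
    def test_jervis_preset_layout(self):
        config, receivers, individuals = jervis2012_preset(duration_days=1.0)
        assert config.n_individuals == len(individuals) == 15
        kinds = {r.receiver_id: r.kind for r in receivers}
        assert kinds["PROXI-1"] == "mobile"
        radii = sorted(r.detection_radius for r in receivers)
        assert radii == [4.0, 10.0, 10.0, 400.0, 400.0]

    def test_open_array_preset(self):
        config, receivers = open_array_preset(seed=1)
        assert len(receivers) == 4
        assert config.p_social == 0.0

    def test_blocked_preferences_zero_rows_for_solitary(self):
        pref = np.asarray(blocked_preferences(5, [[0, 1, 2]]))
        assert pref[3].sum() == 0 and pref[4].sum() == 0
        assert pref[0, 1] == 1.0 and pref[0, 3] == 0.0


class TestRangeBiasInvariant:
    def test_truth_agreement_degrades_with_radius(self):
        # mean Mantel r against the true network is non-increasing over
        # radii 4 -> 10 -> 60 -> 400 for a receiver at the main gutter
        radii = [4.0, 10.0, 60.0, 400.0]
        agreement = {r: [] for r in radii}
        for rep in range(20):
            config, _, _ = jervis2012_preset(duration_days=4.0, seed=200 + rep)
            traj = simulate_trajectories(config)
            pings = generate_pings(traj, config)
            truth = true_association_matrix(true_contacts(traj, config.contact_radius))
            matrices = {}
            for radius in radii:
                receiver = ReceiverSpec(f"R{radius}", "fixed", radius, x=0.0, y=0.0)
                detections = simulate_detections(pings, traj, [receiver], config)
                periods = collapse_to_periods(bin_detections(detections))
                matrices[radius] = simple_ratio_index(dyad_counts(periods))
            common = sorted(
                set.intersection(*(set(m.index) for m in matrices.values()))
            )
            if len(common) < 3:
                continue
            for radius in radii:
                r = mantel_test(
                    matrices[radius].reindex(common),
                    truth.reindex(common),
                    n_permutations=9,
                    seed=0,
                ).r
                agreement[radius].append(r)
        means = [float(np.mean(agreement[r])) for r in radii]
        assert len(agreement[4.0]) >= 15
        for closer, wider in zip(means, means[1:]):
            assert wider <= closer + 0.02, means
        assert means[0] - means[-1] > 0.05, means
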