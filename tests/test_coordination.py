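import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treadscore.coordination import (
    CoordinationScorer,
    ScoreConfig,
    compute_components,
    lateral_sd,
    paw_instability,
    score_cohort,
    step_lengths,
    zone_expectation,
    zone_probabilities,
)
from treadscore.pose import ALL_PARTS, BodyPartTrack, PoseSession


class TestZones:
    def test_all_frames_in_front_zone(self):
        p = zone_probabilities(np.full(100, 0.05))
        np.testing.assert_allclose(p, [1, 0, 0, 0, 0])

    def test_uniform_positions_near_uniform_zones(self):
        rng = np.random.default_rng(0)
        p = zone_probabilities(rng.uniform(0, 1, 50_000))
        np.testing.assert_allclose(p, 0.2, atol=0.01)

    def test_rear_wall_counts_in_last_zone(self):
        p = zone_probabilities(np.array([1.0]))
        np.testing.assert_allclose(p, [0, 0, 0, 0, 1])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            zone_probabilities(np.array([]))

    @pytest.mark.parametrize(
        "probs,expected",
        [([1, 0, 0, 0, 0], 1.0), ([0.2] * 5, 3.0), ([0.5, 0, 0, 0, 0.5], 3.0)],
    )
    def test_zone_expectation(self, probs, expected):
        assert zone_expectation(probs) == pytest.approx(expected)


class TestLateralSD:
    def test_constant_is_zero(self):
        assert lateral_sd(np.full(10, 0.5)) == 0.0

    def test_alternating_population_sd(self):
        y = np.tile([0.4, 0.6], 50)
        assert lateral_sd(y) == pytest.approx(0.1)

    def test_single_frame_degenerate(self):
        assert lateral_sd(np.array([0.7])) == 0.0


class TestStepLengths:
    def test_stationary_paw(self):
        steps, mean = step_lengths((np.full(50, 0.3), np.full(50, 0.5)))
        assert len(steps) == 0 and mean == 0.0

    def test_constant_displacement(self):
        x = np.arange(20) * 0.01
        steps, mean = step_lengths((x, np.zeros(20)))
        assert len(steps) == 19
        assert mean == pytest.approx(0.01)

    def test_matches_bruteforce_filtered_mean(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.choice([0.0005, 0.02], 200, p=[0.7, 0.3]))
        y = x + rng.normal(0, 1e-4, 200)
        # independent enumeration of supra-threshold displacements
        expected = []
        for i in range(199):
            d = np.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            if d >= 0.005:
                expected.append(d)
        steps, mean = step_lengths((x, y))
        assert len(steps) == len(expected)
        assert mean == pytest.approx(np.mean(expected))


class TestPawInstability:
    def test_equal_means_perfectly_stable(self):
        assert paw_instability([0.02] * 4) == 0.0

    def test_known_deviation(self):
        assert paw_instability([1, 1, 1, 2]) == pytest.approx(0.25)

    def test_permutation_invariant(self):
        vals = [0.01, 0.03, 0.02, 0.05]
        assert paw_instability(vals) == paw_instability(vals[::-1])

    def test_requires_four_paws(self):
        with pytest.raises(ValueError):
            paw_instability([1, 2, 3])


class TestComputeComponents:
    def test_expert_beats_novice_on_all_components(
        self, expert_components, novice_components
    ):
        assert expert_components.zone_expectation < novice_components.zone_expectation
        assert expert_components.lateral_sd < novice_components.lateral_sd
        assert expert_components.paw_instability < novice_components.paw_instability

    def test_expert_profile_values(self, expert_components):
        assert expert_components.zone_expectation < 2.0
        assert expert_components.lateral_sd < 0.05

    def test_motionless_mouse_at_front(self, schedule):
        n = schedule.total_duration * 30
        tracks = {
            p: BodyPartTrack(p, np.full(int(n), 0.02), np.full(int(n), 0.5), np.ones(int(n)))
            for p in ALL_PARTS
        }
        session = PoseSession(30.0, np.arange(int(n)) / 30.0, tracks, normalized=True)
        c = compute_components(session, schedule)
        assert c.zone_expectation == 1.0
        assert c.lateral_sd == 0.0
        assert c.mean_step_length == 0.0
        assert c.paw_instability == 0.0

    def test_unnormalized_session_rejected(self, schedule):
        tracks = {p: BodyPartTrack(p, [0.1], [0.5], [1.0]) for p in ALL_PARTS}
        session = PoseSession(30.0, [40.0], tracks, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            compute_components(session, schedule)

    def test_no_run_frames_rejected(self, schedule):
        tracks = {p: BodyPartTrack(p, [0.1, 0.1], [0.5, 0.5], [1, 1]) for p in ALL_PARTS}
        session = PoseSession(30.0, [0.0, 1.0], tracks, normalized=True)  # pre_off only
        with pytest.raises(ValueError, match="run"):
            compute_components(session, schedule)


class TestScoreCohort:
    def test_identical_sessions_all_midrank(self):
        df = score_cohort([[2.0, 0.1, 0.01]] * 5)
        assert (df["score"] == 3.0).all()

    def test_dominating_pair_gets_extremes(self):
        df = score_cohort([[1.5, 0.05, 0.005], [4.0, 0.2, 0.02]])
        assert df["score"].tolist() == [5.0, 1.0]

    def test_single_session_rejected_with_pooling_hint(self):
        with pytest.raises(ValueError, match="cohort"):
            score_cohort([[2.0, 0.1, 0.01]])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.uniform([1, 0, 0], [5, 0.3, 0.05], (20, 3))
        base = score_cohort(X)["score"].to_numpy()
        perm = rng.permutation(20)
        shuffled = score_cohort(X[perm])["score"].to_numpy()
        np.testing.assert_allclose(shuffled, base[perm])

    def test_weights_must_sum_to_100(self):
        with pytest.raises(ValueError):
            score_cohort([[1, 0, 0], [2, 0, 0]], ScoreConfig(weights=(30, 30, 30)))

    def test_transform_scores_new_sessions_against_reference(self):
        rng = np.random.default_rng(7)
        X = rng.uniform([1, 0, 0], [5, 0.3, 0.05], (30, 3))
        scorer = CoordinationScorer().fit(X)
        new = np.array([[1.0, 0.0, 0.0], [5.0, 0.3, 0.05]])
        lo_hi = scorer.transform(new)
        assert lo_hi[0] > lo_hi[1]
        assert np.all((lo_hi >= 1.0) & (lo_hi <= 5.0))

    def test_sklearn_param_interface(self):
        scorer = CoordinationScorer(weights=(10.0, 50.0, 40.0))
        assert scorer.get_params()["weights"] == (10.0, 50.0, 40.0)
        scorer.set_params(weights=(20.0, 40.0, 40.0))
        assert scorer.get_params()["weights"] == (20.0, 40.0, 40.0)


component_matrix = st.lists(
    st.tuples(
        st.floats(1.0, 5.0),
        st.floats(0.0, 0.5),
        st.floats(0.0, 0.1),
    ),
    min_size=2,
    max_size=15,
)


@settings(deadline=None, max_examples=100)
@given(X=component_matrix)
def test_scores_bounded_and_dominance_monotone(X):
    X = np.asarray(X)
    df = score_cohort(X)
    scores = df["score"].to_numpy()
    assert np.all((scores >= 1.0) & (scores <= 5.0))
    # a strictly dominating copy of the first session never scores below it
    improved = X[0] - np.array([0.5, 0.05, 0.01])
    df2 = score_cohort(np.vstack([X, improved]))
    assert df2["score"].iloc[-1] >= df2["score"].iloc[0]
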