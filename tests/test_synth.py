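import numpy as np
import pytest
from scipy import stats as sps

from labtempo.model import NO_ASSESSMENT, NO_CHANGE, TEMPORAL_CORRELATION
from labtempo.pipeline import ConfigurationError, PipelineConfig, extract_episodes
from labtempo.synth import (
    GeneratorConfig,
    PlantedEffect,
    generate_cohort,
    make_panel,
    simulate_raters,
)

from conftest import make_episode


def test_same_seed_gives_identical_event_streams():
    config = GeneratorConfig(n_patients=5, span_days=120, seed=9)
    a = generate_cohort(config)
    b = generate_cohort(config)
    assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2] and a[3] == b[3]


def test_different_seed_changes_the_stream():
    a = generate_cohort(GeneratorConfig(n_patients=5, span_days=120, seed=1))
    b = generate_cohort(GeneratorConfig(n_patients=5, span_days=120, seed=2))
    assert a[1] != b[1]


def test_zero_effect_probability_plants_nothing():
    _, _, _, truth = generate_cohort(
        GeneratorConfig(n_patients=8, span_days=150, p_effect=0.0, seed=3)
    )
    assert truth and all(not t.effect for t in truth.values())


def test_infeasible_span_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(span_days=30)


def test_generated_runs_respect_internal_gap_and_isolation(small_cohort):
    config, (admins, _, _, truth) = small_cohort
    from labtempo.pipeline import filter_isolated, find_administration_runs

    runs = find_administration_runs(admins, 1)
    # every planted episode start appears as a run, and all runs are isolated
    assert {(r.patient_id, r.first_day) for r in runs} == {
        (pid, day) for (pid, day, _) in truth
    } | set()
    assert filter_isolated(runs, admins, 14) == runs


def test_reference_intervals_are_valid_and_one_per_patient_parameter(small_cohort):
    config, (_, _, intervals, _) = small_cohort
    keys = [(i.patient_id, i.parameter_id) for i in intervals]
    assert len(keys) == len(set(keys)) == config.n_patients * len(config.parameters)


# --- rater simulation -------------------------------------------------------


def panel_episode(i, effect, amplitude=1.2):
    return (
        make_episode(str(i), truth_label=effect),
        PlantedEffect(effect=effect, amplitude=amplitude if effect else 0.0),
    )


def test_perfect_panel_is_unanimous_and_correct():
    episodes, truth = [], {}
    for i in range(1, 21):
        ep, planted = panel_episode(i, effect=i % 2 == 0, amplitude=1.5)
        episodes.append(ep)
        truth[ep.episode_id] = planted
    votes = simulate_raters(
        episodes,
        truth,
        make_panel(11, reliability=1.0, abstain_propensity=0.0),
        seed=1,
        null_difficulty=0.0,
    )
    for vs, ep in zip(votes, episodes):
        expected = TEMPORAL_CORRELATION if ep.truth_label else NO_CHANGE
        assert all(category == expected for _, category in vs.votes)


def test_hopeless_panel_abstains_everywhere():
    ep, planted = panel_episode(1, effect=True)
    votes = simulate_raters(
        [ep],
        {ep.episode_id: planted},
        make_panel(11, reliability=0.0, abstain_propensity=1.0),
        seed=1,
    )
    assert all(category == NO_ASSESSMENT for _, category in votes[0].votes)


def test_votes_are_seed_deterministic():
    ep, planted = panel_episode(1, effect=True)
    args = ([ep], {ep.episode_id: planted}, make_panel(), 33)
    assert simulate_raters(*args) == simulate_raters(*args)


def test_majority_call_recovers_truth_on_at_least_95_percent():
    """Monte-Carlo check of the vote model itself: 11 raters at
    reliability 0.9 on 200 episodes with clear effects."""
    from labtempo.assessment import majority_call

    episodes, truth = [], {}
    rng = np.random.default_rng(7)
    for i in range(1, 201):
        effect = bool(rng.random() < 0.5)
        ep, planted = panel_episode(i, effect, amplitude=float(rng.uniform(1.0, 1.5)))
        episodes.append(ep)
        truth[ep.episode_id] = planted
    votes = simulate_raters(episodes, truth, make_panel(11, 0.9), seed=17)
    correct = 0
    for vs, ep in zip(votes, episodes):
        expected = TEMPORAL_CORRELATION if ep.truth_label else NO_CHANGE
        correct += majority_call(vs).call == expected
    assert correct / len(episodes) >= 0.95


def test_zero_amplitude_effects_are_indistinguishable_from_null():
    """With amplitude 0, 'planted' episodes carry no signal: a
    two-sample test on the during-phase mean shift must not reject."""
    config = GeneratorConfig(
        n_patients=20,
        span_days=250,
        p_obs=1.0,
        p_effect=0.5,
        effect_amplitude=(0.0, 0.0),
        seed=13,
    )
    admins, observations, intervals, truth = generate_cohort(config)
    result = extract_episodes(admins, observations, intervals, PipelineConfig(), truth)
    shifts = {True: [], False: []}
    for ep in result.episodes:
        before = [p.value for p in ep.points if p.relative_day < 0]
        during = [
            p.value
            for p in ep.points
            if 0 <= p.relative_day <= ep.last_administration_day
        ]
        shifts[ep.truth_label].append(np.mean(during) - np.mean(before))
    assert min(len(shifts[True]), len(shifts[False])) > 20
    _, p_value = sps.ttest_ind(shifts[True], shifts[False])
    assert p_value > 0.01


def test_large_amplitude_effects_are_detectable():
    """Sanity counterpart: at one interval-width amplitude the planted
    group separates clearly from the null group."""
    config = GeneratorConfig(
        n_patients=20,
        span_days=250,
        p_obs=1.0,
        p_effect=0.5,
        effect_amplitude=(1.0, 1.5),
        effect_lag_days=(0, 1),
        seed=13,
    )
    admins, observations, intervals, truth = generate_cohort(config)
    result = extract_episodes(admins, observations, intervals, PipelineConfig(), truth)
    shifts = {True: [], False: []}
    for ep in result.episodes:
        before = [p.value for p in ep.points if p.relative_day < 0]
        during = [
            p.value
            for p in ep.points
            if 0 <= p.relative_day <= ep.last_administration_day
        ]
        shifts[ep.truth_label].append(abs(np.mean(during) - np.mean(before)))
    _, p_value = sps.ttest_ind(shifts[True], shifts[False])
    assert p_value < 1e-6
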