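"""Synthetic cohorts: profile sampling, score-jitter calibration, event
and score-level simulation, engagement heterogeneity."""

import numpy as np
import pytest
from dataclasses import replace

from rhythmlearn import (
    CohortConfig,
    FixedEffects,
    InputEvent,
    PlayerProfile,
    build_curriculum,
    build_schedule,
    expected_score_given_jitter,
    expected_score_to_jitter,
    get_task_spec,
    linear_predictor,
    match_inputs,
    sample_cohort,
    score_input,
    score_session,
    simulate_longitudinal,
    simulate_session_events,
)

ZERO_INTERACTIONS = {d: 0.0 for d in FixedEffects().time_x}


def intercept_only(value=37.83):
    return FixedEffects(
        intercept=value, age=0, dyscalculia=0, dysgraphia=0, dyslexia=0,
        dysphasia=0, adhd=0, executive_impairment=0, time=0,
        time_x=dict(ZERO_INTERACTIONS),
    )


def quiet_config(**kwargs):
    defaults = dict(
        n_players=10, player_sd=0.0, game_sd=0.0, level_sd=0.0, residual_sd=0.0,
        coefficients=intercept_only(),
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


# --- cohort sampling --------------------------------------------------------

def test_sample_mean_age_near_study_mean():
    cohort = sample_cohort(CohortConfig(), seed=11)
    ages = np.array([p.age for p in cohort])
    se = 2.4 / np.sqrt(98)
    # truncation to [6, 14] shifts the mean up slightly; 3 SE band
    assert abs(ages.mean() - 9.05) < 3 * se + 0.4
    assert ages.min() >= 6 and ages.max() <= 14


def test_degenerate_prevalence_flags_everyone():
    cfg = CohortConfig(prevalences={"dyslexia": 1.0})
    assert all(p.has("dyslexia") for p in sample_cohort(cfg, seed=0))


def test_cohort_is_deterministic_under_seed():
    cfg = CohortConfig(n_players=20)
    assert sample_cohort(cfg, seed=5) == sample_cohort(cfg, seed=5)


def test_profile_validation():
    with pytest.raises(ValueError):
        PlayerProfile(0, age=-1.0)
    with pytest.raises(ValueError):
        PlayerProfile(0, age=9.0, miss_rate=1.5)
    with pytest.raises(ValueError):
        PlayerProfile(0, age=9.0, diagnoses=frozenset({"unknown"}))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_players=1)
    with pytest.raises(ValueError):
        CohortConfig(prevalences={"dyslexia": 1.2})
    with pytest.raises(ValueError):
        CohortConfig(residual_sd=-1)


# --- score <-> jitter calibration -------------------------------------------

@pytest.mark.parametrize("target,threshold", [(30, 0.25), (50, 0.25), (80, 0.3),
                                              (95, 0.14)])
def test_jitter_inversion_against_monte_carlo(target, threshold):
    sigma = expected_score_to_jitter(target, threshold)
    rng = np.random.default_rng(123)
    draws = rng.normal(0.0, sigma, size=100_000)
    mc = np.mean([score_input(d, threshold) for d in draws])
    assert abs(mc - target) < 0.5


def test_expected_score_decreases_with_jitter():
    grid = np.linspace(0.01, 1.0, 40)
    values = [expected_score_given_jitter(s, 0.25) for s in grid]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_near_perfect_target_needs_vanishing_jitter():
    assert expected_score_to_jitter(99.99, 0.25) < 1e-3


def test_jitter_inversion_rejects_boundary_targets():
    for bad in (0.0, 100.0, -5.0):
        with pytest.raises(ValueError):
            expected_score_to_jitter(bad, 0.25)


# --- event-level simulation -------------------------------------------------

def session_setup():
    plan = build_curriculum(())[0]
    spec = get_task_spec(plan.task, "final")
    schedule = build_schedule(spec, plan.tempo_bpm, plan.duration_s, plan.density)
    return plan, spec, schedule


def test_certain_misses_produce_no_events():
    plan, _, schedule = session_setup()
    profile = PlayerProfile(0, age=9.0, miss_rate=1.0)
    cfg = quiet_config(spurious_rate=0.0)
    assert simulate_session_events(profile, plan, schedule, 1, cfg, seed=0) == []


def test_near_perfect_player_scores_three_stars_through_the_engine():
    plan, spec, schedule = session_setup()
    profile = PlayerProfile(0, age=9.0, miss_rate=0.0)
    cfg = quiet_config(coefficients=intercept_only(100.0), spurious_rate=0.0)
    events = simulate_session_events(profile, plan, schedule, 1, cfg, seed=1)
    result = score_session(match_inputs(events, schedule, spec.tolerance))
    assert result.acceptable_ratio == 1.0
    assert result.stars == 3
    assert result.mean_score > 99.0


def test_event_path_mean_score_matches_linear_predictor():
    """Scoring simulated events reproduces the intended mean score."""
    plan, spec, schedule = session_setup()
    cfg = quiet_config(coefficients=intercept_only(55.0), spurious_rate=0.0)
    profile = PlayerProfile(0, age=9.0, miss_rate=0.05)
    rng = np.random.default_rng(7)
    scores, weights = [], []
    for k in range(150):
        events = simulate_session_events(
            profile, plan, schedule, 1, cfg, seed=int(rng.integers(2**31 - 1))
        )
        r = score_session(match_inputs(events, schedule, spec.tolerance))
        scores.append(r.mean_score)
        weights.append(r.n_expected)
    grand_mean = np.average(scores, weights=weights)
    target = linear_predictor(profile, 1, cfg.coefficients)
    assert abs(grand_mean - target) < 1.0  # ~13k expected inputs


# --- score-level simulation -------------------------------------------------

def test_intercept_only_generator_is_constant():
    records, _ = simulate_longitudinal(quiet_config(), seed=3)
    assert np.allclose(records["score"], 37.83)


def test_positive_time_slope_is_monotone_before_clipping():
    cfg = quiet_config(
        coefficients=replace(intercept_only(50.0), time=0.5)
    )
    records, _ = simulate_longitudinal(cfg, seed=4)
    for _, g in records.groupby("player_id"):
        g = g.sort_values("time_index")
        unclipped = g[g["score"] < 100.0]
        assert unclipped["score"].is_monotonic_increasing


def test_time_index_starts_at_one_and_increments():
    records, _ = simulate_longitudinal(CohortConfig(n_players=5), seed=5)
    for _, g in records.groupby("player_id"):
        assert list(g["time_index"]) == list(range(1, len(g) + 1))


def test_cohort_mean_matches_design_matrix_expectation():
    cfg = CohortConfig(n_players=60)
    records, profiles = simulate_longitudinal(cfg, seed=8)
    merged = records.merge(profiles, on="player_id")
    coef = cfg.coefficients
    expected = (
        coef.intercept
        + coef.age * merged["age"]
        + sum(getattr(coef, d) * merged[d] for d in
              ("dyscalculia", "dysgraphia", "dyslexia", "dysphasia", "adhd",
               "executive_impairment"))
        + merged["time_index"]
        * (coef.time + sum(coef.time_x[d] * merged[d] for d in coef.time_x))
    )
    resid = records["score"] - expected
    total_sd = np.sqrt(
        cfg.player_sd**2 + cfg.game_sd**2 + cfg.level_sd**2 + cfg.residual_sd**2
    )
    se = total_sd / np.sqrt(merged["player_id"].nunique())  # player REs dominate
    assert abs(resid.mean()) < 2 * se
    assert records.attrs["clip_rate"] < 0.02


def test_simulation_is_deterministic_under_seed():
    cfg = CohortConfig(n_players=8)
    r1, p1 = simulate_longitudinal(cfg, seed=9)
    r2, p2 = simulate_longitudinal(cfg, seed=9)
    assert r1.equals(r2) and p1.equals(p2)


def test_engagement_median_in_feasibility_band():
    cohort = sample_cohort(CohortConfig(n_players=500), seed=13)
    games = np.array([p.n_games for p in cohort])
    med = np.median(games[games >= 15])
    assert 30 <= med <= 60


def test_level_sequence_follows_the_curriculum():
    records, _ = simulate_longitudinal(CohortConfig(n_players=3), seed=2)
    plans = build_curriculum(())
    one = records[records["player_id"] == records["player_id"].iloc[0]]
    for _, row in one.head(72).iterrows():
        plan = plans[(row["time_index"] - 1) % 72]
        assert row["game_id"] == plan.task
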