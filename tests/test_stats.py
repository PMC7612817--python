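"""Bootstrap accuracy, binomial tests, response maps, variance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from frameloc.models import ModelParams, ModelSpec, get_preset
from frameloc.simulate import balanced_trials_from_model, simulate_session, SessionConfig
from frameloc.stats import (
    ResponseMap,
    adjusted_response_probability,
    binomial_chance_test,
    bootstrap_percent_correct,
    first_n_trials_performance,
    permutation_frame_test,
    response_map,
    variance_by_frame,
)


def _table(n, correct_frac, platform=0.0):
    n_correct = int(round(n * correct_frac))
    return pd.DataFrame({
        "subject_id": "t", "session_id": "s",
        "trial_index": np.arange(1, n + 1),
        "platform_angle": platform, "speaker_world": 0.0, "speaker_head": 0.0,
        "trial_type": "test",
        "response": "West",
        "is_correct": [True] * n_correct + [False] * (n - n_correct),
        "reaction_time_s": 1.0,
    })


def test_bootstrap_percent_correct_trivial_cases(rng):
    assert bootstrap_percent_correct(_table(500, 1.0), rng=rng) == 100.0
    half = bootstrap_percent_correct(_table(2000, 0.5), rng=rng)
    assert half == pytest.approx(50.0, abs=2.0)


def test_bootstrap_insufficient_trials_errors(rng):
    with pytest.raises(ValueError, match="short by"):
        bootstrap_percent_correct(_table(100, 1.0), n_per_sample=400, rng=rng)


def test_bootstrap_agrees_with_multinomial_summary(world_preset_trials, rng):
    """Two independent estimators of trained-condition accuracy agree."""
    from frameloc.simulate import draw_simulation_summary
    pct_boot = bootstrap_percent_correct(world_preset_trials, platform_angle=0.0,
                                         n_per_sample=400, rng=rng)
    summary = draw_simulation_summary(get_preset("world_sim"), n_draws=4000, seed=5)
    pct_sim = summary.percent_correct.dropna().mean()
    # both estimate the same 76.85% quantity; allow 2 joint standard errors
    assert pct_boot == pytest.approx(pct_sim, abs=2 * 100 * np.sqrt(0.77 * 0.23 / 400))


@pytest.mark.parametrize("count,n,expected_p", [
    (200, 400, 1.0),
    (400, 400, 2 * 0.5 ** 400),
])
def test_binomial_chance_test_closed_forms(count, n, expected_p):
    res = binomial_chance_test(count, n)
    assert res.p_value == pytest.approx(expected_p, rel=1e-9)


def test_binomial_chance_test_bonferroni():
    res = binomial_chance_test(240, 400, n_comparisons=12)
    # exact two-sided binomial tail, 12-fold corrected, still below 0.001
    oracle = sps.binomtest(240, 400, 0.5).pvalue * 12
    assert res.p_corrected == pytest.approx(min(1.0, oracle))
    assert res.significant
    with pytest.raises(ValueError):
        binomial_chance_test(500, 400)


def test_response_map_counts_and_extremes(rng):
    always_west = ModelSpec("world_sinusoid",
                            ModelParams(beta0=1.0, beta1=0.0, beta2=0.0, beta_inv_temp=20.0))
    bal = balanced_trials_from_model(always_west, "world_NS", 4, rng)
    rmap = response_map(bal, n_per_cell=3, rng=rng)
    assert rmap.n_resampled == 432
    assert rmap.p_primary.shape == (12, 12)
    assert np.all(rmap.p_primary == 1.0)
    assert rmap.marginal_by_world == pytest.approx(np.ones(12))


def test_response_map_errors_on_missing_cells(rng):
    df = _table(50, 1.0)  # only a single condition populated
    with pytest.raises(ValueError, match="empty"):
        response_map(df, rng=rng)


def test_response_map_marginals_follow_generating_model(rng):
    bal = balanced_trials_from_model(get_preset("world_sim"), "world_NS", 40, rng)
    rmap = response_map(bal, n_per_cell=30, rng=rng)
    thetas = np.array(rmap.angles)
    expected = 1 / (1 + np.exp(-2 * (0.6 * np.cos(np.deg2rad(thetas)))))
    assert rmap.marginal_by_world == pytest.approx(expected, abs=0.06)
    assert rmap.marginal_by_head == pytest.approx(np.full(12, 0.5), abs=0.06)


def test_variance_by_frame_closed_forms():
    flat = ResponseMap(p_primary=np.full((12, 12), 0.3), n_per_cell=3)
    res = variance_by_frame(flat)
    assert res.var_world == pytest.approx(0.0, abs=1e-12)
    assert res.var_head == pytest.approx(0.0, abs=1e-12)

    alternating = ResponseMap(p_primary=np.tile([0.0, 1.0], 6)[None, :].repeat(12, 0),
                              n_per_cell=3)
    assert variance_by_frame(alternating, "n_minus_1").var_world == pytest.approx(3 / 11)
    assert variance_by_frame(alternating, "n").var_world == pytest.approx(0.25)


def test_variance_translation_invariance():
    rng = np.random.default_rng(1)
    base = rng.uniform(0.1, 0.4, size=(12, 12))
    v1 = variance_by_frame(ResponseMap(p_primary=base, n_per_cell=3))
    v2 = variance_by_frame(ResponseMap(p_primary=base + 0.3, n_per_cell=3))
    assert v1.var_world == pytest.approx(v2.var_world)
    assert v1.var_head == pytest.approx(v2.var_head)


def test_permutation_detects_world_modulation(rng):
    """A strongly world-modulated agent attains the minimum possible p."""
    bal = balanced_trials_from_model(get_preset("world_sim"), "world_NS", 12, rng)
    res = permutation_frame_test(bal, n_shuffles=300, rng=rng)
    assert res.var_world > res.var_head
    assert res.p_value == pytest.approx(1 / 301)


def test_permutation_head_task_mirror(rng):
    """Head-modulated behavior yields larger head-frame variance."""
    bal = balanced_trials_from_model(get_preset("head_task_sim"), "head_FB", 12, rng)
    res = permutation_frame_test(bal, n_shuffles=300, rng=rng)
    assert res.var_head > res.var_world
    assert res.p_value == pytest.approx(1 / 301)


def test_permutation_statistic_invariant_to_joint_relabeling(rng):
    """Permuting trials jointly with their (head, world) labels is a no-op."""
    bal = balanced_trials_from_model(get_preset("world_sim"), "world_NS", 6, rng)
    shuffled = bal.sample(frac=1.0, random_state=0).reset_index(drop=True)
    m1 = response_map(bal, rng=np.random.default_rng(42))
    m2 = response_map(shuffled, rng=np.random.default_rng(42))
    assert m1.p_primary == pytest.approx(m2.p_primary)


@pytest.mark.parametrize("p,expected", [(0.5, 0.0), (1.0, 1.0), (0.0, 1.0), (0.75, 0.5)])
def test_adjusted_response_probability(p, expected):
    assert adjusted_response_probability(p) == pytest.approx(expected)


def test_adjusted_response_probability_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjusted_response_probability(1.2)


def test_first_n_trials_performance(world_preset_trials, rng):
    # many short sessions per angle, as when the platform is rotated often
    from frameloc.simulate import simulate_experiment
    trials = simulate_experiment({a: 800 for a in range(-150, 181, 30)},
                                 get_preset("world_sim"), seed=77,
                                 sessions_per_angle=10)
    early = first_n_trials_performance(trials, n=10, n_per_sample=50, rng=rng)
    assert len(early) == 12
    assert set(early.index) == set(float(a) for a in range(-150, 181, 30))
    # a stationary agent performs the same early as overall (sampling error)
    overall = bootstrap_percent_correct(trials, platform_angle=0.0,
                                        n_per_sample=400, rng=rng)
    assert early[0.0] == pytest.approx(overall, abs=15.0)
    # deterministic agents are perfect from trial one
    det = ModelSpec("world_sinusoid",
                    ModelParams(beta0=0.5, beta1=0.3, beta2=0.0, beta_inv_temp=20.0))
    df = simulate_session(SessionConfig(task_variant="world_NS", platform_angle=0.0,
                                        n_trials=80, agent=det, seed=1))
    res = first_n_trials_performance(df, n=60, n_per_sample=50, rng=rng)
    assert res[0.0] == 100.0
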