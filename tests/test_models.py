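"""Choice-model activations, softmax, offset targeting and compensation."""

import numpy as np
import pytest
from scipy.special import expit

from frameloc.geometry import ALL_SLOTS, TASK_VARIANTS, condition_grid, wrap_angle
from frameloc.models import (
    ModelParams,
    ModelSpec,
    SIMULATION_PRESETS,
    compensate,
    get_preset,
    offset_target,
    primary_probability,
    response_probability,
    sinusoidal_activation,
    softmax_choice,
    spec_from_dict,
    spec_to_dict,
)

LAYOUT = TASK_VARIANTS["world_NS"].layout
SIN = ModelParams(beta0=0.5, beta1=0.3, beta2=0.0, beta_inv_temp=2.0)


@pytest.mark.parametrize("theta,expected", [(0, 0.8), (180, 0.2), (90, 0.5)])
def test_sinusoidal_activation_values(theta, expected):
    assert sinusoidal_activation(theta, SIN) == pytest.approx(expected)


def test_softmax_matches_logistic_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        z1, z2 = rng.uniform(-1, 2, size=2)
        eta = rng.uniform(0, 20)
        assert softmax_choice(z1, z2, eta) == pytest.approx(expit(eta * (z1 - z2)))


def test_softmax_symmetry_and_random_limit():
    assert softmax_choice(0.3, 0.3, 7.0) == pytest.approx(0.5)
    assert softmax_choice(0.9, 0.1, 0.0) == pytest.approx(0.5)
    assert softmax_choice(0.8, 0.2, 2.0) == pytest.approx(0.76852, abs=1e-4)


def test_softmax_deterministic_limit():
    # at the upper inverse-temperature bound choice approaches the argmax
    assert softmax_choice(0.8, 0.2, 20.0) > 0.9999
    assert softmax_choice(0.2, 0.8, 20.0) < 0.0001
    # near the lower bound choice approaches random
    assert softmax_choice(0.8, 0.2, 1e-4) == pytest.approx(0.5, abs=1e-4)


@pytest.mark.parametrize("theta,offset,expected", [(180, -90, -90), (0, 0, 0), (120, 90, 30)])
def test_offset_target_examples(theta, offset, expected):
    assert offset_target(theta, offset) == pytest.approx(expected)


def test_offset_target_round_trip():
    for theta in ALL_SLOTS:
        for delta in (-90.0, 30.0, 150.0):
            assert offset_target(offset_target(theta, delta), -delta) == pytest.approx(theta)


def _brute_force_compensate(target, strategy):
    """Independent oracle: explicit enumeration of wrapped distances."""
    def circ_dist(a, b):
        return min(abs(a - b + 360 * k) for k in (-1, 0, 1))

    d_west = circ_dist(target, -90.0)
    d_east = circ_dist(target, 90.0)
    if d_west == 0:
        return (1.0, 0.0)
    if d_east == 0:
        return (0.0, 1.0)
    if strategy == "guess":
        return (0.5, 0.5)
    if strategy == "nearest":
        if d_west < d_east:
            return (1.0, 0.0)
        if d_east < d_west:
            return (0.0, 1.0)
        return (0.5, 0.5)
    total = d_west + d_east
    return (d_east / total, d_west / total)


@pytest.mark.parametrize("strategy", ["guess", "nearest", "weighted"])
def test_compensate_matches_brute_force_on_all_slots(strategy):
    for slot in ALL_SLOTS:
        got = compensate(slot, LAYOUT, strategy)
        assert got == pytest.approx(_brute_force_compensate(slot, strategy))


def test_compensate_weighted_example():
    # target 30 deg from West and 150 deg from East
    a_west, a_east = compensate(-60.0, LAYOUT, "weighted")
    assert a_west == pytest.approx(150 / 180)
    assert a_east == pytest.approx(30 / 180)


def test_compensate_rejects_off_slot_target():
    with pytest.raises(ValueError):
        compensate(17.0, LAYOUT, "nearest")


def test_choice_distributions_sum_to_one_over_grid_and_presets():
    grid = condition_grid()
    for spec in SIMULATION_PRESETS.values():
        layout = TASK_VARIANTS["world_NS" if spec.response_space == "EastWest"
                               else "head_FB"].layout
        for cond in grid[::7]:
            dist = response_probability(spec, cond, layout)
            assert 0.0 <= dist.p_primary <= 1.0
            assert dist.p_primary + dist.p_secondary == pytest.approx(1.0)


def test_world_model_platform_invariant_and_head_model_world_invariant():
    grid = condition_grid()
    world = get_preset("world_sim")
    head = get_preset("head_west_sim")
    for fixed_world in (0.0, 60.0):
        ps = {round(response_probability(world, c, LAYOUT).p_primary, 12)
              for c in grid if c.speaker_world == fixed_world}
        assert len(ps) == 1
    for fixed_head in (0.0, -120.0):
        ps = {round(response_probability(head, c, LAYOUT).p_primary, 12)
              for c in grid if c.speaker_head == fixed_head}
        assert len(ps) == 1


def test_world_model_antisymmetry_about_trained_axis():
    world = get_preset("world_sim")
    for theta in ALL_SLOTS:
        a = primary_probability(world, 0.0, theta, LAYOUT)
        b = primary_probability(world, 0.0, wrap_angle(theta + 180.0), LAYOUT)
        assert a + b == pytest.approx(1.0)


def test_offset_family_is_platform_invariant_in_world_frame():
    # the aimed-at world location wrap(theta_world - beta_offset) does not
    # depend on the platform, so neither does the choice distribution
    grid = condition_grid()
    spec = get_preset("head_offset_sim")
    for fixed_world in ALL_SLOTS[::3]:
        ps = {round(response_probability(spec, c, LAYOUT).p_primary, 12)
              for c in grid if c.speaker_world == fixed_world}
        assert len(ps) == 1


def test_offset_weighted_profile_is_linear_in_world_angle():
    """Equally spaced ports make the weighted activation linear in world angle."""
    spec = get_preset("head_offset_sim")  # beta_offset=+90, eta=1
    thetas = np.array(ALL_SLOTS)
    p = np.array([primary_probability(spec, 0.0, t, LAYOUT) for t in
                  (wrap_angle(t) for t in thetas)])
    # activation a_West = (180 - |theta|)/180 -> logit is linear in |theta|
    expected = expit(1.0 * (2 * (180 - np.abs(thetas)) / 180 - 1))
    assert p == pytest.approx(expected)


def test_offset_without_strategy_errors_on_null_target():
    spec = ModelSpec("head_offset", ModelParams(beta_offset=30.0, beta_inv_temp=1.0),
                     strategy="none")
    with pytest.raises(ValueError, match="null"):
        primary_probability(spec, 0.0, 0.0, LAYOUT)


def test_strategy_only_for_offset_family():
    with pytest.raises(ValueError):
        ModelSpec("world_sinusoid", SIN, strategy="nearest")


def test_params_bounds_validation():
    with pytest.raises(ValueError):
        ModelParams(beta0=1.5, beta1=0.3, beta2=0.0, beta_inv_temp=2.0).validate("world_sinusoid")
    with pytest.raises(ValueError):
        ModelParams(beta0=0.5, beta1=0.3, beta2=0.0, beta_inv_temp=-1.0).validate("world_sinusoid")


def test_spec_round_trips_through_dict():
    for name, spec in SIMULATION_PRESETS.items():
        assert spec_from_dict(spec_to_dict(spec)) == spec
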