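"""World dynamics: transitions, direction assignment, trial/batch structure."""

import math

import numpy as np
import pytest

from nng import GameConfig
from nng.game import (
    BatchRecord,
    Feedback,
    Stimulus,
    assign_directions,
    batch_trial_angles,
    init_trial,
    run_batch,
    step,
    trial_success,
)
from nng.geometry import (
    TWO_PI,
    DegenerateStimulusError,
    angle_to_unit,
    circular_distance,
    target_difference_angle,
)
from nng.synthetic import make_scripted_ensemble


# ---------------------------------------------------------------------------
# geometry primitives


def test_angle_to_unit_examples():
    np.testing.assert_allclose(angle_to_unit(0.0), [1.0, 0.0], atol=1e-15)
    np.testing.assert_allclose(angle_to_unit(math.pi / 2), [0.0, 1.0], atol=1e-15)
    np.testing.assert_allclose(
        angle_to_unit(5 * math.pi / 4), [-math.sqrt(2) / 2, -math.sqrt(2) / 2], atol=1e-12
    )
    with pytest.raises(ValueError):
        angle_to_unit(float("nan"))


def test_angle_to_unit_is_unit_norm():
    rng = np.random.default_rng(0)
    for angle in rng.uniform(-10, 10, size=50):
        v = angle_to_unit(angle)
        assert np.hypot(*v) == pytest.approx(1.0)
        assert (math.atan2(v[1], v[0]) % TWO_PI) == pytest.approx(angle % TWO_PI)


def test_target_difference_angle_examples():
    assert target_difference_angle((0, 0), (1, 0)) == pytest.approx(0.0)
    assert target_difference_angle((0, 0), (0, -2)) == pytest.approx(3 * math.pi / 2)
    with pytest.raises(DegenerateStimulusError):
        target_difference_angle((1, 1), (1, 1))


# ---------------------------------------------------------------------------
# direction assignment


def test_assign_directions_windrose_structure():
    cfg = GameConfig()
    asg = assign_directions(cfg, np.random.default_rng(1))
    for dirs in (asg.sensor_directions, asg.actor_directions):
        assert len(dirs) == 4
        sorted_dirs = np.sort(dirs)
        gaps = np.diff(np.concatenate([sorted_dirs, [sorted_dirs[0] + TWO_PI]]))
        # approximately equiangular: 90 degrees within the 2 x 5 degree jitter
        np.testing.assert_allclose(gaps, math.pi / 2, atol=2 * cfg.windrose_jitter + 1e-9)
    # sensor and actor directions never coincide
    min_sep = min(
        circular_distance(s, a)
        for s in asg.sensor_directions
        for a in asg.actor_directions
    )
    assert min_sep > 0.1


def test_assign_directions_deterministic_under_seed():
    cfg = GameConfig()
    a1 = assign_directions(cfg, np.random.default_rng(7))
    a2 = assign_directions(cfg, np.random.default_rng(7))
    np.testing.assert_array_equal(a1.sensor_directions, a2.sensor_directions)
    np.testing.assert_array_equal(a1.actor_directions, a2.actor_directions)


def test_batch_trial_angles_equiangular():
    cfg = GameConfig()
    angles = batch_trial_angles(cfg, np.random.default_rng(3))
    assert len(angles) == 6
    sorted_a = np.sort(angles)
    gaps = np.diff(np.concatenate([sorted_a, [sorted_a[0] + TWO_PI]]))
    np.testing.assert_allclose(gaps, TWO_PI / 6, atol=2 * cfg.windrose_jitter + 1e-9)


# ---------------------------------------------------------------------------
# trial initialisation and transitions


def test_init_trial_geometry():
    cfg = GameConfig()
    rng = np.random.default_rng(2)
    state = init_trial(cfg, 0.8, rng)
    assert np.hypot(*(state.sensor_target - state.sensor_cursor)) == pytest.approx(840.0)
    np.testing.assert_array_equal(state.actor_cursor, [0.0, 0.0])
    np.testing.assert_array_equal(state.actor_target, [0.0, 0.0])
    assert state.t == 0
    with pytest.raises(DegenerateStimulusError):
        state.stimulus("actor")
    # determinism
    s1 = init_trial(cfg, 0.8, np.random.default_rng(5))
    s2 = init_trial(cfg, 0.8, np.random.default_rng(5))
    np.testing.assert_array_equal(s1.sensor_cursor, s2.sensor_cursor)
    np.testing.assert_array_equal(s1.sensor_target, s2.sensor_target)


def _mk_state(cfg):
    return init_trial(cfg, 0.0, np.random.default_rng(0))


def test_step_identity_with_no_actions():
    cfg = GameConfig()
    state = _mk_state(cfg)
    new = step(state, np.zeros(4, int), np.zeros(4, int), assign_directions(cfg, np.random.default_rng(0)), cfg)
    assert new.t == state.t + 1
    np.testing.assert_array_equal(new.sensor_cursor, state.sensor_cursor)
    np.testing.assert_array_equal(new.actor_cursor, state.actor_cursor)
    np.testing.assert_array_equal(new.actor_target, state.actor_target)


def test_step_single_actor_and_cancellation():
    cfg = GameConfig(step_actor_screen=1.0)
    state = _mk_state(cfg)
    asg = assign_directions(cfg, np.random.default_rng(0))
    asg.actor_directions = np.array([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
    new = step(state, np.zeros(4, int), np.array([1, 0, 0, 0]), asg, cfg)
    np.testing.assert_allclose(new.actor_cursor - state.actor_cursor, [1.0, 0.0], atol=1e-12)
    # two opposite actors cancel exactly
    new2 = step(state, np.zeros(4, int), np.array([1, 0, 1, 0]), asg, cfg)
    np.testing.assert_allclose(new2.actor_cursor, state.actor_cursor, atol=1e-12)
    np.testing.assert_allclose(new2.sensor_cursor, state.sensor_cursor, atol=1e-12)


def test_step_rejects_malformed_actions():
    cfg = GameConfig()
    state = _mk_state(cfg)
    asg = assign_directions(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError):
        step(state, np.zeros(3, int), np.zeros(4, int), asg, cfg)
    with pytest.raises(ValueError):
        step(state, np.zeros(4, int), np.array([0, 2, 0, 0]), asg, cfg)


def test_displacement_conservation_and_target_immobility():
    """Sensor- and actor-cursor displacements are parallel with ratio
    alpha/beta, and the sensor target never moves."""
    cfg = GameConfig(step_sensor_screen=5.0, step_actor_screen=2.0)
    state = _mk_state(cfg)
    asg = assign_directions(cfg, np.random.default_rng(4))
    rng = np.random.default_rng(8)
    for _ in range(200):
        a_s = (rng.random(4) < 0.4).astype(int)
        a_a = (rng.random(4) < 0.4).astype(int)
        new = step(state, a_s, a_a, asg, cfg)
        ds = new.sensor_cursor - state.sensor_cursor
        da = new.actor_cursor - state.actor_cursor
        np.testing.assert_allclose(ds, (5.0 / 2.0) * da, atol=1e-12)
        np.testing.assert_array_equal(new.sensor_target, state.sensor_target)
        state = new


def test_trial_success_boundary():
    cfg = GameConfig(target_radius=50.0)
    state = _mk_state(cfg)
    state.sensor_cursor = state.sensor_target.copy()
    assert trial_success(state, cfg)
    state.sensor_cursor = state.sensor_target + np.array([50.0, 0.0])
    assert trial_success(state, cfg)  # boundary inclusive
    state.sensor_cursor = state.sensor_target + np.array([840.0, 0.0])
    assert not trial_success(state, cfg)


# ---------------------------------------------------------------------------
# run_batch


class IdleAgent:
    def decide(self, stimulus):
        return 0

    def forced_idle(self):
        return 0

    def observe(self, feedback):
        pass

    def reset(self):
        pass


def test_run_batch_idle_agents_truncate():
    cfg = GameConfig(trials_per_batch=1, max_steps_per_trial=50)
    rng = np.random.default_rng(0)
    rec = run_batch([IdleAgent()] * 4, [IdleAgent()] * 4, cfg, rng)
    assert rec.trials[0].truncated
    assert rec.trials[0].n_steps == 50
    # with zero actions forever, all positions are fixed points
    pos = rec.trials[0].positions
    np.testing.assert_array_equal(pos[0], pos[-1])


def test_run_batch_scripted_agents_succeed_within_geometric_bound():
    cfg = GameConfig()
    rng = np.random.default_rng(3)
    asg = assign_directions(cfg, rng)
    sensors, actors = make_scripted_ensemble(asg, rng, p=1.0, q=0.0)
    rec = run_batch(sensors, actors, cfg, rng, assignment=asg)
    # >= 1 aligned unit per step, availability 0.8: generous slack factor 4
    bound = 4 * math.ceil(840.0 / cfg.step_sensor_screen)
    for trial in rec.trials:
        assert not trial.truncated
        assert trial.n_steps <= bound


def test_run_batch_deterministic_under_seed():
    cfg = GameConfig(trials_per_batch=2, max_steps_per_trial=300)

    def run(seed):
        rng = np.random.default_rng(seed)
        asg = assign_directions(cfg, rng)
        sensors, actors = make_scripted_ensemble(asg, rng, p=0.8, q=0.1)
        return run_batch(sensors, actors, cfg, rng, assignment=asg)

    r1, r2 = run(11), run(11)
    for t1, t2 in zip(r1.trials, r2.trials):
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.sensor_spikes, t2.sensor_spikes)
        np.testing.assert_array_equal(t1.actor_spikes, t2.actor_spikes)


def test_decision_availability_frequency():
    """The fraction of steps an agent is queried converges to the configured
    availability (binomial concentration)."""

    class CountingAgent(IdleAgent):
        def __init__(self):
            self.queried = 0
            self.idled = 0

        def decide(self, stimulus):
            self.queried += 1
            return 0

        def forced_idle(self):
            self.idled += 1
            return 0

    cfg = GameConfig(trials_per_batch=3, max_steps_per_trial=4000, decision_availability=0.8)
    agents = [CountingAgent() for _ in range(8)]
    run_batch(agents[:4], agents[4:], cfg, np.random.default_rng(5))
    for agent in agents:
        total = agent.queried + agent.idled
        assert total >= 10_000
        assert agent.queried / total == pytest.approx(0.8, abs=0.02)


def test_batch_record_roundtrip(tmp_path):
    cfg = GameConfig(trials_per_batch=2, max_steps_per_trial=200)
    rng = np.random.default_rng(9)
    asg = assign_directions(cfg, rng)
    sensors, actors = make_scripted_ensemble(asg, rng, p=0.9, q=0.05)
    rec = run_batch(sensors, actors, cfg, rng, assignment=asg)
    rec.save(tmp_path / "batch")
    loaded = BatchRecord.load(tmp_path / "batch")
    assert len(loaded.trials) == len(rec.trials)
    for t1, t2 in zip(rec.trials, loaded.trials):
        np.testing.assert_allclose(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.sensor_spikes, t2.sensor_spikes)
        np.testing.assert_array_equal(t1.actor_spikes, t2.actor_spikes)
        assert t1.truncated == t2.truncated
    np.testing.assert_allclose(
        loaded.assignment.sensor_directions, rec.assignment.sensor_directions
    )
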