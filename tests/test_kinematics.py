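"""BREM templates, embedded-saccade detection, inclusion, kinematic variables."""

import numpy as np
import pytest

from scmotor.config import GeneratorConfig
from scmotor.kinematics import (
    BREMTemplate,
    EmbeddedSaccadeOnset,
    apply_inclusion_criteria,
    build_brem_template,
    detect_embedded_saccade,
    endpoint_accuracy,
    goal_direction,
    project_on_goal,
    residual_velocity,
    vectorial_velocity,
)
from scmotor.synth import brem_template_mean, generate_brem_velocity


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def test_template_identical_traces_sd_floored():
    f = np.sin(np.linspace(0, 3, 100)) * 40.0
    tmpl = build_brem_template([(f, f), (f, f)])
    assert np.allclose(tmpl.mean_h, f)
    assert np.all(tmpl.sd_h == 1e-3)  # floored


def test_template_antisymmetric_pair_analytic_sd():
    f = np.linspace(0, 50, 80)
    tmpl = build_brem_template([(f, f), (-f, -f)])
    assert np.allclose(tmpl.mean_h, 0.0)
    expected = np.abs(f) * np.sqrt(2.0)  # sample s.d., n = 2
    sel = expected > 1e-3
    assert np.allclose(tmpl.sd_h[sel], expected[sel])


def test_template_needs_two_trials():
    f = np.zeros(10)
    with pytest.raises(ValueError):
        build_brem_template([(f, f)])


def test_template_recovers_generator_mean(rng):
    cfg = GeneratorConfig()
    draws = [generate_brem_velocity(cfg, rng) for _ in range(50)]
    tmpl = build_brem_template([(d.h_vel, d.v_vel) for d in draws])
    _, mh, _ = brem_template_mean(cfg)
    n = len(tmpl.mean_h)
    lo, hi = int(0.1 * n), int(0.9 * n)  # central 80% of support
    err = np.abs(tmpl.mean_h[lo:hi] - mh[lo:hi])
    assert err.max() < 0.05 * np.abs(mh).max()


# ---------------------------------------------------------------------------
# embedded-saccade detection
# ---------------------------------------------------------------------------

def _flat_template(n=200, sd=1.0):
    z = np.zeros(n)
    s = np.full(n, sd)
    return BREMTemplate(
        time=np.arange(float(n)), mean_h=z, mean_v=z, sd_h=s, sd_v=s, n_trials=5
    )


def test_detect_template_mean_is_no_saccade():
    tmpl = _flat_template()
    assert detect_embedded_saccade(tmpl.mean_h, tmpl.mean_v, tmpl) is None


def test_detect_constructed_crossing_components():
    tmpl = _flat_template(sd=1.0)
    h = np.zeros(200)
    v = np.zeros(200)
    h[40:60] = 100.0  # exceeds 2.5 s.d. from 40 ms for 20 samples
    v[55:80] = 100.0
    res = detect_embedded_saccade(h, v, tmpl)
    assert res.onset_delay == 40.0
    assert res.component == "horizontal"
    assert res.classification == "triggered"


def test_detect_fifteen_sample_rule():
    tmpl = _flat_template(sd=1.0)
    h = np.zeros(200)
    h[40:54] = 100.0  # 14 samples: too short
    h[70:100] = 100.0  # 30 samples: qualifies
    res = detect_embedded_saccade(h, np.zeros(200), tmpl)
    assert res.onset_delay == 70.0


def test_detect_exactly_fifteen_samples_qualifies():
    tmpl = _flat_template(sd=1.0)
    h = np.zeros(200)
    h[40:55] = 100.0
    res = detect_embedded_saccade(h, np.zeros(200), tmpl)
    assert res.onset_delay == 40.0


def test_detect_plausibility_check_rejects_slow_excursions():
    tmpl = _flat_template(sd=1.0)
    h = np.zeros(200)
    h[30:120] = 10.0  # sustained but far below saccadic speed
    assert detect_embedded_saccade(h, np.zeros(200), tmpl, min_saccade_speed=80.0) is None
    res = detect_embedded_saccade(h, np.zeros(200), tmpl, min_saccade_speed=None)
    assert res is not None and res.onset_delay == 30.0


def test_detect_bound_widening_never_earlier():
    tmpl = _flat_template(sd=4.0)
    rng = np.random.default_rng(3)
    for _ in range(10):
        h = np.zeros(200)
        start = rng.integers(20, 100)
        h[start : start + 40] = rng.uniform(15, 200)
        prev = None
        for mult in (1.5, 2.5, 4.0, 8.0):
            res = detect_embedded_saccade(
                h, np.zeros(200), tmpl, sd_multiplier=mult, min_saccade_speed=None
            )
            onset = np.inf if res is None else res.onset_delay
            if prev is not None:
                assert onset >= prev
            prev = onset


def test_embedded_onset_classification_boundary():
    assert EmbeddedSaccadeOnset(19.0, "horizontal", "early").classification == "early"
    with pytest.raises(ValueError):
        EmbeddedSaccadeOnset(-1.0, "horizontal", "early")


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------

def _det(delay):
    cls = "triggered" if delay >= 20 else "early"
    return EmbeddedSaccadeOnset(float(delay), "horizontal", cls)


def test_inclusion_six_trials_excluded():
    res = apply_inclusion_criteria({i: _det(30) for i in range(6)})
    assert not res.in_threshold_set and not res.in_motor_potential_set


def test_inclusion_threshold_only():
    dets = {i: _det(30 if i < 5 else 5) for i in range(10)}
    res = apply_inclusion_criteria(dets)
    assert res.in_threshold_set
    assert not res.in_motor_potential_set
    assert res.triggered_trial_ids == [0, 1, 2, 3, 4]


def test_inclusion_both_sets():
    dets = {i: _det(25) for i in range(8)}
    dets[99] = None  # undetected trials never count
    res = apply_inclusion_criteria(dets)
    assert res.in_threshold_set and res.in_motor_potential_set
    assert 99 not in res.blink_trial_ids


# ---------------------------------------------------------------------------
# kinematic variables
# ---------------------------------------------------------------------------

def test_vectorial_velocity():
    assert vectorial_velocity([3.0], [4.0])[0] == pytest.approx(5.0)
    assert vectorial_velocity([0.0], [0.0])[0] == 0.0
    rng = np.random.default_rng(1)
    h, v = rng.standard_normal(50), rng.standard_normal(50)
    assert np.array_equal(vectorial_velocity(h, v), np.hypot(h, v))
    with pytest.raises(ValueError):
        vectorial_velocity(np.zeros(3), np.zeros(4))


def test_residual_velocity():
    f = np.linspace(0, 30, 60)
    tmpl = build_brem_template([(f, f), (f, f)])
    rh, rv = residual_velocity(f, f, tmpl)
    assert np.allclose(rh, 0.0) and np.allclose(rv, 0.0)
    rh, rv = residual_velocity(f + 10.0, f, tmpl)
    assert np.allclose(rh, 10.0) and np.allclose(rv, 0.0)
    # beyond template support nothing is subtracted
    long_h = np.concatenate([f, np.full(10, 7.0)])
    rh, _ = residual_velocity(long_h, np.zeros(70), tmpl)
    assert np.allclose(rh[60:], 7.0)


def test_project_on_goal_analytic_cases():
    assert project_on_goal([10.0], [0.0], 0.0)[0] == pytest.approx(10.0)
    assert project_on_goal([10.0], [0.0], 90.0)[0] == pytest.approx(0.0, abs=1e-12)
    assert project_on_goal([-5.0], [5.0], 135.0)[0] == pytest.approx(7.0710678, rel=1e-6)
    assert project_on_goal([5.0], [0.0], 180.0)[0] == pytest.approx(-5.0)
    assert project_on_goal([0.0], [0.0], 30.0)[0] == 0.0


def test_project_rotation_consistency(rng):
    h, v = rng.standard_normal(40), rng.standard_normal(40)
    base = project_on_goal(h, v, 25.0)
    for extra in (10.0, 90.0, 200.0):
        th = np.radians(extra)
        hr = h * np.cos(th) - v * np.sin(th)
        vr = h * np.sin(th) + v * np.cos(th)
        assert np.allclose(project_on_goal(hr, vr, 25.0 + extra), base)


def test_goal_direction_and_endpoint_accuracy():
    assert goal_direction((0, 0), (10, 10)) == pytest.approx(45.0)
    with pytest.raises(ValueError):
        goal_direction((1, 1), (1, 1))
    assert endpoint_accuracy((10.0, 0.0), (10.0, 0.0)) == 0.0
    assert endpoint_accuracy((0.0, 0.0), (10.0, 0.0)) == pytest.approx(1.0)
    assert endpoint_accuracy((10.0, 1.0), (10.0, 0.0)) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        endpoint_accuracy((1.0, 1.0), (0.0, 0.0))


def test_projected_matches_raw_mid_saccade_on_controls(small_processed):
    """Control saccades head at the goal, so the goal projection of the raw
    velocity tracks the vectorial speed during the movement."""
    proj_all, raw_all = [], []
    for t in small_processed.control:
        if t.saccade_onset is None:
            continue
        sel = (t.trial.eye.time >= t.saccade_onset) & (
            t.trial.eye.time <= t.movement_offset
        )
        proj_all.append(t.kinematic_series[sel])
        raw_all.append(vectorial_velocity(t.h_vel[sel], t.v_vel[sel]))
    proj = np.concatenate(proj_all)
    raw = np.concatenate(raw_all)
    assert np.corrcoef(proj, raw)[0, 1] > 0.95
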