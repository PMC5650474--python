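"""Threshold (initiation-criterion) and accumulation-rate analyses."""

import numpy as np
import pytest

from scmotor.initiation import (
    THRESHOLD_BINS,
    RateFitResult,
    binned_activity,
    classify_neuron_timecourse,
    compare_rate_conditions,
    make_surrogate_control,
    per_trial_binned_activity,
    piecewise_rate_fit,
    population_bin_comparison,
    rate_modulation_index,
)


# ---------------------------------------------------------------------------
# binned activity
# ---------------------------------------------------------------------------

def test_bins_tile_without_overlap():
    edges = [b for bin_ in THRESHOLD_BINS for b in bin_]
    assert THRESHOLD_BINS[0] == (-50, -40)
    assert THRESHOLD_BINS[-1] == (10, 20)
    for (lo1, hi1), (lo2, hi2) in zip(THRESHOLD_BINS, THRESHOLD_BINS[1:]):
        assert hi1 == lo2


def test_binned_activity_constant():
    rel = np.arange(-55.0, 25.0)
    mat = np.full((5, len(rel)), 0.6)
    assert np.allclose(binned_activity(rel, mat), 0.6)


def test_binned_activity_linear_ramp():
    rel = np.arange(-50.0, 20.0)
    ramp = (rel + 50.0) / 70.0  # 0 -> 1 over the support
    mat = np.tile(ramp, (4, 1))
    out = binned_activity(rel, mat)
    # half-open [lo, hi): mean of the 10 samples lo..lo+9 = value at lo+4.5
    expected = [np.mean(ramp[(rel >= lo) & (rel < hi)]) for lo, hi in THRESHOLD_BINS]
    assert np.allclose(out, expected)
    assert np.all(np.diff(out) > 0)
    assert out[0] == pytest.approx((4.5) / 70.0)


def test_binned_activity_missing_support():
    rel = np.arange(-20.0, 20.0)
    mat = np.ones((3, len(rel)))
    out = binned_activity(rel, mat)
    assert np.isnan(out[0]) and np.isnan(out[1])  # bins before -20 ms unsupported
    assert out[-1] == 1.0


# ---------------------------------------------------------------------------
# population bin comparison
# ---------------------------------------------------------------------------

def test_population_comparison_identical_conditions():
    rng = np.random.default_rng(0)
    control = rng.uniform(0.2, 1.0, size=(10, 7))
    res = population_bin_comparison(control, control.copy())
    for b in res:
        assert b.p_value == 1.0
        assert not b.control_higher
        assert b.fit_slope == pytest.approx(1.0)
        assert b.fit_intercept == pytest.approx(0.0, abs=1e-12)


def test_population_comparison_scaled_blink():
    rng = np.random.default_rng(1)
    control = rng.uniform(0.2, 1.0, size=(12, 7))
    blink = 0.8 * control
    res = population_bin_comparison(control, blink)
    for b in res:
        assert b.p_value < 0.05
        assert b.control_higher
        assert b.fit_slope == pytest.approx(0.8, abs=1e-9)
        assert b.fit_intercept == pytest.approx(0.0, abs=1e-9)


def test_population_comparison_too_few_pairs():
    control = np.random.default_rng(2).uniform(size=(4, 7))
    res = population_bin_comparison(control, 0.5 * control)
    assert all(np.isnan(b.p_value) for b in res)


def test_population_comparison_normalization_invariant():
    rng = np.random.default_rng(3)
    control = rng.uniform(0.2, 1.0, size=(10, 7))
    blink = control * rng.uniform(0.6, 1.1, size=(10, 7))
    p1 = [b.p_value for b in population_bin_comparison(control, blink)]
    p2 = [b.p_value for b in population_bin_comparison(control * 7.3, blink * 7.3)]
    assert np.allclose(p1, p2)


# ---------------------------------------------------------------------------
# per-neuron classification
# ---------------------------------------------------------------------------

def test_classification_identical_distributions():
    rng = np.random.default_rng(4)
    trials = [rng.uniform(size=(20, 7)) for _ in range(5)]
    classes, props = classify_neuron_timecourse(trials, [t.copy() for t in trials])
    assert np.all(classes == "nodiff")
    assert np.allclose(props["nodiff"], 1.0)
    assert np.allclose(props["higher"] + props["lower"] + props["nodiff"], 1.0)


def test_classification_shifted_blink_lower():
    rng = np.random.default_rng(5)
    control = [rng.uniform(1.0, 1.2, size=(25, 7)) for _ in range(6)]
    blink = [c * 0.5 for c in control]
    classes, props = classify_neuron_timecourse(control, blink)
    assert np.all(classes == "lower")
    assert np.allclose(props["lower"], 1.0)


def test_classification_insufficient_trials_nodiff():
    control = [np.ones((2, 7))]
    blink = [np.zeros((20, 7))]
    classes, _ = classify_neuron_timecourse(control, blink)
    assert np.all(classes == "nodiff")


def test_classification_window_labels_are_right_edged():
    """The class at -10 ms reads the [-20, -10) bin (activity strictly before
    the labeled time)."""
    idx = [i for i, b in enumerate(THRESHOLD_BINS) if b[1] == -10]
    assert idx == [3]
    assert THRESHOLD_BINS[3] == (-20, -10)


# ---------------------------------------------------------------------------
# surrogate construction
# ---------------------------------------------------------------------------

def test_surrogate_single_blink_time():
    surr = make_surrogate_control(10, [137.0], n_pseudo=50, seed=0)
    assert np.all(surr.pseudo_blink_times == 137.0)
    assert len(surr.trial_indices) == 50
    assert surr.trial_indices.max() < 10


def test_surrogate_count_and_determinism():
    a = make_surrogate_control(20, [100.0, 150.0, 200.0], n_pseudo=1000, seed=3)
    b = make_surrogate_control(20, [100.0, 150.0, 200.0], n_pseudo=1000, seed=3)
    assert len(a.pseudo_blink_times) == 1000
    assert np.array_equal(a.trial_indices, b.trial_indices)
    assert np.array_equal(a.pseudo_blink_times, b.pseudo_blink_times)


def test_surrogate_matches_empirical_distribution():
    times = np.array([100.0, 120.0, 150.0, 180.0, 210.0, 240.0])
    surr = make_surrogate_control(30, times, n_pseudo=1000, seed=1)
    # KS distance between the sample ECDF and the true discrete CDF
    ks = 0.0
    for i, t in enumerate(np.sort(times)):
        emp = np.mean(surr.pseudo_blink_times <= t)
        ks = max(ks, abs(emp - (i + 1) / len(times)))
    assert ks < 0.05


def test_surrogate_errors():
    with pytest.raises(ValueError):
        make_surrogate_control(0, [100.0])
    with pytest.raises(ValueError):
        make_surrogate_control(5, [])


# ---------------------------------------------------------------------------
# piecewise fits and the modulation index
# ---------------------------------------------------------------------------

def test_piecewise_single_line():
    t = np.arange(-20.0, 21.0)
    fit = piecewise_rate_fit(t, 0.3 + 0.002 * t, "blink")
    assert fit.rate_pre == pytest.approx(0.002, abs=1e-12)
    assert fit.rate_post == pytest.approx(0.002, abs=1e-12)


def test_piecewise_slope_change_recovered_exactly():
    t = np.arange(-20.0, 21.0)
    y = np.where(t < 0, 0.5 + 0.001 * t, 0.5 + 0.003 * t)
    fit = piecewise_rate_fit(t, y, "blink")
    assert fit.rate_pre == pytest.approx(0.001, abs=1e-12)
    assert fit.rate_post == pytest.approx(0.003, abs=1e-12)
    assert fit.modulation_index == pytest.approx(0.5)


def test_piecewise_too_few_samples():
    t = np.arange(-3.0, 4.0)
    with pytest.raises(ValueError):
        piecewise_rate_fit(t, np.ones_like(t), "blink")


def test_modulation_index_values():
    assert rate_modulation_index(1.0, 1.0) == 0.0
    assert rate_modulation_index(0.5, 1.5) == pytest.approx(0.5)
    assert rate_modulation_index(1.0, 0.0) == -1.0
    assert rate_modulation_index(0.5, -0.5) is None  # undefined, excluded


def test_modulation_index_antisymmetry(rng):
    for _ in range(50):
        pre, post = rng.uniform(-1, 1, size=2)
        if pre + post == 0:
            continue
        assert rate_modulation_index(pre, post) == pytest.approx(
            -rate_modulation_index(post, pre)
        )


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _fits(pre, posts, condition):
    return [RateFitResult(rate_pre=pre, rate_post=p, condition=condition) for p in posts]


def test_compare_identical_conditions():
    rng = np.random.default_rng(6)
    posts = rng.uniform(0.5, 1.5, size=8)
    blink = _fits(0.5, posts, "blink")
    surr = _fits(0.5, posts, "control-surrogate")
    res = compare_rate_conditions(blink, surr)
    assert res.p_index == 1.0
    assert not res.blink_higher


def test_compare_shifted_indices_significant():
    rng = np.random.default_rng(7)
    pre = 1.0
    surr_posts = rng.uniform(0.9, 1.1, size=10)
    blink_posts = surr_posts * 2.0  # clearly higher indices
    res = compare_rate_conditions(_fits(pre, blink_posts, "blink"), _fits(pre, surr_posts, "s"))
    assert res.p_index < 0.05
    assert res.blink_higher
    assert res.blink_index_median > res.surrogate_index_median


def test_compare_too_few_neurons_skipped():
    res = compare_rate_conditions(_fits(1.0, [1.1, 1.2], "b"), _fits(1.0, [1.0, 1.1], "s"))
    assert np.isnan(res.p_index)
    assert res.notes


def test_compare_unpaired_lists_rejected():
    with pytest.raises(ValueError):
        compare_rate_conditions(_fits(1.0, [1.0] * 3, "b"), _fits(1.0, [1.0] * 4, "s"))


def test_per_trial_binned_activity_shape():
    rel = np.arange(-55.0, 25.0)
    mat = np.tile(np.linspace(0, 1, len(rel)), (9, 1))
    out = per_trial_binned_activity(rel, mat)
    assert out.shape == (9, 7)
    assert np.all(np.diff(out, axis=1) > 0)
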