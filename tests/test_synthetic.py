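"""Generator-level tests: schedule, glucose kinetics, spectra, references."""

import numpy as np
import pytest
from dataclasses import replace

from nigm.synthetic import (DEFAULT_PHOTOTYPE_BASELINE, RawFrame,
                            SimulationConfig, apply_isf_lag,
                            clean_frame_components, default_schedule,
                            glucose_timecourse, inject_spikes, make_device,
                            meal_response, render_placement, sample_reference,
                            simulate_cohort)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def test_default_schedule_counts_and_spacing():
    sched = default_schedule()
    day1 = sched.day_slots(1)
    day2 = sched.day_slots(2)
    cal = [s for s in day1 if s.role == "calibration"]
    val1 = [s for s in day1 if s.role == "validation"]
    assert (len(cal), len(val1), len(day2)) == (10, 14, 26)
    assert all(s.role == "validation" for s in day2)
    assert np.allclose(np.diff([s.time_min for s in cal]), 20.0)
    assert np.allclose(np.diff([s.time_min for s in val1]), 15.0)
    assert np.allclose(np.diff([s.time_min for s in day2]), 15.0)


def test_venous_plan_calibration_and_every_second_day1_validation():
    sched = default_schedule()
    assert all(s.venous_planned for s in sched.slots if s.role == "calibration")
    val1 = [s for s in sched.day_slots(1) if s.role == "validation"]
    assert [s.venous_planned for s in val1] == [i % 2 == 0 for i in range(14)]
    assert not any(s.venous_planned for s in sched.day_slots(2))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def test_simulate_cohort_is_seed_deterministic():
    cfg = SimulationConfig(n_subjects=1, rng_seed=7)
    b1 = simulate_cohort(cfg)
    b2 = simulate_cohort(SimulationConfig(n_subjects=1, rng_seed=7))
    s1, s2 = b1.subjects[0], b2.subjects[0]
    assert s1.params.tau_min == s2.params.tau_min
    np.testing.assert_array_equal(s1.traces[1].capillary, s2.traces[1].capillary)
    np.testing.assert_array_equal(s1.sessions[0].placements[0].frames,
                                  s2.sessions[0].placements[0].frames)
    np.testing.assert_array_equal(s1.sessions[3].capillary_refs,
                                  s2.sessions[3].capillary_refs)


def test_empty_cohort_is_allowed():
    bundle = simulate_cohort(SimulationConfig(n_subjects=0, rng_seed=0))
    assert bundle.subjects == []


def test_session_counts_per_subject(tiny_bundle):
    for rec in tiny_bundle.subjects:
        roles = [s.role for s in rec.sessions]
        assert roles.count("calibration") == 10
        assert roles.count("validation") == 40


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="non-decreasing"):
        cfg = SimulationConfig(
            baseline_scale_by_phototype={1: 2.0, 2: 1.0, 3: 1.0, 4: 1.0,
                                         5: 1.0, 6: 1.0})
        cfg.validate()
    with pytest.raises(ValueError, match="carbohydrate"):
        SimulationConfig(meal_carbs_g={1: (-5.0,), 2: ()}).validate()


# ---------------------------------------------------------------------------
# glucose kinetics
# ---------------------------------------------------------------------------


def test_flat_timecourse_without_meals_or_drift(subject_params):
    cfg = SimulationConfig(drift_sd_mmol=0.0, meal_carbs_g={1: (), 2: ()})
    tr = glucose_timecourse(subject_params, cfg.schedule,
                            np.random.default_rng(0), cfg, day=1)
    np.testing.assert_allclose(tr.capillary, 7.0)
    np.testing.assert_allclose(tr.interstitial, 7.0)
    np.testing.assert_allclose(tr.venous, 7.0)


def test_meal_response_peak_and_return():
    t = np.arange(0.0, 360.0, 1.0)
    resp = meal_response(t, 70.0)
    t_peak = t[np.argmax(resp)]
    assert 0 < t_peak < 120
    assert resp[0] == 0.0
    # matches the closed form: difference of exponentials, unit-peak normalized
    t_star = np.log(90 / 15) * 90 * 15 / (90 - 15)
    peak = np.exp(-t_star / 90) - np.exp(-t_star / 15)
    expected_240 = 70 * 0.05 * (np.exp(-240 / 90) - np.exp(-240 / 15)) / peak
    assert resp[240] == pytest.approx(expected_240, rel=1e-9)
    # decayed to under 5% of peak by +6 h
    assert resp[-1] < 0.05 * resp.max()
    np.testing.assert_allclose(meal_response(t, 140.0), 2.0 * resp)
    with pytest.raises(ValueError):
        meal_response(t, -1.0)


def test_hypoglycemia_floor_enforced(subject_params):
    low = replace(subject_params, baseline_glucose_mmol=3.0)
    cfg = SimulationConfig(drift_sd_mmol=0.0, meal_carbs_g={1: (), 2: ()})
    tr = glucose_timecourse(low, cfg.schedule, np.random.default_rng(0), cfg, day=1)
    assert tr.capillary.min() >= 3.9


def test_isf_lag_constant_is_fixed_point():
    const = np.full(100, 6.5)
    np.testing.assert_allclose(apply_isf_lag(const, 10.0), const)


def test_isf_lag_step_response_63_percent():
    # fine grid so the discrete recursion approximates the continuous lag
    dt = 0.1
    step = np.concatenate([np.full(50, 5.0), np.full(600, 10.0)])
    out = apply_isf_lag(step, 10.0, dt_min=dt)
    value_at_tau = out[50 + 100]
    assert abs(value_at_tau - (5.0 + 5.0 * (1 - np.exp(-1)))) < 0.05


def test_isf_lag_tau_at_grid_tracks_with_one_sample_delay():
    x = np.sin(np.linspace(0, 3, 50)) + 6
    out = apply_isf_lag(x, 1.0, dt_min=1.0)
    np.testing.assert_allclose(out[1:], x[:-1])
    with pytest.raises(ValueError):
        apply_isf_lag(x, 0.0)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _noise_free_config():
    return SimulationConfig(shot_noise_scale=0.0, spike_rate_per_frame=0.0,
                            confounder_drift_sd=0.0)


def test_frame_difference_is_scaled_glucose_signature(subject_params):
    cfg = _noise_free_config()
    dev = make_device("D00", np.random.default_rng(1))
    f_lo = render_placement(5.0, subject_params, dev, np.random.default_rng(2), cfg)
    f_hi = render_placement(9.0, subject_params, dev, np.random.default_rng(2), cfg)
    diff = f_hi[0].pixel_intensities - f_lo[0].pixel_intensities
    comp = clean_frame_components(1.0, subject_params, dev, cfg)
    np.testing.assert_allclose(diff, 4.0 * comp["glucose"], atol=1e-9)


def test_zero_coupling_removes_glucose_information(subject_params):
    cfg = replace(_noise_free_config(), glucose_signal_scale=0.0)
    dev = make_device("D00", np.random.default_rng(1))
    f_lo = render_placement(5.0, subject_params, dev, np.random.default_rng(2), cfg)
    f_hi = render_placement(9.0, subject_params, dev, np.random.default_rng(2), cfg)
    np.testing.assert_allclose(f_lo[0].pixel_intensities, f_hi[0].pixel_intensities)


def test_darker_phototype_has_larger_baseline(subject_params):
    cfg = _noise_free_config()
    dev = make_device("D00", np.random.default_rng(1))
    p2 = replace(subject_params, phototype=2)
    p6 = replace(subject_params, phototype=6)
    b2 = clean_frame_components(7.0, p2, dev, cfg)["baseline"]
    b6 = clean_frame_components(7.0, p6, dev, cfg)["baseline"]
    assert np.all(b6 > b2)
    mult = [DEFAULT_PHOTOTYPE_BASELINE[k] for k in range(1, 7)]
    assert mult == sorted(mult)


def test_render_rejects_nonpositive_glucose(subject_params):
    cfg = _noise_free_config()
    dev = make_device("D00", np.random.default_rng(1))
    with pytest.raises(ValueError):
        render_placement(0.0, subject_params, dev, np.random.default_rng(0), cfg)


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def _flat_frame():
    dev = make_device("D00", np.random.default_rng(1))
    return RawFrame(np.full(1024, 900.0), dev.device_id, dev.pixel_map,
                    np.zeros(1024, dtype=bool))


def test_zero_rate_leaves_frame_unchanged():
    f = _flat_frame()
    out = inject_spikes(f, 0.0, np.random.default_rng(0))
    np.testing.assert_array_equal(out.pixel_intensities, f.pixel_intensities)
    assert not out.spike_mask.any()


def test_spike_count_is_poisson_with_requested_rate():
    rng = np.random.default_rng(5)
    counts = []
    for _ in range(2000):
        out = inject_spikes(_flat_frame(), 1.5, rng)
        counts.append(out.spike_mask.sum())
    # spiked pixels >= spikes (width 1-2), so compare against the event count
    # indirectly: mean pixels per frame in [1.5, 3.0] with 3 SE slack
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert 1.5 - 3 * se <= mean <= 2.25 + 3 * se + 0.25


def test_spike_amplitude_at_least_8x_noise_scale():
    rng = np.random.default_rng(6)
    f = _flat_frame()
    out = inject_spikes(f, 5.0, rng)
    delta = out.pixel_intensities - f.pixel_intensities
    noise = np.sqrt(900.0)
    spiked = out.spike_mask
    assert spiked.any()
    assert np.all(delta[spiked] >= 0.999 * (8.0 * 0.6) * noise)
    # primary pixels always clear 8x
    assert delta[spiked].max() >= 8.0 * noise


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------


def test_reference_noise_free_equals_truth():
    cfg = SimulationConfig(bgsm_cv=0.0, venous_cv=0.0)
    rng = np.random.default_rng(0)
    np.testing.assert_allclose(sample_reference(7.5, "capillary", rng, cfg), 7.5)
    np.testing.assert_allclose(sample_reference(7.5, "venous", rng, cfg), 7.5)


def test_reference_cv_recovered_and_method_shapes():
    cfg = SimulationConfig()
    rng = np.random.default_rng(1)
    draws = np.concatenate([
        sample_reference(10.0, "capillary", rng, cfg) for _ in range(5000)
    ])
    cv = draws.std() / draws.mean()
    assert abs(cv - cfg.bgsm_cv) < 0.1 * cfg.bgsm_cv
    assert sample_reference(10.0, "capillary", rng, cfg).shape == (2,)
    assert sample_reference(10.0, "venous", rng, cfg).shape == (1,)
    assert cfg.venous_cv < cfg.bgsm_cv
    with pytest.raises(ValueError):
        sample_reference(10.0, "arterial", rng, cfg)
    with pytest.raises(ValueError):
        sample_reference(-1.0, "venous", rng, cfg)


def test_tau_draws_truncated_positive(tiny_bundle):
    for rec in tiny_bundle.subjects:
        assert rec.params.tau_min >= tiny_bundle.config.tau_floor_min
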