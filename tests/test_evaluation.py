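"""Evaluation tests: QC filtering, pairing, metrics, delay, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nigm.evaluation import (PairedPoint, bootstrap_ci, build_metrics_report,
                             covariate_correlation, estimate_delay,
                             filter_reference_outliers, mard, pair_sessions,
                             points_frame, reference_comparison, rmse)
from nigm.synthetic import Session


def _session(bg1, bg2, venous=None, subject="S1", day=1, index=0,
             role="validation", time_min=700.0):
    return Session(subject_id=subject, day=day, index=index, role=role,
                   time_min=time_min, capillary_refs=np.array([bg1, bg2]),
                   venous_ref=venous, placements=[], true_capillary=bg1,
                   true_interstitial=bg1, true_venous=bg1)


def _points(refs, preds, subject="S1"):
    return pd.DataFrame({
        "ref_mmol": refs, "nigm_mmol": preds,
        "subject_id": [subject] * len(refs) if isinstance(subject, str) else subject,
    })


# ---------------------------------------------------------------------------
# outlier filter and pairing
# ---------------------------------------------------------------------------


def test_duplicate_outlier_rule_is_strictly_greater_than_1mmol():
    s_drop = _session(5.0, 6.2)     # |diff| = 1.2 -> dropped
    s_keep = _session(5.0, 5.8)     # 0.8 -> kept
    s_edge = _session(5.0, 6.0)     # exactly 1.0 -> kept
    s_miss = _session(5.0, np.nan)
    kept, dropped, missing = filter_reference_outliers(
        [s_drop, s_keep, s_edge, s_miss])
    assert kept == [s_keep, s_edge]
    assert dropped == [s_drop]
    assert missing == [s_miss]
    assert len(kept) + len(dropped) + len(missing) == 4


def test_pairing_uses_duplicate_mean_and_skips_missing_venous():
    s1 = _session(5.2, 5.6, venous=5.1, index=0)
    s2 = _session(7.0, 7.4, venous=None, index=1)
    preds = {s1.session_key: 5.5, s2.session_key: 7.1}
    cap = pair_sessions([s1, s2], preds, "capillary")
    assert [p.ref_mmol for p in cap] == [pytest.approx(5.4), pytest.approx(7.2)]
    ven = pair_sessions([s1, s2], preds, "venous")
    assert len(ven) == 1 and ven[0].ref_mmol == 5.1
    assert pair_sessions([], {}, "capillary") == []
    with pytest.raises(ValueError):
        pair_sessions([s1], preds, "arterial")
    with pytest.raises(KeyError):
        pair_sessions([s1], {}, "capillary")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_mard_and_rmse_hand_computed_tables():
    pts = _points([5.0, 10.0], [5.5, 9.0])
    assert mard(pts) == pytest.approx(10.0)
    assert rmse(pts) == pytest.approx(np.sqrt((0.25 + 1.0) / 2))
    perfect = _points([4.0, 8.0], [4.0, 8.0])
    assert mard(perfect) == 0.0
    assert rmse(perfect) == 0.0
    errs = _points([6.0, 6.0], [7.0, 5.0])
    assert rmse(errs) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mard(_points([], []))
    with pytest.raises(ValueError):
        rmse(_points([], []))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=0.5, max_value=50.0))
def test_mard_scale_invariant_rmse_scales_linearly(factor):
    rng = np.random.default_rng(0)
    ref = rng.uniform(4, 12, 30)
    pred = ref * rng.lognormal(0, 0.08, 30)
    base = _points(ref, pred)
    scaled = _points(ref * factor, pred * factor)
    assert mard(scaled) == pytest.approx(mard(base), rel=1e-9)
    assert rmse(scaled) == pytest.approx(factor * rmse(base), rel=1e-9)
    assert rmse(base) >= np.mean(np.abs(pred - ref)) - 1e-12


def test_bootstrap_ci_contracts():
    rng = np.random.default_rng(3)
    n_subj, per = 50, 10
    subj = np.repeat([f"S{i:02d}" for i in range(n_subj)], per)
    ref = rng.uniform(4, 12, n_subj * per)
    # per-subject error scale varies so subject resampling has real spread
    scales = np.repeat(rng.uniform(0.2, 1.0, n_subj), per)
    pred = ref + rng.normal(0, 1, n_subj * per) * scales
    pts = _points(ref, pred, subject=subj)
    lo, hi = bootstrap_ci(pts, mard, n_boot=300, seed=1)
    assert lo <= mard(pts) <= hi
    # deterministic given seed
    assert (lo, hi) == bootstrap_ci(pts, mard, n_boot=300, seed=1)
    # zero-error data -> degenerate zero interval
    z = _points(ref, ref, subject=subj)
    assert bootstrap_ci(z, mard, n_boot=50, seed=0) == (0.0, 0.0)
    # 5 subjects -> wider interval than 50 subjects
    few = _points(ref[:5 * per], pred[:5 * per], subject=subj[:5 * per])
    lo2, hi2 = bootstrap_ci(few, mard, n_boot=300, seed=1)
    assert (hi2 - lo2) > (hi - lo)


# ---------------------------------------------------------------------------
# delay estimation
# ---------------------------------------------------------------------------


def test_delay_zero_for_identical_series():
    t = np.arange(0, 480, 15.0)
    v = np.sin(2 * np.pi * t / 240) + 7
    assert estimate_delay(t, v, t, v) == 0.0


def test_delay_recovers_shifted_sinusoid():
    t = np.arange(0, 480, 15.0)
    ref = np.sin(2 * np.pi * t / 240) + 7
    nigm = np.sin(2 * np.pi * (t - 10.0) / 240) + 7
    assert estimate_delay(t, ref, t, nigm) == pytest.approx(10.0)


def test_delay_errors_on_constant_or_short_series():
    t = np.arange(0, 480, 15.0)
    with pytest.raises(ValueError, match="constant"):
        estimate_delay(t, np.full_like(t, 6.0), t, np.sin(t) + 7)
    with pytest.raises(ValueError, match=">= 8"):
        estimate_delay(t[:4], np.sin(t[:4]) + 7, t[:4], np.sin(t[:4]) + 7)


def test_delay_recovery_on_latent_traces():
    """The shift estimator recovers short time constants to the minute;
    long time constants are underestimated by the low-pass bias."""
    from nigm.synthetic import SimulationConfig, SubjectParams, glucose_timecourse

    cfg = SimulationConfig(drift_sd_mmol=0.0)
    for tau, lo, hi in [(5.0, 4.0, 6.0), (10.0, 9.0, 11.0), (20.0, 15.0, 20.0)]:
        p = SubjectParams("x", 60, 1, 28, 55, 3, 160, 7.0, tau, 1.0,
                          np.ones(8) * 25, "D00")
        tr = glucose_timecourse(p, cfg.schedule, np.random.default_rng(0),
                                cfg, day=2)
        lag = estimate_delay(tr.times_min, tr.capillary,
                             tr.times_min, tr.interstitial)
        assert lo <= lag <= hi, tau


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def test_covariate_correlation_known_values():
    mards = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
    cov = pd.DataFrame({
        "same": [1.0, 2.0, 3.0, 4.0],
        "toy": [2.0, 1.0, 4.0, 3.0],
        "flat": [5.0, 5.0, 5.0, 5.0],
    }, index=list("abcd"))
    tab = covariate_correlation(mards, cov)
    assert tab.loc["same", "r"] == pytest.approx(1.0)
    assert tab.loc["toy", "r"] == pytest.approx(0.6)
    assert not tab.loc["flat", "computable"]
    # symmetry of Pearson r in argument order
    swapped = covariate_correlation(
        dict(zip("abcd", cov["toy"])),
        pd.DataFrame({"m": list(mards.values())}, index=list("abcd")))
    assert swapped.loc["m", "r"] == pytest.approx(0.6)
    with pytest.raises(ValueError):
        covariate_correlation({"a": 1.0, "b": 2.0}, cov.iloc[:2])


# ---------------------------------------------------------------------------
# reference comparison and report
# ---------------------------------------------------------------------------


def _paired(refs, preds, subject="S1"):
    return [PairedPoint(subject, 600.0 + 15 * i, 1, r, p, "capillary")
            for i, (r, p) in enumerate(zip(refs, preds))]


def test_reference_comparison_identity_and_sign():
    preds = [5.5, 7.2, 9.1, 6.3]
    cap = _paired([5.0, 7.0, 9.0, 6.0], preds)
    same = _paired([5.0, 7.0, 9.0, 6.0], preds)
    out = reference_comparison(cap, same)
    assert out["rmse_improvement_pct"] == pytest.approx(0.0)
    assert out["mard_improvement_pct"] == pytest.approx(0.0)
    better = _paired([5.4, 7.1, 9.05, 6.25], preds)   # closer to predictions
    out2 = reference_comparison(cap, better)
    assert out2["rmse_improvement_pct"] > 0
    # swapping roles flips the sign of the improvement direction
    out3 = reference_comparison(better, cap)
    assert out3["rmse_improvement_pct"] < 0
    disjoint = [PairedPoint("S2", 0.0, 2, 5.0, 5.5, "venous")]
    with pytest.raises(ValueError, match="share no sessions"):
        reference_comparison(cap, disjoint)


def test_metrics_report_structure():
    rng = np.random.default_rng(0)
    pts = []
    for s in range(6):
        ref = rng.uniform(4, 11, 40)
        pred = ref * rng.lognormal(0, 0.08, 40)
        pts += [PairedPoint(f"S{s}", 480 + 15 * i, 1 + (i // 20), r, p, "capillary")
                for i, (r, p) in enumerate(zip(ref, pred))]
    rep = build_metrics_report(pts, n_boot=100, seed=0,
                               session_accounting={"scheduled_validation": 240,
                                                   "kept": 240,
                                                   "dropped_outlier": 0,
                                                   "missing_duplicate": 0})
    assert rep.n_points == 240
    assert sum(rep.ceg_zones_pct.values()) == pytest.approx(100.0)
    assert rep.mard_ci[0] <= rep.mard_pct <= rep.mard_ci[1]
    assert len(rep.per_subject_mard) == 6
    acc = rep.session_accounting
    assert acc["kept"] + acc["dropped_outlier"] + acc["missing_duplicate"] \
        == acc["scheduled_validation"]
    d = rep.to_dict()
    assert d["n_points"] == 240
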