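"""Accuracy analyses for non-invasive glucose monitoring validation data.

Implements the full evaluation protocol: duplicate-reference outlier filtering,
session pairing (reference vs NIGM value), MARD and RMSE with subject-level
bootstrap confidence intervals, consensus-error-grid summaries, interstitial
delay estimation by lag-optimized Pearson correlation, Pearson correlations of
per-subject MARD against user covariates, the calibration-size sweep, and the
capillary-versus-venous reference comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ceg import ceg_summary, ceg_zone
from . import model as model_mod
from .synthetic import Session, StudyBundle

__all__ = [
    "PairedPoint",
    "MetricsReport",
    "filter_reference_outliers",
    "pair_sessions",
    "mard",
    "rmse",
    "bootstrap_ci",
    "estimate_delay",
    "covariate_correlation",
    "calibration_sweep",
    "reference_comparison",
    "build_metrics_report",
]

OUTLIER_DELTA_MMOL = 1.0  # duplicate BGSM draws differing by more than this drop


@dataclass
class PairedPoint:
    subject_id: str
    time_min: float
    day: int
    ref_mmol: float
    nigm_mmol: float
    reference_method: str
    role: str = "validation"


@dataclass
class MetricsReport:
    """Aggregate accuracy report mirroring the clinical readout structure."""

    n_points: int
    mard_pct: float
    mard_ci: tuple[float, float]
    rmse_mmol: float
    rmse_ci: tuple[float, float]
    ceg_zones_pct: dict[str, float]
    per_subject_mard: dict[str, float]
    median_mard_pct: float
    median_mard_ci: tuple[float, float]
    delay_mean_min: float | None = None
    delay_sd_min: float | None = None
    covariate_correlations: dict | None = None
    session_accounting: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# QC and pairing
# ---------------------------------------------------------------------------


def filter_reference_outliers(sessions) -> tuple[list, list, list]:
    """Split sessions into (kept, dropped, missing_duplicate).

    A session is dropped iff the two consecutive BGSM duplicates differ by
    strictly more than 1 mmol/L; a difference of exactly 1 mmol/L is kept.
    Sessions without both duplicates are counted separately.
    """
    kept, dropped, missing = [], [], []
    for s in sessions:
        refs = np.asarray(s.capillary_refs, dtype=float)
        if refs.size != 2 or not np.all(np.isfinite(refs)):
            missing.append(s)
        elif abs(refs[0] - refs[1]) > OUTLIER_DELTA_MMOL:
            dropped.append(s)
        else:
            kept.append(s)
    return kept, dropped, missing


def pair_sessions(sessions, session_predictions: dict,
                  reference_method: str = "capillary") -> list[PairedPoint]:
    """Pair each kept session's reference with its NIGM prediction.

    ``session_predictions`` maps ``session.session_key`` to the session NIGM
    value (mean of placements). Capillary reference = duplicate mean; venous
    sessions without a venous draw are skipped.
    """
    if reference_method not in ("capillary", "venous"):
        raise ValueError(f"unknown reference method: {reference_method!r}")
    points: list[PairedPoint] = []
    for s in sessions:
        key = s.session_key
        if key not in session_predictions:
            raise KeyError(f"no prediction for session {key}")
        if reference_method == "capillary":
            ref = float(np.mean(s.capillary_refs))
        else:
            if s.venous_ref is None:
                continue
            ref = float(s.venous_ref)
        points.append(PairedPoint(
            subject_id=s.subject_id, time_min=s.time_min, day=s.day,
            ref_mmol=ref, nigm_mmol=float(session_predictions[key]),
            reference_method=reference_method, role=s.role,
        ))
    return points


def points_frame(points) -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        return points
    points = list(points)
    if points and isinstance(points[0], PairedPoint):
        return pd.DataFrame([asdict(p) for p in points])
    return pd.DataFrame(points)


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------


def _ref_pred(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return (points["ref_mmol"].to_numpy(float),
                points["nigm_mmol"].to_numpy(float),
                points["subject_id"].to_numpy())
    ref = np.array([p.ref_mmol for p in points], dtype=float)
    pred = np.array([p.nigm_mmol for p in points], dtype=float)
    subj = np.array([p.subject_id for p in points])
    return ref, pred, subj


def mard(points) -> float:
    """Mean absolute relative difference, percent: 100 * mean(|pred - ref| / ref)."""
    ref, pred, _ = _ref_pred(points)
    if ref.size == 0:
        raise ValueError("mard of an empty point set")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    return 100.0 * float(np.mean(np.abs(pred - ref) / ref))


def rmse(points) -> float:
    """Root mean squared error, mmol/L."""
    ref, pred, _ = _ref_pred(points)
    if ref.size == 0:
        raise ValueError("rmse of an empty point set")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bootstrap_ci(points, metric, n_boot: int = 2000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling subjects (clusters), seeded.

    Subject-level resampling respects within-subject correlation of paired
    points. With a single subject the interval is degenerate (point estimate
    repeated) — flagged by lo == hi.
    """
    ref, pred, subj = _ref_pred(points)
    df = pd.DataFrame({"ref_mmol": ref, "nigm_mmol": pred, "subject_id": subj})
    subjects = df["subject_id"].unique()
    rng = np.random.default_rng(seed)
    by_subj = {s: g for s, g in df.groupby("subject_id")}
    vals = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        sample = pd.concat([by_subj[s] for s in pick], ignore_index=True)
        vals[b] = metric(sample)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))


# ---------------------------------------------------------------------------
# interstitial delay
# ---------------------------------------------------------------------------


def estimate_delay(ref_times, ref_values, nigm_times, nigm_values,
                   lag_grid=None) -> float:
    """Interstitial delay (min) by lag-optimized Pearson correlation.

    Each candidate lag shifts the reference (capillary) series later in time;
    the shifted series is linearly interpolated onto the NIGM timestamps and
    correlated with the NIGM values. Returns the lag maximizing Pearson r;
    ties break to the smallest lag.
    """
    ref_t = np.asarray(ref_times, dtype=float)
    ref_v = np.asarray(ref_values, dtype=float)
    t = np.asarray(nigm_times, dtype=float)
    v = np.asarray(nigm_values, dtype=float)
    if len(t) < 8 or len(ref_t) < 8:
        raise ValueError("delay estimation needs >= 8 points per series")
    if np.std(v) == 0 or np.std(ref_v) == 0:
        raise ValueError("constant series: correlation undefined")
    lags = np.arange(0.0, 31.0, 1.0) if lag_grid is None else np.asarray(lag_grid, float)
    best_lag, best_r = float(lags[0]), -np.inf
    for lag in lags:
        shifted = np.interp(t - lag, ref_t, ref_v)
        if np.std(shifted) == 0:
            continue
        r = float(np.corrcoef(shifted, v)[0, 1])
        if r > best_r + 1e-12:
            best_r, best_lag = r, float(lag)
    return best_lag


def cohort_delays(points_by_subject: dict[str, pd.DataFrame],
                  lag_grid=None) -> dict[str, float]:
    """Per-subject delay estimates from (time, ref, nigm) validation series."""
    out = {}
    for subj, df in points_by_subject.items():
        # estimate per day (the overnight gap breaks the time axis), average
        lags = []
        for _, day_df in df.groupby("day"):
            if len(day_df) < 8:
                continue
            lags.append(estimate_delay(
                day_df["time_min"], day_df["ref_mmol"],
                day_df["time_min"], day_df["nigm_mmol"], lag_grid))
        if lags:
            out[subj] = float(np.mean(lags))
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def covariate_correlation(per_subject_mard: dict[str, float] | pd.Series,
                          covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided t-distribution p, n-2 df) of MARD vs covariates.

    Covariates must be numerically encoded (phototype ordinal 1-6, sex 0/1).
    Zero-variance covariates are flagged not-computable rather than erroring.
    """
    mard_s = pd.Series(per_subject_mard, dtype=float)
    common = mard_s.index.intersection(covariates.index)
    if len(common) < 3:
        raise ValueError("covariate correlation needs >= 3 subjects")
    rows = []
    y = mard_s.loc[common].to_numpy()
    for col in covariates.columns:
        x = covariates.loc[common, col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"covariate": col, "r": np.nan, "p": np.nan,
                         "n": len(common), "computable": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"covariate": col, "r": float(r), "p": float(p),
                     "n": len(common), "computable": True})
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# calibration sweep and reference comparison
# ---------------------------------------------------------------------------


def calibration_sweep(processed_by_subject: dict, pretrained,
                      sizes=range(1, 11), seeds=(0,),
                      hyper=None) -> pd.DataFrame:
    """MARD as a function of the number of calibration sessions used.

    For each subject and size n, fine-tune on the chronologically first n
    calibration sessions and evaluate on all validation sessions. Returns a
    tidy frame (subject, n_cal, seed, mard_pct).

    ``processed_by_subject`` maps subject id to a dict with keys
    ``cal_X``/``cal_y`` (per-session lists: 4 spectra + reference each) and
    ``val_points_fn``: callable(model) -> paired validation points.
    """
    rows = []
    for subj, data in processed_by_subject.items():
        n_avail = len(data["cal_sessions"])
        for n in sizes:
            if n > n_avail:
                raise ValueError(f"{n} calibration sessions requested, "
                                 f"{n_avail} available for {subj}")
            for seed in seeds:
                X, y = [], []
                for spectra, ref in data["cal_sessions"][:n]:
                    X.extend(spectra)
                    y.extend([ref] * len(spectra))
                m = model_mod.finetune(pretrained, X, y, hyper=hyper,
                                       seed=int(seed), subject_id=subj)
                pts = data["val_points_fn"](m)
                rows.append({"subject_id": subj, "n_cal": int(n),
                             "seed": int(seed), "mard_pct": mard(pts)})
    return pd.DataFrame(rows)


def reference_comparison(paired_capillary, paired_venous) -> dict[str, float]:
    """Relative improvement (%) of RMSE and MARD when using venous references.

    Both pairings must cover the same sessions (the day-1 venous subset);
    improvement = 100 * (metric_cap - metric_ven) / metric_cap, positive when
    the venous (laboratory) reference is kinder to the device.
    """
    cap = points_frame(paired_capillary)
    ven = points_frame(paired_venous)
    key = ["subject_id", "day", "time_min"]
    merged = cap.merge(ven, on=key, suffixes=("_cap", "_ven"))
    if merged.empty:
        raise ValueError("capillary and venous pairings share no sessions")
    cap_pts = merged.rename(columns={"ref_mmol_cap": "ref_mmol",
                                     "nigm_mmol_cap": "nigm_mmol"})
    ven_pts = merged.rename(columns={"ref_mmol_ven": "ref_mmol",
                                     "nigm_mmol_ven": "nigm_mmol"})
    out = {}
    for name, fn in (("rmse", rmse), ("mard", mard)):
        m_cap, m_ven = fn(cap_pts), fn(ven_pts)
        out[f"{name}_capillary"] = m_cap
        out[f"{name}_venous"] = m_ven
        out[f"{name}_improvement_pct"] = 100.0 * (m_cap - m_ven) / m_cap
    out["n_sessions"] = int(len(merged))
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def build_metrics_report(points, grid_variant: str = "type2",
                         n_boot: int = 2000, seed: int = 0,
                         session_accounting: dict | None = None,
                         delays: dict[str, float] | None = None,
                         covariate_table: pd.DataFrame | None = None,
                         metadata: dict | None = None) -> MetricsReport:
    """Assemble the full accuracy report from paired validation points."""
    df = points_frame(points)
    per_subj = {s: mard(g) for s, g in df.groupby("subject_id")}
    per_subj_vals = np.array(list(per_subj.values()))
    rng = np.random.default_rng(seed)
    med_boot = np.array([
        np.median(rng.choice(per_subj_vals, size=len(per_subj_vals), replace=True))
        for _ in range(n_boot)
    ]) if len(per_subj_vals) > 1 else np.array([np.median(per_subj_vals)])
    delay_vals = np.array(list(delays.values())) if delays else None
    return MetricsReport(
        n_points=len(df),
        mard_pct=mard(df),
        mard_ci=bootstrap_ci(df, mard, n_boot=n_boot, seed=seed),
        rmse_mmol=rmse(df),
        rmse_ci=bootstrap_ci(df, rmse, n_boot=n_boot, seed=seed + 1),
        ceg_zones_pct=ceg_summary(df["ref_mmol"], df["nigm_mmol"], grid_variant),
        per_subject_mard=per_subj,
        median_mard_pct=float(np.median(per_subj_vals)),
        median_mard_ci=(float(np.quantile(med_boot, 0.025)),
                        float(np.quantile(med_boot, 0.975))),
        delay_mean_min=float(np.mean(delay_vals)) if delay_vals is not None else None,
        delay_sd_min=float(np.std(delay_vals, ddof=1))
        if delay_vals is not None and len(delay_vals) > 1 else None,
        covariate_correlations=covariate_table.to_dict("index")
        if covariate_table is not None else None,
        session_accounting=session_accounting or {},
        metadata=metadata or {},
    )
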