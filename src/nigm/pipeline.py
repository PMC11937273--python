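"""End-to-end study pipeline: simulate, preprocess, pretrain, fine-tune, evaluate.

Raw frames are processed per subject and discarded immediately (steps 1-5 of
the preprocessing chain yield one 700-point spectrum per placement), so a full
cohort fits comfortably in memory. Mean-centering (step 6) is applied lazily by
subtracting the corpus mean spectrum at model time, which keeps the fitted mean
attached to the model artifact. One master seed fans out into named substreams
(simulation, pretraining, fine-tuning, bootstrap), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import model as model_mod
from .model import TrainedModel, TrainingHyper
from .preprocessing import (MeanSpectrum, align_axis, average_frames, despike,
                            fit_mean_spectrum, normalize)
from .synthetic import (Device, Session, SimulationConfig, StudyBundle,
                        SubjectParams, SubjectRecord, simulate_subject)

__all__ = [
    "PipelineConfig",
    "ProcessedSession",
    "ProcessedSubject",
    "StudyResult",
    "process_subject",
    "simulate_processed_cohort",
    "assemble_corpus",
    "session_reference",
    "predict_sessions",
    "run_pipeline",
    "covariate_frame",
]


@dataclass
class ProcessedSession:
    """One session after preprocessing steps 1-5 (not yet centered)."""

    session: Session                # frames stripped
    spectra_s5: np.ndarray          # (n_placements, 700)
    n_spikes_removed: int


@dataclass
class ProcessedSubject:
    params: SubjectParams
    sessions: list[ProcessedSession]
    traces: dict
    spike_detection: dict = field(default_factory=dict)  # tp/fp/fn vs truth


@dataclass
class PipelineConfig:
    """Study-scale pipeline settings (cohort sizes, seeds via run_pipeline)."""

    n_pretrain_subjects: int = 40
    n_study_subjects: int = 50
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    hyper: TrainingHyper = field(default_factory=TrainingHyper)
    k_mad: float = 6.0
    norm_method: str = "l2"
    grid_variant: str = "type2"
    n_boot: int = 2000


@dataclass
class StudyResult:
    config: PipelineConfig
    seed: int
    mean_spectrum: MeanSpectrum
    pretrained: TrainedModel
    finetuned: dict[str, TrainedModel]
    study_subjects: list[ProcessedSubject]
    points: list                    # kept validation PairedPoints (capillary)
    report: ev.MetricsReport


def session_reference(session: Session) -> float:
    """Training reference for a session: venous when drawn, else BGSM mean."""
    if session.venous_ref is not None:
        return float(session.venous_ref)
    return float(np.mean(session.capillary_refs))


def process_subject(record: SubjectRecord, k_mad: float = 6.0,
                    norm_method: str = "l2") -> ProcessedSubject:
    """Apply preprocessing steps 1-5 to every placement; free the raw frames."""
    out_sessions: list[ProcessedSession] = []
    tp = fp = fn = 0
    for sess in record.sessions:
        rows, n_spikes = [], 0
        for plc in sess.placements:
            cleaned, mask = despike(plc.frames.astype(float), k_mad=k_mad)
            truth = plc.spike_mask
            tp += int(np.sum(mask & truth))
            fp += int(np.sum(mask & ~truth))
            fn += int(np.sum(~mask & truth))
            n_spikes += int(mask.sum())
            nu = Device(plc.device_id, plc.pixel_map).wavenumbers()
            aligned = [align_axis((nu, row)) for row in np.atleast_2d(cleaned)]
            rows.append(normalize(average_frames(aligned), method=norm_method))
        stripped = replace(sess, placements=[])
        out_sessions.append(ProcessedSession(
            session=stripped,
            spectra_s5=np.stack(rows) if rows else np.empty((0, 700)),
            n_spikes_removed=n_spikes,
        ))
    return ProcessedSubject(
        params=record.params, sessions=out_sessions, traces=record.traces,
        spike_detection={"tp": tp, "fp": fp, "fn": fn},
    )


def simulate_processed_cohort(sim: SimulationConfig, n_subjects: int, seed: int,
                              k_mad: float = 6.0, norm_method: str = "l2",
                              id_prefix: str = "S") -> list[ProcessedSubject]:
    """Simulate a cohort subject by subject, preprocessing and freeing frames."""
    cfg = replace(sim, n_subjects=n_subjects, rng_seed=seed)
    cfg.validate()
    master = np.random.SeedSequence(seed)
    dev_seq, subj_seq = master.spawn(2)
    dev_rng = np.random.default_rng(dev_seq)
    from .synthetic import make_device
    devices = [make_device(f"D{k:02d}", dev_rng) for k in range(cfg.n_devices)]
    out: list[ProcessedSubject] = []
    seqs = subj_seq.spawn(max(n_subjects, 1))[:n_subjects]
    for i, sseq in enumerate(seqs):
        rec = simulate_subject(f"{id_prefix}{i + 1:03d}", devices[i % len(devices)],
                               sseq, cfg, include_frames=True)
        out.append(process_subject(rec, k_mad=k_mad, norm_method=norm_method))
    return out


def assemble_corpus(subjects: list[ProcessedSubject]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (spectrum, reference, subject) training triples over all sessions."""
    X, y, g = [], [], []
    for subj in subjects:
        for ps in subj.sessions:
            ref = session_reference(ps.session)
            for row in ps.spectra_s5:
                X.append(row)
                y.append(ref)
                g.append(subj.params.subject_id)
    return np.stack(X), np.array(y), np.array(g)


def predict_sessions(subject: ProcessedSubject, model: TrainedModel,
                     mean: MeanSpectrum, role: str | None = "validation"
                     ) -> dict[tuple, float]:
    """Session NIGM values (mean of per-placement predictions) keyed by session."""
    out = {}
    for ps in subject.sessions:
        if role is not None and ps.session.role != role:
            continue
        centered = ps.spectra_s5 - mean.values
        preds = model_mod.predict(model, centered)
        out[ps.session.session_key] = float(np.mean(preds))
    return out


def calibration_data(subject: ProcessedSubject, mean: MeanSpectrum,
                     n_sessions: int | None = None) -> tuple[list, list]:
    """(spectra, references) training pairs from the first n calibration sessions."""
    X, y = [], []
    cal = [ps for ps in subject.sessions if ps.session.role == "calibration"]
    if n_sessions is not None:
        cal = cal[:n_sessions]
    for ps in cal:
        ref = session_reference(ps.session)
        for row in ps.spectra_s5:
            X.append(row - mean.values)
            y.append(ref)
    return X, y


def covariate_frame(subjects: list[ProcessedSubject]) -> pd.DataFrame:
    """Numeric covariate table (sex 0/1, phototype ordinal 1-6) per subject."""
    rows = {}
    for s in subjects:
        p = s.params
        rows[p.subject_id] = {
            "age": p.age, "sex": p.sex, "bmi": p.bmi,
            "hba1c": p.hba1c_mmol_mol, "phototype": p.phototype,
            "sc_thickness": p.sc_thickness_um,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 estimate_delays: bool = True) -> StudyResult:
    """Full study: pretrain cohort -> study cohort -> fine-tune -> evaluate."""
    cfg = config or PipelineConfig()
    master = np.random.SeedSequence(seed)
    s_pre_sim, s_study_sim, s_pretrain, s_finetune, s_boot = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(5)
    ]

    # pretraining corpus (decoupled cohort, like the historical training study)
    pre_subjects = simulate_processed_cohort(
        cfg.sim, cfg.n_pretrain_subjects, s_pre_sim,
        k_mad=cfg.k_mad, norm_method=cfg.norm_method, id_prefix="P")
    X_s5, y, groups = assemble_corpus(pre_subjects)
    mean = fit_mean_spectrum(X_s5)
    pretrained = model_mod.pretrain(X_s5 - mean.values, y, groups,
                                    hyper=cfg.hyper, seed=s_pretrain,
                                    mean_spectrum=mean)
    del pre_subjects, X_s5

    # study cohort
    study = simulate_processed_cohort(
        cfg.sim, cfg.n_study_subjects, s_study_sim,
        k_mad=cfg.k_mad, norm_method=cfg.norm_method, id_prefix="S")

    finetuned: dict[str, TrainedModel] = {}
    predictions: dict[tuple, float] = {}
    ft_seqs = np.random.SeedSequence(s_finetune).spawn(len(study))
    for subj, fseq in zip(study, ft_seqs):
        fseed = int(fseq.generate_state(1)[0] % (2 ** 31))
        cal_X, cal_y = calibration_data(subj, mean)
        m = model_mod.finetune(pretrained, cal_X, cal_y, hyper=cfg.hyper,
                               seed=fseed, subject_id=subj.params.subject_id)
        finetuned[subj.params.subject_id] = m
        predictions.update(predict_sessions(subj, m, mean))

    # QC + pairing
    val_sessions = [ps.session for s in study for ps in s.sessions
                    if ps.session.role == "validation"]
    kept, dropped, missing = ev.filter_reference_outliers(val_sessions)
    points = ev.pair_sessions(kept, predictions, "capillary")
    accounting = {
        "scheduled_validation": len(val_sessions),
        "kept": len(kept), "dropped_outlier": len(dropped),
        "missing_duplicate": len(missing),
    }

    delays = None
    if estimate_delays:
        df = ev.points_frame(points)
        delays = ev.cohort_delays({s: g for s, g in df.groupby("subject_id")})

    cov = covariate_frame(study)
    df = ev.points_frame(points)
    per_subj_mard = {s: ev.mard(g) for s, g in df.groupby("subject_id")}
    cov_table = (ev.covariate_correlation(per_subj_mard, cov)
                 if len(per_subj_mard) >= 3 else None)

    report = ev.build_metrics_report(
        points, grid_variant=cfg.grid_variant, n_boot=cfg.n_boot, seed=s_boot,
        session_accounting=accounting, delays=delays, covariate_table=cov_table,
        metadata={"seed": seed, "n_pretrain_subjects": cfg.n_pretrain_subjects,
                  "n_study_subjects": cfg.n_study_subjects},
    )
    return StudyResult(
        config=cfg, seed=seed, mean_spectrum=mean, pretrained=pretrained,
        finetuned=finetuned, study_subjects=study, points=points, report=report,
    )
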