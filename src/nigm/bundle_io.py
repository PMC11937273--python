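"""Study-bundle persistence: CSV tables, HDF5 spectral arrays, YAML manifest.

Bundle layout::

    bundle/
      manifest.yaml   # config summary + seed
      subjects.csv    # covariates + latent subject parameters
      sessions.csv    # timestamps, roles, reference values
      frames.h5       # /<subject>/d<day>_s<idx>/p<k> -> (n_frames, 1024)
      truth.h5        # latent traces + spike masks (simulation only)

Validation errors name the offending file and dataset.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import (Device, LatentTraces, N_PIXELS, PlacementData, Session,
                        SimulationConfig, StudyBundle, SubjectParams,
                        SubjectRecord, default_schedule)

__all__ = ["write_bundle", "read_bundle"]


def _session_group(sess: Session) -> str:
    return f"d{sess.day}_s{sess.index:02d}"


def write_bundle(bundle: StudyBundle, path) -> Path:
    """Write a simulated study bundle to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cfg = bundle.config
    manifest = {
        "seed": int(bundle.seed),
        "n_subjects": int(cfg.n_subjects),
        "frames_per_placement": int(cfg.frames_per_placement),
        "placements_per_session": int(cfg.placements_per_session),
        "tau_mean_min": float(cfg.tau_mean_min),
        "tau_sd_min": float(cfg.tau_sd_min),
        "bgsm_cv": float(cfg.bgsm_cv),
        "venous_cv": float(cfg.venous_cv),
        "spike_rate_per_frame": float(cfg.spike_rate_per_frame),
        "glucose_signal_scale": float(cfg.glucose_signal_scale),
        "devices": {d.device_id: [float(c) for c in d.pixel_map]
                    for d in bundle.devices.values()},
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    subj_rows, sess_rows = [], []
    for rec in bundle.subjects:
        p = rec.params
        subj_rows.append({
            "subject_id": p.subject_id, "age": p.age, "sex": p.sex,
            "bmi": p.bmi, "hba1c_mmol_mol": p.hba1c_mmol_mol,
            "phototype": p.phototype, "sc_thickness_um": p.sc_thickness_um,
            "baseline_glucose_mmol": p.baseline_glucose_mmol,
            "tau_min": p.tau_min, "baseline_factor": p.baseline_factor,
            "device_id": p.device_id,
            "confounder_amps": ";".join(f"{a:.6g}" for a in p.confounder_amps),
        })
        for s in rec.sessions:
            sess_rows.append({
                "subject_id": s.subject_id, "day": s.day, "index": s.index,
                "role": s.role, "time_min": s.time_min,
                "bg1": float(s.capillary_refs[0]), "bg2": float(s.capillary_refs[1]),
                "venous": float(s.venous_ref) if s.venous_ref is not None else np.nan,
                "true_capillary": s.true_capillary,
                "true_interstitial": s.true_interstitial,
                "true_venous": s.true_venous,
            })
    pd.DataFrame(subj_rows).to_csv(path / "subjects.csv", index=False)
    pd.DataFrame(sess_rows).to_csv(path / "sessions.csv", index=False)

    with h5py.File(path / "frames.h5", "w") as f, \
            h5py.File(path / "truth.h5", "w") as t:
        for rec in bundle.subjects:
            fg = f.create_group(rec.params.subject_id)
            tg = t.create_group(rec.params.subject_id)
            for day, tr in rec.traces.items():
                g = tg.create_group(f"traces_d{day}")
                for name in ("times_min", "capillary", "interstitial", "venous"):
                    g.create_dataset(name, data=getattr(tr, name))
            for s in rec.sessions:
                sg = fg.create_group(_session_group(s))
                stg = tg.create_group(_session_group(s))
                for k, plc in enumerate(s.placements):
                    d = sg.create_dataset(f"p{k}", data=plc.frames,
                                          compression="gzip", compression_opts=1)
                    d.attrs["device_id"] = plc.device_id
                    d.attrs["pixel_map"] = np.asarray(plc.pixel_map)
                    stg.create_dataset(f"spikes_p{k}", data=plc.spike_mask,
                                       compression="gzip", compression_opts=1)
    return path


def read_bundle(path) -> StudyBundle:
    """Read and validate a study bundle directory."""
    path = Path(path)
    mf = path / "manifest.yaml"
    if not mf.exists():
        raise FileNotFoundError(f"missing manifest.yaml in {path}")
    manifest = yaml.safe_load(mf.read_text())

    devices = {}
    for dev_id, coeffs in manifest.get("devices", {}).items():
        dev = Device(dev_id, tuple(coeffs))
        nu = dev.wavenumbers()
        if np.any(np.diff(nu) <= 0):
            raise ValueError(f"manifest.yaml: pixel map of {dev_id} is not monotone")
        devices[dev_id] = dev

    subjects_df = pd.read_csv(path / "subjects.csv")
    sessions_df = pd.read_csv(path / "sessions.csv")

    cfg = SimulationConfig(
        n_subjects=int(manifest["n_subjects"]),
        rng_seed=int(manifest["seed"]),
        frames_per_placement=int(manifest["frames_per_placement"]),
        placements_per_session=int(manifest["placements_per_session"]),
        tau_mean_min=float(manifest["tau_mean_min"]),
        tau_sd_min=float(manifest["tau_sd_min"]),
        bgsm_cv=float(manifest["bgsm_cv"]),
        venous_cv=float(manifest["venous_cv"]),
        spike_rate_per_frame=float(manifest["spike_rate_per_frame"]),
        glucose_signal_scale=float(manifest["glucose_signal_scale"]),
    )

    truth_path = path / "truth.h5"
    truth = h5py.File(truth_path, "r") if truth_path.exists() else None
    records: list[SubjectRecord] = []
    try:
        with h5py.File(path / "frames.h5", "r") as f:
            for _, row in subjects_df.iterrows():
                sid = row["subject_id"]
                params = SubjectParams(
                    subject_id=sid, age=row["age"], sex=int(row["sex"]),
                    bmi=row["bmi"], hba1c_mmol_mol=row["hba1c_mmol_mol"],
                    phototype=int(row["phototype"]),
                    sc_thickness_um=row["sc_thickness_um"],
                    baseline_glucose_mmol=row["baseline_glucose_mmol"],
                    tau_min=row["tau_min"], baseline_factor=row["baseline_factor"],
                    confounder_amps=np.array(
                        [float(x) for x in str(row["confounder_amps"]).split(";")]),
                    device_id=row["device_id"],
                )
                traces = {}
                if truth is not None and sid in truth:
                    for day in (1, 2):
                        key = f"traces_d{day}"
                        if key in truth[sid]:
                            g = truth[sid][key]
                            traces[day] = LatentTraces(
                                day=day, times_min=g["times_min"][:],
                                capillary=g["capillary"][:],
                                interstitial=g["interstitial"][:],
                                venous=g["venous"][:],
                            )
                sessions = []
                for _, srow in sessions_df[sessions_df.subject_id == sid].iterrows():
                    skey = f"d{int(srow['day'])}_s{int(srow['index']):02d}"
                    placements = []
                    if sid in f and skey in f[sid]:
                        sg = f[sid][skey]
                        for k in sorted(sg.keys()):
                            frames = sg[k][:]
                            if frames.shape[1] != N_PIXELS:
                                raise ValueError(
                                    f"frames.h5:/{sid}/{skey}/{k}: frame length "
                                    f"{frames.shape[1]} != {N_PIXELS}")
                            pm = tuple(float(c) for c in sg[k].attrs["pixel_map"])
                            spikes = np.zeros(frames.shape, dtype=bool)
                            if truth is not None and sid in truth \
                                    and skey in truth[sid] \
                                    and f"spikes_{k}" in truth[sid][skey]:
                                spikes = truth[sid][skey][f"spikes_{k}"][:].astype(bool)
                            placements.append(PlacementData(
                                frames=frames, spike_mask=spikes,
                                device_id=str(sg[k].attrs["device_id"]),
                                pixel_map=pm))
                    sessions.append(Session(
                        subject_id=sid, day=int(srow["day"]),
                        index=int(srow["index"]), role=srow["role"],
                        time_min=float(srow["time_min"]),
                        capillary_refs=np.array([srow["bg1"], srow["bg2"]]),
                        venous_ref=None if pd.isna(srow["venous"]) else float(srow["venous"]),
                        placements=placements,
                        true_capillary=float(srow["true_capillary"]),
                        true_interstitial=float(srow["true_interstitial"]),
                        true_venous=float(srow["true_venous"]),
                    ))
                records.append(SubjectRecord(params=params, sessions=sessions,
                                             traces=traces))
    finally:
        if truth is not None:
            truth.close()
    return StudyBundle(config=cfg, subjects=records, devices=devices,
                       seed=int(manifest["seed"]))
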