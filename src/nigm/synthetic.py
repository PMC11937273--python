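"""Seeded simulation of a two-day in-clinic non-invasive glucose monitoring study.

The generator produces everything the downstream analysis consumes: per-subject
capillary/interstitial/venous glucose traces with meal-induced excursions, raw
1024-pixel Raman detector frames (fluorescence background, glucose signature,
confounder bands, shot noise, cosmic-ray spikes), duplicate capillary (BGSM) and
venous reference draws, and the full session schedule (10 calibration + 14
validation sessions on day 1, 26 validation sessions on day 2; 4 hand placements
per session).

Latent truth (noise-free traces, spike masks) is retained on every record so that
despiking, delay estimation and model accuracy can be scored against ground truth.
All randomness flows from one ``numpy.random.SeedSequence`` fanned out into named
substreams, so identical seed + config give byte-identical bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "StudySchedule",
    "SessionSlot",
    "LatentTraces",
    "RawFrame",
    "Device",
    "SubjectParams",
    "PlacementData",
    "Session",
    "SubjectRecord",
    "StudyBundle",
    "default_schedule",
    "simulate_cohort",
    "simulate_subject",
    "glucose_timecourse",
    "meal_response",
    "apply_isf_lag",
    "render_placement",
    "inject_spikes",
    "sample_reference",
    "make_device",
]

N_PIXELS = 1024

#: Fitzpatrick phototype -> fluorescence background multiplier. Darker skin
#: fluoresces more strongly, so multipliers are non-decreasing I -> VI.
DEFAULT_PHOTOTYPE_BASELINE = {1: 0.8, 2: 1.0, 3: 1.3, 4: 1.7, 5: 2.2, 6: 2.8}

#: Observed phototype frequencies in a Caucasian type-2-diabetes cohort
#: (I..VI); used to sample subject phototypes.
PHOTOTYPE_FREQ = np.array([0.0, 3.0, 22.0, 24.0, 1.0, 0.0]) / 50.0

# Glucose Raman bands (cm^-1): C-O-H/C-C-H stretches of D-glucose reported in
# the chemometrics literature. Positions are configuration, not hard-coded in
# the renderer.
DEFAULT_GLUCOSE_BANDS = ((911.0, 12.0, 1.0), (1060.0, 12.0, 0.8), (1125.0, 12.0, 0.9))

# Confounder bands: skin protein/lipid features. Entries are
# (center, width, population-mean amplitude in counts, between-subject log-sd).
# Strong structural bands (phenylalanine 1003, CH2 1445) are relatively stable
# across subjects; weaker collagen/lipid features adjacent to the glucose bands
# vary more, producing subject-specific spectral interference that per-subject
# calibration has to absorb.
DEFAULT_CONFOUNDER_BANDS = (
    (855.0, 18.0, 30.0, 0.12),
    (898.0, 14.0, 20.0, 0.30),
    (1003.0, 8.0, 40.0, 0.10),
    (1065.0, 16.0, 28.0, 0.30),
    (1128.0, 14.0, 25.0, 0.30),
    (1302.0, 20.0, 35.0, 0.12),
    (1445.0, 16.0, 50.0, 0.10),
    (1655.0, 22.0, 25.0, 0.15),
)


# ---------------------------------------------------------------------------
# configuration and schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionSlot:
    """One scheduled measurement event."""

    day: int                 # 1 or 2
    index: int               # 0-based within day
    role: str                # "calibration" | "validation"
    time_min: float          # clock time, minutes after midnight of its day
    venous_planned: bool


@dataclass(frozen=True)
class StudySchedule:
    """Ordered session slots per study day plus meal times.

    The default layout follows the two-day in-clinic design: 10 calibration
    sessions at 20-min spacing in the morning of day 1, then 14 validation
    sessions at 15-min spacing; 26 validation sessions at 15-min spacing on
    day 2. Venous samples accompany every calibration session and every second
    validation session on day 1.
    """

    slots: tuple[SessionSlot, ...]
    meal_times_min: dict[int, tuple[float, ...]]  # day -> meal clock times
    day_window_min: tuple[float, float] = (420.0, 990.0)  # latent-trace window

    def day_slots(self, day: int) -> list[SessionSlot]:
        return [s for s in self.slots if s.day == day]

    def validate(self) -> None:
        for day in (1, 2):
            times = [s.time_min for s in self.day_slots(day)]
            if len(times) != len(set(times)):
                raise ValueError(f"overlapping session slots on day {day}")
            if times != sorted(times):
                raise ValueError(f"session slots on day {day} are not ordered")
        n_cal = sum(s.role == "calibration" for s in self.slots)
        if n_cal and [s.role for s in self.day_slots(1)][:n_cal] != ["calibration"] * n_cal:
            raise ValueError("calibration slots must precede validation on day 1")

    @property
    def n_calibration(self) -> int:
        return sum(s.role == "calibration" for s in self.slots)

    @property
    def n_validation(self) -> int:
        return sum(s.role == "validation" for s in self.slots)


def default_schedule() -> StudySchedule:
    """Two-day schedule: 10 cal + 14 val (day 1), 26 val (day 2)."""
    slots: list[SessionSlot] = []
    # Day 1: calibration 08:00-11:00 at 20-min spacing.
    for i in range(10):
        slots.append(SessionSlot(1, i, "calibration", 480.0 + 20.0 * i, True))
    # Day 1: validation from 11:15 at 15-min spacing; venous every second session.
    for j in range(14):
        slots.append(
            SessionSlot(1, 10 + j, "validation", 675.0 + 15.0 * j, j % 2 == 0)
        )
    # Day 2: validation only, from 08:00 at 15-min spacing.
    for j in range(26):
        slots.append(SessionSlot(2, j, "validation", 480.0 + 15.0 * j, False))
    return StudySchedule(
        slots=tuple(slots),
        meal_times_min={1: (670.0, 790.0), 2: (500.0, 680.0)},
    )


@dataclass
class SimulationConfig:
    """All knobs of the study simulator.

    Defaults encode the study conditions: interstitial delay tau ~ N(10, 9) min
    truncated at 1 min, 70 g / 80 g carbohydrate meals, duplicate capillary
    references at 3% CV versus a single, more accurate venous reference at
    1.5% CV, and ten 5-s detector frames per 50-s hand placement.
    """

    n_subjects: int = 50
    schedule: StudySchedule = field(default_factory=default_schedule)
    tau_mean_min: float = 10.0
    tau_sd_min: float = 9.0
    tau_floor_min: float = 1.0
    meal_carbs_g: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: {1: (70.0, 80.0), 2: (70.0, 80.0)}
    )
    bgsm_cv: float = 0.03
    venous_cv: float = 0.015
    spike_rate_per_frame: float = 1.5
    frames_per_placement: int = 10
    placements_per_session: int = 4
    # spectral model
    glucose_signal_scale: float = 6.0      # counts of peak amplitude per mmol/L
    glucose_bands: tuple = DEFAULT_GLUCOSE_BANDS
    confounder_bands: tuple = DEFAULT_CONFOUNDER_BANDS
    confounder_subject_sigma: float = 0.2  # fallback log-sd for 3-tuple bands
    confounder_drift_sd: float = 0.05      # within-day slow relative drift
    baseline_counts: float = 1000.0        # fluorescence amplitude, phototype I-II skin
    baseline_scale_by_phototype: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHOTOTYPE_BASELINE)
    )
    baseline_subject_sigma: float = 0.15   # log-sd of subject fluorescence jitter
    shot_noise_scale: float = 1.0          # 0 disables detector noise
    # glucose kinetics
    meal_rise_min: float = 15.0
    meal_decay_min: float = 90.0
    carb_peak_mmol_per_g: float = 0.05     # peak excursion per gram of carbohydrate
    drift_sd_mmol: float = 0.3
    drift_corr_min: float = 60.0
    glucose_floor_mmol: float = 3.9        # study observed no hypoglycemia
    venous_lag_min: float = 5.0
    venous_attenuation: float = 0.9
    trace_dt_min: float = 1.0
    n_devices: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("bgsm_cv", "venous_cv", "spike_rate_per_frame",
                     "shot_noise_scale", "tau_sd_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_floor_min <= 0:
            raise ValueError("tau_floor_min must be > 0 (tau draws are truncated above 0)")
        mult = [self.baseline_scale_by_phototype[k] for k in sorted(self.baseline_scale_by_phototype)]
        if any(b < a for a, b in zip(mult, mult[1:])):
            raise ValueError("phototype fluorescence multipliers must be non-decreasing I->VI")
        for day, carbs in self.meal_carbs_g.items():
            if any(c < 0 for c in carbs):
                raise ValueError("negative carbohydrate load")
        self.schedule.validate()


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class Device:
    """One spectrometer with its pixel -> wavenumber map (quadratic)."""

    device_id: str
    pixel_map: tuple[float, float, float]  # (a0, a1, a2): nu = a0 + a1*p + a2*p^2

    def wavenumbers(self) -> np.ndarray:
        p = np.arange(N_PIXELS, dtype=float)
        a0, a1, a2 = self.pixel_map
        return a0 + a1 * p + a2 * p * p


@dataclass
class RawFrame:
    """One 1024-pixel detector readout."""

    pixel_intensities: np.ndarray          # (1024,) non-negative counts
    device_id: str
    pixel_map: tuple[float, float, float]
    spike_mask: np.ndarray | None = None   # simulation truth

    def __post_init__(self) -> None:
        self.pixel_intensities = np.asarray(self.pixel_intensities, dtype=float)
        if self.pixel_intensities.shape != (N_PIXELS,):
            raise ValueError(f"frame must have exactly {N_PIXELS} pixels")

    def wavenumbers(self) -> np.ndarray:
        return Device(self.device_id, self.pixel_map).wavenumbers()


@dataclass
class LatentTraces:
    """Noise-free glucose traces on a uniform 1-min grid, per study day."""

    day: int
    times_min: np.ndarray
    capillary: np.ndarray
    interstitial: np.ndarray
    venous: np.ndarray

    def at(self, which: str, t: float) -> float:
        return float(np.interp(t, self.times_min, getattr(self, which)))


@dataclass
class SubjectParams:
    subject_id: str
    age: float
    sex: int                    # 0 = female, 1 = male
    bmi: float
    hba1c_mmol_mol: float
    phototype: int              # Fitzpatrick I..VI as 1..6
    sc_thickness_um: float
    baseline_glucose_mmol: float
    tau_min: float              # interstitial delay
    baseline_factor: float      # subject fluorescence jitter (multiplies phototype scale)
    confounder_amps: np.ndarray # per-band subject amplitudes, counts
    device_id: str


@dataclass
class PlacementData:
    frames: np.ndarray          # (n_frames, 1024) float32
    spike_mask: np.ndarray      # (n_frames, 1024) bool, truth
    device_id: str
    pixel_map: tuple[float, float, float]

    def as_raw_frames(self) -> list[RawFrame]:
        return [
            RawFrame(self.frames[i].astype(float), self.device_id, self.pixel_map,
                     self.spike_mask[i])
            for i in range(self.frames.shape[0])
        ]


@dataclass
class Session:
    subject_id: str
    day: int
    index: int
    role: str
    time_min: float
    capillary_refs: np.ndarray          # (2,) duplicate BGSM draws
    venous_ref: float | None
    placements: list[PlacementData]
    true_capillary: float               # latent truth at session time
    true_interstitial: float
    true_venous: float

    @property
    def session_key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.day, self.index)


@dataclass
class SubjectRecord:
    params: SubjectParams
    sessions: list[Session]
    traces: dict[int, LatentTraces]     # day -> latent traces


@dataclass
class StudyBundle:
    config: SimulationConfig
    subjects: list[SubjectRecord]
    devices: dict[str, Device]
    seed: int

    def all_sessions(self, role: str | None = None) -> list[Session]:
        out = []
        for rec in self.subjects:
            for s in rec.sessions:
                if role is None or s.role == role:
                    out.append(s)
        return out


# ---------------------------------------------------------------------------
# glucose kinetics
# ---------------------------------------------------------------------------


def meal_response(t_min: np.ndarray, grams: float, rise_min: float = 15.0,
                  decay_min: float = 90.0, peak_per_g: float = 0.05) -> np.ndarray:
    """Post-prandial excursion: difference of two exponentials, linear in grams.

    The curve is normalized to unit peak, then scaled by ``grams * peak_per_g``
    (mmol/L). Zero before the meal.
    """
    if grams < 0:
        raise ValueError("negative carbohydrate load")
    t = np.asarray(t_min, dtype=float)
    shape = np.where(t > 0, np.exp(-t / decay_min) - np.exp(-t / rise_min), 0.0)
    t_peak = math.log(decay_min / rise_min) * decay_min * rise_min / (decay_min - rise_min)
    peak = math.exp(-t_peak / decay_min) - math.exp(-t_peak / rise_min)
    return grams * peak_per_g * shape / peak


def apply_isf_lag(capillary: np.ndarray, tau_min: float, dt_min: float = 1.0) -> np.ndarray:
    """First-order interstitial lag of a capillary trace on a uniform grid.

    Discrete low-pass ``G_isf[k+1] = G_isf[k] + (dt/tau) (G_cap[k] - G_isf[k])``
    initialized at ``G_cap[0]``. For a step input the output reaches 63.2%
    (1 - 1/e) of the step after one time constant.
    """
    if tau_min <= 0:
        raise ValueError("tau must be > 0")
    cap = np.asarray(capillary, dtype=float)
    a = dt_min / tau_min
    if a >= 1.0:
        # tau at or below the grid spacing: pure one-sample tracking
        out = np.empty_like(cap)
        out[0] = cap[0]
        out[1:] = cap[:-1]
        return out
    out = np.empty_like(cap)
    out[0] = cap[0]
    for k in range(len(cap) - 1):
        out[k + 1] = out[k] + a * (cap[k] - out[k])
    return out


def _shift_trace(values: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples <= 0:
        return values.copy()
    out = np.empty_like(values)
    out[:lag_samples] = values[0]
    out[lag_samples:] = values[:-lag_samples]
    return out


def glucose_timecourse(params: SubjectParams, schedule: StudySchedule,
                       rng: np.random.Generator,
                       config: SimulationConfig | None = None,
                       day: int = 1) -> LatentTraces:
    """Latent capillary/interstitial/venous traces for one study day.

    Capillary = subject baseline + per-meal difference-of-exponentials responses
    (linear in grams of carbohydrate) + slow AR(1) drift, clipped at the
    hypoglycemia floor. Interstitial = first-order lag with the subject's tau.
    Venous = capillary delayed a few minutes with the post-prandial excursion
    mildly attenuated.
    """
    cfg = config or SimulationConfig()
    t0, t1 = schedule.day_window_min
    t = np.arange(t0, t1 + cfg.trace_dt_min / 2, cfg.trace_dt_min)
    cap = np.full_like(t, params.baseline_glucose_mmol)

    meals = list(zip(schedule.meal_times_min.get(day, ()),
                     cfg.meal_carbs_g.get(day, ())))
    for meal_time, grams in meals:
        if not (t0 <= meal_time <= t1):
            raise ValueError(f"meal at {meal_time} min outside day window {t0}-{t1}")
        cap += meal_response(t - meal_time, grams, cfg.meal_rise_min,
                             cfg.meal_decay_min, cfg.carb_peak_mmol_per_g)

    if cfg.drift_sd_mmol > 0:
        rho = math.exp(-cfg.trace_dt_min / cfg.drift_corr_min)
        innov_sd = cfg.drift_sd_mmol * math.sqrt(1.0 - rho * rho)
        drift = np.empty_like(t)
        drift[0] = rng.normal(0.0, cfg.drift_sd_mmol)
        eps = rng.normal(0.0, innov_sd, size=len(t) - 1)
        for k in range(len(t) - 1):
            drift[k + 1] = rho * drift[k] + eps[k]
        cap += drift

    cap = np.clip(cap, cfg.glucose_floor_mmol, None)
    isf = apply_isf_lag(cap, params.tau_min, cfg.trace_dt_min)

    lag_samples = int(round(cfg.venous_lag_min / cfg.trace_dt_min))
    base = params.baseline_glucose_mmol
    ven = base + cfg.venous_attenuation * (_shift_trace(cap, lag_samples) - base)
    ven = np.clip(ven, cfg.glucose_floor_mmol, None)
    return LatentTraces(day=day, times_min=t, capillary=cap, interstitial=isf, venous=ven)


# ---------------------------------------------------------------------------
# spectral rendering
# ---------------------------------------------------------------------------


def make_device(device_id: str, rng: np.random.Generator) -> Device:
    """Device with a jittered, strictly increasing quadratic pixel map
    covering at least 300-1615 cm^-1."""
    a0 = 290.0 + rng.normal(0.0, 2.0)
    a2 = max(5e-5 * (1.0 + rng.normal(0.0, 0.2)), 0.0)
    # solve the linear term so the last pixel lands just past the axis end:
    # jittered ends, guaranteed coverage of 300-1615 and monotonicity
    nu_end = 1620.0 + rng.uniform(0.0, 10.0)
    p_last = N_PIXELS - 1
    a1 = (nu_end - a0 - a2 * p_last * p_last) / p_last
    return Device(device_id, (a0, a1, a2))


def _gaussian_bands(nu: np.ndarray, bands, amps) -> np.ndarray:
    out = np.zeros_like(nu)
    for band, amp in zip(bands, amps):
        center, width, rel = band[0], band[1], band[2]
        out += amp * rel * np.exp(-0.5 * ((nu - center) / width) ** 2)
    return out


def _baseline_shape(nu: np.ndarray) -> np.ndarray:
    """Smooth broad fluorescence profile (arbitrary count scale, max ~1)."""
    x = (nu - 300.0) / 1315.0
    return 0.35 + 0.65 * np.exp(-((x - 0.15) / 0.55) ** 2)


def clean_frame_components(glucose_mmol: float, params: SubjectParams,
                           device: Device, config: SimulationConfig,
                           drift_factors: np.ndarray | None = None
                           ) -> dict[str, np.ndarray]:
    """Noise-free additive components of one frame, for truth-based tests."""
    nu = device.wavenumbers()
    ptype_scale = config.baseline_scale_by_phototype[params.phototype]
    baseline = (config.baseline_counts * ptype_scale * params.baseline_factor
                * _baseline_shape(nu))
    glucose = config.glucose_signal_scale * glucose_mmol * _gaussian_bands(
        nu, config.glucose_bands, np.ones(len(config.glucose_bands)))
    amps = params.confounder_amps
    if drift_factors is not None:
        amps = amps * drift_factors
    confounders = _gaussian_bands(
        nu, [(b[0], b[1], 1.0) for b in config.confounder_bands], amps)
    return {"baseline": baseline, "glucose": glucose, "confounders": confounders}


def inject_spikes(frame: RawFrame, rate: float, rng: np.random.Generator) -> RawFrame:
    """Add Poisson(rate) cosmic-ray/hot-pixel spikes to a frame.

    Each spike is a positive excursion of >= 8x the local shot-noise scale,
    1-2 pixels wide; locations are recorded in ``spike_mask`` so despiking can
    be scored as detection against truth.
    """
    if rate < 0:
        raise ValueError("spike rate must be >= 0")
    intens = frame.pixel_intensities.copy()
    mask = np.zeros(N_PIXELS, dtype=bool) if frame.spike_mask is None \
        else frame.spike_mask.copy()
    n_spikes = rng.poisson(rate)
    noise_scale = np.sqrt(np.maximum(intens, 1.0))
    for _ in range(n_spikes):
        pos = int(rng.integers(0, N_PIXELS))
        width = int(rng.integers(1, 3))
        extra = rng.exponential(6.0)
        for k in range(width):
            j = pos + k
            if j < N_PIXELS:
                # every spiked pixel exceeds 8x the local shot-noise scale
                intens[j] += (8.0 + (extra if k == 0 else 0.6 * extra)) * noise_scale[j]
                mask[j] = True
    return RawFrame(intens, frame.device_id, frame.pixel_map, mask)


def render_placement(glucose_isf: float, params: SubjectParams, device: Device,
                     rng: np.random.Generator, config: SimulationConfig,
                     ) -> list[RawFrame]:
    """Render one 50-s hand placement as a series of raw detector frames.

    Each frame = fluorescence baseline (scaled by the subject's phototype
    multiplier) + glucose signature (Gaussian bands linear in interstitial
    glucose) + subject-specific confounder bands with slow drift, plus
    signal-dependent shot noise and injected spikes.
    """
    if glucose_isf <= 0:
        raise ValueError("glucose must be > 0")
    n_frames = config.frames_per_placement
    n_bands = len(config.confounder_bands)
    # slow within-placement drift of confounder amplitudes
    drift = 1.0 + config.confounder_drift_sd * rng.standard_normal(n_bands)
    frames: list[RawFrame] = []
    comp = clean_frame_components(glucose_isf, params, device, config, drift)
    clean = comp["baseline"] + comp["glucose"] + comp["confounders"]
    for _ in range(n_frames):
        intens = clean.copy()
        if config.shot_noise_scale > 0:
            sigma = config.shot_noise_scale * np.sqrt(np.maximum(clean, 0.0))
            intens = intens + sigma * rng.standard_normal(N_PIXELS)
        frame = RawFrame(np.maximum(intens, 0.0), device.device_id, device.pixel_map,
                         np.zeros(N_PIXELS, dtype=bool))
        if config.spike_rate_per_frame > 0:
            frame = inject_spikes(frame, config.spike_rate_per_frame, rng)
        frames.append(frame)
    return frames


def sample_reference(true_value: float, method: str, rng: np.random.Generator,
                     config: SimulationConfig) -> np.ndarray:
    """Measured reference draw(s) with method-specific multiplicative noise.

    capillary -> two independent BGSM draws at ``bgsm_cv``; venous -> one
    laboratory draw at the smaller ``venous_cv``.
    """
    if true_value <= 0:
        raise ValueError("true glucose must be > 0")
    if method == "capillary":
        cv, n = config.bgsm_cv, 2
    elif method == "venous":
        cv, n = config.venous_cv, 1
    else:
        raise ValueError(f"unknown reference method: {method!r}")
    return true_value * (1.0 + cv * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _draw_subject_params(subject_id: str, device_id: str,
                         rng: np.random.Generator,
                         config: SimulationConfig) -> SubjectParams:
    age = float(rng.uniform(38, 83))
    sex = int(rng.random() < 0.56)  # cohort skews slightly male
    bmi = float(np.clip(rng.lognormal(math.log(28.0), 0.15), 22.0, 48.0))
    hba1c = float(np.clip(rng.normal(57.0, 12.0), 36.0, 95.0))
    phototype = int(rng.choice(np.arange(1, 7), p=PHOTOTYPE_FREQ))
    sc_um = float(np.clip(rng.lognormal(math.log(165.0), 0.25), 85.0, 320.0))
    # fasting baseline loosely tied to HbA1c (estimated average glucose)
    eag = 0.0585 * hba1c + 2.87
    baseline = float(np.clip(rng.normal(0.9 * eag, 0.6), 4.5, 13.0))
    tau = float(max(rng.normal(config.tau_mean_min, config.tau_sd_min),
                    config.tau_floor_min))
    baseline_factor = float(rng.lognormal(0.0, config.baseline_subject_sigma))
    conf_mean = np.array([b[2] for b in config.confounder_bands])
    conf_sigma = np.array([
        b[3] if len(b) > 3 else config.confounder_subject_sigma
        for b in config.confounder_bands
    ])
    conf_amps = conf_mean * np.exp(rng.normal(0.0, 1.0, size=len(conf_mean))
                                   * conf_sigma)
    return SubjectParams(
        subject_id=subject_id, age=age, sex=sex, bmi=bmi, hba1c_mmol_mol=hba1c,
        phototype=phototype, sc_thickness_um=sc_um,
        baseline_glucose_mmol=baseline, tau_min=tau,
        baseline_factor=baseline_factor, confounder_amps=conf_amps,
        device_id=device_id,
    )


def simulate_subject(subject_id: str, device: Device, seed_seq: np.random.SeedSequence,
                     config: SimulationConfig, include_frames: bool = True
                     ) -> SubjectRecord:
    """Simulate one subject: parameters, latent traces, all scheduled sessions."""
    rng_params, rng_trace, rng_ref, rng_spec = [
        np.random.default_rng(s) for s in seed_seq.spawn(4)
    ]
    params = _draw_subject_params(subject_id, device.device_id, rng_params, config)
    traces = {
        day: glucose_timecourse(params, config.schedule, rng_trace, config, day=day)
        for day in (1, 2)
    }
    sessions: list[Session] = []
    for slot in config.schedule.slots:
        tr = traces[slot.day]
        g_cap = tr.at("capillary", slot.time_min)
        g_isf = tr.at("interstitial", slot.time_min)
        g_ven = tr.at("venous", slot.time_min)
        cap_refs = sample_reference(g_cap, "capillary", rng_ref, config)
        ven_ref = (float(sample_reference(g_ven, "venous", rng_ref, config)[0])
                   if slot.venous_planned else None)
        placements: list[PlacementData] = []
        if include_frames:
            for _ in range(config.placements_per_session):
                raw = render_placement(g_isf, params, device, rng_spec, config)
                placements.append(PlacementData(
                    frames=np.stack([f.pixel_intensities for f in raw]).astype(np.float32),
                    spike_mask=np.stack([f.spike_mask for f in raw]),
                    device_id=device.device_id,
                    pixel_map=device.pixel_map,
                ))
        sessions.append(Session(
            subject_id=subject_id, day=slot.day, index=slot.index, role=slot.role,
            time_min=slot.time_min, capillary_refs=cap_refs, venous_ref=ven_ref,
            placements=placements, true_capillary=g_cap, true_interstitial=g_isf,
            true_venous=g_ven,
        ))
    return SubjectRecord(params=params, sessions=sessions, traces=traces)


def simulate_cohort(config: SimulationConfig, include_frames: bool = True
                    ) -> StudyBundle:
    """Simulate a full study cohort; fully reproducible given ``config.rng_seed``."""
    config.validate()
    master = np.random.SeedSequence(config.rng_seed)
    dev_seq, subj_seq = master.spawn(2)
    dev_rng = np.random.default_rng(dev_seq)
    devices = {
        f"D{k:02d}": make_device(f"D{k:02d}", dev_rng)
        for k in range(config.n_devices)
    }
    dev_ids = list(devices)
    subjects: list[SubjectRecord] = []
    for i, sseq in enumerate(subj_seq.spawn(max(config.n_subjects, 1))[: config.n_subjects]):
        device = devices[dev_ids[i % len(dev_ids)]]
        subjects.append(simulate_subject(f"S{i + 1:03d}", device, sseq, config,
                                         include_frames=include_frames))
    return StudyBundle(config=config, subjects=subjects, devices=devices,
                       seed=config.rng_seed)
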