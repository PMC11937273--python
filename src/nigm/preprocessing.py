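"""Six-step spectral standardization: despike, align, average, normalize, center.

Raw 1024-pixel frames from one hand placement are cleaned of cosmic-ray/hot-pixel
spikes, interpolated from the device's pixel->wavenumber map onto the common
Raman axis (700 equidistant points spanning 300-1615 cm^-1), averaged to improve
signal-to-noise, scaled to unit Euclidean norm, and mean-centered against a
population mean spectrum fitted once on the pretraining corpus. The resulting
spectra vary around the zero line and feed the calibration network directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .synthetic import RawFrame, N_PIXELS

__all__ = [
    "N_AXIS_POINTS",
    "AXIS_MIN",
    "AXIS_MAX",
    "target_axis",
    "MeanSpectrum",
    "ProcessedSpectrum",
    "despike",
    "align_axis",
    "average_frames",
    "normalize",
    "center",
    "fit_mean_spectrum",
    "preprocess_placement",
]

N_AXIS_POINTS = 700
AXIS_MIN = 300.0
AXIS_MAX = 1615.0

#: Gaussian-consistency factor so k_mad thresholds are in sigma-like units.
MAD_SCALE = 1.4826


def target_axis() -> np.ndarray:
    """Common Raman axis: 700 equidistant points from 300 to 1615 cm^-1 inclusive."""
    return np.linspace(AXIS_MIN, AXIS_MAX, N_AXIS_POINTS)


@dataclass
class MeanSpectrum:
    """Population mean spectrum (after steps 1-5) subtracted in step 6.

    Fitted once on the pretraining corpus and applied identically to calibration
    and validation spectra.
    """

    values: np.ndarray
    version: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AXIS_POINTS,):
            raise ValueError(f"mean spectrum must have {N_AXIS_POINTS} points")


@dataclass
class ProcessedSpectrum:
    """Model-ready 700-point spectrum with processing provenance."""

    values: np.ndarray
    subject_id: str = ""
    session_key: tuple = ()
    placement: int = -1
    n_frames_averaged: int = 0
    n_spikes_removed: int = 0
    steps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AXIS_POINTS,):
            raise ValueError(f"processed spectrum must have {N_AXIS_POINTS} points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("processed spectrum contains non-finite values")


# ---------------------------------------------------------------------------
# step 2: despiking
# ---------------------------------------------------------------------------


def _frames_matrix(frames) -> tuple[np.ndarray, list[RawFrame] | None]:
    if isinstance(frames, np.ndarray):
        mat = np.atleast_2d(np.asarray(frames, dtype=float))
        return mat, None
    raws = list(frames)
    return np.stack([f.pixel_intensities for f in raws]).astype(float), raws


def despike(frames, k_mad: float = 6.0):
    """Remove positive spike artifacts from a placement's frame series.

    With >= 4 frames the test is temporal: per pixel, values exceeding
    ``median + k_mad * MAD`` across the series (MAD in sigma-consistent units)
    are replaced by the temporal median of that pixel. With fewer frames a
    rolling Hampel test along the pixel axis (window 7) is used instead, since
    cosmic spikes are narrow in both time and wavenumber. A zero-MAD
    (all-constant) series falls back to a small absolute floor threshold, so
    constant input passes through unchanged. The operation is idempotent and
    leaves spike-free data untouched within float tolerance.

    Accepts either a list of :class:`RawFrame` or an ``(n_frames, 1024)`` array;
    returns the same type plus the boolean detection mask.
    """
    mat, raws = _frames_matrix(frames)
    if mat.shape[0] < 1:
        raise ValueError("despike requires at least one frame")
    if mat.shape[0] >= 4:
        med = np.median(mat, axis=0)
        mad = MAD_SCALE * np.median(np.abs(mat - med), axis=0)
        # pool the noise-scale estimate over neighboring pixels: with few frames
        # the per-pixel MAD is noisy, and shot noise varies smoothly in nu
        mad = median_filter(mad, size=15, mode="nearest")
        floor = 1e-6 * np.maximum(np.abs(med), 1.0)
        thresh = med + k_mad * np.maximum(mad, floor)
        mask = mat > thresh
        cleaned = np.where(mask, med, mat)
    else:
        cleaned = mat.copy()
        mask = np.zeros_like(mat, dtype=bool)
        for i in range(mat.shape[0]):
            row = mat[i]
            med = median_filter(row, size=7, mode="nearest")
            mad = MAD_SCALE * median_filter(np.abs(row - med), size=7, mode="nearest")
            floor = 1e-6 * np.maximum(np.abs(med), 1.0)
            row_mask = row > med + k_mad * np.maximum(mad, floor)
            cleaned[i] = np.where(row_mask, med, row)
            mask[i] = row_mask
    if raws is None:
        out = cleaned if isinstance(frames, np.ndarray) and frames.ndim == 2 else cleaned[0]
        return out, mask
    out_frames = [
        RawFrame(cleaned[i], raws[i].device_id, raws[i].pixel_map, raws[i].spike_mask)
        for i in range(len(raws))
    ]
    return out_frames, mask


# ---------------------------------------------------------------------------
# step 3: axis alignment
# ---------------------------------------------------------------------------


def align_axis(frame: RawFrame | tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Linearly interpolate one frame onto the common 700-point Raman axis.

    Accepts a :class:`RawFrame` (wavenumbers from its pixel map) or a
    ``(wavenumbers, intensities)`` pair. The device grid must cover the target
    range; otherwise the uncovered interval is named in the error.
    """
    if isinstance(frame, RawFrame):
        nu, y = frame.wavenumbers(), frame.pixel_intensities
    else:
        nu, y = np.asarray(frame[0], dtype=float), np.asarray(frame[1], dtype=float)
    if np.any(np.diff(nu) <= 0):
        raise ValueError("pixel map must be strictly increasing")
    if nu[0] > AXIS_MIN or nu[-1] < AXIS_MAX:
        lo = f"[{AXIS_MIN}, {nu[0]:.1f})" if nu[0] > AXIS_MIN else ""
        hi = f"({nu[-1]:.1f}, {AXIS_MAX}]" if nu[-1] < AXIS_MAX else ""
        raise ValueError(
            "device wavenumber grid does not cover the target axis; "
            f"uncovered interval(s): {' '.join(x for x in (lo, hi) if x)}"
        )
    return np.interp(target_axis(), nu, y)


# ---------------------------------------------------------------------------
# steps 4-6
# ---------------------------------------------------------------------------


def average_frames(spectra) -> np.ndarray:
    """Pointwise arithmetic mean of aligned spectra (step 4)."""
    spectra = [np.asarray(s, dtype=float) for s in spectra]
    if len(spectra) == 0:
        raise ValueError("average_frames requires at least one spectrum")
    lengths = {s.shape for s in spectra}
    if len(lengths) != 1:
        raise ValueError("spectra have unequal lengths")
    return np.mean(np.stack(spectra), axis=0)


def normalize(spectrum: np.ndarray, method: str = "l2") -> np.ndarray:
    """Scale a spectrum to unit norm (step 5). ``method``: 'l2' (default) or 'l1'."""
    x = np.asarray(spectrum, dtype=float)
    if method == "l2":
        n = float(np.linalg.norm(x))
    elif method in ("l1", "area"):
        n = float(np.sum(np.abs(x)))
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    if n == 0.0:
        raise ValueError("cannot normalize a zero spectrum")
    return x / n


def center(spectrum: np.ndarray, mean_spectrum: MeanSpectrum) -> np.ndarray:
    """Subtract the fitted population mean spectrum (step 6)."""
    x = np.asarray(spectrum, dtype=float)
    if x.shape != mean_spectrum.values.shape:
        raise ValueError("spectrum/mean length mismatch")
    return x - mean_spectrum.values


def fit_mean_spectrum(spectra, version: str = "1") -> MeanSpectrum:
    """Pointwise mean over the pretraining corpus (after steps 1-5)."""
    spectra = [np.asarray(s, dtype=float) for s in spectra]
    if len(spectra) == 0:
        raise ValueError("cannot fit a mean spectrum on an empty corpus")
    return MeanSpectrum(np.mean(np.stack(spectra), axis=0), version=version)


def preprocess_placement(frames, mean_spectrum: MeanSpectrum,
                         k_mad: float = 6.0,
                         norm_method: str = "l2",
                         subject_id: str = "", session_key: tuple = (),
                         placement: int = -1) -> ProcessedSpectrum:
    """Full chain for one placement: despike -> align -> average -> normalize -> center.

    ``frames`` is a list of :class:`RawFrame` or a
    :class:`~nigm.synthetic.PlacementData` (stacked frame matrix + pixel map).
    """
    from .synthetic import Device, PlacementData

    if isinstance(frames, PlacementData):
        cleaned, mask = despike(frames.frames.astype(float), k_mad=k_mad)
        nu = Device(frames.device_id, frames.pixel_map).wavenumbers()
        aligned = [align_axis((nu, row)) for row in np.atleast_2d(cleaned)]
    else:
        cleaned, mask = despike(frames, k_mad=k_mad)
        aligned = [align_axis(f) for f in cleaned]
    avg = average_frames(aligned)
    norm = normalize(avg, method=norm_method)
    cen = center(norm, mean_spectrum)
    return ProcessedSpectrum(
        values=cen, subject_id=subject_id, session_key=session_key,
        placement=placement,
        n_frames_averaged=len(aligned),
        n_spikes_removed=int(mask.sum()),
        steps=("despike", "align", "average", "normalize", "center"),
    )
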