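"""Per-measurement deformation features.

From the corneal-reaction decomposition of one air-puff measurement the
following features are computed:

* ``w1`` / ``w2`` — first and second applanation time (ms): the moments the
  central cornea passes through geometric flatness on indentation and recovery;
* ``w3`` — maximum corneal deformation (mm): peak apex reaction amplitude;
* ``w4`` — dominant corneal vibration frequency above 100 Hz (Hz);
* ``w5`` — intraocular pressure as reported by the tonometer (mmHg), a
  pass-through value that is never image-derived;
* ``w6`` — blood-pulsation phase bin at the measurement trigger (degrees).

Applanation is detected on the central-region flatness curve (see
:mod:`oculopulse.curvature`).  The apex and curvature series are low-pass
filtered (moving average, default 2.5 ms) before thresholding and peak
refinement so that the >100 Hz corneal vibration — which is a separate feature
— does not alias into the slow-deformation features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import NYQUIST_HZ, PHASE_BIN_DEG
from .contour import ContourSet, ResponseDecomposition
from .curvature import central_curvature, curvature_to_flatness_mm, _line_residual_rms
from .exceptions import NoApplanationError, NoVibrationError

__all__ = [
    "DeformationProfile",
    "FeatureVector",
    "deformation_profile",
    "applanation_times",
    "max_deformation",
    "vibration_frequency",
    "assemble_feature_vector",
]


@dataclass
class DeformationProfile:
    """Per-frame apex amplitude and central flatness of one measurement.

    Attributes
    ----------
    time_ms : ndarray
        Frame timestamps (ms), strictly increasing.
    apex_mm : ndarray
        Corneal-reaction amplitude at the apex column (mm, positive toward
        the eye).
    central_flatness : ndarray
        RMS deviation (mm) of the quadratic-fitted central contour from its
        best straight line; ~0 at applanation.
    central_curvature : ndarray or None
        Signed curvature coefficient (1/mm) behind ``central_flatness``;
        kept so applanation detection can low-pass the signed series.
    flatness_scale_mm2 : float
        Factor converting ``|curvature|`` into flatness RMS on the central
        grid (mm^2).
    """

    time_ms: np.ndarray
    apex_mm: np.ndarray
    central_flatness: np.ndarray
    central_curvature: np.ndarray | None = None
    flatness_scale_mm2: float = float("nan")

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.apex_mm = np.asarray(self.apex_mm, dtype=float)
        self.central_flatness = np.asarray(self.central_flatness, dtype=float)
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if not (self.time_ms.size == self.apex_mm.size == self.central_flatness.size):
            raise ValueError("profile arrays must have equal length")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass(frozen=True)
class FeatureVector:
    """Features ``w1``-``w6`` of one measurement."""

    w1_ms: float
    w2_ms: float
    w3_mm: float
    w4_hz: float
    w5_mmHg: float
    w6_deg: int

    def __post_init__(self) -> None:
        if not self.w1_ms < self.w2_ms:
            raise ValueError("first applanation must precede the second (w1 < w2)")
        if not self.w3_mm > 0:
            raise ValueError("maximum deformation w3 must be positive")
        if not self.w4_hz > 100:
            raise ValueError("vibration frequency w4 must exceed 100 Hz")
        if self.w6_deg % PHASE_BIN_DEG or not 0 <= self.w6_deg < 360:
            raise ValueError("phase bin w6 must be a multiple of 30 in [0, 330]")


# --------------------------------------------------------------- profile
def deformation_profile(
    contours: ContourSet,
    decomposition: ResponseDecomposition,
    central_halfwidth_cols: int = 75,
    apex_halfwidth_cols: int = 3,
) -> DeformationProfile:
    """Build the apex/flatness time profile from extracted contours.

    The apex column is located at the maximum corneal reaction over the whole
    sequence; apex amplitude per frame averages a small column window around
    it.  Central flatness is computed from a quadratic fit of the (completed)
    contour over ``2 * central_halfwidth_cols`` columns around the apex.
    """
    reaction = decomposition.corneal_reaction_mm
    valid = contours.frame_valid
    if not valid.any():
        raise ValueError("no valid frames in sequence")
    peak_per_col = np.nanmax(np.where(valid[:, None], reaction, np.nan), axis=0)
    apex_col = int(np.nanargmax(peak_per_col))

    n_frames, n_cols = contours.y.shape
    scale_mm = contours.pixel_scale_um / 1000.0
    lo = max(0, apex_col - central_halfwidth_cols)
    hi = min(n_cols, apex_col + central_halfwidth_cols)
    x_mm = (np.arange(lo, hi) - apex_col) * scale_mm
    flat_scale = _line_residual_rms(x_mm)

    a_lo = max(0, apex_col - apex_halfwidth_cols)
    a_hi = min(n_cols, apex_col + apex_halfwidth_cols + 1)

    apex = np.full(n_frames, np.nan)
    curv = np.full(n_frames, np.nan)
    for i in range(n_frames):
        if not valid[i]:
            continue
        apex[i] = np.nanmean(reaction[i, a_lo:a_hi])
        curv[i] = central_curvature(contours.y[i, lo:hi] * scale_mm, x_mm)

    time_ms = np.arange(n_frames) * contours.frame_interval_us / 1000.0
    return DeformationProfile(
        time_ms=time_ms,
        apex_mm=apex,
        central_flatness=np.abs(curv) * flat_scale,
        central_curvature=curv,
        flatness_scale_mm2=flat_scale,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge-value padding; window forced odd."""
    window = max(1, int(window) | 1)
    if window == 1:
        return x.astype(float)
    pad = window // 2
    padded = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _smooth_ms(x: np.ndarray, dt_ms: float, smooth_ms: float) -> np.ndarray:
    return _moving_average(np.asarray(x, dtype=float), int(round(smooth_ms / dt_ms)))


# ------------------------------------------------------------ applanation
def applanation_times(
    profile: DeformationProfile,
    flatness_threshold_mm: float = 0.005,
    smooth_ms: float = 2.5,
) -> tuple[float, float]:
    """First and second applanation time (ms).

    The signed central curvature is low-pass filtered and converted to the
    flatness RMS; the contiguous below-threshold episodes are located with
    linearly interpolated entry/exit times, and each applanation time is the
    midpoint of its episode (first episode -> ``w1``, last -> ``w2``), which
    is unbiased for the locally symmetric V-shaped flatness curve.

    Raises
    ------
    NoApplanationError
        If the flatness curve has fewer than two below-threshold episodes.
    """
    if profile.central_curvature is not None:
        curv = _smooth_ms(profile.central_curvature, profile.dt_ms, smooth_ms)
        flat = np.abs(curv) * profile.flatness_scale_mm2
    else:
        flat = _smooth_ms(profile.central_flatness, profile.dt_ms, smooth_ms)
    t = profile.time_ms
    below = flat < flatness_threshold_mm
    if not below.any():
        raise NoApplanationError("central flatness never drops below threshold")

    episodes: list[tuple[float, float]] = []
    i = 0
    n = below.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        # linear interpolation of the crossing instants
        if i > 0:
            frac = (flat[i - 1] - flatness_threshold_mm) / (flat[i - 1] - flat[i])
            t_in = t[i - 1] + frac * (t[i] - t[i - 1])
        else:
            t_in = t[0]
        if j + 1 < n:
            frac = (flatness_threshold_mm - flat[j]) / (flat[j + 1] - flat[j])
            t_out = t[j] + frac * (t[j + 1] - t[j])
        else:
            t_out = t[-1]
        episodes.append((t_in, t_out))
        i = j + 1

    if len(episodes) < 2:
        raise NoApplanationError(
            f"found {len(episodes)} flattening episode(s); two are required"
        )
    w1 = 0.5 * (episodes[0][0] + episodes[0][1])
    w2 = 0.5 * (episodes[-1][0] + episodes[-1][1])
    return float(w1), float(w2)


# ---------------------------------------------------------------- w3, w4
def max_deformation(profile: DeformationProfile, smooth_ms: float = 2.5) -> float:
    """Peak apex deformation (mm) with parabolic sub-frame refinement.

    The apex series is moving-average filtered to reject the >100 Hz
    vibration; the attenuation this causes at a locally quadratic peak is
    exactly ``a2 * var`` (``var`` the variance of the averaging window), so
    the refined vertex is corrected by that amount and a clean parabola is
    recovered exactly.
    """
    y_raw = np.nan_to_num(profile.apex_mm)
    window = max(1, int(round(smooth_ms / profile.dt_ms)) | 1)
    y = _moving_average(y_raw, window)
    i = int(np.argmax(y))
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:
            vertex = y[i] - (y[i - 1] - y[i + 1]) ** 2 / (8 * denom)
            a2 = denom / 2.0  # per frame^2
            var = (window**2 - 1) / 12.0  # frames^2
            return float(vertex - a2 * var)
    return float(y[i])


def vibration_frequency(
    profile: DeformationProfile,
    lowcut_hz: float = 100.0,
    smooth_ms: float = 2.5,
    pad_factor: int = 4,
    min_peak_factor: float = 15.0,
) -> float:
    """Dominant corneal vibration frequency above ``lowcut_hz`` (feature w4).

    The slow deformation pulse is removed by subtracting a best-fit line and
    the ``smooth_ms`` moving average (a high-pass whose passband comfortably
    contains the >100 Hz vibration); the residual is Hann-windowed and
    zero-padded at least ``pad_factor`` times, and the strongest *local*
    spectral peak above the low-cut is refined by parabolic interpolation of
    the log-magnitude.  A genuine vibration shows as a narrow line standing
    on a quiet background; the deformation bump only leaves a smooth decaying
    continuum, on which any local maximum sits at the level of its
    surroundings.  The peak is therefore required to exceed
    ``min_peak_factor`` times the median magnitude in an annulus around it
    (65-150 Hz away, outside the windowing main lobe).

    Raises
    ------
    NoVibrationError
        If no sufficiently prominent peak exists above the low-cut (nothing
        oscillates there).
    """
    from scipy.signal import find_peaks

    x = np.nan_to_num(profile.apex_mm, nan=0.0)
    if x.size < 64:
        raise ValueError("need at least 64 frames for spectral estimation")
    dt_s = profile.dt_ms / 1000.0
    u = np.arange(x.size, dtype=float)
    line = np.polynomial.polynomial.polyfit(u, x, 1)
    x = x - (line[0] + line[1] * u)
    window = max(1, int(round(smooth_ms / profile.dt_ms)) | 1)
    resid = (x - _moving_average(x, window)) * np.hanning(x.size)
    n_fft = 1 << int(np.ceil(np.log2(x.size * pad_factor)))
    mag = np.abs(np.fft.rfft(resid, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=dt_s)
    band = (freqs > lowcut_hz) & (freqs <= NYQUIST_HZ)
    if not band.any():
        raise NoVibrationError("no spectral bins above the low-cut frequency")
    peaks, _ = find_peaks(mag)
    in_band = [p for p in peaks if band[p]]
    if not in_band:
        raise NoVibrationError("no spectral peak above the low-cut frequency")
    peak = max(in_band, key=lambda p: mag[p])
    annulus = (np.abs(freqs - freqs[peak]) > 65.0) & (np.abs(freqs - freqs[peak]) <= 150.0)
    floor = float(np.median(mag[annulus]))
    if floor <= 0 or mag[peak] < min_peak_factor * floor:
        raise NoVibrationError("no spectral peak rises above the noise floor")
    # parabolic refinement on log magnitude
    f = freqs[peak]
    if 0 < peak < mag.size - 1 and mag[peak - 1] > 0 and mag[peak + 1] > 0:
        lm = np.log(mag[peak - 1 : peak + 2])
        denom = lm[0] - 2 * lm[1] + lm[2]
        if denom < 0:
            delta = 0.5 * (lm[0] - lm[2]) / denom
            f = freqs[peak] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return float(f)


def assemble_feature_vector(
    w1_ms: float,
    w2_ms: float,
    w3_mm: float,
    w4_hz: float,
    iop_mmHg: float,
    phase_bin_deg: int,
) -> FeatureVector:
    """Validate and assemble the per-measurement feature vector.

    ``iop_mmHg`` is the tonometer's own reading (``w5``); it is never derived
    from the images.  Raises ``ValueError`` on any invariant violation
    (``w1 >= w2``, ``w4 <= 100`` Hz, off-grid phase bin, ...), which marks the
    measurement as a rejected record.
    """
    return FeatureVector(
        w1_ms=float(w1_ms),
        w2_ms=float(w2_ms),
        w3_mm=float(w3_mm),
        w4_hz=float(w4_hz),
        w5_mmHg=float(iop_mmHg),
        w6_deg=int(phase_bin_deg),
    )
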