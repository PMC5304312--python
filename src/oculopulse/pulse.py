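"""Cardiac phase from a finger pulse-oximeter trace.

The tonometer trigger time is located within the photoplethysmographic (PPG)
waveform and expressed as an angular phase: 0 deg at the systolic peak, growing
linearly to 360 deg at the next peak.  Phase is interpolated between the two
peaks that bracket the trigger, so beat-to-beat rate variability (typically a
few percent) does not accumulate.  The phase is finally snapped to the 12-bin,
30-degree grid used throughout the correlation analysis (feature ``w6``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .constants import PHASE_BIN_DEG, PULSE_RATE_MAX_BPM, PULSE_RATE_MIN_BPM
from .exceptions import InsufficientBeatsError, PhaseUndefinedError

__all__ = ["PulseTrace", "BeatTimes", "detect_beats", "phase_at", "bin_phase"]


@dataclass
class PulseTrace:
    """Uniformly sampled pulse-oximeter amplitude trace.

    Attributes
    ----------
    samples : ndarray
        Pulse amplitude in percent, within [0, 100].
    sample_rate_hz : float
        Sampling rate of the trace.
    trigger_time_s : float
        Time of the tonometer measurement trigger within the trace.
    """

    samples: np.ndarray
    sample_rate_hz: float
    trigger_time_s: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 4:
            raise ValueError("samples must be a 1-D array with at least 4 points")
        if self.samples.min() < 0 or self.samples.max() > 100:
            raise ValueError("pulse amplitudes must lie within [0, 100] %")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0 <= self.trigger_time_s <= self.duration_s:
            raise ValueError("trigger_time_s must lie inside the trace")

    @property
    def duration_s(self) -> float:
        return (self.samples.size - 1) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class BeatTimes:
    """Systolic peak times with summary rhythm statistics."""

    peak_times_s: np.ndarray
    mean_period_s: float
    period_cv: float

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size < 2:
            raise ValueError("need at least 2 peaks")
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if self.period_cv < 0:
            raise ValueError("period_cv must be non-negative")


def _dominant_period_samples(x: np.ndarray, fs: float) -> float:
    """Dominant beat period from the autocorrelation, in samples.

    The search is restricted to the physiological rate range of the emulated
    oximeter (20-254 beats/minute).
    """
    x = x - x.mean()
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    lag_min = max(2, int(fs * 60.0 / PULSE_RATE_MAX_BPM))
    lag_max = min(n - 1, int(np.ceil(fs * 60.0 / PULSE_RATE_MIN_BPM)))
    if lag_max <= lag_min:
        raise InsufficientBeatsError("trace too short to estimate a beat period")
    window = acf[lag_min : lag_max + 1]
    return float(lag_min + int(np.argmax(window)))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of a parabola through (i-1, i, i+1); returns offset."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_beats(trace: PulseTrace, min_separation_frac: float = 0.5) -> BeatTimes:
    """Locate systolic peaks in a pulse trace.

    Peaks are local maxima separated by at least ``min_separation_frac`` of the
    dominant period (estimated from the autocorrelation), refined to sub-sample
    precision by parabolic interpolation.

    Raises
    ------
    InsufficientBeatsError
        If fewer than two peaks are found (e.g. a constant trace).
    """
    x = trace.samples
    if np.ptp(x) == 0:
        raise InsufficientBeatsError("constant trace contains no beats")
    fs = trace.sample_rate_hz
    period = _dominant_period_samples(x, fs)
    distance = max(1, int(round(min_separation_frac * period)))
    prominence = 0.2 * np.ptp(x)
    idx, _ = find_peaks(x, distance=distance, prominence=prominence)
    if idx.size < 2:
        raise InsufficientBeatsError(f"found {idx.size} peak(s); need at least 2")
    refined = np.array([i + _parabolic_refine(x, i) for i in idx])
    times = refined / fs
    periods = np.diff(times)
    mean_period = float(periods.mean())
    cv = float(periods.std(ddof=0) / mean_period) if periods.size > 1 else 0.0
    return BeatTimes(peak_times_s=times, mean_period_s=mean_period, period_cv=cv)


def phase_at(trace: PulseTrace, t_s: float, beats: BeatTimes | None = None) -> float:
    """Cardiac phase (degrees, [0, 360)) at time ``t_s`` within the trace.

    Phase is 0 at each systolic peak and interpolated linearly between the
    bracketing peaks.  Times up to one mean period past the last detected peak
    are extrapolated with the mean period.

    Raises
    ------
    PhaseUndefinedError
        If ``t_s`` precedes the first detected peak or lies more than one mean
        period past the last one.
    """
    if beats is None:
        beats = detect_beats(trace)
    peaks = beats.peak_times_s
    if t_s < peaks[0]:
        raise PhaseUndefinedError(f"t={t_s:.4f}s precedes the first systolic peak")
    if t_s >= peaks[-1]:
        nxt = peaks[-1] + beats.mean_period_s
        if t_s > nxt:
            raise PhaseUndefinedError(f"t={t_s:.4f}s is beyond the last beat")
        prev = peaks[-1]
    else:
        i = int(np.searchsorted(peaks, t_s, side="right")) - 1
        prev, nxt = peaks[i], peaks[i + 1]
    return float((360.0 * (t_s - prev) / (nxt - prev)) % 360.0)


def bin_phase(phase_deg: float) -> int:
    """Snap a phase to the nearest 30-degree bin (feature ``w6``).

    The bins are {0, 30, ..., 330}; 345-360 wraps to 0.  Exact midpoints
    (15, 45, ...) round toward the lower bin.
    """
    phase = float(phase_deg)
    if not 0 <= phase < 360:
        raise ValueError("phase must lie in [0, 360)")
    idx = int(np.ceil(phase / PHASE_BIN_DEG - 0.5)) % (360 // PHASE_BIN_DEG)
    return idx * PHASE_BIN_DEG
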