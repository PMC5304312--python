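"""Synthetic pulse traces, IOP readings and rendered deformation sequences.

Every downstream stage of the analysis is testable against this module's
fully known ground truth:

* :func:`generate_pulse_trace` emulates a finger pulse-oximeter waveform —
  a two-harmonic, asymmetric beat (fast systolic upstroke, slow decay) with
  per-beat period jitter — and places the tonometer trigger at a requested
  cardiac phase.
* :func:`generate_iop_readings` applies the assumed coupling law: IOP varies
  as a single cosine of the cardiac phase, peaking at ``phase_offset_deg``,
  plus Gaussian device noise.
* :func:`render_deformation_sequence` draws 140 Scheimpflug-like frames of a
  bright corneal band over a dark background: a parabolic resting cornea
  (radius 7.8 mm), a bell-shaped indentation whose central region passes
  through geometric flatness exactly at the requested applanation times, a
  whole-eye retraction ramp after the deformation peak, and a windowed
  >100 Hz apex vibration.
* :func:`generate_cohort` assembles a study-sized cohort (10 subjects x 6
  measurements by default) in either *fast* mode (feature vectors emitted
  directly, for statistical tests) or *render* mode (full image sequences,
  exercising the imaging stages).

Phase conventions.  The correlation scan downstream correlates a feature
against the *wrapped linear phase*; for a cosine-modulated feature that scan
attains its maximum at the shift ``(270 - peak_phase) mod 360``, not at the
cosine peak itself.  The cohort is therefore parameterized by the *group
optimum shift* (default 60 deg, spread 40 deg between subjects) and each
subject's cosine-peak phase is derived via :func:`shift_to_peak_phase`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .constants import (
    FRAME_COLS,
    FRAME_COUNT,
    FRAME_INTERVAL_US,
    FRAME_ROWS,
    NYQUIST_HZ,
    PIXEL_SCALE_UM,
    PULSE_RATE_MAX_BPM,
    PULSE_RATE_MIN_BPM,
    SEQUENCE_DURATION_MS,
)
from .curvature import central_curvature
from .exceptions import RenderGeometryError
from .features import FeatureVector
from .frames import FrameSequence
from .pulse import PulseTrace, bin_phase
from .records import MeasurementRecord

__all__ = [
    "SyntheticTruth",
    "CohortConfig",
    "generate_pulse_trace",
    "generate_iop_readings",
    "render_deformation_sequence",
    "generate_cohort",
    "shift_to_peak_phase",
    "peak_phase_to_shift",
]


def shift_to_peak_phase(shift_deg: float) -> float:
    """Cosine-peak phase whose linear-phase scan optimum is ``shift_deg``."""
    return float((270.0 - shift_deg) % 360.0)


def peak_phase_to_shift(peak_deg: float) -> float:
    """Scan optimum shift produced by a cosine peaking at ``peak_deg``."""
    return float((270.0 - peak_deg) % 360.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one synthetic measurement.

    ``phase_offset_deg`` is the cardiac phase (finger-pulse convention, 0 deg
    at the systolic peak) at which the noiseless IOP is maximal.  The default,
    210 deg, is the peak phase whose recovered optimum scan shift is the
    group value of 60 deg (see module docstring).
    """

    applanation1_ms: float = 7.47
    applanation2_ms: float = 21.54
    max_deformation_mm: float = 1.04
    vibration_hz: float = 416.0
    vibration_amp_um: float = 40.0
    eye_motion_mm: float = 0.3
    iop_baseline_mmHg: float = 15.25
    iop_mod_amp_mmHg: float = 0.75
    phase_offset_deg: float = 210.0
    noise_sd_mmHg: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_deformation_mm > 0:
            if not 0 < self.applanation1_ms < self.applanation2_ms < SEQUENCE_DURATION_MS:
                raise ValueError(
                    "need 0 < applanation1 < applanation2 < "
                    f"{SEQUENCE_DURATION_MS:.2f} ms"
                )
        if not 100.0 < self.vibration_hz < NYQUIST_HZ:
            raise ValueError(f"vibration_hz must lie in (100, {NYQUIST_HZ:.0f}) Hz")
        for name in ("max_deformation_mm", "vibration_amp_um", "eye_motion_mm",
                     "iop_mod_amp_mmHg", "noise_sd_mmHg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.phase_offset_deg < 360:
            raise ValueError("phase_offset_deg must lie in [0, 360)")


# ------------------------------------------------------------------ pulse
#: Beat waveform harmonics: cos(t) + A2*cos(2t) gives a narrowed peak at
#: phase 0; B2*(sin(2t) - 2 sin(t)) adds upstroke/decay asymmetry while
#: keeping the derivative zero (and the maximum) exactly at phase 0.
_PULSE_A2 = 0.25
_PULSE_B2 = 0.18


def _pulse_shape(theta_rad: np.ndarray) -> np.ndarray:
    return (
        np.cos(theta_rad)
        + _PULSE_A2 * np.cos(2 * theta_rad)
        + _PULSE_B2 * (np.sin(2 * theta_rad) - 2 * np.sin(theta_rad))
    )


def generate_pulse_trace(
    rate_bpm: float = 84.0,
    duration_s: float = 5.0,
    jitter_frac: float = 0.04,
    trigger_phase_deg: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 250.0,
    quantize_pct: bool = False,
) -> PulseTrace:
    """Quasi-periodic finger-pulse waveform with a phase-placed trigger.

    Per-beat periods are ``T0 * (1 + jitter_frac * U(-1/2, 1/2))``, so
    successive periods differ by at most ``jitter_frac`` of the mean.  The
    trigger time is placed inside a beat at exactly ``trigger_phase_deg``
    (linear-in-time phase between the bracketing systolic peaks), with at
    least two full beats recorded before it.

    ``quantize_pct`` rounds amplitudes to the emulated oximeter's 1 %
    resolution (off by default: the flat-topped quantized peaks defeat
    sub-sample peak refinement).
    """
    if not PULSE_RATE_MIN_BPM <= rate_bpm <= PULSE_RATE_MAX_BPM:
        raise ValueError(
            f"rate_bpm={rate_bpm} outside the device range "
            f"[{PULSE_RATE_MIN_BPM:.0f}, {PULSE_RATE_MAX_BPM:.0f}]"
        )
    if not 0 <= jitter_frac <= 0.1:
        raise ValueError("jitter_frac must lie in [0, 0.1]")
    t0 = 60.0 / rate_bpm
    if duration_s < 3 * t0:
        raise ValueError("duration_s must cover at least 3 beats")
    rng = np.random.default_rng(seed)
    n_beats = int(np.ceil(duration_s / t0)) + 2
    periods = t0 * (1.0 + jitter_frac * rng.uniform(-0.5, 0.5, size=n_beats))
    peaks = 0.3 * t0 + np.concatenate([[0.0], np.cumsum(periods)])

    times = np.arange(int(np.floor(duration_s * sample_rate_hz)) + 1) / sample_rate_hz
    # unwrapped phase, piecewise linear between peaks, extrapolated at the ends
    unwrapped = np.interp(times, peaks, 360.0 * np.arange(peaks.size))
    head = times < peaks[0]
    unwrapped[head] = 360.0 * (times[head] - peaks[0]) / periods[0]
    shape = _pulse_shape(np.deg2rad(unwrapped))
    lo, hi = _pulse_shape(np.deg2rad(np.linspace(0, 360, 721))).min(), _pulse_shape(
        np.array([0.0])
    )[0]
    samples = 15.0 + 70.0 * (shape - lo) / (hi - lo)
    if quantize_pct:
        samples = np.round(samples)

    # trigger beat: past at least two full beats, near 60 % of the trace
    last_start = np.searchsorted(peaks, times[-1]) - 2
    i0 = int(np.clip(round(0.6 * times[-1] / t0), 2, max(2, last_start)))
    trig = peaks[i0] + (trigger_phase_deg % 360.0) / 360.0 * (peaks[i0 + 1] - peaks[i0])
    return PulseTrace(samples=samples, sample_rate_hz=sample_rate_hz, trigger_time_s=float(trig))


# -------------------------------------------------------------------- IOP
def generate_iop_readings(
    truth: SyntheticTruth, phases_deg, seed: int | None = None
) -> np.ndarray:
    """IOP readings (mmHg) for measurements at the given cardiac phases.

    ``baseline + amp * cos(phase - phase_offset) + N(0, noise_sd)``, one value
    per phase; the noiseless maximum falls exactly at ``phase_offset_deg``.
    """
    phases = np.asarray(phases_deg, dtype=float)
    if np.any((phases < 0) | (phases >= 360)):
        raise ValueError("phases must lie in [0, 360)")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    clean = truth.iop_baseline_mmHg + truth.iop_mod_amp_mmHg * np.cos(
        np.deg2rad(phases - truth.phase_offset_deg)
    )
    if truth.noise_sd_mmHg > 0:
        clean = clean + rng.normal(0.0, truth.noise_sd_mmHg, size=phases.shape)
    return clean


# ----------------------------------------------------------------- render
def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def render_deformation_sequence(
    truth: SyntheticTruth,
    rest_radius_mm: float = 7.8,
    apex_row_px: float = 40.0,
    band_thickness_um: float = 550.0,
    indent_halfwidth_mm: float = 3.0,
    central_halfwidth_mm: float = 1.5,
    noise_sd: float = 3.0,
    blur_sigma_px: float = 0.8,
    edge_width_px: float = 0.7,
) -> tuple[FrameSequence, SyntheticTruth]:
    """Render the 140-frame corneal deformation sequence for a ground truth.

    The anterior contour is ``rest(x) + d(t) * bell(x) + eye_motion(t)`` (rows
    grow into the eye): a parabolic resting cornea, a quartic-bell indentation
    of half-width ``indent_halfwidth_mm`` whose apex amplitude follows a
    raised-cosine rise-peak-recovery profile, a smoothstep whole-eye
    retraction starting at the deformation peak, and a Hann-windowed sinusoid
    at ``vibration_hz`` added to the apex.  The raised-cosine profile is
    solved so that the central region (as measured by the package's own
    flatness criterion) passes through zero curvature exactly at the two
    requested applanation times.

    A zero-deformation truth renders a static scene (all frames identical
    before noise).  Returns the sequence and the (unchanged) truth.
    """
    scale_mm = PIXEL_SCALE_UM / 1000.0
    x_mm = (np.arange(FRAME_COLS) - (FRAME_COLS - 1) / 2.0) * scale_mm
    rest_mm = x_mm**2 / (2.0 * rest_radius_mm)

    w = indent_halfwidth_mm
    bell = np.clip(1.0 - (x_mm / w) ** 2, 0.0, None) ** 2

    central = np.abs(x_mm) <= central_halfwidth_mm
    a2_rest = central_curvature(rest_mm[central], x_mm[central])
    a2_bell = central_curvature(bell[central], x_mm[central])
    times_ms = np.arange(FRAME_COUNT) * FRAME_INTERVAL_US / 1000.0

    amp = truth.max_deformation_mm
    if amp > 0:
        d_flat = -a2_rest / a2_bell  # bell flattens the centre at this depth
        if d_flat <= 0 or amp <= d_flat:
            raise RenderGeometryError(
                f"peak deformation {amp} mm cannot reach the applanation "
                f"amplitude {d_flat:.3f} mm"
            )
        t1, t2 = truth.applanation1_ms, truth.applanation2_ms
        t_mid = 0.5 * (t1 + t2)
        half = 0.5 * (t2 - t1)
        length = half * np.pi / np.arccos(np.sqrt(d_flat / amp))
        t_start = t_mid - 0.5 * length
        t_end = t_mid + 0.5 * length
        if t_start <= 0.3 or t_end >= SEQUENCE_DURATION_MS:
            raise RenderGeometryError(
                "deformation profile does not fit inside the sequence "
                f"(support {t_start:.2f}-{t_end:.2f} ms)"
            )
        inside = (times_ms >= t_start) & (times_ms <= t_end)
        d_t = np.where(
            inside, amp * np.sin(np.pi * (times_ms - t_start) / length) ** 2, 0.0
        )
        vib_window = np.where(
            inside, np.sin(np.pi * (times_ms - t_start) / length) ** 2, 0.0
        )
        vib_t = (
            truth.vibration_amp_um
            / 1000.0
            * np.sin(2 * np.pi * truth.vibration_hz * (times_ms - t_start) / 1000.0)
            * vib_window
        )
        eye_t = truth.eye_motion_mm * _smoothstep(
            (times_ms - t_mid) / (SEQUENCE_DURATION_MS - t_mid)
        )
    else:
        d_t = np.zeros(FRAME_COUNT)
        vib_t = np.zeros(FRAME_COUNT)
        eye_t = np.zeros(FRAME_COUNT)

    # contour rows per frame; check the geometry stays inside the frame
    depth_mm = rest_mm[None, :] + (d_t + vib_t)[:, None] * bell[None, :] + eye_t[:, None]
    y_rows = apex_row_px + depth_mm / scale_mm
    thick_px = band_thickness_um / PIXEL_SCALE_UM
    if y_rows.min() < 2 or (y_rows.max() + thick_px) > FRAME_ROWS - 2:
        raise RenderGeometryError("contour would leave the frame; adjust geometry")

    rng = np.random.default_rng(truth.seed)
    rows = np.arange(FRAME_ROWS, dtype=float)[:, None]
    bg, fg = 20.0, 180.0
    frames = np.empty((FRAME_COUNT, FRAME_ROWS, FRAME_COLS), dtype=np.float32)
    for i in range(FRAME_COUNT):
        top = expit((rows - y_rows[i][None, :]) / edge_width_px)
        bottom = expit((rows - y_rows[i][None, :] - thick_px) / edge_width_px)
        img = bg + (fg - bg) * (top - bottom)
        if blur_sigma_px > 0:
            img = gaussian_filter(img, blur_sigma_px)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0.0, 255.0)

    seq = FrameSequence(
        frames=frames,
        frame_interval_us=FRAME_INTERVAL_US,
        pixel_scale_um=PIXEL_SCALE_UM,
        meta={
            "apex_col": int((FRAME_COLS - 1) // 2),
            "flat_amplitude_mm": float(-a2_rest / a2_bell) if amp > 0 else np.nan,
        },
    )
    return seq, truth


# ----------------------------------------------------------------- cohort
@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of a synthetic study cohort.

    Defaults emulate the study conditions: 84 beats/min pulse with 4 % rate
    variability, measurement phases spread quasi-evenly over the cycle, a
    group optimum shift of 60 deg with 40 deg between-subject spread, cosine
    IOP modulation of 0.75 mmHg with 0.25 mmHg reading noise, and feature
    populations matching a healthy adult cohort.
    """

    group_shift_deg: float = 60.0
    group_shift_sd_deg: float = 40.0
    iop_baseline_mean_mmHg: float = 11.9
    iop_baseline_sd_mmHg: float = 2.4
    iop_mod_amp_mmHg: float = 0.75
    iop_noise_sd_mmHg: float = 0.25
    phase_jitter_deg: float = 10.0
    rate_bpm: float = 84.0
    rate_jitter_frac: float = 0.04
    # fast-mode feature populations: (population mean, between-subject sd,
    # within-subject sd)
    w1_pop: tuple = (7.1, 0.30, 0.15)
    w2_pop: tuple = (22.0, 0.40, 0.15)
    w3_pop: tuple = (1.09, 0.05, 0.025)
    w4_pop: tuple = (415.0, 15.0, 3.0)
    # render-mode extras
    vibration_amp_um: float = 40.0
    eye_motion_mm: float = 0.3
    render_noise_sd: float = 3.0


def generate_cohort(
    n_subjects: int = 10,
    n_meas_per_subject: int = 6,
    config: CohortConfig | None = None,
    seed: int = 0,
    mode: str = "fast",
) -> tuple[list[MeasurementRecord], list[SyntheticTruth]]:
    """Generate a synthetic study cohort with known ground truth.

    In ``fast`` mode each record carries a complete feature vector (w1-w6)
    drawn from the configured populations, with w5 following the cosine
    phase-coupling law; in ``render`` mode each record instead carries a
    rendered frame sequence and a pulse trace with the trigger placed at the
    measurement's cardiac phase, leaving feature extraction to the imaging
    pipeline.  Returns one ground-truth object per measurement.
    """
    if n_meas_per_subject < 3:
        raise ValueError("need at least 3 measurements per subject")
    if mode not in ("fast", "render"):
        raise ValueError("mode must be 'fast' or 'render'")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    records: list[MeasurementRecord] = []
    truths: list[SyntheticTruth] = []
    k_phase_step = 360.0 / n_meas_per_subject

    for v in range(1, n_subjects + 1):
        eye = "right" if v <= (n_subjects + 1) // 2 else "left"
        shift_v = float(rng.normal(cfg.group_shift_deg, cfg.group_shift_sd_deg) % 360.0)
        peak_v = shift_to_peak_phase(shift_v)
        baseline_v = float(np.clip(rng.normal(cfg.iop_baseline_mean_mmHg, cfg.iop_baseline_sd_mmHg), 5.0, 30.0))
        means = {
            name: rng.normal(pop[0], pop[1])
            for name, pop in (
                ("w1", cfg.w1_pop), ("w2", cfg.w2_pop),
                ("w3", cfg.w3_pop), ("w4", cfg.w4_pop),
            )
        }
        start = rng.uniform(0.0, 360.0)
        phases = (
            start
            + np.arange(n_meas_per_subject) * k_phase_step
            + rng.normal(0.0, cfg.phase_jitter_deg, n_meas_per_subject)
        ) % 360.0

        for k in range(1, n_meas_per_subject + 1):
            theta = float(phases[k - 1])
            meas_seed = int(rng.integers(0, 2**31 - 1))
            truth = SyntheticTruth(
                applanation1_ms=float(np.clip(means["w1"] + rng.normal(0, cfg.w1_pop[2]), 4.0, 12.0)),
                applanation2_ms=float(np.clip(means["w2"] + rng.normal(0, cfg.w2_pop[2]), 18.0, 27.0)),
                max_deformation_mm=float(np.clip(means["w3"] + rng.normal(0, cfg.w3_pop[2]), 0.7, 1.4)),
                vibration_hz=float(np.clip(means["w4"] + rng.normal(0, cfg.w4_pop[2]), 150.0, 900.0)),
                vibration_amp_um=cfg.vibration_amp_um,
                eye_motion_mm=cfg.eye_motion_mm,
                iop_baseline_mmHg=baseline_v,
                iop_mod_amp_mmHg=cfg.iop_mod_amp_mmHg,
                phase_offset_deg=peak_v,
                noise_sd_mmHg=cfg.iop_noise_sd_mmHg,
                seed=meas_seed,
            )
            iop = float(np.round(generate_iop_readings(truth, [theta], seed=meas_seed)[0], 1))
            truths.append(truth)

            if mode == "fast":
                fv = FeatureVector(
                    w1_ms=truth.applanation1_ms,
                    w2_ms=truth.applanation2_ms,
                    w3_mm=truth.max_deformation_mm,
                    w4_hz=truth.vibration_hz,
                    w5_mmHg=iop,
                    w6_deg=bin_phase(theta),
                )
                records.append(
                    MeasurementRecord(subject=v, measurement=k, eye=eye, features=fv, iop_mmHg=iop)
                )
            else:
                seq, _ = render_deformation_sequence(truth, noise_sd=cfg.render_noise_sd)
                trace = generate_pulse_trace(
                    rate_bpm=cfg.rate_bpm,
                    duration_s=5.0,
                    jitter_frac=cfg.rate_jitter_frac,
                    trigger_phase_deg=theta,
                    seed=meas_seed,
                )
                records.append(
                    MeasurementRecord(
                        subject=v, measurement=k, eye=eye,
                        frames=seq, pulse=trace, iop_mmHg=iop,
                    )
                )
    return records, truths
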