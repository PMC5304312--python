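"""Applanation timing, peak deformation and vibration frequency extraction."""

import numpy as np
import pytest

from oculopulse import (
    DeformationProfile,
    applanation_times,
    assemble_feature_vector,
    max_deformation,
    vibration_frequency,
)
from oculopulse.curvature import _line_residual_rms
from oculopulse.exceptions import NoApplanationError, NoVibrationError

DT_MS = 0.231
N_FRAMES = 140


def analytic_profile(
    a1=7.47, a2=21.54, amp=1.04, d_flat=0.30, vib_hz=None, vib_amp_mm=0.0
):
    """Profile of a raised-cosine deformation that crosses the flatness
    amplitude ``d_flat`` exactly at the requested applanation times."""
    t = np.arange(N_FRAMES) * DT_MS
    t_mid, half = 0.5 * (a1 + a2), 0.5 * (a2 - a1)
    length = half * np.pi / np.arccos(np.sqrt(d_flat / amp))
    t_start = t_mid - 0.5 * length
    inside = (t >= t_start) & (t <= t_start + length)
    d = np.where(inside, amp * np.sin(np.pi * (t - t_start) / length) ** 2, 0.0)
    v = np.zeros_like(d)
    if vib_hz is not None:
        v = vib_amp_mm * np.sin(2 * np.pi * vib_hz * t / 1000.0) * inside
    a2_rest = 1.0 / (2 * 7.8)
    a2_bell = -a2_rest / d_flat
    curv = a2_rest + (d + v) * a2_bell
    x_mm = (np.arange(-75, 75)) * 0.02
    scale = _line_residual_rms(x_mm)
    return DeformationProfile(
        time_ms=t,
        apex_mm=d + v,
        central_flatness=np.abs(curv) * scale,
        central_curvature=curv,
        flatness_scale_mm2=scale,
    )


class TestApplanationTimes:
    def test_crossing_times_recovered(self):
        w1, w2 = applanation_times(analytic_profile())
        assert w1 == pytest.approx(7.47, abs=0.1)
        assert w2 == pytest.approx(21.54, abs=0.1)

    def test_recovery_with_superimposed_vibration(self):
        """A 40 um, 416 Hz vibration does not disturb the applanation times."""
        prof = analytic_profile(vib_hz=416.0, vib_amp_mm=0.04)
        w1, w2 = applanation_times(prof)
        assert w1 == pytest.approx(7.47, abs=0.3)
        assert w2 == pytest.approx(21.54, abs=0.3)

    def test_flatness_never_crossing_raises(self):
        t = np.arange(N_FRAMES) * DT_MS
        curv = np.full(N_FRAMES, 0.064)  # resting curvature, never flattens
        prof = DeformationProfile(
            time_ms=t, apex_mm=np.zeros(N_FRAMES),
            central_flatness=np.abs(curv) * 0.5,
            central_curvature=curv, flatness_scale_mm2=0.5,
        )
        with pytest.raises(NoApplanationError):
            applanation_times(prof)

    def test_symmetric_profile_times_are_equidistant_from_peak(self):
        prof = analytic_profile(a1=8.0, a2=20.0)
        w1, w2 = applanation_times(prof)
        t_peak = 14.0
        assert abs((t_peak - w1) - (w2 - t_peak)) <= DT_MS


class TestMaxDeformation:
    def test_parabolic_vertex_recovered_exactly(self):
        """Samples of a parabola: the analytic vertex comes back exactly,
        including the moving-average attenuation correction."""
        t = np.arange(N_FRAMES) * DT_MS
        apex = 1.0 - 0.0008 * (np.arange(N_FRAMES) - 70.3) ** 2
        prof = DeformationProfile(time_ms=t, apex_mm=apex, central_flatness=np.zeros(N_FRAMES))
        assert max_deformation(prof) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_profile_gives_zero(self):
        t = np.arange(N_FRAMES) * DT_MS
        prof = DeformationProfile(time_ms=t, apex_mm=np.zeros(N_FRAMES), central_flatness=np.zeros(N_FRAMES))
        assert max_deformation(prof) == 0.0

    def test_monotone_under_pointwise_scaling(self):
        prof = analytic_profile()
        doubled = DeformationProfile(
            time_ms=prof.time_ms, apex_mm=2 * prof.apex_mm, central_flatness=prof.central_flatness
        )
        assert max_deformation(doubled) == pytest.approx(2 * max_deformation(prof), rel=1e-9)


class TestVibrationFrequency:
    def test_injected_tone_recovered(self):
        prof = analytic_profile(vib_hz=416.0, vib_amp_mm=0.04)
        assert vibration_frequency(prof) == pytest.approx(416.0, abs=15.0)

    def test_pure_slow_deformation_has_no_vibration(self):
        with pytest.raises(NoVibrationError):
            vibration_frequency(analytic_profile())

    def test_strongest_of_two_tones_wins(self):
        """150 Hz (weak) + 430 Hz (strong): the 430 Hz line is reported, as a
        brute-force argmax over the residual spectrum predicts."""
        t = np.arange(N_FRAMES) * DT_MS
        prof = analytic_profile(vib_hz=430.0, vib_amp_mm=0.04)
        apex = prof.apex_mm + 0.008 * np.sin(2 * np.pi * 150.0 * t / 1000.0)
        prof2 = DeformationProfile(
            time_ms=t, apex_mm=apex, central_flatness=prof.central_flatness
        )
        assert vibration_frequency(prof2) == pytest.approx(430.0, abs=15.0)

    def test_invariant_to_constant_and_linear_trend(self):
        prof = analytic_profile(vib_hz=380.0, vib_amp_mm=0.04)
        f0 = vibration_frequency(prof)
        trended = DeformationProfile(
            time_ms=prof.time_ms,
            apex_mm=prof.apex_mm + 0.5 + 0.01 * prof.time_ms,
            central_flatness=prof.central_flatness,
        )
        assert vibration_frequency(trended) == pytest.approx(f0, abs=1e-9)

    def test_short_sequence_rejected(self):
        t = np.arange(40) * DT_MS
        prof = DeformationProfile(time_ms=t, apex_mm=np.zeros(40), central_flatness=np.zeros(40))
        with pytest.raises(ValueError):
            vibration_frequency(prof)


class TestAssembleFeatureVector:
    def test_reference_measurement_is_valid(self):
        fv = assemble_feature_vector(7.363, 21.444, 1.015, 432.0, 15.0, 0)
        assert fv.w5_mmHg == 15.0 and fv.w6_deg == 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(w1_ms=21.444, w2_ms=21.444),          # w1 must precede w2
            dict(w4_hz=100.0),                          # strict >100 Hz
            dict(w3_mm=0.0),
            dict(phase_bin_deg=45),                     # off the 30-degree grid
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        base = dict(w1_ms=7.363, w2_ms=21.444, w3_mm=1.015, w4_hz=432.0,
                    iop_mmHg=15.0, phase_bin_deg=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            assemble_feature_vector(**base)


class TestRenderedRecovery:
    def test_features_recovered_from_default_noise_render(self, extracted):
        """Full imaging chain at default noise recovers the injected features
        within the stated resolution bounds."""
        _, _, profile, truth = extracted
        w1, w2 = applanation_times(profile)
        assert abs(w1 - truth.applanation1_ms) <= 0.3
        assert abs(w2 - truth.applanation2_ms) <= 0.3
        assert abs(max_deformation(profile) - truth.max_deformation_mm) <= 0.02
        assert abs(vibration_frequency(profile) - truth.vibration_hz) <= 15.0
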