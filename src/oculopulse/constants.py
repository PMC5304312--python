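"""Acquisition constants of the emulated ultra-high-speed Scheimpflug tonometer.

The imaging geometry is fixed by the device: each measurement records
``FRAME_COUNT`` cross-sectional frames of ``FRAME_ROWS`` x ``FRAME_COLS``
pixels, one frame every ``FRAME_INTERVAL_US`` microseconds, with an average
lateral scale of ``PIXEL_SCALE_UM`` per pixel.
"""

FRAME_COUNT = 140
FRAME_ROWS = 200
FRAME_COLS = 576
FRAME_INTERVAL_US = 231.0
PIXEL_SCALE_UM = 20.0

#: Frame rate implied by the inter-frame interval (Hz).
FRAME_RATE_HZ = 1e6 / FRAME_INTERVAL_US

#: Nyquist limit for corneal-vibration frequency estimation (Hz).
NYQUIST_HZ = FRAME_RATE_HZ / 2.0

#: Total duration of one deformation sequence (ms).
SEQUENCE_DURATION_MS = FRAME_COUNT * FRAME_INTERVAL_US / 1000.0

#: Width of one blood-pulsation phase bin (degrees); 12 bins cover the cycle.
PHASE_BIN_DEG = 30

#: Pulse-rate range accepted by the emulated pulse oximeter (beats/minute).
PULSE_RATE_MIN_BPM = 20.0
PULSE_RATE_MAX_BPM = 254.0
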