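"""Anterior corneal contour extraction and motion decomposition.

Each frame of a deformation sequence is median-filtered, edge-detected with a
Canny filter (hysteresis thresholds expressed as fractions of the per-frame
gradient-magnitude maximum, so exposure differences do not matter), and the
uppermost dark-to-bright transition per column is taken as the anterior
surface, refined to sub-pixel precision by parabolic interpolation of the
gradient peak.  Gaps (blinks, occlusions, dropouts) are completed with a
5th-degree polynomial fitted to the detected columns — a degree consistent
with anthropometric corneal curvature.

The per-frame contours are then decomposed into three components: the resting
shape (frame 0, before the air puff acts), a per-frame scalar whole-eye
displacement (the globe retracting rigidly under the puff, tracked by the
peripheral columns), and the corneal reaction proper — the indentation left
after removing the first two.

Coordinates: row 0 is the top of the image, columns run left to right, and
sub-pixel rows are real-valued.  Displacements *into* the eye (downward in the
image) count positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .constants import FRAME_INTERVAL_US, PIXEL_SCALE_UM
from .exceptions import ContourRejectedError
from .frames import FrameSequence

__all__ = [
    "ContourSet",
    "ResponseDecomposition",
    "median_filter_frame",
    "detect_corneal_edge",
    "complete_contour",
    "extract_contours",
    "decompose_response",
]


@dataclass
class ContourSet:
    """Sub-pixel anterior-edge rows for every frame of a sequence.

    ``y[i, n]`` is the edge row in frame ``i`` at column ``n`` (NaN where the
    whole frame is invalid); ``valid`` marks directly detected columns and
    ``filled`` marks polynomial-completed spans.
    """

    y: np.ndarray
    valid: np.ndarray
    filled: np.ndarray
    frame_valid: np.ndarray
    pixel_scale_um: float = PIXEL_SCALE_UM
    frame_interval_us: float = FRAME_INTERVAL_US


@dataclass
class ResponseDecomposition:
    """Separation of contour motion into rest shape, eye motion and reaction.

    ``corneal_reaction_mm[i, n]`` is the indentation depth (mm, positive
    toward the eye) at column ``n`` of frame ``i`` after subtracting the
    resting contour and the per-frame scalar whole-eye displacement
    ``eye_motion_mm[i]``.
    """

    rest_shape_px: np.ndarray
    eye_motion_mm: np.ndarray
    corneal_reaction_mm: np.ndarray
    frame_valid: np.ndarray = field(default=None)  # type: ignore[assignment]


def median_filter_frame(frame: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication (suppresses <=4 px artefacts)."""
    frame = np.asarray(frame)
    if frame.shape[0] < 3 or frame.shape[1] < 3:
        raise ValueError("frame must be at least 3x3")
    return ndimage.median_filter(frame, size=3, mode="nearest")


def detect_corneal_edge(
    frame: np.ndarray,
    low_frac: float = 0.1,
    high_frac: float = 0.3,
    sigma: float = 1.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-column anterior-edge rows from one (filtered) frame.

    Canny edges are computed with hysteresis thresholds ``low_frac``/
    ``high_frac`` of the per-frame gradient-magnitude maximum; per column the
    uppermost edge with a dark-to-bright (downward-brightening) transition is
    kept — in this imaging geometry the anterior surface is the first bright
    transition scanning top-down.  Returns ``(edge_rows, valid_mask)`` with
    NaN rows where no edge was found.
    """
    f = np.asarray(frame, dtype=float)
    gmag = ndimage.gaussian_gradient_magnitude(f, sigma)
    gmax = float(gmag.max())
    n_cols = f.shape[1]
    if gmax <= 0:
        return np.full(n_cols, np.nan), np.zeros(n_cols, dtype=bool)
    edges = canny(f, sigma=sigma, low_threshold=low_frac * gmax, high_threshold=high_frac * gmax)
    dy = ndimage.gaussian_filter1d(f, sigma, axis=0, order=1)
    anterior = edges & (dy > 0)

    valid = anterior.any(axis=0)
    rows = np.where(valid, np.argmax(anterior, axis=0), 0)
    # parabolic sub-pixel refinement on the gradient magnitude profile
    r = np.clip(rows, 1, f.shape[0] - 2)
    cols = np.arange(n_cols)
    g0, g1, g2 = gmag[r - 1, cols], gmag[r, cols], gmag[r + 1, cols]
    denom = g0 - 2 * g1 + g2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (g0 - g2) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    edge_rows = np.where(valid, rows + delta, np.nan)
    return edge_rows, valid


def reject_edge_outliers(
    edge_rows: np.ndarray,
    valid_mask: np.ndarray,
    window: int = 31,
    max_dev_px: float = 4.0,
) -> np.ndarray:
    """Invalidate detected points far from the local (rolling-median) contour.

    The anterior contour is smooth across columns; an isolated noise edge that
    survives hysteresis sits many pixels away from its neighbours.  Points
    deviating more than ``max_dev_px`` from the centred rolling median of the
    detected points are flagged invalid (and later polynomial-filled), which
    preserves contour continuity.  Returns the tightened validity mask.

    Only columns with a complete centred window are tested: at the image
    borders the truncated window is asymmetric and the steep peripheral
    contour slope would masquerade as a deviation (border glitches in frames
    past the first are caught by the temporal guard instead).
    """
    import pandas as pd

    s = pd.Series(np.where(valid_mask, edge_rows, np.nan))
    med = s.rolling(window, center=True, min_periods=window).median().to_numpy()
    with np.errstate(invalid="ignore"):
        bad = np.abs(edge_rows - med) > max_dev_px
    return valid_mask & ~np.nan_to_num(bad).astype(bool)


def complete_contour(
    edge_rows: np.ndarray,
    valid_mask: np.ndarray,
    degree: int = 5,
    min_valid: int = 12,
    min_span_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill gaps in a raw contour with a least-squares polynomial (degree 5).

    Detected columns are retained verbatim; invalid spans take the
    polynomial's values and are flagged in the returned ``fill_mask``.
    Re-running on an already complete contour is a no-op.

    Raises
    ------
    ContourRejectedError
        If fewer than ``min_valid`` columns are valid or the valid columns
        span less than ``min_span_frac`` of the analysis window.
    """
    edge_rows = np.asarray(edge_rows, dtype=float)
    valid = np.asarray(valid_mask, dtype=bool)
    n = edge_rows.size
    cols = np.flatnonzero(valid)
    if cols.size < min_valid:
        raise ContourRejectedError(f"only {cols.size} valid columns (<{min_valid})")
    if (cols[-1] - cols[0]) < min_span_frac * (n - 1):
        raise ContourRejectedError("valid columns span less than half the window")
    poly = np.polynomial.Polynomial.fit(cols, edge_rows[cols], degree)
    y = edge_rows.copy()
    fill = ~valid
    if fill.any():
        y[fill] = poly(np.flatnonzero(fill))
    return y, valid, fill


def extract_contours(
    seq: FrameSequence,
    low_frac: float = 0.1,
    high_frac: float = 0.3,
    sigma: float = 1.4,
    degree: int = 5,
    median: bool = True,
    spatial_max_dev_px: float = 4.0,
    temporal_max_px: float = 5.0,
) -> ContourSet:
    """Run the full per-frame contour pipeline on a sequence.

    Besides per-frame detection and completion, two continuity guards drop
    implausible edge points before the polynomial fill: a spatial one
    (deviation from the rolling median across columns above
    ``spatial_max_dev_px``) and a temporal one (deviation from the previous
    valid frame's completed contour above ``temporal_max_px`` — inter-frame
    corneal motion is bounded well below that).
    """
    n_frames = seq.n_frames
    n_cols = seq.shape[1]
    y = np.full((n_frames, n_cols), np.nan)
    valid = np.zeros((n_frames, n_cols), dtype=bool)
    filled = np.zeros((n_frames, n_cols), dtype=bool)
    frame_ok = np.zeros(n_frames, dtype=bool)
    prev_y: np.ndarray | None = None
    for i in range(n_frames):
        frame = seq.frames[i]
        if median:
            frame = median_filter_frame(frame)
        raw, vmask = detect_corneal_edge(frame, low_frac, high_frac, sigma)
        if spatial_max_dev_px > 0:
            vmask = reject_edge_outliers(raw, vmask, max_dev_px=spatial_max_dev_px)
        if prev_y is not None and temporal_max_px > 0:
            with np.errstate(invalid="ignore"):
                jump = np.abs(raw - prev_y) > temporal_max_px
            vmask = vmask & ~np.nan_to_num(jump).astype(bool)
        if not vmask.any():
            continue
        try:
            yi, vi, fi = complete_contour(raw, vmask, degree=degree)
        except ContourRejectedError:
            continue
        y[i], valid[i], filled[i] = yi, vi, fi
        frame_ok[i] = True
        prev_y = yi
    return ContourSet(
        y=y,
        valid=valid,
        filled=filled,
        frame_valid=frame_ok,
        pixel_scale_um=seq.pixel_scale_um,
        frame_interval_us=seq.frame_interval_us,
    )


def decompose_response(
    contours: ContourSet, peripheral_frac: float = 0.1
) -> ResponseDecomposition:
    """Split contour motion into rest shape, whole-eye motion and reaction.

    The whole-eye displacement of frame ``i`` is the mean contour displacement
    (relative to frame 0) over the outermost ``peripheral_frac`` of columns on
    each side — the air puff indents the centre while the periphery tracks the
    rigid retraction of the globe.  The corneal reaction is the remaining
    displacement, converted to mm, positive toward the eye.

    Raises
    ------
    ContourRejectedError
        If frame 0 (the resting reference) is invalid.
    """
    if not contours.frame_valid[0]:
        raise ContourRejectedError("frame 0 invalid: no resting reference")
    y = contours.y
    n_frames, n_cols = y.shape
    rest = y[0].copy()
    scale_mm = contours.pixel_scale_um / 1000.0
    disp_mm = (y - rest[None, :]) * scale_mm  # positive = downward = into eye
    k = max(1, int(round(peripheral_frac * n_cols)))
    peripheral = np.r_[0:k, n_cols - k : n_cols]
    eye_motion = np.nanmean(disp_mm[:, peripheral], axis=1)
    eye_motion[~contours.frame_valid] = np.nan
    reaction = disp_mm - eye_motion[:, None]
    return ResponseDecomposition(
        rest_shape_px=rest,
        eye_motion_mm=eye_motion,
        corneal_reaction_mm=reaction,
        frame_valid=contours.frame_valid,
    )
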