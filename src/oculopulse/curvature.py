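"""Central-region curvature and flatness of a corneal contour.

Applanation ("momentary flattening") is detected geometrically: the central
portion of the anterior contour is fitted with a quadratic in the lateral
coordinate, and flatness is measured as the RMS deviation of that fit from its
own best straight line.  For a symmetric lateral grid this reduces to
``|a2| * rms(x^2 - line)`` with ``a2`` the fitted curvature coefficient, so the
measure is a pure curvature magnitude and is insensitive to uncorrelated
per-column contour noise (which a raw point-wise RMS is not).

The same helper is used by the synthetic renderer to place the flatness
crossings of a rendered sequence exactly at the requested applanation times,
keeping rendered ground truth and the extraction criterion mutually consistent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["central_curvature", "curvature_to_flatness_mm"]


def central_curvature(y_mm: np.ndarray, x_mm: np.ndarray) -> float:
    """Quadratic-fit curvature coefficient ``a2`` (1/mm) of a contour segment.

    Parameters
    ----------
    y_mm : array
        Contour elevation (mm) at each lateral position; orientation is
        irrelevant, only the magnitude of curvature enters the flatness.
    x_mm : array
        Lateral positions (mm), typically centred on the deformation apex.
    """
    y_mm = np.asarray(y_mm, dtype=float)
    x_mm = np.asarray(x_mm, dtype=float)
    if y_mm.shape != x_mm.shape or y_mm.size < 3:
        raise ValueError("need matching x/y arrays with at least 3 points")
    coeffs = np.polynomial.polynomial.polyfit(x_mm, y_mm, 2)
    return float(coeffs[2])


def _line_residual_rms(x_mm: np.ndarray) -> float:
    """RMS of ``x^2`` about its least-squares line on the given grid (mm^2)."""
    x_mm = np.asarray(x_mm, dtype=float)
    x2 = x_mm**2
    design = np.column_stack([np.ones_like(x_mm), x_mm])
    coef, *_ = np.linalg.lstsq(design, x2, rcond=None)
    resid = x2 - design @ coef
    return float(np.sqrt(np.mean(resid**2)))


def curvature_to_flatness_mm(a2_per_mm: float, x_mm: np.ndarray) -> float:
    """Convert a curvature coefficient into the flatness RMS (mm) on a grid."""
    return abs(float(a2_per_mm)) * _line_residual_rms(x_mm)
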