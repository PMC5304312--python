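"""Measurement records: one air-puff measurement of one subject's eye."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .features import FeatureVector
from .frames import FrameSequence
from .pulse import PulseTrace

__all__ = ["MeasurementRecord", "records_to_dataframe"]


@dataclass
class MeasurementRecord:
    """One measurement ``k`` of subject ``v``.

    ``features`` is None until extraction has run (rendered cohorts carry the
    raw frames and pulse trace instead); ``iop_mmHg`` holds the device reading
    that becomes ``w5``.
    """

    subject: int
    measurement: int
    eye: str
    features: Optional[FeatureVector] = None
    frames: Optional[FrameSequence] = None
    pulse: Optional[PulseTrace] = None
    iop_mmHg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")


def records_to_dataframe(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Tabulate records with assembled features into the analysis frame."""
    rows = []
    for rec in records:
        if rec.features is None:
            continue
        f = rec.features
        rows.append(
            {
                "subject": rec.subject,
                "measurement": rec.measurement,
                "eye": rec.eye,
                "w1_ms": f.w1_ms,
                "w2_ms": f.w2_ms,
                "w3_mm": f.w3_mm,
                "w4_hz": f.w4_hz,
                "w5_mmHg": f.w5_mmHg,
                "w6_deg": f.w6_deg,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and df.duplicated(["subject", "measurement"]).any():
        raise ValueError("duplicate (subject, measurement) pairs")
    return df
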