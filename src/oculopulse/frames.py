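"""Calibrated grayscale frame stacks and their on-disk formats.

A :class:`FrameSequence` is the in-memory form of one air-puff measurement:
``I`` frames of ``M x N`` pixels with a fixed inter-frame interval and lateral
pixel scale.  On disk a sequence is either a directory of per-frame JPEGs
(``frame_000.jpg`` ...) or a single AVI; both are read through :mod:`imageio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .constants import FRAME_INTERVAL_US, PIXEL_SCALE_UM

__all__ = ["FrameSequence"]


@dataclass
class FrameSequence:
    """Stack of grayscale frames with a time base and pixel calibration.

    Attributes
    ----------
    frames : ndarray, shape (I, M, N)
        Grayscale intensities (arbitrary units, float or integer).
    frame_interval_us : float
        Time between successive frames (microseconds).
    pixel_scale_um : float
        Lateral size of one pixel (micrometres).
    """

    frames: np.ndarray
    frame_interval_us: float = FRAME_INTERVAL_US
    pixel_scale_um: float = PIXEL_SCALE_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (I, M, N) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.frame_interval_us <= 0:
            raise ValueError("frame_interval_us must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp of each frame in milliseconds from sequence start."""
        return np.arange(self.n_frames) * self.frame_interval_us / 1000.0

    @property
    def frame_rate_hz(self) -> float:
        return 1e6 / self.frame_interval_us

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_jpeg_dir(cls, path: str | Path, **kwargs) -> "FrameSequence":
        """Load a per-frame JPEG directory (files sorted lexicographically)."""
        path = Path(path)
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".jpg", ".jpeg", ".png"))
        if len(files) < 2:
            raise ValueError(f"no frame images found in {path}")
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
        if frames.ndim == 4:  # RGB saved by some writers; collapse to gray
            frames = frames.mean(axis=-1)
        return cls(frames=frames, **kwargs)

    @classmethod
    def from_avi(cls, path: str | Path, **kwargs) -> "FrameSequence":
        frames = np.asarray(iio.imread(Path(path), plugin="pyav"))
        if frames.ndim == 4:
            frames = frames.mean(axis=-1)
        return cls(frames=frames, **kwargs)

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "FrameSequence":
        """Dispatch on path type: directory of JPEGs or a single AVI file."""
        path = Path(path)
        if path.is_dir():
            return cls.from_jpeg_dir(path, **kwargs)
        if path.suffix.lower() == ".avi":
            return cls.from_avi(path, **kwargs)
        raise ValueError(f"unsupported frame source: {path}")

    def to_jpeg_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        stack = np.clip(self.frames, 0, 255).astype(np.uint8)
        for i, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{i:03d}.jpg", frame)
        return path
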