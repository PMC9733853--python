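"""Segmentation of annotated recordings into fixed-length labeled windows.

Windows are non-overlapping, anchored at each annotation interval's start, and
trailing partial windows are discarded, so every window carries exactly one
task label and exactly ``window_s * sampling_rate`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AccelRecording, AnnotationTrack

logger = logging.getLogger(__name__)


@dataclass
class WindowingConfig:
    """Window length in seconds (4 and 10 are the standard choices: 128 and
    320 samples at 32 Hz) plus the sampling rate."""

    window_s: float
    sampling_rate: float

    def __post_init__(self) -> None:
        n = self.window_s * self.sampling_rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window_s * sampling_rate must be a positive integer, got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.window_s * self.sampling_rate))


@dataclass
class Window:
    """One fixed-length single-task segment, traceable to subject and time."""

    subject_id: str
    label: str
    start_s: float
    samples: np.ndarray  # (L, 3)
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError(f"window samples must be (L, 3), got {self.samples.shape}")
        if not np.isfinite(self.samples).all():
            raise ValueError("window samples contain NaN or Inf")

    @property
    def window_s(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


def segment(
    rec: AccelRecording, track: AnnotationTrack, cfg: WindowingConfig
) -> list[Window]:
    """Cut each annotated interval into consecutive non-overlapping windows.

    The first window starts at the interval start (rounded up to the next
    sample); a trailing partial window is dropped.  The number of windows per
    interval is therefore ``floor(interval_length / window_s)``.
    """
    L = cfg.n_samples
    fs = cfg.sampling_rate
    n_total = rec.samples.shape[0]
    windows: list[Window] = []
    for label, start_s, end_s in track.entries:
        i0 = int(np.ceil(start_s * fs - 1e-9))
        i_end = min(int(np.floor(end_s * fs + 1e-9)), n_total)
        i = i0
        while i + L <= i_end:
            windows.append(
                Window(
                    subject_id=rec.subject_id,
                    label=label,
                    start_s=i / fs,
                    samples=rec.samples[i : i + L],
                    sampling_rate=fs,
                )
            )
            i += L
    if not windows:
        logger.warning(
            "no interval long enough for a %.3g s window; returning empty list",
            cfg.window_s,
        )
    return windows
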