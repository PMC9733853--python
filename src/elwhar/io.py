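"""Plain-text I/O for annotated tri-axial accelerometer recordings.

The recording dialect mirrors wrist-device CSV exports: three metadata header
lines (``subject_id``, ``sampling_rate``, ``start_time``), an ``x,y,z`` column
header, then one row of acceleration samples (in g) per time step.
Annotations are a separate CSV of ``label,start_s,end_s`` rows with times in
seconds relative to the recording start.

Samples are written with 6 decimal places, so a write/read round trip is
exact to 1e-6 g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tasks import TASKS


class ParseError(ValueError):
    """Malformed recording or annotation file; message names the line."""


class ValidationError(ValueError):
    """Structurally parseable but semantically invalid data."""


@dataclass
class AccelRecording:
    """One subject's tri-axial acceleration stream.

    Parameters
    ----------
    subject_id : str
        Identifier of the wearer.
    sampling_rate : float
        Samples per second; must be positive.
    samples : ndarray of shape (n, 3)
        Acceleration in g, axis order X, Y, Z.
    start_time : float
        Recording start in seconds (0-based by convention).
    """

    subject_id: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"samples must be an (n, 3) array, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValidationError("samples contain NaN or Inf")

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


@dataclass
class AnnotationTrack:
    """Sorted, non-overlapping task annotations in seconds from recording start."""

    entries: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [(str(l), float(s), float(e)) for l, s, e in self.entries]
        for label, start, end in self.entries:
            if label not in TASKS:
                raise ValidationError(
                    f"unknown task label {label!r}; expected one of {sorted(TASKS)}"
                )
            if not start < end:
                raise ValidationError(
                    f"annotation {label!r} has start_s {start} >= end_s {end}"
                )
        for (la, sa, ea), (lb, sb, eb) in zip(self.entries, self.entries[1:]):
            if sb < ea:
                raise ValidationError(
                    f"overlapping annotations: ({la!r}, {sa}, {ea}) and "
                    f"({lb!r}, {sb}, {eb})"
                )

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.entries]


def write_recording(rec: AccelRecording, path) -> None:
    """Write a recording in the header+samples CSV dialect."""
    with open(path, "w") as fh:
        fh.write(f"subject_id,{rec.subject_id}\n")
        fh.write(f"sampling_rate,{rec.sampling_rate:g}\n")
        fh.write(f"start_time,{rec.start_time:g}\n")
        fh.write("x,y,z\n")
        np.savetxt(fh, rec.samples, fmt="%.6f", delimiter=",")


def read_recording(path) -> AccelRecording:
    """Read a recording; raises :class:`ParseError` naming the first bad line."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise ParseError(f"{path}: file too short ({len(lines)} lines)")

    header: dict[str, str] = {}
    for lineno, key in ((1, "subject_id"), (2, "sampling_rate"), (3, "start_time")):
        parts = lines[lineno - 1].split(",")
        if len(parts) != 2 or parts[0] != key:
            raise ParseError(
                f"{path}: line {lineno}: expected '{key},<value>', got {lines[lineno - 1]!r}"
            )
        header[key] = parts[1]
    try:
        fs = float(header["sampling_rate"])
        start_time = float(header["start_time"])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric header value: {exc}") from None
    if fs <= 0:
        raise ParseError(f"{path}: line 2: sampling_rate must be positive, got {fs}")
    if lines[3] != "x,y,z":
        raise ParseError(f"{path}: line 4: expected column header 'x,y,z'")

    rows = []
    for lineno, line in enumerate(lines[4:], start=5):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(
                f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell") from None
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return AccelRecording(
        subject_id=header["subject_id"],
        sampling_rate=fs,
        samples=np.asarray(rows),
        start_time=start_time,
    )


def write_annotations(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("label,start_s,end_s\n")
        for label, start, end in track.entries:
            fh.write(f"{label},{start:g},{end:g}\n")


def read_annotations(path) -> AnnotationTrack:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != "label,start_s,end_s":
        raise ParseError(f"{path}: line 1: expected header 'label,start_s,end_s'")
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(
                f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            entries.append((parts[0], float(parts[1]), float(parts[2])))
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric time") from None
    return AnnotationTrack(entries=entries)


def validate_pair(rec: AccelRecording, track: AnnotationTrack) -> None:
    """Check that annotation times fall inside the recording extent."""
    for label, start, end in track.entries:
        if start < 0 or end > rec.duration_s + 1e-9:
            raise ValidationError(
                f"annotation ({label!r}, {start}, {end}) outside recording "
                f"extent [0, {rec.duration_s:.3f}]"
            )
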