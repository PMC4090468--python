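"""Recording I/O, line-noise suppression and window segmentation.

A :class:`Recording` is a plain (n_samples x d_channels) matrix in microvolts
with a sampling rate and a list of seizure annotations in seconds from the
start of the recording.  CSV is the canonical on-disk format (one header row
of channel names, one column per channel, sampling rate in a JSON sidecar or
passed explicitly); EDF reading is a thin adapter over :mod:`mne`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

PREICTAL = "preictal"
INTERICTAL = "interictal"
ICTAL = "ictal"
UNLABELED = "unlabeled"


class SpredictError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(SpredictError):
    pass


class ParseError(SpredictError):
    pass


class ConfigurationError(SpredictError):
    pass


@dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure: onset and offset in seconds from recording start."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValidationError(
                f"annotation must satisfy 0 <= onset < offset, got "
                f"[{self.onset_s}, {self.offset_s}]"
            )


@dataclass
class Recording:
    """Multichannel EEG time series with annotations.

    data : (n_samples, d_channels) float array, microvolts
    fs : sampling rate in Hz
    """

    data: np.ndarray
    fs: float
    channel_names: List[str] = field(default_factory=list)
    annotations: List[SeizureAnnotation] = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[1] < 2:
            raise ValidationError("a recording needs at least 2 channels")
        if not self.channel_names:
            self.channel_names = [f"ch{i+1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError("channel_names length does not match data")
        dur = self.duration_s
        prev_off = -np.inf
        for ann in self.annotations:
            if ann.onset_s < prev_off:
                raise ValidationError("annotations must be sorted and non-overlapping")
            if ann.offset_s > dur + 1e-9:
                raise ValidationError(
                    f"annotation [{ann.onset_s}, {ann.offset_s}] outside recording "
                    f"span [0, {dur:.3f}]"
                )
            prev_off = ann.offset_s

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def d_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 10 s windows, 50 % overlap by default."""

    length_s: float = 10.0
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValidationError("window length must be positive")
        if not (0 <= self.overlap_frac < 1):
            raise ValidationError("overlap fraction must lie in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.length_s * (1.0 - self.overlap_frac)


@dataclass
class Segment:
    """One analysis window cut from a recording."""

    start_s: float
    data: np.ndarray
    fs: float
    label: str = UNLABELED

    @property
    def end_s(self) -> float:
        return self.start_s + self.data.shape[0] / self.fs


def read_recording(
    path,
    format: str = "csv",
    annotations_path=None,
    fs: Optional[float] = None,
    patient_id: str = "",
) -> Recording:
    """Read a recording from CSV (canonical) or EDF.

    For CSV the sampling rate comes from ``fs`` or from a ``<path>.meta.json``
    sidecar written by :func:`write_recording`.  Annotations are a CSV with
    columns ``onset_s, offset_s``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if format == "csv":
        frame = pd.read_csv(path)
        names = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=float)
        bad = ~np.isfinite(data)
        if bad.any():
            row = int(np.argwhere(bad.any(axis=1))[0, 0])
            raise ParseError(f"non-numeric or non-finite value in data row {row} of {path}")
        if fs is None:
            sidecar = path.with_name(path.name + ".meta.json")
            if not sidecar.exists():
                raise ConfigurationError(
                    f"sampling rate not given and no sidecar {sidecar} found"
                )
            meta = json.loads(sidecar.read_text())
            fs = float(meta["fs"])
            patient_id = patient_id or meta.get("patient_id", "")
    elif format == "edf":
        import mne  # optional dependency, only needed for EDF input

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data().T * 1e6  # mne uses volts; recordings are in microvolts
        names = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    annotations: List[SeizureAnnotation] = []
    if annotations_path is not None:
        ann_frame = pd.read_csv(annotations_path)
        for _, row in ann_frame.iterrows():
            annotations.append(
                SeizureAnnotation(float(row["onset_s"]), float(row["offset_s"]))
            )
    return Recording(
        data=data, fs=float(fs), channel_names=names,
        annotations=annotations, patient_id=patient_id,
    )


def write_recording(rec: Recording, path, annotations_path=None) -> None:
    """Write recording data as CSV plus a JSON sidecar holding the rate."""
    path = Path(path)
    pd.DataFrame(rec.data, columns=rec.channel_names).to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps({"fs": rec.fs, "patient_id": rec.patient_id}))
    if annotations_path is not None:
        pd.DataFrame(
            [{"onset_s": a.onset_s, "offset_s": a.offset_s} for a in rec.annotations],
            columns=["onset_s", "offset_s"],
        ).to_csv(annotations_path, index=False)


def notch_filter(rec: Recording, f0: float = 50.0, quality: float = 30.0) -> Recording:
    """Suppress the AC line component with a zero-phase IIR notch.

    Forward-backward filtering keeps the group delay at zero so annotation
    times stay aligned with the data.
    """
    if rec.fs <= 2 * f0:
        raise ConfigurationError(
            f"sampling rate {rec.fs} Hz too low to notch at {f0} Hz"
        )
    b, a = _sig.iirnotch(f0, quality, fs=rec.fs)
    filtered = _sig.filtfilt(b, a, rec.data, axis=0)
    return replace(rec, data=filtered)


def segment_windows(
    rec: Recording,
    spec: WindowSpec = WindowSpec(),
    t0: float = 0.0,
    t1: Optional[float] = None,
) -> List[Segment]:
    """Cut [t0, t1] into overlapping windows; windows crossing t1 are dropped.

    Start times are t0, t0+step, ...; the window count equals
    floor((t1-t0-length)/step)+1 when the span fits at least one window.
    """
    if t1 is None:
        t1 = rec.duration_s
    if not (t0 < t1 <= rec.duration_s + 1e-9):
        raise ValidationError(f"need t0 < t1 <= duration, got [{t0}, {t1}]")
    length, step = spec.length_s, spec.step_s
    span = t1 - t0
    if span + 1e-9 < length:
        return []
    count = int(np.floor((span - length) / step + 1e-9)) + 1
    win_samples = int(round(length * rec.fs))
    out: List[Segment] = []
    for k in range(count):
        start = t0 + k * step
        i0 = int(round(start * rec.fs))
        out.append(Segment(start_s=start, data=rec.data[i0 : i0 + win_samples], fs=rec.fs))
    return out


def label_windows(
    segments: Sequence[Segment],
    annotations: Sequence[SeizureAnnotation],
    preictal_span_s: float,
) -> List[Segment]:
    """Assign ictal / preictal / interictal labels to windows.

    A window overlapping any [onset, offset] is ictal (ictal wins over
    preictal); a window ending within the half-open interval
    (onset - preictal_span, onset] is preictal; anything else is interictal.
    """
    if preictal_span_s <= 0:
        raise ValidationError("preictal span must be positive")
    out = []
    for seg in segments:
        s, e = seg.start_s, seg.end_s
        label = INTERICTAL
        for ann in annotations:
            if s < ann.offset_s and e > ann.onset_s:
                label = ICTAL
                break
            if ann.onset_s - preictal_span_s < e <= ann.onset_s:
                label = PREICTAL
                # keep scanning: a later annotation could still make it ictal
        out.append(replace(seg, label=label))
    return out
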