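"""HHT-ELM feature extraction.

For each window the multichannel phase matrix (one column per channel/IMF
pair) is fed to a small ELM trained for one-step phase prediction: inputs are
the phases at sample t, targets the phases at t+1.  The solved output-weight
matrix B captures how every phase column helps predict every other one —
i.e. the cross-channel phase-interaction structure — and its row-major
flattening is the feature vector of the window.

The random hidden layer is generated once per run and shared by every
window; without a common basis the output weights of different windows would
not be comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from spredict.elm import ElmParams, fit, init_hidden
from spredict.hht import window_phases
from spredict.signal_io import Segment, ValidationError


@dataclass
class FeatureVector:
    values: np.ndarray
    window_start_s: float
    label: str


@dataclass
class FeatureExtractor:
    """Per-run feature extraction context: HHT config + shared hidden layer.

    n_f = d * max_imf phase columns; the feature length is L * n_f
    (180 for the defaults d=6, max_imf=3, L=10).
    """

    d_channels: int
    max_imf: int = 3
    elm_params: ElmParams = field(default_factory=lambda: ElmParams(L=10))
    hidden: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.hidden is None:
            self.hidden = init_hidden(self.n_f, self.elm_params)

    @property
    def n_f(self) -> int:
        return self.d_channels * self.max_imf

    @property
    def n_features(self) -> int:
        return self.elm_params.L * self.n_f


def extract(segment: Segment, extractor: FeatureExtractor) -> FeatureVector:
    """One window -> flattened one-step phase-prediction output weights."""
    if segment.data.shape[0] < 2:
        raise ValidationError("window too short for one-step prediction")
    if segment.data.shape[1] != extractor.d_channels:
        raise ValidationError("segment channel count does not match extractor")
    phases = window_phases(segment, max_imf=extractor.max_imf)
    inputs = phases[:-1]
    targets = phases[1:]
    model = fit(inputs, targets, extractor.elm_params, hidden=extractor.hidden)
    return FeatureVector(
        values=model.B.ravel(order="C").copy(),
        window_start_s=segment.start_s,
        label=segment.label,
    )


def extract_batch(
    segments: Sequence[Segment],
    extractor: FeatureExtractor,
    progress: bool = False,
) -> Tuple[np.ndarray, List[str], np.ndarray]:
    """Feature matrix (one row per window, order preserved) + labels + starts."""
    if len(segments) == 0:
        raise ValidationError("cannot extract features from an empty window list")
    rows = []
    labels: List[str] = []
    starts = []
    for i, seg in enumerate(segments):
        try:
            fv = extract(seg, extractor)
        except ValidationError as exc:
            raise ValidationError(f"window {i} (t={seg.start_s:.1f} s): {exc}") from exc
        rows.append(fv.values)
        labels.append(fv.label)
        starts.append(fv.window_start_s)
        if progress and (i + 1) % 200 == 0:
            print(f"  extracted {i + 1}/{len(segments)} windows")
    return np.vstack(rows), labels, np.asarray(starts)
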