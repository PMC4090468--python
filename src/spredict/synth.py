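"""Synthetic multichannel EEG with a preictal phase-synchronization ramp.

Each channel is a noisy narrowband oscillator (6-12 Hz, plus a weaker
secondary component and 50 Hz line contamination) whose phase is pulled
toward a common reference rhythm with a time-varying coupling strength
kappa(t): weak in the interictal baseline, ramping up linearly across the
preictal period before each seizure onset, and fully locked to a
high-amplitude common 4 Hz discharge during the ictal period.  This mimics
the premise that seizures are preceded by abnormally synchronized neuronal
discharge, which is exactly what the phase-based feature extractor is built
to detect.  An optional drift mode slides the interictal oscillator
frequencies slowly over time, emulating the changing patient state that the
dynamic-update framework is meant to track.

This generator is first-class, tested code: it is the test bed standing in
for clinical recordings, not a fixture.  It does not attempt physiological
realism (no neural mass dynamics, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from spredict.signal_io import Recording, SeizureAnnotation, ValidationError

INTERICTAL_CODE = 0
PREICTAL_CODE = 1
ICTAL_CODE = 2

_LOCK_GAIN = 2.0 * np.pi * 2.0  # rad/s phase pull at full coupling


@dataclass
class SynthConfig:
    """Study conditions for one generated recording (times as noted)."""

    d: int = 6
    fs: float = 256.0
    duration_min: float = 10.0
    seizure_onsets_min: Tuple[float, ...] = ()
    preictal_ramp_min: float = 30.0
    ictal_len_s: float = 60.0
    base_freqs_hz: Optional[Tuple[float, ...]] = None  # default spread over 6-12 Hz
    coupling_inter: float = 0.05
    coupling_pre: float = 0.8
    amp: float = 10.0           # microvolt scale of the main oscillation
    line_amp: float = 2.0       # 50 Hz contamination amplitude
    noise_sd: float = 0.5       # additive white noise, microvolts
    phase_noise: float = 0.2    # rad / sqrt(s) phase diffusion
    drift_rate: float = 0.0     # Hz of frequency drift per hour (interictal)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_freqs_hz is None:
            self.base_freqs_hz = tuple(np.linspace(6.0, 12.0, self.d))
        if len(self.base_freqs_hz) != self.d:
            raise ValidationError("base_freqs_hz length must equal channel count d")
        if not (self.coupling_pre > self.coupling_inter >= 0):
            raise ValidationError("need coupling_pre > coupling_inter >= 0")
        onsets = list(self.seizure_onsets_min)
        if onsets != sorted(onsets):
            raise ValidationError("seizure onsets must be sorted")
        dur_s = self.duration_min * 60.0
        prev_off = -np.inf
        for o in onsets:
            onset_s = o * 60.0
            if onset_s + self.ictal_len_s > dur_s:
                raise ValidationError(
                    f"seizure at {o} min extends beyond the {self.duration_min} min recording"
                )
            if onset_s - self.preictal_ramp_min * 60.0 < prev_off:
                raise ValidationError(
                    "seizures too close: preictal ramp overlaps the previous seizure"
                )
            prev_off = onset_s + self.ictal_len_s


@dataclass
class SynthTruth:
    """Ground truth beside a generated recording: per-sample regime labels
    (0 interictal / 1 preictal / 2 ictal) and the realized coupling kappa(t)."""

    labels: np.ndarray
    kappa: np.ndarray


@njit(cache=True)
def _integrate(n, d, fs, freqs, f_ref, kappa, ictal, drift_hz_per_s,
               amp, line_amp, noise_sd, phase_noise, seed):
    np.random.seed(seed)
    theta = np.empty(d)
    theta2 = np.empty(d)
    for j in range(d):
        theta[j] = np.random.uniform(0.0, 2.0 * np.pi)
        theta2[j] = np.random.uniform(0.0, 2.0 * np.pi)
    theta_ref = np.random.uniform(0.0, 2.0 * np.pi)
    dt = 1.0 / fs
    sqdt = np.sqrt(dt)
    two_pi = 2.0 * np.pi
    X = np.empty((n, d))
    for t in range(n):
        drift = drift_hz_per_s * t * dt
        if ictal[t]:
            fr = 4.0
            a = 4.0 * amp
            kk = 1.0
        else:
            fr = f_ref + drift
            a = amp
            kk = kappa[t]
        theta_ref += two_pi * fr * dt
        line = line_amp * np.cos(two_pi * 50.0 * t * dt)
        for j in range(d):
            fj = 4.0 if ictal[t] else freqs[j] + drift
            omega = two_pi * ((1.0 - kk) * fj + kk * fr)
            theta[j] += (
                omega * dt
                + kk * _LOCK_GAIN * np.sin(theta_ref - theta[j]) * dt
                + phase_noise * sqdt * np.random.normal()
            )
            theta2[j] += two_pi * 2.1 * fj * dt
            X[t, j] = (
                a * np.cos(theta[j])
                + 0.3 * a * np.cos(theta2[j])
                + line
                + noise_sd * np.random.normal()
            )
    return X


def gen_recording(cfg: SynthConfig, patient_id: str = "synth") -> Tuple[Recording, SynthTruth]:
    """Generate one annotated recording; deterministic for a given seed."""
    n = int(round(cfg.duration_min * 60.0 * cfg.fs))
    fs = cfg.fs
    labels = np.zeros(n, dtype=np.int8)
    kappa = np.full(n, cfg.coupling_inter, dtype=np.float64)
    ictal = np.zeros(n, dtype=np.bool_)
    annotations: List[SeizureAnnotation] = []
    for o_min in cfg.seizure_onsets_min:
        onset = o_min * 60.0
        offset = onset + cfg.ictal_len_s
        i_on, i_off = int(round(onset * fs)), int(round(offset * fs))
        i_ramp = max(0, int(round((onset - cfg.preictal_ramp_min * 60.0) * fs)))
        ramp_len = i_on - i_ramp
        if ramp_len > 0:
            kappa[i_ramp:i_on] = cfg.coupling_inter + (
                cfg.coupling_pre - cfg.coupling_inter
            ) * np.arange(ramp_len) / ramp_len
        labels[i_ramp:i_on] = PREICTAL_CODE
        labels[i_on:i_off] = ICTAL_CODE
        ictal[i_on:i_off] = True
        annotations.append(SeizureAnnotation(onset, offset))
    freqs = np.asarray(cfg.base_freqs_hz, dtype=float)
    X = _integrate(
        n, cfg.d, fs, freqs, float(freqs.mean()), kappa, ictal,
        cfg.drift_rate / 3600.0, cfg.amp, cfg.line_amp, cfg.noise_sd,
        cfg.phase_noise, cfg.seed % (2 ** 31),
    )
    rec = Recording(
        data=X, fs=fs, annotations=annotations, patient_id=patient_id,
        channel_names=[f"ch{j+1}" for j in range(cfg.d)],
    )
    kappa[ictal] = 1.0
    return rec, SynthTruth(labels=labels, kappa=kappa.astype(np.float32))


def gen_dataset(
    cfg_template: SynthConfig,
    n_seizures: int,
    seed: int,
    lead_min: float = 40.0,
    tail_min: float = 5.0,
    interictal_min: float = 155.0,
) -> List[Tuple[Recording, SynthTruth]]:
    """A patient-scale dataset: ``n_seizures`` single-seizure recordings plus
    one seizure-free interictal recording (last element).

    Sizes guarantee the training pools can be filled: each seizure recording
    has at least 37.6 min of data immediately preceding its onset, and the
    interictal recording spans at least 150 min.
    """
    if n_seizures < 3:
        raise ValidationError("need at least 3 seizures (2 for training, 1+ to test)")
    if lead_min * 60.0 < 37.6 * 60.0:
        raise ValidationError("lead time too short to cut the preictal training span")
    if interictal_min < 150.0:
        raise ValidationError("interictal recording must span at least 150 min")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n_seizures + 1)
    out: List[Tuple[Recording, SynthTruth]] = []
    dur = lead_min + cfg_template.ictal_len_s / 60.0 + tail_min
    for k in range(n_seizures):
        cfg = replace(
            cfg_template,
            duration_min=dur,
            seizure_onsets_min=(lead_min,),
            seed=int(sub_seeds[k]),
        )
        out.append(gen_recording(cfg, patient_id=f"synth-sz{k+1}"))
    cfg_inter = replace(
        cfg_template,
        duration_min=interictal_min,
        seizure_onsets_min=(),
        seed=int(sub_seeds[-1]),
    )
    out.append(gen_recording(cfg_inter, patient_id="synth-inter"))
    return out
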