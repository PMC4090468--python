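"""Event-based evaluation: sensitivity, false-positive rate, advance time, P.

A seizure counts as predicted when at least one alarm falls inside the
prediction horizon before its onset; the advance time is measured from the
*first* such alarm, and a missed seizure contributes an advance of 0.  The
false-positive rate is false alarms per interictal hour, where interictal
time excludes the horizon-length span before each onset, the ictal period
and the postictal skip.  The group performance index combines mean
sensitivity s_e (as a fraction) and specificity s_p = 1 - mean fpr (clamped
to 0 when the mean fpr exceeds 1 per hour):

    P = sqrt((s_e^2 + s_p^2) / 2)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from spredict.predictor import FALSE_ALARM, PredictionLog
from spredict.signal_io import SeizureAnnotation, ValidationError


@dataclass
class PatientEval:
    n_seizures_tested: int
    n_predicted: int
    sensitivity_pct: float
    false_alarms: int
    interictal_hours: float
    fpr_per_h: float
    advance_min: List[float]


@dataclass
class GroupEval:
    mean_sensitivity_pct: float
    mean_fpr_per_h: float
    mean_advance_min: float
    P: float


def _union_length(spans, lo: float, hi: float) -> float:
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in spans if e > lo and s < hi
    )
    total, cur_s, cur_e = 0.0, None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def evaluate(
    log: PredictionLog,
    annotations: Sequence[SeizureAnnotation],
    H_time_min: float,
    allow_zero_interictal: bool = False,
) -> PatientEval:
    """Score one streamed recording against its seizure annotations.

    A short recording may contain no scoreable interictal time at all (the
    horizon before the onset plus ictal/postictal can cover it); that is an
    error unless ``allow_zero_interictal`` is set, in which case the fpr is
    left at 0 and only :func:`merge_evals` across recordings gives it meaning.
    """
    H_s = H_time_min * 60.0
    postictal_s = (log.config.postictal_min if log.config else 10.0) * 60.0
    advance: List[float] = []
    n_pred = 0
    for ann in annotations:
        qualifying = [
            a.time_s
            for a in log.alarms
            if ann.onset_s - H_s < a.time_s < ann.onset_s
        ]
        if qualifying:
            n_pred += 1
            advance.append((ann.onset_s - min(qualifying)) / 60.0)
        else:
            advance.append(0.0)
    false_alarms = sum(1 for a in log.alarms if a.resolved == FALSE_ALARM)
    spans = []
    for ann in annotations:
        spans.append((ann.onset_s - H_s, ann.onset_s))          # credited preictal
        spans.append((ann.onset_s, ann.offset_s + postictal_s))  # ictal + postictal
    interictal_h = (log.duration_s - _union_length(spans, 0.0, log.duration_s)) / 3600.0
    if interictal_h <= 0:
        if not allow_zero_interictal:
            raise ValidationError("recording has no interictal time to score fpr on")
        interictal_h = 0.0
    n = len(annotations)
    return PatientEval(
        n_seizures_tested=n,
        n_predicted=n_pred,
        sensitivity_pct=100.0 * n_pred / n if n else 0.0,
        false_alarms=false_alarms,
        interictal_hours=interictal_h,
        fpr_per_h=false_alarms / interictal_h if interictal_h > 0 else 0.0,
        advance_min=advance,
    )


def merge_evals(evals: Sequence[PatientEval]) -> PatientEval:
    """Combine the per-recording scores of one patient (counts are summed)."""
    if not evals:
        raise ValidationError("nothing to merge")
    n = sum(e.n_seizures_tested for e in evals)
    n_pred = sum(e.n_predicted for e in evals)
    fa = sum(e.false_alarms for e in evals)
    hours = sum(e.interictal_hours for e in evals)
    advance = [a for e in evals for a in e.advance_min]
    return PatientEval(
        n_seizures_tested=n,
        n_predicted=n_pred,
        sensitivity_pct=100.0 * n_pred / n if n else 0.0,
        false_alarms=fa,
        interictal_hours=hours,
        fpr_per_h=fa / hours if hours > 0 else 0.0,
        advance_min=advance,
    )


def performance_index(mean_sensitivity_pct: float, mean_fpr_per_h: float) -> float:
    """P = sqrt((s_e^2 + s_p^2)/2); s_p = 1 - fpr, forced to 0 when fpr > 1."""
    if not (0 <= mean_sensitivity_pct <= 100):
        raise ValidationError("sensitivity must be a percentage in [0, 100]")
    if mean_fpr_per_h < 0:
        raise ValidationError("fpr must be >= 0")
    se = mean_sensitivity_pct / 100.0
    sp = 0.0 if mean_fpr_per_h > 1.0 else 1.0 - mean_fpr_per_h
    return float(np.sqrt((se * se + sp * sp) / 2.0))


def aggregate(evals: Sequence[PatientEval]) -> GroupEval:
    """Group means over patients; advance averages over all tested seizures
    (missed ones included as 0)."""
    if not evals:
        raise ValidationError("cannot aggregate an empty evaluation list")
    mean_sens = float(np.mean([e.sensitivity_pct for e in evals]))
    mean_fpr = float(np.mean([e.fpr_per_h for e in evals]))
    all_adv = [a for e in evals for a in e.advance_min]
    mean_adv = float(np.mean(all_adv)) if all_adv else 0.0
    return GroupEval(
        mean_sensitivity_pct=mean_sens,
        mean_fpr_per_h=mean_fpr,
        mean_advance_min=mean_adv,
        P=round(performance_index(mean_sens, mean_fpr), 2),
    )
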