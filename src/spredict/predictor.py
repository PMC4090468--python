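"""Streaming seizure prediction with the dynamic sample-pool update.

The basic model slides 10 s / 50 %-overlap windows over the recording,
classifies each window's feature vector as preictal (1) or interictal (0),
and keeps a rolling buffer of decisions spanning the trailing observation
window win_os.  When the buffer is full and the preictal density
Den = N_preictal / (N_preictal + N_interictal) exceeds the threshold gamma,
an alarm is raised.  An alarm is a true positive if a seizure onset falls
within the prediction horizon H_time after it, otherwise it lapses into a
false alarm.  While an alarm is pending no new alarm is raised.

With updates enabled the state machine adds two maintenance paths:

* Condition A (false alarm): when an alarm's horizon lapses with no
  seizure, the features that filled the triggering observation window form
  the observed set S_obs; if S_obs is *not* abnormal (it genuinely looks
  interictal), the interictal pool absorbs it and the classifier is refit.
* Condition B (missed seizure): when an onset arrives with no alarm in the
  preceding H_time, the features from the span [onset - preonset_lo,
  onset - preonset_hi] refresh the preictal pool, the classifier is refit,
  and observation resumes only at ictal end + postictal + H_time.

Ictal and postictal windows are never classified, and any skip clears the
decision buffer so densities never mix non-contiguous windows.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from spredict.elm import ElmModel, ElmParams, fit, init_hidden, predict
from spredict.features import FeatureExtractor, extract
from spredict.pools import ObservedSet, SamplePool, is_abnormal, update_inter, update_pre
from spredict.signal_io import Recording, Segment, ValidationError, WindowSpec, segment_windows

PENDING = "pending"
TRUE_POSITIVE = "true_positive"
FALSE_ALARM = "false_alarm"


@dataclass
class PredictorConfig:
    """Design parameters of the prediction system (times in minutes)."""

    H_time_min: float = 110.0
    win_os_min: float = 1.5
    gamma: float = 0.7
    lam: float = 1.0
    preonset_lo_min: float = 40.0
    preonset_hi_min: float = 30.0
    postictal_min: float = 10.0
    update_enabled: bool = True
    window_s: float = 10.0
    overlap_frac: float = 0.5
    sort_order: str = "asc"

    def __post_init__(self) -> None:
        if not (0 < self.gamma < 1):
            raise ValidationError("gamma must lie in (0, 1)")
        if self.H_time_min <= self.win_os_min:
            raise ValidationError("H_time must exceed the observation window")
        if self.preonset_hi_min >= self.preonset_lo_min:
            raise ValidationError("preonset_hi must be closer to onset than preonset_lo")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_s, self.overlap_frac)

    @property
    def buffer_len(self) -> int:
        """Decisions of windows wholly inside the trailing win_os."""
        step = self.window_spec.step_s
        return int(np.floor((self.win_os_min * 60.0 - self.window_s) / step + 1e-9)) + 1


@dataclass
class AlarmEvent:
    time_s: float
    density: float
    resolved: str = PENDING


@dataclass
class PredictionLog:
    """Chronological record of one streamed recording."""

    times_s: List[float] = field(default_factory=list)
    decisions: List[int] = field(default_factory=list)
    densities: List[float] = field(default_factory=list)
    alarms: List[AlarmEvent] = field(default_factory=list)
    events: List[dict] = field(default_factory=list)  # updates / retrains / skips
    duration_s: float = 0.0
    config: Optional[PredictorConfig] = None
    final_pools: Optional[Tuple[SamplePool, SamplePool]] = None
    final_model: Optional[ElmModel] = None

    def n_false_alarms(self) -> int:
        return sum(1 for a in self.alarms if a.resolved == FALSE_ALARM)

    def n_updates(self, kind: Optional[str] = None) -> int:
        return sum(
            1
            for e in self.events
            if e["kind"].startswith("update") and (kind is None or e["kind"] == kind)
        )


def train(
    pre: SamplePool,
    inter: SamplePool,
    clf_params: ElmParams,
    hidden: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> ElmModel:
    """Fit the preictal/interictal classifier on the pooled features.

    Targets are 1 for preictal-pool samples and 0 for interictal-pool ones.
    """
    if pre.n == 0 or inter.n == 0:
        raise ValidationError("both sample pools must be non-empty")
    S = np.vstack([pre.features, inter.features])
    O = np.concatenate([np.ones(pre.n), np.zeros(inter.n)])
    return fit(S, O, clf_params, hidden=hidden)


def classify(model: ElmModel, f: np.ndarray) -> int:
    """1 iff the raw network output exceeds 0.5 (strict)."""
    raw = float(predict(model, np.atleast_2d(np.asarray(f, dtype=float)))[0, 0])
    return 1 if raw > 0.5 else 0


def preictal_density(decisions: Sequence[int]) -> float:
    """Fraction of preictal decisions in the observation window (Den)."""
    if len(decisions) == 0:
        raise ValidationError("cannot compute a density from no decisions")
    return float(np.mean(np.asarray(decisions, dtype=float)))


def step_alarm(den: float, gamma: float) -> bool:
    """Alarm iff Den strictly exceeds the density threshold."""
    return den > gamma


def _overlaps_excluded(start: float, end: float, spans: Sequence[Tuple[float, float]]) -> bool:
    return any(start < e and end > s for s, e in spans)


def process_stream(
    rec: Recording,
    cfg: PredictorConfig,
    pre_pool: SamplePool,
    inter_pool: SamplePool,
    model: ElmModel,
    extractor: Optional[FeatureExtractor] = None,
    features: Optional[np.ndarray] = None,
    clf_params: Optional[ElmParams] = None,
    decision_fn: Optional[Callable[[int, Segment], int]] = None,
) -> PredictionLog:
    """Stream one recording through the predictor.

    ``features`` may carry precomputed per-window feature rows (aligned with
    the window grid over the full recording); otherwise ``extractor`` is used
    on the fly.  ``decision_fn(window_index, segment) -> {0,1}`` overrides the
    classifier, which lets tests script exact decision sequences.
    Returns the full prediction log; the (possibly updated) pools and model
    are attached to it.
    """
    windows = segment_windows(rec, cfg.window_spec)
    if not windows:
        raise ValidationError("recording shorter than one analysis window")
    if decision_fn is None and features is None and extractor is None:
        raise ValidationError("need features, an extractor, or a scripted decision_fn")
    if clf_params is None:
        clf_params = ElmParams(L=model.L, seed=0, ridge=1e-6)
    clf_hidden = (model.W, model.b)

    H_s = cfg.H_time_min * 60.0
    excluded = []  # ictal + postictal spans, never classified
    for ann in rec.annotations:
        excluded.append((ann.onset_s, ann.offset_s + cfg.postictal_min * 60.0))

    log = PredictionLog(duration_s=rec.duration_s, config=cfg)
    buffer: deque = deque(maxlen=cfg.buffer_len)
    buffer_windows: deque = deque(maxlen=cfg.buffer_len)  # window indices in buffer
    feat_cache: dict = {}
    pending: Optional[AlarmEvent] = None
    pending_obs: Optional[np.ndarray] = None
    resume_t = 0.0
    onsets = [(a.onset_s, a.offset_s) for a in rec.annotations]
    next_onset = 0

    def feature_row(i: int) -> np.ndarray:
        if features is not None:
            return features[i]
        if i not in feat_cache:
            feat_cache[i] = extract(windows[i], extractor).values
        return feat_cache[i]

    def retrain(now: float) -> None:
        nonlocal model
        model = train(pre_pool, inter_pool, clf_params, hidden=clf_hidden)
        log.events.append({"time_s": now, "kind": "retrain"})

    def lapse_false_alarm(now: float, at_stream_end: bool = False) -> None:
        nonlocal pending, pending_obs, pre_pool, inter_pool
        pending.resolved = FALSE_ALARM
        if cfg.update_enabled and not at_stream_end and pending_obs is not None:
            obs = ObservedSet(pending_obs, source="false_alarm_window")
            if not is_abnormal(obs, pre_pool, inter_pool, cfg.lam):
                inter_pool = update_inter(inter_pool, obs, pre_pool, cfg.sort_order)
                log.events.append(
                    {"time_s": now, "kind": "update_inter", "n_obs": obs.n}
                )
                retrain(now)
        pending, pending_obs = None, None

    def handle_onset(onset: float, offset: float, now: float) -> None:
        nonlocal pending, pending_obs, pre_pool, inter_pool, resume_t
        predicted = False
        if pending is not None and onset > pending.time_s:
            pending.resolved = TRUE_POSITIVE
            pending, pending_obs = None, None
            predicted = True
        else:
            # any earlier alarm still within its horizon would have been pending
            predicted = any(
                a.resolved == TRUE_POSITIVE and 0.0 < onset - a.time_s <= H_s
                for a in log.alarms
            )
        if predicted:
            # seizure in progress: no classification until after the postictal skip
            resume_t = max(resume_t, offset + cfg.postictal_min * 60.0)
        elif not cfg.update_enabled:
            # basic static model: a missed seizure only skips ictal+postictal
            resume_t = max(resume_t, offset + cfg.postictal_min * 60.0)
        else:
            if features is not None or extractor is not None:
                lo = onset - cfg.preonset_lo_min * 60.0
                hi = onset - cfg.preonset_hi_min * 60.0
                obs_idx = [
                    i
                    for i, w in enumerate(windows)
                    if w.start_s >= lo - 1e-9 and w.end_s <= hi + 1e-9
                ]
                if obs_idx:
                    obs = ObservedSet(
                        np.vstack([feature_row(i) for i in obs_idx]),
                        source="pre_onset_span",
                    )
                    pre_pool = update_pre(pre_pool, obs, inter_pool, cfg.sort_order)
                    log.events.append(
                        {"time_s": now, "kind": "update_pre", "n_obs": obs.n}
                    )
                    retrain(now)
            # Condition B: resume observation only after ictal + postictal + horizon
            resume_t = max(resume_t, offset + cfg.postictal_min * 60.0 + H_s)
            log.events.append({"time_s": now, "kind": "resume_at", "resume_s": resume_t})

    for i, w in enumerate(windows):
        now = w.end_s
        # timeline events preceding this window, in time order (an onset at
        # exactly the lapse instant wins: the horizon is the half-open (a, a+H])
        while True:
            t_on = onsets[next_onset][0] if next_onset < len(onsets) else np.inf
            t_lapse = pending.time_s + H_s if pending is not None else np.inf
            if t_on <= now and t_on <= t_lapse:
                handle_onset(*onsets[next_onset], now=t_on)
                next_onset += 1
            elif pending is not None and t_lapse < now and t_lapse < t_on:
                lapse_false_alarm(t_lapse)
            else:
                break

        if now < resume_t or _overlaps_excluded(w.start_s, now, excluded):
            if buffer:
                buffer.clear()
                buffer_windows.clear()
            continue

        if decision_fn is not None:
            dec = int(decision_fn(i, w))
        else:
            dec = classify(model, feature_row(i))
        buffer.append(dec)
        buffer_windows.append(i)
        den = preictal_density(list(buffer)) if len(buffer) == cfg.buffer_len else float("nan")
        log.times_s.append(now)
        log.decisions.append(dec)
        log.densities.append(den)
        if (
            len(buffer) == cfg.buffer_len
            and pending is None
            and step_alarm(den, cfg.gamma)
        ):
            pending = AlarmEvent(time_s=now, density=den)
            log.alarms.append(pending)
            if features is not None or extractor is not None:
                pending_obs = np.vstack([feature_row(j) for j in buffer_windows])
            else:
                pending_obs = None

    # end of stream: resolve anything still open
    end = rec.duration_s
    while next_onset < len(onsets) and onsets[next_onset][0] <= end + 1e-9:
        handle_onset(*onsets[next_onset], now=onsets[next_onset][0])
        next_onset += 1
    if pending is not None:
        lapse = pending.time_s + H_s
        lapse_false_alarm(min(lapse, end), at_stream_end=lapse > end)

    log.final_pools = (pre_pool, inter_pool)
    log.final_model = model
    return log
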