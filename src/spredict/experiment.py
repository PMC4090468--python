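"""Wiring for whole-study runs on synthetic data.

This is the desk-scale analogue of a per-patient evaluation: the first two
seizures fill the preictal pool (450 windows each, 10 s / 50 % overlap from
the 37.6 min before onset), 150 min of interictal recording fills the
interictal pool (900 non-overlapping windows), a classifier is trained, and
the remaining seizure recordings plus a fresh interictal recording are
streamed — with and/or without the dynamic pool update — and scored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from spredict.elm import ElmModel, ElmParams, init_hidden
from spredict.features import FeatureExtractor, extract_batch
from spredict.metrics import PatientEval, evaluate, merge_evals
from spredict.pools import SamplePool
from spredict.predictor import PredictionLog, PredictorConfig, process_stream, train
from spredict.signal_io import (
    PREICTAL,
    INTERICTAL,
    Recording,
    WindowSpec,
    notch_filter,
    segment_windows,
)
from spredict.synth import SynthConfig, gen_dataset, gen_recording

PREICTAL_TRAIN_SPAN_S = 37.6 * 60.0  # yields 450 windows at 10 s / 50 %
INTER_POOL_SPAN_S = 150.0 * 60.0     # yields 900 windows at 10 s / 0 %
FEATURE_ELM_L = 10
CLASSIFIER_ELM_L = 1000
CLASSIFIER_RIDGE = 1e-6


def build_pools(
    train_recs: Sequence[Recording],
    inter_rec: Recording,
    extractor: FeatureExtractor,
    window_s: float = 10.0,
) -> Tuple[SamplePool, SamplePool]:
    """Fill S_pre from the span before each training onset and S_inter from
    the interictal recording; capacities equal the initial fill."""
    pre_rows = []
    for rec in train_recs:
        onset = rec.annotations[0].onset_s
        segs = segment_windows(
            rec, WindowSpec(window_s, 0.5), onset - PREICTAL_TRAIN_SPAN_S, onset
        )
        for s in segs:
            s.label = PREICTAL
        F, _, _ = extract_batch(segs, extractor)
        pre_rows.append(F)
    pre_feats = np.vstack(pre_rows)
    span = min(INTER_POOL_SPAN_S, inter_rec.duration_s)
    segs = segment_windows(inter_rec, WindowSpec(window_s, 0.0), 0.0, span)
    for s in segs:
        s.label = INTERICTAL
    inter_feats, _, _ = extract_batch(segs, extractor)
    pre = SamplePool(pre_feats, capacity=pre_feats.shape[0], role="pre")
    inter = SamplePool(inter_feats, capacity=inter_feats.shape[0], role="inter")
    return pre, inter


@dataclass
class StudyContext:
    """Everything needed to stream the test set under either arm."""

    extractor: FeatureExtractor
    pre_pool: SamplePool
    inter_pool: SamplePool
    model: ElmModel
    clf_params: ElmParams
    test_recs: List[Recording]
    test_features: List[np.ndarray]


def prepare_study(
    seed: int,
    n_seizures: int = 5,
    n_train: int = 2,
    test_inter_min: float = 60.0,
    synth_cfg: Optional[SynthConfig] = None,
) -> StudyContext:
    """Generate data, build pools, train the classifier, pre-extract test
    features (shared by the update and no-update arms)."""
    base = synth_cfg if synth_cfg is not None else SynthConfig(seed=seed)
    data = gen_dataset(base, n_seizures, seed)
    recs = [notch_filter(r) for r, _ in data]
    train_recs = recs[:n_train]
    test_recs = recs[n_train:n_seizures]
    inter_rec = recs[-1]
    if test_inter_min > 0:
        rng = np.random.default_rng([seed, 17])
        cfg_ti = replace(
            base,
            duration_min=test_inter_min,
            seizure_onsets_min=(),
            seed=int(rng.integers(2 ** 31)),
        )
        ti, _ = gen_recording(cfg_ti, patient_id="synth-test-inter")
        test_recs = test_recs + [notch_filter(ti)]

    extractor = FeatureExtractor(
        d_channels=base.d, max_imf=3, elm_params=ElmParams(L=FEATURE_ELM_L, seed=seed)
    )
    pre_pool, inter_pool = build_pools(train_recs, inter_rec, extractor)
    clf_params = ElmParams(L=CLASSIFIER_ELM_L, seed=seed + 1, ridge=CLASSIFIER_RIDGE)
    hidden = init_hidden(extractor.n_features, clf_params)
    model = train(pre_pool, inter_pool, clf_params, hidden=hidden)

    test_features = []
    for rec in test_recs:
        segs = segment_windows(rec, WindowSpec(10.0, 0.5))
        F, _, _ = extract_batch(segs, extractor)
        test_features.append(F)
    return StudyContext(
        extractor=extractor,
        pre_pool=pre_pool,
        inter_pool=inter_pool,
        model=model,
        clf_params=clf_params,
        test_recs=test_recs,
        test_features=test_features,
    )


def run_arm(
    ctx: StudyContext, cfg: PredictorConfig
) -> Tuple[PatientEval, List[PredictionLog]]:
    """Stream every test recording in order, carrying pools and model across
    recordings when updates are enabled; score and merge."""
    pre, inter, model = ctx.pre_pool, ctx.inter_pool, ctx.model
    logs: List[PredictionLog] = []
    evals: List[PatientEval] = []
    for rec, F in zip(ctx.test_recs, ctx.test_features):
        log = process_stream(
            rec, cfg, pre, inter, model, features=F, clf_params=ctx.clf_params
        )
        logs.append(log)
        evals.append(
            evaluate(log, rec.annotations, cfg.H_time_min, allow_zero_interictal=True)
        )
        if cfg.update_enabled:
            pre, inter = log.final_pools
            model = log.final_model
    return merge_evals(evals), logs


def run_study(
    seed: int,
    n_seizures: int = 5,
    arms: Sequence[str] = ("update", "no_update"),
    **prepare_kwargs,
) -> Dict[str, Tuple[PatientEval, List[PredictionLog]]]:
    """End-to-end synthetic study; returns per-arm merged evaluations."""
    ctx = prepare_study(seed, n_seizures=n_seizures, **prepare_kwargs)
    out = {}
    for arm in arms:
        cfg = PredictorConfig(update_enabled=(arm == "update"))
        out[arm] = run_arm(ctx, cfg)
    return out


def run_drift_comparison(
    seed: int,
    drift_rate_hz_per_h: float = 2.0,
    stream_min: float = 90.0,
    train_lead_min: float = 40.0,
    inter_pool_min: float = 75.0,
    H_time_min: float = 15.0,
) -> Dict[str, int]:
    """False-alarm counts with vs without updates on drifting interictal EEG.

    A reduced-scale study: one training seizure + a shorter interictal pool,
    then a seizure-free stream whose oscillator frequencies drift away from
    the training conditions.  The prediction horizon is shortened so that a
    false alarm can lapse — and trigger a Condition-A update — several times
    within the desk-scale stream.  Returns ``{"update": n_fa, "no_update": n_fa}``.
    """
    base = SynthConfig(seed=seed)
    rng = np.random.default_rng([seed, 29])
    sub = [int(s) for s in rng.integers(2 ** 31, size=3)]
    cfg_sz = replace(
        base,
        duration_min=train_lead_min + base.ictal_len_s / 60.0 + 2.0,
        seizure_onsets_min=(train_lead_min,),
        seed=sub[0],
    )
    cfg_in = replace(base, duration_min=inter_pool_min, seizure_onsets_min=(), seed=sub[1])
    cfg_stream = replace(
        base,
        duration_min=stream_min,
        seizure_onsets_min=(),
        drift_rate=drift_rate_hz_per_h,
        seed=sub[2],
    )
    rec_sz = notch_filter(gen_recording(cfg_sz)[0])
    rec_in = notch_filter(gen_recording(cfg_in)[0])
    rec_stream = notch_filter(gen_recording(cfg_stream)[0])

    extractor = FeatureExtractor(
        d_channels=base.d, max_imf=3, elm_params=ElmParams(L=FEATURE_ELM_L, seed=seed)
    )
    pre, inter = build_pools([rec_sz], rec_in, extractor)
    clf_params = ElmParams(L=CLASSIFIER_ELM_L, seed=seed + 1, ridge=CLASSIFIER_RIDGE)
    hidden = init_hidden(extractor.n_features, clf_params)
    model = train(pre, inter, clf_params, hidden=hidden)

    segs = segment_windows(rec_stream, WindowSpec(10.0, 0.5))
    F, _, _ = extract_batch(segs, extractor)
    out = {}
    for arm, enabled in (("update", True), ("no_update", False)):
        cfg = PredictorConfig(update_enabled=enabled, H_time_min=H_time_min)
        log = process_stream(
            rec_stream, cfg, pre, inter, model, features=F, clf_params=clf_params
        )
        out[arm] = log.n_false_alarms()
    return out
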