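import numpy as np
import pytest

from spredict.elm import ElmParams, init_hidden, predict
from spredict.pools import SamplePool
from spredict.predictor import (
    FALSE_ALARM,
    TRUE_POSITIVE,
    PredictorConfig,
    classify,
    preictal_density,
    process_stream,
    step_alarm,
    train,
)
from spredict.signal_io import Recording, SeizureAnnotation, ValidationError
from conftest import make_recording

CFG_FAST = dict(window_s=10.0, overlap_frac=0.5)


def make_pools(rng, p=4, n=20, sep=5.0):
    pre = SamplePool(rng.normal(sep, 1.0, (n, p)), capacity=n, role="pre")
    inter = SamplePool(rng.normal(-sep, 1.0, (n, p)), capacity=n, role="inter")
    return pre, inter


def scripted(decisions):
    """decision_fn replaying a fixed 0/1 sequence, 0 beyond its end."""

    def fn(i, seg):
        return decisions[i] if i < len(decisions) else 0

    return fn


class TestTrainClassify:
    def test_separable_pools_high_training_accuracy(self, rng):
        pre, inter = make_pools(rng)
        model = train(pre, inter, ElmParams(L=100, seed=0, ridge=1e-6))
        X = np.vstack([pre.features, inter.features])
        y = np.concatenate([np.ones(pre.n), np.zeros(inter.n)])
        pred = (predict(model, X)[:, 0] > 0.5).astype(float)
        assert np.mean(pred == y) >= 0.95

    def test_label_swap_inverts_decisions(self, rng):
        pre, inter = make_pools(rng)
        p = ElmParams(L=50, seed=1, ridge=1e-6)
        hidden = init_hidden(4, p)
        m1 = train(pre, inter, p, hidden=hidden)
        m2 = train(
            SamplePool(inter.features, capacity=inter.n, role="pre"),
            SamplePool(pre.features, capacity=pre.n, role="inter"),
            p,
            hidden=hidden,
        )
        X = np.vstack([pre.features, inter.features])
        acc1 = np.mean((predict(m1, X)[:, 0] > 0.5) == (np.arange(len(X)) < pre.n))
        acc2 = np.mean((predict(m2, X)[:, 0] > 0.5) == (np.arange(len(X)) < pre.n))
        assert acc2 == pytest.approx(1.0 - acc1, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        pre, inter = make_pools(rng)
        p = ElmParams(L=20, seed=3, ridge=1e-6)
        np.testing.assert_array_equal(
            train(pre, inter, p).B, train(pre, inter, p).B
        )

    def test_classify_threshold(self):
        from spredict.elm import ElmModel

        # single neuron with zero weights: raw output = 0.5 * B
        m = ElmModel(W=np.zeros((1, 2)), b=np.zeros(1), B=np.array([[1.8]]))
        assert classify(m, [0.0, 0.0]) == 1  # raw 0.9
        m.B = np.array([[0.2]])
        assert classify(m, [0.0, 0.0]) == 0  # raw 0.1
        m.B = np.array([[1.0]])
        assert classify(m, [0.0, 0.0]) == 0  # raw exactly 0.5: strict >


class TestDensityAndAlarm:
    def test_density_fraction(self):
        assert preictal_density([1, 1, 1, 1, 1, 1, 1, 0, 0]) == pytest.approx(7 / 9)

    def test_density_extremes(self):
        assert preictal_density([0, 0, 0]) == 0.0
        assert preictal_density([1, 1]) == 1.0

    def test_density_empty_rejected(self):
        with pytest.raises(ValidationError):
            preictal_density([])

    def test_step_alarm_strict_threshold(self):
        assert step_alarm(0.778, 0.7)
        assert not step_alarm(0.7, 0.7)
        assert step_alarm(0.1, 0.0)


class TestStream:
    """Scripted-classifier traces of the alarm state machine."""

    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.pre, self.inter = make_pools(self.rng)
        self.clf = ElmParams(L=20, seed=1, ridge=1e-6)
        self.model = train(self.pre, self.inter, self.clf)
        # win_os=1.5 min, 10 s / 50% windows -> buffer of 17 decisions
        self.cfg = PredictorConfig(update_enabled=False)

    def _stream(self, rec, decisions, cfg=None, **kw):
        return process_stream(
            rec,
            cfg or self.cfg,
            self.pre,
            self.inter,
            self.model,
            clf_params=self.clf,
            decision_fn=scripted(decisions),
            **kw,
        )

    def test_buffer_length_is_17(self):
        assert self.cfg.buffer_len == 17

    def test_hand_traced_single_alarm(self):
        """17 consecutive preictal decisions then zeros: exactly one alarm,
        at the end of the 17th window (t = 90 s), density 1."""
        rec = make_recording(1200.0, onsets_s=())
        log = self._stream(rec, [1] * 17 + [0] * 300)
        assert len(log.alarms) == 1
        assert log.alarms[0].time_s == pytest.approx(90.0)
        assert log.alarms[0].density == pytest.approx(1.0)

    def test_alarm_waits_for_full_buffer(self):
        """No alarm can fire before 17 decisions accumulated: a recording
        with room for only 16 windows never alarms, even on all-preictal
        decisions."""
        rec = make_recording(85.0)  # 16 windows at 10 s / 50 %
        log = self._stream(rec, [1] * 16)
        assert len(log.times_s) == 16
        assert log.alarms == []

    def test_density_threshold_trace(self):
        """12/17 ones (density 0.706 > 0.7) alarms; 11/17 does not."""
        rec = make_recording(1200.0)
        log = self._stream(rec, [1] * 12 + [0] * 300)
        assert len(log.alarms) == 1
        assert log.alarms[0].time_s == pytest.approx(90.0)
        assert log.alarms[0].density == pytest.approx(12 / 17)
        log2 = self._stream(rec, [1] * 11 + [0] * 300)
        assert log2.alarms == []

    def test_refractory_until_resolution(self):
        """A pending alarm suppresses new alarms until its horizon lapses."""
        cfg = PredictorConfig(update_enabled=False, H_time_min=5.0)
        rec = make_recording(3600.0)
        log = self._stream(rec, [1] * 400, cfg=cfg)
        # first alarm at 90 s; next possible only after 90+300 s horizon
        assert len(log.alarms) >= 2
        assert log.alarms[0].time_s == pytest.approx(90.0)
        assert log.alarms[1].time_s - log.alarms[0].time_s > 300.0 - 1e-9
        assert all(a.resolved == FALSE_ALARM for a in log.alarms[:-1])

    def test_no_seizure_all_zero_no_alarms_no_updates(self):
        rec = make_recording(1800.0)
        cfg = PredictorConfig(update_enabled=True)
        log = self._stream(rec, [0] * 400, cfg=cfg)
        assert log.alarms == [] and log.events == []

    def test_true_positive_resolution(self):
        """Alarm followed by an onset inside the horizon is a true positive."""
        rec = make_recording(3600.0, onsets_s=(1800.0,))
        log = self._stream(rec, [1] * 17 + [0] * 1000)
        assert len(log.alarms) == 1
        assert log.alarms[0].resolved == TRUE_POSITIVE

    def test_ictal_windows_never_classified(self):
        rec = make_recording(3600.0, onsets_s=(600.0,), ictal_len_s=30.0)
        log = self._stream(rec, [0] * 1000)
        post_end = 630.0 + self.cfg.postictal_min * 60.0
        for t in log.times_s:
            assert not (600.0 < t <= post_end + 10.0 - 1e-9)

    def test_every_alarm_resolved(self):
        rec = make_recording(3600.0, onsets_s=(1800.0,))
        log = self._stream(rec, ([1] * 17 + [0] * 40) * 12)
        assert log.alarms and all(a.resolved != "pending" for a in log.alarms)


class TestConditions:
    """Condition A (false alarm -> interictal update) and Condition B
    (missed seizure -> preictal update) event traces."""

    def _setup(self, seed=0, p=6):
        rng = np.random.default_rng(seed)
        pre = SamplePool(rng.normal(5.0, 1.0, (20, p)), capacity=20, role="pre")
        inter = SamplePool(rng.normal(-5.0, 1.0, (20, p)), capacity=20, role="inter")
        clf = ElmParams(L=20, seed=1, ridge=1e-6)
        model = train(pre, inter, clf)
        return rng, pre, inter, clf, model

    def test_condition_a_updates_interictal_pool(self):
        """A lapsed false alarm whose windows look interictal triggers
        exactly one update_inter and one retrain."""
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(update_enabled=True, H_time_min=5.0)
        rec = make_recording(3600.0)
        n_windows = 718
        F = np.tile(rng.normal(-5.0, 1.0, (1, 6)), (n_windows, 1))
        decisions = [1] * 17 + [0] * 1000
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted(decisions),
        )
        assert [a.resolved for a in log.alarms] == [FALSE_ALARM]
        kinds = [e["kind"] for e in log.events]
        assert kinds.count("update_inter") == 1 and kinds.count("retrain") == 1
        # the lapse (and hence the update) happens one horizon after the alarm
        assert log.events[0]["time_s"] == pytest.approx(90.0 + 300.0)

    def test_condition_a_abnormal_set_is_discarded(self):
        """Preictal-looking windows behind a false alarm must NOT enter the
        interictal pool."""
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(update_enabled=True, H_time_min=5.0)
        rec = make_recording(3600.0)
        F = np.tile(rng.normal(5.0, 1.0, (1, 6)), (719, 1))  # preictal-like
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted([1] * 17 + [0] * 1000),
        )
        assert [a.resolved for a in log.alarms] == [FALSE_ALARM]
        assert log.events == []

    def test_condition_b_missed_seizure_trace(self):
        """One unalarmed onset: exactly one update_pre + retrain, and
        classification resumes only at ictal end + postictal + H_time."""
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(
            update_enabled=True,
            H_time_min=20.0,
            preonset_lo_min=10.0,
            preonset_hi_min=5.0,
            postictal_min=10.0,
        )
        onset, ictal_len = 3000.0, 30.0
        rec = make_recording(7200.0, onsets_s=(onset,), ictal_len_s=ictal_len)
        F = rng.normal(-5.0, 1.0, (1439, 6))
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted([0] * 2000),
        )
        kinds = [e["kind"] for e in log.events]
        assert kinds.count("update_pre") == 1 and kinds.count("retrain") == 1
        resume = onset + ictal_len + 10.0 * 60.0 + 20.0 * 60.0
        classified_after = [t for t in log.times_s if t > onset]
        assert min(classified_after) >= resume
        # the observed set spans [onset-10 min, onset-5 min]: 55 windows at 5 s step
        upd = next(e for e in log.events if e["kind"] == "update_pre")
        assert upd["n_obs"] == 59

    def test_predicted_seizure_triggers_no_update(self):
        rng, pre, inter, clf, model = self._setup()
        # horizon long enough that the early alarm still covers the onset
        cfg = PredictorConfig(update_enabled=True, H_time_min=40.0)
        rec = make_recording(3600.0, onsets_s=(1800.0,))
        F = np.tile(rng.normal(-5.0, 1.0, (1, 6)), (719, 1))
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted([1] * 17 + [0] * 1000),
        )
        assert log.alarms[0].resolved == TRUE_POSITIVE
        assert log.events == []

    def test_no_update_mode_keeps_pools_and_model(self):
        """With updates disabled the stream reduces to the static model."""
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(update_enabled=False, H_time_min=5.0)
        rec = make_recording(3600.0, onsets_s=(3000.0,))
        F = np.tile(rng.normal(-5.0, 1.0, (1, 718 * 6)).reshape(718, 6)[:1], (719, 1))
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted([1] * 17 + [0] * 1000),
        )
        assert log.events == []
        assert log.final_pools[0] is pre and log.final_pools[1] is inter
        assert log.final_model is model

    def test_updates_always_have_a_trigger(self):
        """Every pool update in the log is preceded by a lapsed false alarm
        (update_inter) or a missed onset (update_pre)."""
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(
            update_enabled=True, H_time_min=5.0,
            preonset_lo_min=4.0, preonset_hi_min=2.0, postictal_min=1.0,
        )
        rec = make_recording(7200.0, onsets_s=(5000.0,), ictal_len_s=30.0)
        F = rng.normal(-5.0, 1.0, (1439, 6))
        decisions = ([1] * 17 + [0] * 60) * 20
        log = process_stream(
            rec, cfg, pre, inter, model,
            features=F, clf_params=clf, decision_fn=scripted(decisions),
        )
        n_fa = sum(1 for a in log.alarms if a.resolved == FALSE_ALARM)
        missed = 0 if any(a.resolved == TRUE_POSITIVE for a in log.alarms) else 1
        assert log.n_updates("update_inter") <= n_fa
        assert log.n_updates("update_pre") <= missed

    def test_determinism_full_rerun(self):
        rng, pre, inter, clf, model = self._setup()
        cfg = PredictorConfig(update_enabled=True, H_time_min=5.0)
        rec = make_recording(3600.0)
        F = np.random.default_rng(9).normal(-5, 1, (719, 6))
        kw = dict(features=F, clf_params=clf, decision_fn=scripted([1] * 30 + [0] * 1000))
        log1 = process_stream(rec, cfg, pre, inter, model, **kw)
        log2 = process_stream(rec, cfg, pre, inter, model, **kw)
        assert log1.times_s == log2.times_s
        assert log1.decisions == log2.decisions
        assert [a.time_s for a in log1.alarms] == [a.time_s for a in log2.alarms]
        assert log1.events == log2.events

    def test_too_short_recording_rejected(self):
        rng, pre, inter, clf, model = self._setup()
        rec = make_recording(5.0)
        with pytest.raises(ValidationError):
            process_stream(rec, PredictorConfig(), pre, inter, model,
                           decision_fn=scripted([0]))
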