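"""Event detection: windowing, classifiers, threshold, interval rebuild."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import somnoflow as sf
from somnoflow import respiratory as resp
from somnoflow import synthetic as syn
from somnoflow.events import (
    EventInterval,
    WINDOW_COVER_S,
    make_windows,
    scores_to_events,
    select_threshold,
    train_event_cnn,
    train_event_rf,
)
from somnoflow.evaluation import prepare_subject_features, roc_auc
from somnoflow.motion import FlowSequence


def _zero_flow(n_fields, h=4, w=4):
    return FlowSequence(np.zeros((n_fields, h, w, 2), np.float32), rate=2.0)


class TestMakeWindows:
    def test_19_frames_give_one_window_of_18_fields(self):
        windows = make_windows(_zero_flow(18), mode="test")
        assert len(windows) == 1
        assert windows[0].flow_stack.shape[0] == 18

    def test_60s_event_yields_101_event_windows(self):
        windows = make_windows(
            _zero_flow(239), [EventInterval(0.0, 60.0, "apnea")], "train"
        )
        ev = [w for w in windows if w.label == "event"]
        assert len(ev) == 101
        assert ev[0].start_time == 0.0
        assert ev[-1].start_time == 50.0

    def test_normal_stride_15s_without_events(self):
        windows = make_windows(_zero_flow(599), [], "train")
        assert [w.start_time for w in windows] == [float(s) for s in range(0, 290, 15)]
        assert all(w.label == "normal" for w in windows)

    def test_straddling_windows_discarded(self):
        ev = [EventInterval(30.0, 60.0, "apnea")]
        windows = make_windows(_zero_flow(239), ev, "train")
        for w in windows:
            t0, t1 = w.start_time, w.start_time + WINDOW_COVER_S
            if w.label == "event":
                assert t0 >= 30.0 and t1 < 60.0
            else:
                assert t1 <= 30.0 or t0 >= 60.0

    def test_short_recording_warns(self):
        with pytest.warns(UserWarning):
            assert make_windows(_zero_flow(10), mode="test") == []


class TestSelectThreshold:
    def test_perfect_separation_returns_gap_midpoint(self):
        thr = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)

    def test_published_fallback_default(self):
        with pytest.warns(UserWarning):
            thr = select_threshold([0.4, 0.4, 0.4], [0, 1, 1])
        assert thr == 0.1

    def test_matches_exhaustive_cutpoint_sweep(self):
        rng = np.random.default_rng(3)
        scores = rng.random(300)
        y = rng.random(300) < 0.3
        uniq = np.unique(scores)
        cands = (uniq[:-1] + uniq[1:]) / 2
        best_j, best_c = -np.inf, None
        for c in cands:
            pred = scores >= c
            j = (pred & y).sum() / y.sum() - (pred & ~y).sum() / (~y).sum()
            if j > best_j:
                best_j, best_c = j, c
        assert select_threshold(scores, y) == pytest.approx(best_c)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            select_threshold([0.1, 0.9], [1, 1])


class TestScoresToEvents:
    def test_all_below_threshold_gives_no_events(self):
        assert scores_to_events(np.full(50, 0.05), threshold=0.1) == []

    def test_isolated_positive_window_covers_9_5_s(self):
        scores = np.zeros(50)
        scores[10] = 0.9
        ev = scores_to_events(scores, threshold=0.5)
        assert len(ev) == 1
        assert (ev[0].start_s, ev[0].end_s) == (5.0, 14.5)

    def test_adjacent_positives_merge_by_cover_union(self):
        scores = np.zeros(60)
        scores[[20, 21, 22]] = 1.0  # starts 10.0, 10.5, 11.0
        ev = scores_to_events(scores, threshold=0.5, merge_gap_s=0.0)
        assert len(ev) == 1
        assert (ev[0].start_s, ev[0].end_s) == (10.0, 20.5)

    def test_matches_brute_force_cover_union(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        thr = 0.8
        got = scores_to_events(scores, threshold=thr)
        # oracle: mark half-second ticks covered by any positive window
        ticks = np.zeros(2 * 200 + 19, bool)
        for i in np.flatnonzero(scores >= thr):
            ticks[i : i + 19] = True  # 9.5 s = 19 half-second ticks
        intervals = []
        in_run = False
        for j, v in enumerate(ticks):
            if v and not in_run:
                start, in_run = j, True
            if not v and in_run:
                intervals.append((start / 2.0, j / 2.0))
                in_run = False
        if in_run:
            intervals.append((start / 2.0, len(ticks) / 2.0))
        assert [(e.start_s, e.end_s) for e in got] == intervals

    def test_min_duration_filter(self):
        scores = np.zeros(100)
        scores[10] = 1.0
        assert scores_to_events(scores, threshold=0.5, min_duration_s=9.5) == []
        assert len(scores_to_events(scores, threshold=0.5, min_duration_s=9.0)) == 1

    @given(st.lists(st.floats(0, 1), min_size=20, max_size=60),
           st.floats(0.05, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity_and_idempotence(self, scores, thr):
        scores = np.asarray(scores)
        lo = scores_to_events(scores, threshold=max(thr - 0.05, 0.0))
        hi = scores_to_events(scores, threshold=thr)
        assert sum(e.duration_s for e in lo) >= sum(e.duration_s for e in hi)
        # idempotence: rebuilding from the indicator of the output intervals
        # returns the same intervals
        indicator = np.zeros_like(scores)
        for e in hi:
            i0 = int(round(e.start_s * 2))
            i1 = int(round((e.end_s - WINDOW_COVER_S) * 2))
            indicator[i0 : i1 + 1] = 1.0
        again = scores_to_events(indicator, threshold=0.5)
        assert [(e.start_s, e.end_s) for e in again] == [
            (e.start_s, e.end_s) for e in hi
        ]


class TestRandomForestDetector:
    def test_default_tree_count_is_50(self, small_subject):
        rec = sf.SubjectRecord("s0", *small_subject, duration_s=600.0)
        feats = prepare_subject_features(rec)
        rf = train_event_rf(feats, feats["label"].to_numpy(), seed=0)
        assert rf.n_estimators == 50

    def test_single_class_raises(self):
        df = pd.DataFrame(
            {
                "respiratory_rate": [0.3, 0.3],
                "movement_power": [1.0, 1.1],
                "total_displacement": [5.0, 6.0],
            }
        )
        with pytest.raises(ValueError):
            train_event_rf(df, [0, 0])

    def test_missing_feature_column_raises(self):
        df = pd.DataFrame({"respiratory_rate": [0.3], "movement_power": [1.0]})
        with pytest.raises(KeyError):
            train_event_rf(df, [0])

    def test_out_of_bag_accuracy_on_clean_cohort(self):
        cohort = sf.generate_cohort(3, duration_s=900.0, ahi_range=(20, 50),
                                    seed=17)
        for rec in cohort:
            prepare_subject_features(rec)
        df = pd.concat([r.features for r in cohort], ignore_index=True)
        rf = train_event_rf(df, df["label"].to_numpy(), seed=0)
        assert rf.oob_score_ > 0.85

    def test_per_window_f1_on_clean_cohort(self):
        """End-to-end detection quality of the baseline classifier."""
        from sklearn.metrics import f1_score

        cohort = sf.generate_cohort(10, duration_s=900.0, ahi_range=(10, 50),
                                    seed=23)
        for rec in cohort:
            prepare_subject_features(rec)
        train = pd.concat([r.features for r in cohort[:5]], ignore_index=True)
        rf = train_event_rf(train, train["label"].to_numpy(), seed=0)
        oob = rf.oob_decision_function_[:, 1]
        ok = np.isfinite(oob)
        y_train = train.dropna(subset=["respiratory_rate"])["label"].to_numpy()
        thr = select_threshold(oob[ok], y_train[ok])
        test = pd.concat([r.features for r in cohort[5:]], ignore_index=True)
        x = test[["respiratory_rate", "movement_power", "total_displacement"]]
        x = x.fillna({"respiratory_rate": 0.1})
        pred = rf.predict_proba(x.to_numpy())[:, 1] >= thr
        assert f1_score(test["label"].to_numpy(), pred) >= 0.8


@pytest.fixture(scope="module")
def tiny_windows():
    trace, truth = sf.generate_subject(600.0, 40.0, "single_position", seed=31)
    flow = syn.exact_flow(trace, truth.positions, 24, 32, 2.0)
    return make_windows(flow, truth.events, "train")


class TestEventCnn:
    def test_default_class_weight_ratio_is_5_to_1(self, tiny_windows):
        model = train_event_cnn(tiny_windows, config={"epochs": 1}, seed=0)
        assert model.class_weights[1] / model.class_weights[0] == 5.0
        assert model.learning_rate == 0.001
        assert model.batch_size == 25

    def test_fixed_seed_reproduces_loss_trajectory(self, tiny_windows):
        a = train_event_cnn(tiny_windows, config={"epochs": 2}, seed=7)
        b = train_event_cnn(tiny_windows, config={"epochs": 2}, seed=7)
        assert a.loss_history == b.loss_history

    def test_single_class_raises(self, tiny_windows):
        only_events = [w for w in tiny_windows if w.label == "event"]
        with pytest.raises(ValueError):
            train_event_cnn(only_events, config={"epochs": 1})

    def test_separable_data_reaches_high_auc(self, tiny_windows):
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(tiny_windows))
        split = int(0.7 * len(idx))
        train = [tiny_windows[i] for i in idx[:split]]
        test = [tiny_windows[i] for i in idx[split:]]
        model = train_event_cnn(train, config={"epochs": 20}, seed=0)
        x = np.stack([w.flow_stack for w in test]).astype(np.float32)
        y = np.array([1 if w.label == "event" else 0 for w in test])
        assert roc_auc(model.predict_proba(x)[:, 1], y) > 0.9
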