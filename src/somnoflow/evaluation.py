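"""Validation harness: LOOCV, agreement statistics, screening metrics.

Performance of AHI estimation is assessed the way the clinical literature
does: leave-one-person-out cross-validation, Spearman rank correlation
between estimated and reference AHI, Bland-Altman agreement (mean
difference and 1.96-SD limits), and confusion-matrix metrics for screening
at the conventional AHI >= 15 cutoff.  Percentages are reported to 2
decimals; undefined ratios (zero denominators) propagate as NaN, never
silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from . import ahi as ahi_mod
from . import events as events_mod
from . import respiratory as resp_mod
from .motion import total_displacement
from .synthetic import SubjectRecord, exact_point_trajectories, exact_flow

logger = logging.getLogger(__name__)

#: Conventional screening cutoff, events/hour.
SCREENING_AHI_THRESHOLD = 15.0

#: Desk-scale analysis resolution (height, width).
DESK_RESOLUTION = (48, 64)
#: Analysis frame rate after downsampling, Hz.
ANALYSIS_RATE_HZ = 2.0


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AgreementSummary:
    """Bland-Altman bias and limits, plus rank correlation."""

    bias: float
    loa_half_width: float
    spearman_rho: float


# ---------------------------------------------------------------------------
# metric arithmetic
# ---------------------------------------------------------------------------

def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy/precision/recall/F1 as percentages (NaN when undefined)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    precision = ratio(cm.tp, cm.tp + cm.fp)
    recall = ratio(cm.tp, cm.tp + cm.fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, in percent."""
    if precision_pct + recall_pct == 0:
        return float("nan")
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def confusion_from_rates(precision_pct: float, recall_pct: float, n: int,
                         decimals: int = 2) -> ConfusionMatrix:
    """The integer confusion matrix implied by printed precision/recall.

    Enumerates all non-negative integer matrices of size ``n`` whose
    precision and recall round (to ``decimals`` places) to the printed
    values; exactly one must match, otherwise an error is raised.  This is
    how printed accuracy/F1 values can be cross-checked against printed
    precision/recall and cohort size.
    """
    matches = []
    for tp in range(0, n + 1):
        for fp in range(0, n + 1 - tp):
            prec = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
            if not np.isfinite(prec) or round(prec, decimals) != round(precision_pct, decimals):
                continue
            for fn in range(0, n + 1 - tp - fp):
                rec = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
                if not np.isfinite(rec) or round(rec, decimals) != round(recall_pct, decimals):
                    continue
                matches.append(ConfusionMatrix(tp, fp, fn, n - tp - fp - fn))
    if len(matches) != 1:
        raise ValueError(
            f"printed rates match {len(matches)} confusion matrices at n={n}"
        )
    return matches[0]


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman requires equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input; Spearman correlation undefined")
        return float("nan")
    return float(scipy.stats.spearmanr(x, y).statistic)


def bland_altman(estimates, references) -> AgreementSummary:
    """Mean difference and 1.96-SD (n-1 denominator) limits of agreement."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.size < 2:
        raise ValueError("bland_altman requires equal-length vectors, n >= 2")
    diff = est - ref
    sd = float(np.std(diff, ddof=1))
    rho = spearman(est, ref) if est.size >= 3 else float("nan")
    return AgreementSummary(
        bias=float(diff.mean()), loa_half_width=1.96 * sd, spearman_rho=rho
    )


def screen_apnea(ahi_estimates, ahi_truth,
                 threshold: float = SCREENING_AHI_THRESHOLD) -> ConfusionMatrix:
    """Confusion matrix for sleep-apnea screening at ``AHI >= threshold``."""
    est = np.asarray(ahi_estimates, dtype=float)
    ref = np.asarray(ahi_truth, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("vectors must have equal length")
    p_est, p_ref = est >= threshold, ref >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(p_est & p_ref)),
        fp=int(np.sum(p_est & ~p_ref)),
        fn=int(np.sum(~p_est & p_ref)),
        tn=int(np.sum(~p_est & ~p_ref)),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def event_frame_span(duration_s: float = 10.0, fps: float = 2.0,
                     n_offsets: int = 200) -> Tuple[int, int]:
    """(typical, worst-case) frame counts spanned by an event.

    Counts sampling instants falling strictly inside an event of the given
    duration, over a sweep of start-time alignments relative to the frame
    grid: a minimum-duration 10 s event at 2 Hz spans 20 frames, or 19 when
    the event boundaries land exactly on sampling instants.
    """
    counts = []
    for off in np.linspace(0.0, 1.0 / fps, n_offsets, endpoint=False):
        k_min = int(np.floor(off * fps + 1e-9)) + 1
        k_max = int(np.ceil((off + duration_s) * fps - 1e-9)) - 1
        counts.append(k_max - k_min + 1)
    return int(max(counts)), int(min(counts))


# ---------------------------------------------------------------------------
# pipeline preparation
# ---------------------------------------------------------------------------

def prepare_subject_features(
    record: SubjectRecord,
    height: int = DESK_RESOLUTION[0],
    width: int = DESK_RESOLUTION[1],
    rate: float = ANALYSIS_RATE_HZ,
    n_points: int = 768,
) -> pd.DataFrame:
    """Baseline per-window features for one simulated subject (cached).

    Motion extraction (exact-flow point trajectories, windowed PCA, feature
    windows) does not depend on cross-validation folds, so it is computed
    once per subject and cached on the record.
    """
    if record.features is not None:
        return record.features
    traj = exact_point_trajectories(
        record.trace, record.truth.positions, height, width,
        rate=rate, n_points=n_points,
    )
    signal = resp_mod.extract_respiratory(traj)
    feats = resp_mod.compute_baseline_features(
        traj, signal, annotations=record.truth.events
    )
    record.features = feats
    return feats


def _detect_events_baseline(model, threshold: float, features: pd.DataFrame,
                            window_s: float = resp_mod.FEATURE_WINDOW_S):
    """Window scores -> merged event intervals for the baseline detector."""
    x = features[events_mod.BASELINE_FEATURES].copy()
    x["respiratory_rate"] = x["respiratory_rate"].fillna(
        resp_mod.RESPIRATORY_BAND_HZ[0]
    )
    scores = model.predict_proba(x.to_numpy(dtype=float))[:, 1]
    return events_mod.scores_to_events(
        scores, threshold=threshold, stride_s=1.0, cover_s=window_s
    )


def _oob_threshold(model, labels, fallback: float) -> float:
    oob = model.oob_decision_function_[:, 1]
    ok = np.isfinite(oob)
    return events_mod.select_threshold(oob[ok], np.asarray(labels)[ok],
                                       fallback=fallback)


# ---------------------------------------------------------------------------
# leave-one-person-out cross-validation
# ---------------------------------------------------------------------------

def loocv(
    cohort: Sequence[SubjectRecord],
    pipeline: str = "baseline",
    seed: int = 0,
    fallback_threshold: float = events_mod.DEFAULT_THRESHOLD,
    cnn_config: Optional[dict] = None,
) -> pd.DataFrame:
    """Leave-one-person-out AHI estimation over a cohort.

    For each held-out subject, the event classifier, operating threshold
    and AHI regression are fitted on the remaining subjects only.  Motion
    extraction and per-window features are fold-independent preprocessing.
    Deterministic given the seed.

    Returns one row per subject: ``subject_id, true_ahi, est_ahi,
    n_detected_events``.
    """
    if len(cohort) < 3:
        raise ValueError("LOOCV requires at least 3 subjects")
    if pipeline == "baseline":
        return _loocv_baseline(cohort, seed, fallback_threshold)
    if pipeline == "cnn":
        return _loocv_cnn(cohort, seed, fallback_threshold, cnn_config)
    raise ValueError(f"unknown pipeline: {pipeline!r}")


def _loocv_baseline(cohort, seed, fallback_threshold):
    for rec in cohort:
        prepare_subject_features(rec)
    rows = []
    for k, test_rec in enumerate(cohort):
        train_recs = [r for i, r in enumerate(cohort) if i != k]
        train_df = pd.concat([r.features for r in train_recs], ignore_index=True)
        rf = events_mod.train_event_rf(
            train_df, train_df["label"].to_numpy(), seed=seed
        )
        labels_used = train_df.dropna(
            subset=events_mod.BASELINE_FEATURES
        )["label"].to_numpy()
        threshold = _oob_threshold(rf, labels_used, fallback_threshold)
        feats, ys = [], []
        for r in train_recs:
            ev = _detect_events_baseline(rf, threshold, r.features)
            feats.append(ahi_mod.ahi_features_baseline(ev, r.duration_s / 3600.0))
            ys.append(r.truth.true_ahi)
        lm = ahi_mod.fit_ahi_regression(pd.DataFrame(feats), ys, "baseline2")
        ev_test = _detect_events_baseline(rf, threshold, test_rec.features)
        f_test = ahi_mod.ahi_features_baseline(
            ev_test, test_rec.duration_s / 3600.0
        )
        est = float(ahi_mod.predict_ahi(lm, pd.DataFrame([f_test]))[0])
        logger.info("fold %d: subject %s est AHI %.1f (true %.1f)",
                    k, test_rec.subject_id, est, test_rec.truth.true_ahi)
        rows.append(
            {
                "subject_id": test_rec.subject_id,
                "true_ahi": test_rec.truth.true_ahi,
                "est_ahi": est,
                "n_detected_events": len(ev_test),
            }
        )
    return pd.DataFrame(rows)


def _cnn_windows(rec, height, width):
    if getattr(rec, "_cnn_cache", None) is None:
        flow = exact_flow(rec.trace, rec.truth.positions, height, width,
                          ANALYSIS_RATE_HZ)
        train = events_mod.make_windows(flow, rec.truth.events, mode="train")
        test = events_mod.make_windows(flow, mode="test")
        rec._cnn_cache = (train, test)
    return rec._cnn_cache


def _loocv_cnn(cohort, seed, fallback_threshold, cnn_config):
    height, width = DESK_RESOLUTION
    rows = []
    for k, test_rec in enumerate(cohort):
        train_recs = [r for i, r in enumerate(cohort) if i != k]
        samples = [w for r in train_recs for w in _cnn_windows(r, height, width)[0]]
        model = events_mod.train_event_cnn(samples, config=cnn_config, seed=seed)
        x_train = np.stack([s.flow_stack for s in samples]).astype(np.float32)
        y_train = np.array([1 if s.label == "event" else 0 for s in samples])
        threshold = events_mod.select_threshold(
            model.predict_proba(x_train)[:, 1], y_train,
            fallback=fallback_threshold,
        )
        feats, ys = [], []
        for r in train_recs + [test_rec]:
            test_windows = _cnn_windows(r, height, width)[1]
            xt = np.stack([w.flow_stack for w in test_windows]).astype(np.float32)
            scores = model.predict_proba(xt)[:, 1]
            ev = events_mod.scores_to_events(scores, threshold=threshold)
            feats.append(ahi_mod.ahi_features_cnn(ev, r.duration_s / 3600.0))
            ys.append(r.truth.true_ahi)
        lm = ahi_mod.fit_ahi_regression(pd.DataFrame(feats[:-1]), ys[:-1], "cnn3")
        est = float(ahi_mod.predict_ahi(lm, pd.DataFrame([feats[-1]]))[0])
        rows.append(
            {
                "subject_id": test_rec.subject_id,
                "true_ahi": test_rec.truth.true_ahi,
                "est_ahi": est,
                "n_detected_events": int(feats[-1]["n_events"]),
            }
        )
    return pd.DataFrame(rows)


def loocv_positional(features: pd.DataFrame, labels, seed: int = 0,
                     n_trees: int = 3) -> List[str]:
    """Leave-one-out predictions of the 3-tree positional forest.

    Undetermined subjects pass through unchanged and are excluded from
    every training fold.
    """
    from . import positional as positional_mod

    labels = list(labels)
    out = []
    for k in range(len(features)):
        train_idx = [i for i in range(len(features)) if i != k]
        model = positional_mod.train_positional_rf(
            features.iloc[train_idx], [labels[i] for i in train_idx],
            n_trees=n_trees, seed=seed,
        )
        out.append(positional_mod.predict_positional(model, features.iloc[[k]])[0])
    return out


def save_agreement_plots(estimates, references, outdir) -> None:
    """Scatter and Bland-Altman plots of AHI agreement (requires matplotlib)."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    fig, ax = plt.subplots()
    ax.scatter(ref, est)
    lim = [0, max(est.max(), ref.max()) * 1.05]
    ax.plot(lim, lim, "r--", label="unity")
    ax.set_xlabel("reference AHI (events/h)")
    ax.set_ylabel("estimated AHI (events/h)")
    ax.legend()
    fig.savefig(outdir / "ahi_scatter.png", dpi=120)
    plt.close(fig)
    agg = bland_altman(est, ref)
    fig, ax = plt.subplots()
    ax.scatter((est + ref) / 2, est - ref)
    for y, style in ((agg.bias, "-"), (agg.bias + agg.loa_half_width, "--"),
                     (agg.bias - agg.loa_half_width, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean AHI (events/h)")
    ax.set_ylabel("difference (events/h)")
    fig.savefig(outdir / "ahi_bland_altman.png", dpi=120)
    plt.close(fig)
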