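"""Splits, sweeps, bias slicing and rejection analysis for discrete models.

The harness operates on lists of segmented :class:`GestureTemplate` objects
(carrying user, repetition, condition and demographic metadata through their
source recording) and on *pipelines* — objects with ``fit(templates)`` and
``predict(template) -> DiscretePrediction``.  Available pipeline ids:

====================  =====================================================
``mvlda``             majority-vote LDA over 200 ms / 25 ms RMS windows
``dtw``               1NN-DTW over 25 ms RMS windows, full template bank
``dtw_closest``       1NN-DTW against per-class DTW-medoid templates
``dtw_mean``          1NN-DTW against per-class resampled mean templates
``lstm``              the recurrent temporal network
====================  =====================================================

Every run produces an :class:`EvalReport` whose per-template prediction table
(a pandas DataFrame) is the single source for aggregate accuracy, demographic
slicing and confidence-based rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import DTW1NNClassifier, MVLDAClassifier
from .dataio import EMGRecording, GestureTemplate, segment_by_indices
from .features import WindowingConfig
from .synth import Cohort
from .temporal import TemporalNetClassifier, TemporalNetConfig

__all__ = [
    "PIPELINE_IDS",
    "make_pipeline",
    "cohort_templates",
    "SplitSpec",
    "EvalReport",
    "run_split",
    "sweep_subjects_reps",
    "sweep_window_increment",
    "slice_by_attribute",
    "cohens_d",
    "rejection_curve",
    "out_of_set_rejection",
    "gesture_subset_eval",
]

PIPELINE_IDS = ("mvlda", "dtw", "dtw_closest", "dtw_mean", "lstm")


def make_pipeline(
    pipeline_id: str,
    net_config: TemporalNetConfig | None = None,
    windowing: WindowingConfig | None = None,
    feature_set: str = "RMS",
):
    """Instantiate a fresh (unfitted) pipeline by id."""
    if pipeline_id == "mvlda":
        kw = {"feature_set": feature_set}
        if windowing is not None:
            kw["cfg"] = windowing
        return MVLDAClassifier(**kw)
    if pipeline_id in ("dtw", "dtw_closest", "dtw_mean"):
        reduction = {"dtw": None, "dtw_closest": "closest",
                     "dtw_mean": "mean"}[pipeline_id]
        kw = {"feature_set": feature_set, "reduction": reduction}
        if windowing is not None:
            kw["cfg"] = windowing
        return DTW1NNClassifier(**kw)
    if pipeline_id == "lstm":
        cfg = net_config or TemporalNetConfig()
        if windowing is not None:
            cfg = TemporalNetConfig(
                **{**cfg.__dict__, "windowing": windowing,
                   "feature_set": feature_set}
            )
        return TemporalNetClassifier(cfg)
    raise ValueError(f"unknown pipeline id {pipeline_id!r}")


def cohort_templates(
    recordings: list[EMGRecording] | Cohort,
    include_out_of_set: bool = False,
    out_of_set_labels: set[str] | None = None,
) -> list[GestureTemplate]:
    """Segment a cohort's recordings into templates via their true indices."""
    if isinstance(recordings, Cohort):
        oos = {g.gesture_id for g in recordings.config.out_of_set_specs}
        recs = recordings.recordings
    else:
        oos = out_of_set_labels or set()
        recs = recordings
    out = []
    for rec in recs:
        if not include_out_of_set and rec.gesture in oos:
            continue
        out.append(segment_by_indices(rec))
    return out


def _meta(t: GestureTemplate) -> dict:
    demo = {}
    if t.source is not None and getattr(t.source, "demographics", None):
        demo = dict(t.source.demographics)
    return demo


@dataclass(frozen=True)
class SplitSpec:
    """How to split templates into train and test sets.

    kind:
      - ``leave_one_repetition_out``: one fold per repetition index.
      - ``cross_user``: train on ``train_users``, test on ``test_users``
        (must be disjoint).
      - ``condition_holdout``: train on ``train_conditions``, test on
        ``test_conditions`` (any users).
    """

    kind: str
    train_users: tuple[str, ...] | None = None
    test_users: tuple[str, ...] | None = None
    train_conditions: tuple[str, ...] | None = None
    test_conditions: tuple[str, ...] | None = None
    reps: tuple[int, ...] | None = None  # restrict LORO to these reps
    seed: int = 0


@dataclass
class EvalReport:
    """Per-template predictions plus aggregates."""

    predictions: pd.DataFrame
    pipeline_id: str = ""
    split_kind: str = ""
    subset_id: str | None = None

    @property
    def accuracy(self) -> float:
        return float(self.predictions["correct"].mean())

    def to_json(self) -> dict:
        return {
            "pipeline": self.pipeline_id,
            "split": self.split_kind,
            "subset": self.subset_id,
            "n": int(len(self.predictions)),
            "accuracy": self.accuracy,
        }


def _predict_all(pipeline, templates: list[GestureTemplate]) -> pd.DataFrame:
    rows = []
    for t in templates:
        pred = pipeline.predict(t)
        row = {
            "user_id": t.user_id,
            "true": t.label,
            "rep": t.rep,
            "condition": t.condition,
            "predicted": pred.label,
            "max_confidence": pred.max_confidence,
            "correct": pred.label == t.label,
        }
        row.update(_meta(t))
        rows.append(row)
    return pd.DataFrame(rows)


def run_split(
    pipeline_id: str,
    templates: list[GestureTemplate],
    split: SplitSpec,
    **pipeline_kwargs,
) -> EvalReport:
    """Train per the split, predict every test template once, aggregate."""
    if split.kind == "leave_one_repetition_out":
        reps = split.reps or tuple(sorted({t.rep for t in templates}))
        pool = [t for t in templates if t.rep in reps]
        frames = []
        for fold_rep in reps:
            train = [t for t in pool if t.rep != fold_rep]
            test = [t for t in pool if t.rep == fold_rep]
            pipe = make_pipeline(pipeline_id, **pipeline_kwargs).fit(train)
            frames.append(_predict_all(pipe, test))
        df = pd.concat(frames, ignore_index=True)
    elif split.kind == "cross_user":
        tr, te = set(split.train_users), set(split.test_users)
        if tr & te:
            raise ValueError(f"train/test users overlap: {sorted(tr & te)}")
        train = [t for t in templates if t.user_id in tr]
        test = [t for t in templates if t.user_id in te]
        pipe = make_pipeline(pipeline_id, **pipeline_kwargs).fit(train)
        df = _predict_all(pipe, test)
    elif split.kind == "condition_holdout":
        train = [t for t in templates if t.condition in split.train_conditions]
        test = [t for t in templates if t.condition in split.test_conditions]
        pipe = make_pipeline(pipeline_id, **pipeline_kwargs).fit(train)
        df = _predict_all(pipe, test)
    else:
        raise ValueError(f"unknown split kind {split.kind!r}")
    return EvalReport(df, pipeline_id=pipeline_id, split_kind=split.kind)


def sweep_subjects_reps(
    templates: list[GestureTemplate],
    user_counts: list[int],
    rep_counts: list[int],
    test_users: list[str],
    folds: int = 10,
    pipeline_id: str = "lstm",
    seed: int = 0,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Mean held-out-user accuracy per (user count, repetition count) cell.

    For each fold, training users are drawn randomly from the non-test pool
    once per user count and held constant across repetition counts.  Returns
    a DataFrame indexed by user count with one column per repetition count.
    """
    pool = sorted({t.user_id for t in templates} - set(test_users))
    if max(user_counts) > len(pool):
        raise ValueError(
            f"max user count {max(user_counts)} exceeds pool of {len(pool)}"
        )
    test = [t for t in templates if t.user_id in set(test_users)]
    grid = np.zeros((len(user_counts), len(rep_counts)))
    for f in range(folds):
        for ui, n_users in enumerate(user_counts):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, 11, f, n_users))
            )
            users = set(rng.choice(pool, size=n_users, replace=False).tolist())
            for ri, n_reps in enumerate(rep_counts):
                train = [
                    t for t in templates
                    if t.user_id in users and t.rep < n_reps
                ]
                pipe = make_pipeline(pipeline_id, **pipeline_kwargs).fit(train)
                df = _predict_all(pipe, test)
                grid[ui, ri] += df["correct"].mean()
    grid /= folds
    return pd.DataFrame(grid, index=user_counts, columns=rep_counts)


def sweep_window_increment(
    templates: list[GestureTemplate],
    window_lengths: list[int],
    increments: list[int],
    split: SplitSpec,
    pipeline_id: str = "mvlda",
    **pipeline_kwargs,
) -> pd.DataFrame:
    """One train/test accuracy per (window length, increment) cell.

    Cells whose window length exceeds the shortest template are skipped with
    a warning and reported as NaN.
    """
    min_len = min(t.length for t in templates)
    grid = np.full((len(window_lengths), len(increments)), np.nan)
    for li, L in enumerate(window_lengths):
        if L > min_len:
            warnings.warn(
                f"window length {L} exceeds shortest template ({min_len}); "
                "cell skipped"
            )
            continue
        for ii, inc in enumerate(increments):
            report = run_split(
                pipeline_id, templates, split,
                windowing=WindowingConfig(L, inc), **pipeline_kwargs,
            )
            grid[li, ii] = report.accuracy
    return pd.DataFrame(grid, index=window_lengths, columns=increments)


def slice_by_attribute(report: EvalReport, attribute: str) -> pd.DataFrame:
    """Accuracy and group size per value of a metadata attribute."""
    df = report.predictions
    if attribute not in df.columns:
        raise ValueError(f"attribute {attribute!r} not in report metadata")
    g = df.groupby(attribute)["correct"]
    return pd.DataFrame({"accuracy": g.mean(), "n": g.size()})


def cohens_d(group1, group2) -> float:
    """Standardized mean difference with (n1-1, n2-1)-weighted pooled sd."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    n1, n2 = len(a), len(b)
    pooled_var = (
        (n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def rejection_curve(
    report: EvalReport, thresholds: list[float]
) -> pd.DataFrame:
    """Rejection rate and accepted-set accuracy per confidence threshold.

    Predictions with top confidence below the threshold are rejected; the
    accepted-set accuracy is NaN when everything is rejected.
    """
    df = report.predictions
    rows = []
    for tau in thresholds:
        accepted = df[df["max_confidence"] >= tau]
        rows.append({
            "threshold": tau,
            "rejection_rate": 1.0 - len(accepted) / len(df),
            "accepted_accuracy": (
                float(accepted["correct"].mean()) if len(accepted) else np.nan
            ),
            "n_accepted": len(accepted),
        })
    return pd.DataFrame(rows)


def out_of_set_rejection(
    pipeline,
    out_templates: list[GestureTemplate],
    thresholds: list[float],
) -> pd.DataFrame:
    """Fraction of out-of-set templates rejected at each threshold."""
    conf = np.array(
        [pipeline.predict(t).max_confidence for t in out_templates]
    )
    rows = [
        {"threshold": tau, "rejection_rate": float(np.mean(conf < tau))}
        for tau in thresholds
    ]
    return pd.DataFrame(rows)


def gesture_subset_eval(
    templates: list[GestureTemplate],
    subset: tuple[str, ...],
    split: SplitSpec,
    pipeline_id: str = "lstm",
    **pipeline_kwargs,
) -> EvalReport:
    """Retrain and evaluate with gestures outside ``subset`` omitted."""
    if len(set(subset)) < 2:
        raise ValueError("gesture subset needs at least 2 classes")
    kept = [t for t in templates if t.label in set(subset)]
    report = run_split(pipeline_id, kept, split, **pipeline_kwargs)
    report.subset_id = "+".join(sorted(set(subset)))
    bad = set(report.predictions["predicted"]) - set(subset)
    assert not bad, f"predictions outside subset: {bad}"
    return report
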