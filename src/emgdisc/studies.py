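"""Self-contained mini-studies on synthetic cohorts.

Each function generates (or receives) a seeded synthetic cohort, runs one of
the analyses the package exists for — classifier-family comparison on held-out
users, training-set size trends, gesture-subset ablation, demographic-bias
slicing with transfer-learning mitigation, speed confounds, confidence
rejection — and returns plain numbers.  Both the test suite and the
reproduction script build on these.

The studies use a scaled network (one LSTM layer of 32 units, 32/16 head,
learning rate 3e-3, at most 25 epochs) so a full study runs on one CPU core
in minutes; the full-size defaults in :class:`TemporalNetConfig` remain the
reference protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .dataio import GestureTemplate, segment_by_indices
from .evaluate import (
    EvalReport,
    SplitSpec,
    cohort_templates,
    out_of_set_rejection,
    rejection_curve,
    run_split,
)
from .synth import (
    CohortConfig,
    Condition,
    GroupEffect,
    default_gesture_specs,
    generate_cohort,
    make_user_profile,
    out_of_set_gesture_specs,
    synthesize_recording,
    _rng,
    _STREAM_RECORDING,
)
from .temporal import TemporalNetConfig, TemporalNetClassifier
from .transfer import compute_centroids, transfer_contrastive

__all__ = [
    "study_net_config",
    "noise_ceiling_study",
    "CrossUserStudy",
    "run_crossuser_study",
    "usercount_trend",
    "subset_accuracy",
    "speed_confound_accuracy",
    "rejection_summary",
    "bias_transfer_study",
]

#: rejection thresholds including the skewed-confidence extremes
REJECTION_THRESHOLDS = (
    0.0, 0.5, 0.7, 0.9, 0.95, 0.99, 0.999, 0.9999,
)


def study_net_config(seed: int, max_epochs: int = 25) -> TemporalNetConfig:
    """The scaled recurrent model used throughout the studies."""
    return TemporalNetConfig(
        hidden=32,
        n_lstm_layers=1,
        head_sizes=(32, 16),
        lr=3e-3,
        batch_size=512,
        max_epochs=max_epochs,
        early_stop_patience=4,
        track_train_accuracy=False,
        seed=seed,
    )


def noise_ceiling_study(
    seed: int, n_users: int = 10, n_reps: int = 10
) -> dict[str, float]:
    """Leave-one-repetition-out accuracy with zero inter-user variability.

    With identical users and distinct per-gesture envelopes the only error
    source is sampling noise, so every architecture should sit at (or near)
    a 100% ceiling.
    """
    config = CohortConfig(
        n_users=n_users,
        n_reps=n_reps,
        inter_user_gain_sd=0.0,
        speed_factor_sd=0.0,
        rotation_sd=0.0,
        seed=seed,
    )
    templates = cohort_templates(generate_cohort(config))
    split = SplitSpec("leave_one_repetition_out")
    # small training folds need the small-data protocol: smaller batches
    # (more updates per epoch) and a longer minimum number of epochs
    small_net = dc_replace(
        study_net_config(seed), batch_size=128, max_epochs=60, min_epochs=20
    )
    out = {}
    for pid in ("mvlda", "dtw", "lstm"):
        kwargs = {"net_config": small_net} if pid == "lstm" else {}
        out[pid] = run_split(pid, templates, split, **kwargs).accuracy
    return out


@dataclass
class CrossUserStudy:
    """A generated cohort with its cross-user split and fitted models."""

    config: CohortConfig
    templates: list[GestureTemplate]
    train_users: tuple[str, ...]
    test_users: tuple[str, ...]
    reports: dict[str, EvalReport]
    lstm: TemporalNetClassifier

    @property
    def accuracies(self) -> dict[str, float]:
        return {pid: r.accuracy for pid, r in self.reports.items()}

    @property
    def train_templates(self) -> list[GestureTemplate]:
        tr = set(self.train_users)
        return [t for t in self.templates if t.user_id in tr]

    @property
    def test_templates(self) -> list[GestureTemplate]:
        te = set(self.test_users)
        return [t for t in self.templates if t.user_id in te]


def run_crossuser_study(
    seed: int,
    n_train: int = 40,
    n_test: int = 10,
    n_reps: int = 20,
    pipelines: tuple[str, ...] = ("mvlda", "dtw_mean", "lstm"),
) -> CrossUserStudy:
    """Zero-shot cross-user comparison of the discrete architectures.

    Generates a moderate-variability cohort, trains each pipeline on the
    first ``n_train`` users and evaluates on the remaining ``n_test``
    held-out users.
    """
    config = CohortConfig(n_users=n_train + n_test, n_reps=n_reps, seed=seed)
    cohort = generate_cohort(config)
    templates = cohort_templates(cohort)
    users = sorted({t.user_id for t in templates})
    train_users, test_users = tuple(users[:n_train]), tuple(users[n_train:])
    split = SplitSpec(
        "cross_user", train_users=train_users, test_users=test_users,
        seed=seed,
    )
    from .evaluate import _predict_all

    train = [t for t in templates if t.user_id in set(train_users)]
    test = [t for t in templates if t.user_id in set(test_users)]
    reports = {}
    lstm = None
    for pid in pipelines:
        if pid == "lstm":
            # fit once by hand so the fitted pipeline stays reusable
            lstm = TemporalNetClassifier(study_net_config(seed)).fit(train)
            reports[pid] = EvalReport(
                _predict_all(lstm, test), pipeline_id=pid,
                split_kind="cross_user",
            )
        else:
            reports[pid] = run_split(pid, templates, split)
    return CrossUserStudy(
        config=config,
        templates=templates,
        train_users=train_users,
        test_users=test_users,
        reports=reports,
        lstm=lstm,
    )


def usercount_trend(
    study: CrossUserStudy, user_counts: tuple[int, ...] = (5, 10, 20, 40),
    n_reps: int = 10,
) -> list[float]:
    """Held-out accuracy of the recurrent model vs. training-user count."""
    seed = study.config.seed
    test = study.test_templates
    accs = []
    for n_users in user_counts:
        users = set(study.train_users[:n_users])
        train = [
            t for t in study.templates
            if t.user_id in users and t.rep < n_reps
        ]
        clf = TemporalNetClassifier(
            study_net_config(seed, max_epochs=20)
        ).fit(train)
        accs.append(
            float(np.mean([clf.predict(t).label == t.label for t in test]))
        )
    return accs


def subset_accuracy(
    study: CrossUserStudy,
    subset: tuple[str, ...] = ("rest", "wave_in", "wave_out"),
) -> float:
    """Cross-user accuracy after omitting all gestures outside ``subset``."""
    split = SplitSpec(
        "cross_user", train_users=study.train_users,
        test_users=study.test_users, seed=study.config.seed,
    )
    kept = [t for t in study.templates if t.label in set(subset)]
    report = run_split(
        "lstm", kept, split, net_config=study_net_config(study.config.seed)
    )
    return report.accuracy


def _extra_condition_templates(
    study: CrossUserStudy,
    condition: Condition,
    specs,
    n_reps: int,
    stream_tag: int,
) -> list[GestureTemplate]:
    """Synthesize additional recordings for the held-out users only."""
    config = study.config
    users = sorted({t.user_id for t in study.templates})
    out = []
    for uid in study.test_users:
        ui = users.index(uid)
        profile = make_user_profile(config, ui)
        for gi, spec in enumerate(specs):
            for rep in range(n_reps):
                rng = _rng(config.seed, _STREAM_RECORDING, ui,
                           stream_tag + gi, rep, stream_tag)
                rec = synthesize_recording(
                    profile, spec, condition, config=config, rep=rep, rng=rng
                )
                out.append(segment_by_indices(rec))
    return out


def speed_confound_accuracy(
    study: CrossUserStudy, speed: float = 1.5, n_reps: int = 10
) -> dict[str, float]:
    """Held-out accuracy at default vs. shifted elicitation speed.

    ``speed`` multiplies the gesture duration (1.5 = 50% slower).  The model
    is the study's cross-user recurrent model, trained on default-speed data
    only.
    """
    slow = _extra_condition_templates(
        study,
        Condition(name=f"speed{speed:g}", speed=speed),
        study.config.in_set_specs,
        n_reps,
        stream_tag=100,
    )
    clf = study.lstm
    slow_acc = float(np.mean([clf.predict(t).label == t.label for t in slow]))
    return {
        "default": study.reports["lstm"].accuracy,
        "shifted": slow_acc,
    }


def rejection_summary(
    study: CrossUserStudy,
    thresholds: tuple[float, ...] = REJECTION_THRESHOLDS,
    n_out_reps: int = 10,
):
    """In-set rejection curve and out-of-set rejection rates.

    Out-of-set gestures (classes never shown at training) are synthesized for
    the held-out users and pushed through the cross-user recurrent model.
    """
    curve = rejection_curve(study.reports["lstm"], list(thresholds))
    out_templates = _extra_condition_templates(
        study,
        Condition(),
        out_of_set_gesture_specs(),
        n_out_reps,
        stream_tag=200,
    )
    oos = out_of_set_rejection(study.lstm, out_templates, list(thresholds))
    return curve, oos


def bias_transfer_study(
    seed: int,
    n_users: int = 60,
    n_reps: int = 16,
    minority_share: float = 0.1,
    transfer_reps: int = 10,
    k: int = 10,
) -> dict[str, float]:
    """Demographic-bias gap, zero-shot and after contrastive transfer.

    Group B is underrepresented (10% by default) and generatively shifted
    (slower elicitation, rotated electrode pattern).  The cross-user model is
    trained on the majority-heavy pool; held-out users of both groups are
    evaluated zero-shot, then each held-out user is adapted with contrastive
    transfer (first ``transfer_reps`` repetitions) and re-evaluated on their
    remaining repetitions.
    """
    config = CohortConfig(
        n_users=n_users,
        n_reps=n_reps,
        demographic_mix={"group": {"A": 1 - minority_share,
                                   "B": minority_share}},
        group_effects={
            "group": {"B": GroupEffect(duration_scale=1.25,
                                       extra_rotation=1.0)}
        },
        seed=seed,
    )
    cohort = generate_cohort(config)
    templates = cohort_templates(cohort)
    by_group: dict[str, list[str]] = {"A": [], "B": []}
    for p in cohort.profiles:
        by_group[p.demographics["group"]].append(p.user_id)
    n_b_test = min(3, max(1, len(by_group["B"]) - 1))
    test_users = tuple(sorted(by_group["B"][:n_b_test] + by_group["A"][:4]))
    train_users = tuple(
        sorted(set(u.user_id for u in cohort.profiles) - set(test_users))
    )
    train = [t for t in templates if t.user_id in set(train_users)]
    clf = TemporalNetClassifier(study_net_config(seed)).fit(train)
    group_of = {p.user_id: p.demographics["group"] for p in cohort.profiles}

    def group_acc(predict, pool) -> dict[str, float]:
        hits: dict[str, list[bool]] = {"A": [], "B": []}
        for t in pool:
            hits[group_of[t.user_id]].append(predict(t).label == t.label)
        return {g: float(np.mean(v)) for g, v in hits.items() if v}

    eval_pool = [
        t for t in templates
        if t.user_id in set(test_users) and t.rep >= transfer_reps
    ]
    zero_shot = group_acc(clf.predict, eval_pool)
    centroids = compute_centroids(clf.net, train)

    post_hits: dict[str, list[bool]] = {"A": [], "B": []}
    for uid in test_users:
        batch = [
            t for t in templates
            if t.user_id == uid and t.rep < transfer_reps
        ]
        _, knn, _ = transfer_contrastive(clf.net, batch, centroids, k=k)
        for t in eval_pool:
            if t.user_id == uid:
                post_hits[group_of[uid]].append(knn.predict(t).label == t.label)
    post = {g: float(np.mean(v)) for g, v in post_hits.items() if v}
    return {
        "zero_shot_A": zero_shot.get("A", np.nan),
        "zero_shot_B": zero_shot.get("B", np.nan),
        "gap_zero_shot": zero_shot.get("A", np.nan) - zero_shot.get("B", np.nan),
        "post_transfer_A": post.get("A", np.nan),
        "post_transfer_B": post.get("B", np.nan),
        "gap_post_transfer": post.get("A", np.nan) - post.get("B", np.nan),
        "n_test_users_B": float(n_b_test),
    }
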