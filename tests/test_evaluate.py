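"""Evaluation harness: splits, slicing, effect size, rejection."""

import numpy as np
import pandas as pd
import pytest

from emgdisc.evaluate import (
    EvalReport,
    SplitSpec,
    cohens_d,
    cohort_templates,
    gesture_subset_eval,
    out_of_set_rejection,
    rejection_curve,
    run_split,
    slice_by_attribute,
    sweep_subjects_reps,
    sweep_window_increment,
)
from emgdisc.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def loro_report(tiny_templates):
    return run_split(
        "mvlda", tiny_templates, SplitSpec("leave_one_repetition_out")
    )


class TestRunSplit:
    def test_loro_partition(self, tiny_templates, loro_report):
        # every template tested exactly once
        df = loro_report.predictions
        assert len(df) == len(tiny_templates)
        counts = df.groupby(["user_id", "true", "rep"]).size()
        assert (counts == 1).all()

    def test_accuracy_equals_recount(self, loro_report):
        df = loro_report.predictions
        recount = sum(
            1 for _, r in df.iterrows() if r["predicted"] == r["true"]
        ) / len(df)
        assert loro_report.accuracy == pytest.approx(recount)

    def test_cross_user_disjointness_enforced(self, tiny_templates):
        with pytest.raises(ValueError, match="overlap"):
            run_split(
                "mvlda", tiny_templates,
                SplitSpec("cross_user",
                          train_users=("user0000", "user0001"),
                          test_users=("user0001",)),
            )

    def test_cross_user_tests_only_held_out(self, tiny_templates):
        report = run_split(
            "mvlda", tiny_templates,
            SplitSpec("cross_user",
                      train_users=("user0000", "user0001", "user0002"),
                      test_users=("user0003",)),
        )
        assert set(report.predictions["user_id"]) == {"user0003"}


class TestSweeps:
    def test_subjects_reps_grid_shape_and_reproducibility(self,
                                                          tiny_templates):
        g1 = sweep_subjects_reps(
            tiny_templates, [2, 3], [2, 4], test_users=["user0003"],
            folds=2, pipeline_id="mvlda", seed=5,
        )
        g2 = sweep_subjects_reps(
            tiny_templates, [2, 3], [2, 4], test_users=["user0003"],
            folds=2, pipeline_id="mvlda", seed=5,
        )
        assert g1.shape == (2, 2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_insufficient_users_rejected(self, tiny_templates):
        with pytest.raises(ValueError, match="exceeds"):
            sweep_subjects_reps(
                tiny_templates, [99], [2], test_users=["user0003"],
                folds=1, pipeline_id="mvlda",
            )

    def test_window_increment_grid(self, tiny_templates):
        split = SplitSpec(
            "cross_user",
            train_users=("user0000", "user0001", "user0002"),
            test_users=("user0003",),
        )
        grid = sweep_window_increment(
            tiny_templates, [10, 20], [10, 20], split, pipeline_id="mvlda",
        )
        assert grid.shape == (2, 2)
        assert np.isfinite(grid.to_numpy()).all()

    def test_overlong_window_skipped_with_warning(self, tiny_templates):
        split = SplitSpec(
            "cross_user",
            train_users=("user0000", "user0001", "user0002"),
            test_users=("user0003",),
        )
        min_len = min(t.length for t in tiny_templates)
        with pytest.warns(UserWarning, match="skipped"):
            grid = sweep_window_increment(
                tiny_templates, [min_len + 1], [5], split,
                pipeline_id="mvlda",
            )
        assert np.isnan(grid.to_numpy()).all()


class TestSlicing:
    def test_single_valued_attribute_equals_overall(self, loro_report):
        df = loro_report.predictions.copy()
        df["site"] = "lab"
        report = EvalReport(df)
        sl = slice_by_attribute(report, "site")
        assert sl.loc["lab", "accuracy"] == pytest.approx(report.accuracy)

    def test_demographics_flow_into_report(self, loro_report):
        assert "group" in loro_report.predictions.columns

    def test_identical_groups_statistically_equal(self):
        """Two demographic groups with identical generative parameters score
        within 3 standard errors of each other."""
        cfg = CohortConfig(
            n_users=8, n_reps=5,
            demographic_mix={"group": {"A": 0.5, "B": 0.5}},
            seed=31,
        )
        temps = cohort_templates(generate_cohort(cfg))
        report = run_split(
            "mvlda", temps, SplitSpec("leave_one_repetition_out")
        )
        sl = slice_by_attribute(report, "group")
        if len(sl) == 2:
            pa, pb = sl["accuracy"].tolist()
            na, nb = sl["n"].tolist()
            se = np.sqrt(pa * (1 - pa) / na + pb * (1 - pb) / nb + 1e-12)
            assert abs(pa - pb) <= 3 * se + 1e-12

    def test_unknown_attribute(self, loro_report):
        with pytest.raises(ValueError, match="not in report"):
            slice_by_attribute(loro_report, "shoe_size")


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_unit_case(self):
        a = [1.0, 2.0, 0.0]  # mean 1, var 1
        b = [0.0, 1.0, -1.0]  # mean 0, var 1
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        import pingouin

        a = rng.normal(0.9, 0.05, size=12)
        b = rng.normal(0.8, 0.08, size=9)
        want = pingouin.compute_effsize(a, b, eftype="cohen")
        assert cohens_d(a, b) == pytest.approx(want, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestRejection:
    def _report(self, rows):
        df = pd.DataFrame(rows)
        df["correct"] = df["predicted"] == df["true"]
        return EvalReport(df)

    def test_zero_threshold_reproduces_overall(self, loro_report):
        curve = rejection_curve(loro_report, [0.0])
        assert curve.loc[0, "rejection_rate"] == 0.0
        assert curve.loc[0, "accepted_accuracy"] == pytest.approx(
            loro_report.accuracy
        )

    def test_above_one_rejects_everything(self, loro_report):
        curve = rejection_curve(loro_report, [1.01])
        assert curve.loc[0, "rejection_rate"] == 1.0
        assert np.isnan(curve.loc[0, "accepted_accuracy"])

    def test_counting_example(self):
        report = self._report([
            {"true": "a", "predicted": "a", "max_confidence": 0.8},
            {"true": "a", "predicted": "b", "max_confidence": 0.6},
            {"true": "c", "predicted": "c", "max_confidence": 0.9},
        ])
        curve = rejection_curve(report, [0.7])
        assert curve.loc[0, "rejection_rate"] == pytest.approx(1 / 3)
        assert curve.loc[0, "accepted_accuracy"] == 1.0

    def test_monotone_in_threshold(self, loro_report, rng):
        taus = np.sort(rng.uniform(0, 1.05, size=25))
        curve = rejection_curve(loro_report, taus.tolist())
        rates = curve["rejection_rate"].to_numpy()
        assert np.all(np.diff(rates) >= 0)

    def test_out_of_set_rates(self, tiny_templates):
        from emgdisc.classifiers import MVLDAClassifier

        clf = MVLDAClassifier().fit(tiny_templates)
        out = tiny_templates[:20]  # any templates exercise the mechanics
        taus = [0.0, 0.5, 0.9, 1.01]
        rates = out_of_set_rejection(clf, out, taus)["rejection_rate"]
        assert rates.iloc[0] == 0.0
        assert rates.iloc[-1] == 1.0
        assert (rates.diff().dropna() >= 0).all()


class TestGestureSubset:
    def test_subset_restricts_label_space(self, tiny_templates):
        report = gesture_subset_eval(
            tiny_templates, ("rest", "wave_in", "hand_close"),
            SplitSpec("leave_one_repetition_out"), pipeline_id="mvlda",
        )
        assert set(report.predictions["predicted"]) <= {
            "rest", "wave_in", "hand_close"
        }
        assert set(report.predictions["true"]) == {
            "rest", "wave_in", "hand_close"
        }

    def test_full_subset_equals_run_split(self, tiny_templates, loro_report):
        labels = tuple(sorted({t.label for t in tiny_templates}))
        report = gesture_subset_eval(
            tiny_templates, labels, SplitSpec("leave_one_repetition_out"),
            pipeline_id="mvlda",
        )
        assert report.accuracy == pytest.approx(loro_report.accuracy)

    def test_single_class_subset_rejected(self, tiny_templates):
        with pytest.raises(ValueError, match="at least 2"):
            gesture_subset_eval(
                tiny_templates, ("rest",),
                SplitSpec("leave_one_repetition_out"), pipeline_id="mvlda",
            )
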