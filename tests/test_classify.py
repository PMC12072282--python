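import numpy as np
import pytest

from glio_select import (
    MODEL_NAMES,
    ConfusionCounts,
    OmicsDataset,
    PreprocessSpec,
    accuracy,
    evaluate_subset,
    full_sweep_evaluation,
    make_fold_plan,
    select_best,
    soft_vote,
)
from glio_select.classify import (
    SweepReport,
    SweepReportRow,
    confusion_counts,
    evaluate_all_models,
    make_model,
)
from glio_select.weighting import SweepRow


class TestAccuracy:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (ConfusionCounts(3, 2, 0, 0), 1.0),
            (ConfusionCounts(0, 0, 2, 3), 0.0),
            (ConfusionCounts(45, 30, 5, 20), 0.75),
            (ConfusionCounts(1, 0, 0, 1), 0.5),
        ],
    )
    def test_closed_form(self, c, expected):
        assert accuracy(c) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_permutation_and_relabel_symmetry(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 40)
        y_pred = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        assert accuracy(confusion_counts(y_true, y_pred)) == accuracy(
            confusion_counts(y_true[perm], y_pred[perm])
        )
        # swapping class labels swaps TP<->TN and FP<->FN, accuracy unchanged
        assert accuracy(confusion_counts(1 - y_true, 1 - y_pred)) == accuracy(
            confusion_counts(y_true, y_pred)
        )


class TestSoftVote:
    def test_unanimity(self):
        assert soft_vote([np.array([0.9, 0.1])] * 5) == 0

    def test_tie_goes_to_class_zero(self):
        assert soft_vote([np.array([0.5, 0.5])] * 5) == 0

    def test_majority_by_probability_mass(self):
        members = [np.array([1.0, 0.0])] * 3 + [np.array([0.0, 1.0])] * 2
        assert soft_vote(members) == 0

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError, match="5 member"):
            soft_vote([np.array([0.5, 0.5])] * 4)


class TestEvaluateSubset:
    def test_perfectly_separable_feature(self, tiny_dataset):
        plan = make_fold_plan(tiny_dataset.labels, 2, seed=0)
        for model in ("LR", "SVM", "RF"):
            acc = evaluate_subset(tiny_dataset, {0}, model, plan)
            assert acc == 1.0

    def test_deterministic(self, planted_small):
        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        a = evaluate_subset(ds, {0, 1, 2}, "RF", plan)
        b = evaluate_subset(ds, {0, 1, 2}, "RF", plan)
        assert a == b

    def test_empty_panel_rejected(self, tiny_dataset):
        plan = make_fold_plan(tiny_dataset.labels, 2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate_subset(tiny_dataset, set(), "LR", plan)

    def test_all_models_route_matches_per_model_route(self, planted_small):
        # shared-fit evaluation (voting from summed member probabilities)
        # must equal the one-model-at-a-time route, including the
        # VotingClassifier-backed ensemble
        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        panel = frozenset({0, 1, 2, 50, 60})
        combined = evaluate_all_models(ds, panel, plan)
        for model in MODEL_NAMES:
            assert combined[model] == pytest.approx(
                evaluate_subset(ds, panel, model, plan), abs=1e-12
            ), model


class TestPooledAccuracy:
    def test_pooled_close_to_mean_of_folds(self, planted_small):
        from glio_select.classify import pooled_accuracy

        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        panel = {0, 1, 2}
        pooled = pooled_accuracy(ds, panel, "LR", plan)
        mean = evaluate_subset(ds, panel, "LR", plan)
        assert 0.0 <= pooled <= 1.0
        # equal fold sizes here, so pooled and mean-of-folds coincide
        assert pooled == pytest.approx(mean, abs=1e-12)


class TestFullSweepEvaluation:
    def test_cardinality_and_duplicate_rows(self, planted_small):
        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        sweeps = {
            "L2M1": [SweepRow(k, frozenset({0, 1})) for k in (1, 2)],
            "L1M2": [SweepRow(1, frozenset({0, 1, 2}))],
        }
        report = full_sweep_evaluation(ds, plan, sweeps, models=("LR", "KNN"))
        assert len(report.rows) == 3
        assert sum(len(r.accuracies) for r in report.rows) == 6
        # identical feature sets -> identical accuracies per model
        assert report.rows[0].accuracies == report.rows[1].accuracies
        for row in report.rows:
            for acc in row.accuracies.values():
                assert 0.0 <= acc <= 1.0


def _row(assignment, k, feats, accs):
    return SweepReportRow(
        assignment=assignment,
        k=k,
        feature_set=frozenset(feats),
        accuracies=dict(accs),
    )


class TestSelectBest:
    def test_accuracy_then_fewest_features(self):
        report = SweepReport(
            rows=(
                _row("L2M1", 3, range(10), {m: 0.98 for m in MODEL_NAMES}),
                _row("L2M1", 5, range(4), {m: 0.98 for m in MODEL_NAMES}),
                _row("L2M1", 6, range(2), {m: 0.95 for m in MODEL_NAMES}),
            )
        )
        best = select_best(report, [f"f{i}" for i in range(10)])
        assert best.k == 5 and best.n_features == 4
        assert best.mean_accuracy == pytest.approx(0.98)

    def test_single_row(self):
        report = SweepReport(
            rows=(_row("L2M1", 1, [0], {m: 0.7 for m in MODEL_NAMES}),)
        )
        best = select_best(report, ["f0"])
        assert best.k == 1 and best.feature_names == ("f0",)

    def test_model_order_breaks_ties(self):
        accs = {m: 0.5 for m in MODEL_NAMES}
        accs["KNN"] = 0.9
        accs["RF"] = 0.9
        report = SweepReport(rows=(_row("L2M1", 2, [0, 1], accs),))
        best = select_best(report, ["f0", "f1"])
        assert best.model == "KNN"  # KNN precedes RF in the canonical order

    def test_assignment_order_breaks_final_ties(self):
        accs = {m: 0.8 for m in MODEL_NAMES}
        report = SweepReport(
            rows=(
                _row("L1M2", 2, [0, 1], accs),
                _row("L2M1", 2, [2, 3], accs),
            )
        )
        assert select_best(report, ["a", "b", "c", "d"]).assignment == "L2M1"

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_best(SweepReport(rows=()), [])


def test_make_model_rejects_unknown():
    with pytest.raises(ValueError, match="unknown model"):
        make_model("MLP")


def test_null_labels_accuracy_near_class_share():
    # labels independent of features: mean CV accuracy should sit in a
    # calibration band around the majority-class share
    rng = np.random.default_rng(12)
    accs = []
    for rep in range(5):
        y = np.array([0] * 16 + [1] * 34)
        X = rng.normal(size=(50, 10))
        ds = OmicsDataset(
            [f"s{i}" for i in range(50)],
            [f"f{j}" for j in range(10)],
            X,
            y,
        )
        plan = make_fold_plan(y, 5, seed=rep)
        accs.append(evaluate_subset(ds, set(range(10)), "LR", plan))
    share = 34 / 50
    assert share - 0.15 <= np.mean(accs) <= share + 0.15
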