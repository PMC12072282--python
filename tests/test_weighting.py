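import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glio_select import (
    LASSO_FIRST,
    MRMR_FIRST,
    PreprocessSpec,
    RankAssignment,
    SelectorConfig,
    SelectorOutput,
    accumulate_weights,
    dynamic_rank_per_fold,
    make_fold_plan,
    run_fold_selections,
    threshold_sweep,
)
from glio_select.weighting import accumulate_weights_dynamic, weight_table_frame
from oracles import naive_accumulate, random_selections


def _sel(method, fold, feats):
    return SelectorOutput(
        method=method,
        fold_index=fold,
        selected=tuple(feats),
        scores=tuple(1.0 for _ in feats),
    )


# 2 folds; lasso selects {A,B} then {A}; mrmr selects {B,C} then {A,C}
A, B, C = 0, 1, 2
EXAMPLE = [
    _sel("lasso", 0, [A, B]),
    _sel("lasso", 1, [A]),
    _sel("mrmr", 0, [B, C]),
    _sel("mrmr", 1, [A, C]),
]


class TestRankAssignment:
    def test_weights_must_split_one_two(self):
        with pytest.raises(ValueError):
            RankAssignment(2, 2)
        with pytest.raises(ValueError):
            RankAssignment(1, 1)


class TestAccumulateWeights:
    def test_lasso_first_example(self):
        table = accumulate_weights(EXAMPLE, LASSO_FIRST)
        assert table.weights == {A: 5, B: 3, C: 2}

    def test_mrmr_first_example(self):
        table = accumulate_weights(EXAMPLE, MRMR_FIRST)
        assert table.weights == {A: 4, B: 3, C: 4}

    def test_empty_selections(self):
        sels = [_sel(m, f, []) for f in range(2) for m in ("lasso", "mrmr")]
        assert accumulate_weights(sels, LASSO_FIRST).weights == {}

    def test_duplicate_fold_method_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            accumulate_weights(EXAMPLE + [_sel("lasso", 0, [C])], LASSO_FIRST)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sels = random_selections(
                rng, int(rng.integers(1, 7)), int(rng.integers(1, 51))
            )
            for assignment in (LASSO_FIRST, MRMR_FIRST):
                assert (
                    accumulate_weights(sels, assignment).weights
                    == naive_accumulate(sels, assignment)
                )

    def test_swapped_assignments_sum_to_three_counts(self):
        rng = np.random.default_rng(1)
        sels = random_selections(rng, 5, 30)
        w21 = accumulate_weights(sels, LASSO_FIRST).weights
        w12 = accumulate_weights(sels, MRMR_FIRST).weights
        counts = {}
        for s in sels:
            for f in s.selected:
                counts[f] = counts.get(f, 0) + 1
        for f, c in counts.items():
            assert w21[f] + w12[f] == 3 * c


class TestThresholdSweep:
    def test_example_sizes(self):
        table = accumulate_weights(EXAMPLE, LASSO_FIRST)  # {A:5, B:3, C:2}
        rows = threshold_sweep(table)
        # direct enumeration of {f : weight >= k}: C (weight 2) leaves at
        # k=3, B (weight 3) at k=4, A (weight 5) persists to k=5
        assert [r.k for r in rows] == [1, 2, 3, 4, 5]
        assert [r.n_features for r in rows] == [3, 3, 2, 1, 1]
        assert rows[-1].feature_set == {A}

    def test_constant_table_full_set_everywhere(self):
        sels = [_sel("lasso", 0, [A, B]), _sel("mrmr", 0, [A, B])]
        rows = threshold_sweep(accumulate_weights(sels, LASSO_FIRST))
        assert all(r.feature_set == {A, B} for r in rows)

    def test_single_feature_weight_one(self):
        sels = [_sel("lasso", 0, [A]), _sel("mrmr", 0, [])]
        rows = threshold_sweep(accumulate_weights(sels, RankAssignment(1, 2)))
        assert len(rows) == 1 and rows[0].feature_set == {A}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nesting_property(self, seed):
        rng = np.random.default_rng(seed)
        n_folds = int(rng.integers(1, 7))
        sels = random_selections(rng, n_folds, int(rng.integers(1, 40)))
        table = accumulate_weights(sels, LASSO_FIRST)
        assert table.max_weight <= 3 * n_folds
        rows = threshold_sweep(table)
        for r1, r2 in zip(rows, rows[1:]):
            assert r2.feature_set <= r1.feature_set
            assert r2.n_features <= r1.n_features


class TestRunFoldSelections:
    def test_cardinality(self, planted_small):
        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        sels = run_fold_selections(
            ds, plan, SelectorConfig(lasso_alpha=0.01, mrmr_k=10)
        )
        assert len(sels) == 10
        assert sum(s.method == "lasso" for s in sels) == 5

    def test_planted_features_dominate_lasso_folds(self, planted_small):
        ds, truth = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        sels = run_fold_selections(
            ds, plan, SelectorConfig(lasso_alpha=0.01, mrmr_k=10)
        )
        lasso_hits = {
            f: sum(f in s.selected for s in sels if s.method == "lasso")
            for f in truth
        }
        assert sum(h >= 4 for h in lasso_hits.values()) >= 4

    def test_noise_labels_rarely_unanimous(self, planted_small):
        # folds share 80% of samples, so the most spuriously correlated
        # feature can survive all 10 (fold, method) selections even under
        # the null; the discriminating property is that unanimous features
        # are FEW under noise labels but include the whole planted panel
        # when a real signal exists
        from glio_select import ContinuousSpec, generate_continuous

        cfg = SelectorConfig(lasso_alpha=0.01, mrmr_k=10)
        null_unanimous = []
        for rep in range(5):
            ds, _ = generate_continuous(
                ContinuousSpec(
                    n_samples=60, n_features=150, n_informative=0, effect_size=0.0
                ),
                seed=100 + rep,
            )
            plan = make_fold_plan(ds.labels, 5, seed=rep)
            table = accumulate_weights(
                run_fold_selections(ds, plan, cfg), LASSO_FIRST
            )
            null_unanimous.append(
                sum(1 for w in table.weights.values() if w == 15)
            )
        assert max(null_unanimous) <= 3

        ds, truth = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        table = accumulate_weights(run_fold_selections(ds, plan, cfg), LASSO_FIRST)
        planted_unanimous = sum(1 for f in truth if table.weights.get(f, 0) == 15)
        assert planted_unanimous >= 4
        assert planted_unanimous > max(null_unanimous)


class TestDynamicRank:
    def _ds_plan_sels(self, planted_small):
        ds, _ = planted_small
        plan = make_fold_plan(ds.labels, 5, seed=0)
        sels = run_fold_selections(
            ds, plan, SelectorConfig(lasso_alpha=0.01, mrmr_k=10)
        )
        return ds, plan, sels

    def test_assignments_are_valid_per_fold(self, planted_small):
        ds, plan, sels = self._ds_plan_sels(planted_small)
        per_fold = dynamic_rank_per_fold(ds, plan, sels)
        assert set(per_fold) == set(range(5))
        for a in per_fold.values():
            assert {a.w_lasso, a.w_mrmr} == {1, 2}
        table = accumulate_weights_dynamic(sels, per_fold, 5)
        assert table.max_weight <= 15

    def test_empty_method_selection_gets_weight_one(self, planted_small):
        ds, plan, _ = self._ds_plan_sels(planted_small)
        sels = []
        for f in range(5):
            sels.append(_sel("lasso", f, [0, 1]))
            sels.append(_sel("mrmr", f, []))
        per_fold = dynamic_rank_per_fold(ds, plan, sels)
        assert all(a.w_mrmr == 1 for a in per_fold.values())


def test_weight_table_frame_columns(planted_small):
    ds, _ = planted_small
    plan = make_fold_plan(ds.labels, 5, seed=0)
    sels = run_fold_selections(ds, plan, SelectorConfig(lasso_alpha=0.01, mrmr_k=10))
    df = weight_table_frame(sels, ds.feature_names, 5)
    assert list(df.columns) == [
        "feature_name",
        "selection_count_lasso",
        "selection_count_mrmr",
        "weight_21",
        "weight_12",
    ]
    assert (
        df["weight_21"]
        == 2 * df["selection_count_lasso"] + df["selection_count_mrmr"]
    ).all()
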