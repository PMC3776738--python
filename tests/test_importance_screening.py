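"""Forest screening machinery: tasks, subsampling, OOB importance, decision rule."""

import numpy as np
import pandas as pd
import pytest

from pacscreen.importance_screening import (
    CONTROL_NAME,
    ScreeningConfig,
    SubsampleForest,
    fit_forest,
    flag_matrix,
    inject_control,
    majority_baseline,
    make_pair_tasks,
    permutation_importance,
    rank_matrix,
    run_screening,
    subsample_rows,
)
from pacscreen.pac_features import FEATURE_NAMES


class TestPairTasks:
    def test_default_tasks_in_canonical_order(self):
        tasks = make_pair_tasks(range(1, 8))
        assert [t.name for t in tasks] == [
            "Bronze-Gold",
            "Silver-Platinum",
            "Gold-Diamond",
            "Platinum-Masters",
            "Diamond-Professional",
            "Bronze-Professional",
        ]

    def test_adjacent_spacing_without_extreme_pair(self):
        cfg = ScreeningConfig(league_spacing=1, include_extreme_pair=False)
        tasks = make_pair_tasks(range(1, 8), cfg)
        assert [(t.league_lo, t.league_hi) for t in tasks] == [
            (i, i + 1) for i in range(1, 7)
        ]

    def test_two_league_table_single_task(self):
        tasks = make_pair_tasks({1, 3})
        assert [(t.league_lo, t.league_hi) for t in tasks] == [(1, 3)]
        assert tasks[0].name == "Bronze-Gold"

    def test_no_formable_pair_is_an_error(self):
        with pytest.raises(ValueError):
            make_pair_tasks({4}, ScreeningConfig(include_extreme_pair=False))


class TestMajorityBaseline:
    @pytest.mark.parametrize(
        "n_lo,n_hi,expected",
        [(347, 811, 0.7003), (553, 806, 0.5931), (50, 50, 0.5)],
    )
    def test_known_values(self, n_lo, n_hi, expected):
        assert majority_baseline(n_lo, n_hi) == pytest.approx(expected, abs=5e-5)

    def test_empty_task_rejected(self):
        with pytest.raises(ValueError):
            majority_baseline(0, 0)


class TestSubsampling:
    def test_full_fraction_is_identity_up_to_order(self, rng):
        table = pd.DataFrame({"a": np.arange(20)})
        out = subsample_rows(table, 1.0, rng)
        assert sorted(out["a"]) == list(range(20))

    def test_seventy_percent_of_hundred_gives_seventy_distinct(self, rng):
        table = pd.DataFrame({"a": np.arange(100)})
        out = subsample_rows(table, 0.7, rng)
        assert len(out) == 70 and out["a"].nunique() == 70

    def test_reproducible_from_seed(self):
        table = pd.DataFrame({"a": np.arange(50)})
        draws = [
            set(subsample_rows(table, 0.7, np.random.default_rng(5))["a"])
            for _ in range(2)
        ]
        assert draws[0] == draws[1]

    def test_empty_table_rejected(self, rng):
        with pytest.raises(ValueError):
            subsample_rows(pd.DataFrame({"a": []}), 0.7, rng)


class TestControlInjection:
    def test_adds_exactly_one_column(self, rng):
        table = pd.DataFrame(np.zeros((30, 15)), columns=FEATURE_NAMES)
        out = inject_control(table, rng)
        assert out.shape[1] == 16 and CONTROL_NAME in out.columns
        assert ((0 <= out[CONTROL_NAME]) & (out[CONTROL_NAME] <= 1)).all()

    def test_fresh_noise_per_seed(self):
        table = pd.DataFrame(np.zeros((30, 2)), columns=["a", "b"])
        c1 = inject_control(table, np.random.default_rng(1))[CONTROL_NAME]
        c2 = inject_control(table, np.random.default_rng(2))[CONTROL_NAME]
        assert not np.allclose(c1, c2)

    def test_name_collision_rejected(self, rng):
        table = pd.DataFrame({CONTROL_NAME: [1.0]})
        with pytest.raises(ValueError):
            inject_control(table, rng)

    def test_independent_of_labels(self):
        # Monte-Carlo: correlation with a label vector stays below 3/sqrt(n)
        n = 4000
        labels = np.repeat([0, 1], n // 2)
        table = pd.DataFrame({"a": np.zeros(n)})
        out = inject_control(table, np.random.default_rng(99))
        r = np.corrcoef(out[CONTROL_NAME], labels)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = y * 10.0 + rng.normal(0, 0.1, n)
    return pd.DataFrame({"signal": x}), y


class TestForest:
    def test_separable_data_near_perfect_oob(self):
        X, y = _separable()
        forest = fit_forest(X, y, ScreeningConfig(n_trees=50, mtry=1), seed=0)
        assert forest.oob_accuracy() > 0.95

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(ValueError):
            fit_forest(X, np.zeros(len(X)), ScreeningConfig(n_trees=10, mtry=1))

    def test_permuted_labels_fall_to_baseline(self):
        # over several seeds, mean OOB accuracy on label-shuffled data stays
        # within Monte-Carlo error of the 50% majority baseline
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
            y = rng.permutation(np.repeat([0, 1], 40))
            forest = fit_forest(X, y, ScreeningConfig(n_trees=60, mtry=2), seed=seed)
            accs.append(forest.oob_accuracy())
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < 3 * max(se, 0.01)

    def test_oob_predictions_deterministic_under_seed(self):
        X, y = _separable()
        p1 = fit_forest(X, y, ScreeningConfig(n_trees=30, mtry=1), seed=7).oob_predictions()
        p2 = fit_forest(X, y, ScreeningConfig(n_trees=30, mtry=1), seed=7).oob_predictions()
        assert np.array_equal(p1, p2)


class TestPermutationImportance:
    def test_constant_variable_zero_importance(self):
        X, y = _separable()
        X["flat"] = 3.14
        forest = fit_forest(X, y, ScreeningConfig(n_trees=30, mtry=1), seed=1)
        imp = permutation_importance(forest, X, y, 0)
        assert imp["flat"] == 0.0

    def test_sole_informative_variable_dominates(self):
        rng = np.random.default_rng(3)
        X, y = _separable(seed=3)
        for i in range(4):
            X[f"noise{i}"] = rng.normal(size=len(X))
        forest = fit_forest(X, y, ScreeningConfig(n_trees=60, mtry=2), seed=3)
        imp = permutation_importance(forest, X, y, 3)
        assert max(imp, key=imp.get) == "signal"

    def test_duplicated_informative_column_masks_itself(self):
        # permutation importance splits credit between correlated copies
        solo_scores, dup_scores = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 120
            y = np.repeat([0, 1], n // 2)
            sig = y * 2.0 + rng.normal(0, 1.0, n)
            noise = rng.normal(size=(n, 3))
            X1 = pd.DataFrame(np.column_stack([sig, noise]), columns=["s", "n1", "n2", "n3"])
            cfg = ScreeningConfig(n_trees=80, mtry=2)
            f1 = fit_forest(X1, y, cfg, seed=seed)
            solo_scores.append(permutation_importance(f1, X1, y, seed)["s"])
            X2 = X1.copy()
            X2["s_copy"] = sig
            f2 = fit_forest(X2, y, cfg, seed=seed)
            imp2 = permutation_importance(f2, X2, y, seed)
            dup_scores.append(imp2["s"])
        assert np.mean(dup_scores) < np.mean(solo_scores)


def _league_table(n_per_league=40, leagues=(1, 3), seed=0, shift=0.0, shifted="apm"):
    """Feature-shaped table of pure noise plus an optional league-mean shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for lg in leagues:
        block = pd.DataFrame(
            rng.normal(size=(n_per_league, len(FEATURE_NAMES))), columns=FEATURE_NAMES
        )
        if shift and lg == max(leagues):
            block[shifted] += shift
        block.insert(0, "league", lg)
        block.insert(0, "player_id", [f"L{lg}_{i}" for i in range(n_per_league)])
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


SMALL_CFG = ScreeningConfig(n_trees=40, mtry=4, n_reps=8, seed=5)


class TestRunScreening:
    def test_report_structure_and_rank_permutation(self):
        table = _league_table(seed=1, shift=2.0)
        result = run_screening(table, SMALL_CFG)
        assert [t.task.name for t in result.tasks] == ["Bronze-Gold"]
        tr = result.tasks[0]
        assert tr.importance.shape == (8, 16)
        assert sorted(tr.rank.values()) == list(range(1, 17))
        for var, flag in tr.flagged.items():
            assert flag == (tr.median_importance[var] > tr.critical_value)
        assert 0.0 <= tr.classification_rate <= 1.0
        assert tr.majority_baseline == 0.5

    def test_strong_signal_flagged_and_ranked_first(self):
        table = _league_table(seed=2, shift=2.0)
        tr = run_screening(table, SMALL_CFG).tasks[0]
        assert tr.rank["apm"] == 1 and tr.flagged["apm"]

    def test_bitwise_reproducible(self):
        table = _league_table(seed=3, shift=1.0)
        r1 = run_screening(table, SMALL_CFG)
        r2 = run_screening(table, SMALL_CFG)
        pd.testing.assert_frame_equal(r1.tasks[0].importance, r2.tasks[0].importance)
        assert r1.tasks[0].oob_accuracies == r2.tasks[0].oob_accuracies

    def test_balanced_mode_draws_exact_class_sizes(self):
        table = _league_table(n_per_league=50, seed=4, shift=1.0)
        cfg = ScreeningConfig(n_trees=20, mtry=4, n_reps=3, balanced_n=20, seed=1)
        tr = run_screening(table, cfg).tasks[0]
        assert tr.n_lo == tr.n_hi == 20
        assert tr.majority_baseline == 0.5

    def test_small_league_named_in_error(self):
        table = _league_table(n_per_league=8, seed=5)
        with pytest.raises(ValueError, match="Bronze"):
            run_screening(table, SMALL_CFG)

    def test_missing_league_column_rejected(self):
        table = _league_table().drop(columns=["league"])
        with pytest.raises(ValueError, match="league"):
            run_screening(table, SMALL_CFG)

    def test_zero_pac_rows_dropped_not_fatal(self):
        table = _league_table(seed=6, shift=1.5)
        table.loc[0, "action_latency_ms"] = np.nan
        tr = run_screening(table, SMALL_CFG).tasks[0]
        assert tr.n_dropped == 1 and tr.n_lo == 39

    def test_matrices_shapes(self):
        table = _league_table(seed=7, shift=1.0)
        result = run_screening(table, SMALL_CFG)
        rm = rank_matrix(result)
        fm = flag_matrix(result)
        assert rm.shape == (16, 1) and fm.shape == (16, 1)
        assert set(rm.index) == set(FEATURE_NAMES) | {CONTROL_NAME}
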