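"""Generator structure, determinism, parameter recovery, and gradients."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pacscreen.pac_features import build_feature_table, extract_features
from pacscreen.synthetic_cohort import (
    CohortSpec,
    DEFAULT_COHORT_SIZES,
    DEFAULT_LEAGUE_PARAMS,
    LeagueParams,
    base_params_table,
    calibrate_params,
    iter_cohort,
    params_table_from_flat,
    params_table_to_flat,
    simulate_cohort,
    simulate_player,
    validate_params,
    validate_params_table,
)
from pacscreen.telemetry_io import apply_game_filters


class TestParams:
    def test_default_table_satisfies_gradient_invariants(self):
        validate_params_table(DEFAULT_LEAGUE_PARAMS)
        validate_params_table(base_params_table())

    def test_jump_jitter_ordering_enforced(self):
        p = dataclasses.replace(base_params_table()[1], jump_scale=4.0)
        with pytest.raises(ValueError):
            validate_params(p)

    def test_flat_round_trip(self):
        table = base_params_table()
        back = params_table_from_flat(params_table_to_flat(table))
        assert back == table

    def test_cohort_spec_default_sizes_sum(self):
        assert sum(CohortSpec().league_sizes.values()) == 3360
        assert CohortSpec().league_sizes == DEFAULT_COHORT_SIZES


class TestSimulatePlayer:
    def test_zero_jitter_recovers_one_pov_per_fixation(self):
        p = dataclasses.replace(
            base_params_table()[4], jitter_scale=0.0, pac_action_fraction=0.0,
            hotkey_select_rate=0.0, hotkey_assign_rate=0.0,
            minimap_right_click_rate=0.0, minimap_attack_rate=0.0,
            worker_train_rate=0.0, unit_train_rate=0.0,
            complex_unit_train_rate=0.0, complex_ability_rate=0.0,
        )
        log, truth = simulate_player(p, 5, return_truth=True)
        _, diags = extract_features(log)
        assert diags["n_povs"] == truth["n_fixations"]

    def test_no_action_fixations_mean_zero_pacs(self):
        p = dataclasses.replace(
            base_params_table()[2],
            pac_action_fraction=0.0,
            hotkey_assign_rate=0.0,
            minimap_right_click_rate=0.0,
            minimap_attack_rate=0.0,
            worker_train_rate=0.0,
            unit_train_rate=0.0,
            complex_unit_train_rate=0.0,
            complex_ability_rate=0.0,
        )
        log = simulate_player(p, 11)
        feats, diags = extract_features(log)
        assert diags["n_pacs"] == 0
        assert np.isnan(feats["action_latency_ms"])

    def test_latency_parameter_recovery(self):
        # plant a 700 ms mean first-action latency with no background events
        # competing for "first action"; the extracted pooled mean must land
        # within 3 standard errors over 120 players
        p = dataclasses.replace(
            base_params_table()[4],
            first_action_latency_mean_ms=700.0,
            hotkey_assign_rate=0.0,
            minimap_right_click_rate=0.0,
            minimap_attack_rate=0.0,
            worker_train_rate=0.0,
            unit_train_rate=0.0,
            complex_unit_train_rate=0.0,
            complex_ability_rate=0.0,
        )
        means = []
        for seed in range(120):
            log = simulate_player(p, seed)
            feats, _ = extract_features(log)
            means.append(feats["action_latency_ms"])
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        # truncation at the dwell end shaves a little off the planted mean
        assert abs(grand - 700.0) < max(3 * se, 25.0)

    def test_every_log_passes_default_filters(self):
        table = base_params_table()
        for lg in (1, 4, 7):
            for seed in range(3):
                log = simulate_player(table[lg], seed, league=lg)
                assert apply_game_filters(log).accepted

    def test_deterministic_under_seed(self):
        p = base_params_table()[3]
        a = simulate_player(p, 42)
        b = simulate_player(p, 42)
        assert a.equals(b)


class TestCohort:
    SMALL = {1: 5, 2: 5, 3: 5, 4: 5, 5: 5, 6: 5, 7: 5}

    def test_league_counts_and_ids(self):
        spec = CohortSpec(league_sizes=dict(self.SMALL), seed=1)
        logs = simulate_cohort(spec)
        counts = pd.Series([l.league for l in logs]).value_counts()
        assert counts.to_dict() == self.SMALL
        assert len({l.player_id for l in logs}) == len(logs)

    def test_same_seed_identical_cohort(self):
        spec = CohortSpec(league_sizes={1: 3, 3: 3}, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert all(x.equals(y) for x, y in zip(a, b))

    def test_null_mode_labels_independent_of_features(self):
        sizes = {1: 60, 3: 60}
        spec = CohortSpec(league_sizes=sizes, seed=4, null_mode=True)
        table = build_feature_table(iter_cohort(spec))
        feats = table.drop(columns=["player_id", "league"]).dropna(axis=0)
        labels = table.loc[feats.index, "league"].to_numpy()
        n1 = (labels == 1).sum()
        n3 = (labels == 3).sum()
        # 3.5 sigma per variable: Bonferroni-style allowance for testing a
        # family of 15 variables at once (3 sigma each would false-alarm
        # on ~4% of cohorts)
        bound = 3.5 * np.sqrt(1 / n1 + 1 / n3)
        for col in feats.columns:
            x = feats[col].to_numpy()
            sd = x.std(ddof=1)
            if sd == 0:
                continue
            smd = (x[labels == 3].mean() - x[labels == 1].mean()) / sd
            assert abs(smd) < bound, col

    def test_latency_gradient_propagates_through_pipeline(self):
        sizes = {lg: 40 for lg in range(1, 8)}
        spec = CohortSpec(league_sizes=sizes, seed=7)
        table = build_feature_table(iter_cohort(spec))
        means = table.groupby("league")["action_latency_ms"].mean()
        assert list(means.index) == list(range(1, 8))
        assert (means.diff().dropna() < 0).all()


class TestCalibration:
    def test_already_met_targets_fixed_point(self):
        # measure once, then calibrate against those very values: the table
        # must come back unchanged after a single iteration
        base = base_params_table()
        sizes = {lg: max(4, n // 20) for lg, n in DEFAULT_COHORT_SIZES.items()}
        spec = CohortSpec(league_sizes=sizes, seed=21)
        feats = build_feature_table(iter_cohort(spec, base), diagnostics=True)
        measured = feats.drop(columns=["player_id", "league"]).mean()
        targets = {
            "action_latency_ms": float(measured["action_latency_ms"]),
            "apm": float(measured["apm"]),
        }
        fitted, report = calibrate_params(
            targets, base, cohort_scale=0.05, seed=21, tol=0.05
        )
        assert len(report) == 1
        assert fitted == base
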