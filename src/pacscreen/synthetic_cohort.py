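"""Skill-graded synthetic replay cohorts.

The original replay corpus is not redistributable, so this module generates
replay-like event streams whose *pipeline outputs* (PoV/PAC variables, event
rates, APM) reproduce the published pooled summary statistics of the 3360
player cohort.  Each player's stream alternates fixation epochs — a cluster
of slightly jittered screen moves dwelling at one map point — with
saccade-like jumps larger than the I-DT dispersion threshold.  Action-bearing
fixations receive a first action after a gamma-distributed latency followed
by a burst of generic commands; hotkey, minimap and production events arrive
as Poisson background at league-graded rates.

League structure: dwell/gap cycle times shrink from ~5 s (Bronze) to about
half that (Professional), first-action latencies strictly decrease with
league, and every event rate is non-decreasing in league.  Distribution
families (lognormal dwell, gamma latency and gap, Poisson counts) are chosen
for positivity and right skew.

The default parameter table is the output of :func:`calibrate_params` run
against the published pooled means; the pre-calibration gradient structure
is available from :func:`base_params_table`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .pac_features import FeatureConfig, build_feature_table
from .telemetry_io import ReplayLog

__all__ = [
    "LeagueParams",
    "CohortSpec",
    "DEFAULT_COHORT_SIZES",
    "DEFAULT_LEAGUE_PARAMS",
    "DEFAULT_CALIBRATION_TARGETS",
    "CalibrationError",
    "base_params_table",
    "validate_params",
    "validate_params_table",
    "simulate_player",
    "iter_cohort",
    "simulate_cohort",
    "calibrate_params",
    "params_table_to_flat",
    "params_table_from_flat",
]

logger = logging.getLogger(__name__)

#: Published league sample sizes (Bronze .. Professional).
DEFAULT_COHORT_SIZES = {1: 167, 2: 347, 3: 553, 4: 811, 5: 806, 6: 621, 7: 55}

MIN_GAME_MINUTES = 5.2  # keeps every log above the 25000-timestamp filter
MIN_DWELL_TS = 25
MIN_GAP_TS = 3
# Consecutive fixation centers stay at least this far apart so that the
# between-fixation transition move always violates the dispersion cap from
# both the closing and the opening fixation window.
MIN_JUMP = 16.0
N_ANCHORS = 3  # recurrently revisited map locations (bases, army)


@dataclass
class LeagueParams:
    """Generative parameters for one league."""

    fixation_dwell_mean_ts: float
    fixation_dwell_sd_ts: float
    fixation_gap_mean_ts: float
    jump_scale: float
    far_jump_prob: float
    home_prob: float
    jitter_scale: float
    move_interval_ts: float
    first_action_latency_mean_ms: float
    latency_shape: float
    actions_per_pac_mean: float
    pac_action_fraction: float
    hotkey_select_rate: float
    hotkey_assign_rate: float
    minimap_right_click_rate: float
    minimap_attack_rate: float
    worker_train_rate: float
    unit_train_rate: float
    complex_unit_train_rate: float
    complex_ability_rate: float
    n_hotkeys_used: int
    unique_unit_pool: int
    game_minutes_mean: float
    game_minutes_sd: float


RATE_FIELDS = (
    "hotkey_select_rate",
    "hotkey_assign_rate",
    "minimap_right_click_rate",
    "minimap_attack_rate",
    "worker_train_rate",
    "unit_train_rate",
    "complex_unit_train_rate",
    "complex_ability_rate",
)


def validate_params(p: LeagueParams, dispersion_threshold: float = 6.0) -> None:
    if not (p.jump_scale > dispersion_threshold > p.jitter_scale):
        raise ValueError(
            "need jump_scale > dispersion threshold > jitter_scale "
            f"({p.jump_scale}, {dispersion_threshold}, {p.jitter_scale})"
        )
    for name in RATE_FIELDS:
        if getattr(p, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    if (
        p.fixation_dwell_mean_ts <= 0
        or p.fixation_gap_mean_ts <= 0
        or p.move_interval_ts <= 0
        or p.first_action_latency_mean_ms <= 0
        or not 0 <= p.pac_action_fraction <= 1
        or p.actions_per_pac_mean < 1
        or p.game_minutes_mean < MIN_GAME_MINUTES
        or not 0 <= p.far_jump_prob <= 1
        or not 0 <= p.home_prob <= 1
        or p.far_jump_prob + p.home_prob > 1
    ):
        raise ValueError("invalid league parameters")


def validate_params_table(table: Mapping[int, LeagueParams]) -> None:
    """Check the monotone skill gradient across leagues 1..7."""
    leagues = sorted(table)
    for p in table.values():
        validate_params(p)
    lat = [table[lg].first_action_latency_mean_ms for lg in leagues]
    if not all(a > b for a, b in zip(lat, lat[1:])):
        raise ValueError("first-action latency must strictly decrease with league")
    for name in RATE_FIELDS + ("n_hotkeys_used",):
        vals = [getattr(table[lg], name) for lg in leagues]
        if not all(a <= b for a, b in zip(vals, vals[1:])):
            raise ValueError(f"{name} must be non-decreasing with league")


@dataclass
class CohortSpec:
    """Cohort composition and heterogeneity.

    League placement is a noisy measure of underlying skill: each player
    draws a continuous skill ``league + Normal(0, skill_sd)`` and their
    generative parameters are interpolated between league levels at that
    skill, so adjacent leagues overlap heavily while leagues two apart
    remain separable.  Professionals are a more homogeneous group and get
    their own, smaller spread.  ``trait_jitter_sd`` adds mean-preserving
    lognormal player-to-player variation on top of the skill axis.
    """

    league_sizes: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    seed: int = 0
    null_mode: bool = False
    skill_sd: float = 1.2
    pro_skill_sd: float = 0.4
    trait_jitter_sd: float = 0.12

    def __post_init__(self):
        if any(n < 0 for n in self.league_sizes.values()):
            raise ValueError("league sizes must be >= 0")
        if sum(self.league_sizes.values()) == 0:
            raise ValueError("empty cohort")
        if self.skill_sd < 0 or self.pro_skill_sd < 0 or self.trait_jitter_sd < 0:
            raise ValueError("heterogeneity parameters must be >= 0")


def base_params_table() -> dict[int, LeagueParams]:
    """Pre-calibration parameter table.

    Cycle times interpolate geometrically from a 5 s Bronze perception-action
    cycle to half that for Professionals; latency decreases ~7% per league;
    event rates rise geometrically at per-rate factors chosen so the
    size-weighted pooled rate lands near its published value.
    """
    table = {}
    for lg in range(1, 8):
        i = lg - 1
        cycle_s = 5.0 * 2.0 ** (-i / 6.0)
        dwell_ts = 0.874 * cycle_s / 0.0115
        gap_ts = 0.126 * cycle_s / 0.0115
        table[lg] = LeagueParams(
            fixation_dwell_mean_ts=dwell_ts,
            fixation_dwell_sd_ts=0.35 * dwell_ts,
            fixation_gap_mean_ts=gap_ts,
            jump_scale=18.0,
            far_jump_prob=0.03,
            home_prob=0.57,
            jitter_scale=0.8,
            move_interval_ts=dwell_ts / 2.6,
            first_action_latency_mean_ms=900.0 * 0.93**i,
            latency_shape=4.0,
            actions_per_pac_mean=4.6,
            pac_action_fraction=0.97,
            hotkey_select_rate=2.611 * 1.8**i,
            hotkey_assign_rate=0.9389 * 1.25**i,
            minimap_right_click_rate=0.9719 * 1.25**i,
            minimap_attack_rate=0.2129 * 1.3**i,
            worker_train_rate=3.789 * 1.12**i,
            unit_train_rate=1.264 * 1.15**i,
            complex_unit_train_rate=0.09944 * 1.4**i,
            complex_ability_rate=0.23306 * 1.4**i,
            n_hotkeys_used=(2, 3, 3, 4, 5, 6, 8)[i],
            unique_unit_pool=(2, 3, 4, 4, 5, 5, 6)[i],
            game_minutes_mean=8.0,
            game_minutes_sd=1.5,
        )
    return table


#: Fields interpolated geometrically along the continuous skill axis.
_SKILL_LOG_FIELDS = (
    "fixation_dwell_mean_ts",
    "fixation_dwell_sd_ts",
    "fixation_gap_mean_ts",
    "move_interval_ts",
    "first_action_latency_mean_ms",
) + RATE_FIELDS

#: Fields receiving independent mean-preserving trait jitter.
_TRAIT_JITTER_FIELDS = ("first_action_latency_mean_ms",) + RATE_FIELDS


def interpolate_params(
    table: Mapping[int, LeagueParams], skill: float
) -> LeagueParams:
    """League parameters at a continuous skill level.

    Positive graded fields interpolate log-linearly between the bracketing
    league levels (matching the geometric league gradients); discrete pool
    sizes round a linear interpolation; ungraded fields interpolate
    linearly.  Skill is clamped to the table's league range.
    """
    leagues = sorted(table)
    skill = float(np.clip(skill, leagues[0], leagues[-1]))
    lo = int(np.floor(skill))
    hi = min(lo + 1, leagues[-1])
    if lo not in table or hi not in table:
        raise ValueError(f"skill {skill} outside the parameter table")
    if lo == hi:
        return replace(table[lo])
    w = skill - lo
    p_lo, p_hi = table[lo], table[hi]
    kwargs = {}
    for name in LeagueParams.__dataclass_fields__:
        a, b = getattr(p_lo, name), getattr(p_hi, name)
        if name in ("n_hotkeys_used", "unique_unit_pool"):
            kwargs[name] = int(round((1 - w) * a + w * b))
        elif name in _SKILL_LOG_FIELDS and a > 0 and b > 0:
            kwargs[name] = float(a ** (1 - w) * b**w)
        else:
            kwargs[name] = float((1 - w) * a + w * b)
    return LeagueParams(**kwargs)


def draw_player_params(
    table: Mapping[int, LeagueParams],
    league: int,
    rng: np.random.Generator,
    spec: CohortSpec,
) -> LeagueParams:
    """Interpolated parameters for one player of a given league."""
    sd = spec.pro_skill_sd if league == max(table) else spec.skill_sd
    skill = league + rng.normal(0.0, sd)
    p = interpolate_params(table, skill)
    if spec.trait_jitter_sd > 0:
        s = spec.trait_jitter_sd
        jitter = {
            name: getattr(p, name)
            * float(rng.lognormal(-0.5 * s * s, s))
            for name in _TRAIT_JITTER_FIELDS
        }
        p = replace(p, **jitter)
    return p


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def simulate_player(
    params: LeagueParams,
    seed,
    player_id: str = "p0",
    league: int = 1,
    map_size: float = 128.0,
    ms_per_timestamp: float = 11.5,
    return_truth: bool = False,
):
    """Generate one player's replay-like event stream.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    With ``return_truth=True`` also returns the planted ground truth
    (fixation count, action-bearing count, realized first-action latencies).
    """
    validate_params(params)
    rng = np.random.default_rng(seed)
    minutes = max(
        MIN_GAME_MINUTES, rng.normal(params.game_minutes_mean, params.game_minutes_sd)
    )
    max_t = int(round(minutes * 60000.0 / ms_per_timestamp))

    # Fixation timeline: alternating dwell / gap, truncated at the game end.
    mu, sigma = _lognormal_params(
        params.fixation_dwell_mean_ts, params.fixation_dwell_sd_ts
    )
    est = int(max_t / (params.fixation_dwell_mean_ts + params.fixation_gap_mean_ts) * 1.5) + 16
    dwell = np.maximum(MIN_DWELL_TS, np.round(rng.lognormal(mu, sigma, est))).astype(
        np.int64
    )
    gap = np.maximum(
        MIN_GAP_TS, np.round(rng.gamma(2.0, params.fixation_gap_mean_ts / 2.0, est))
    ).astype(np.int64)
    start = np.empty(est, dtype=np.int64)
    start[0] = gap[0] // 2
    np.cumsum(dwell[:-1] + gap[:-1], out=start[1:])
    start[1:] += start[0]
    keep = start + dwell + 4 < max_t
    n_fix = int(keep.sum())
    start, dwell, gap = start[:n_fix], dwell[:n_fix], gap[:n_fix]

    # Fixation centers: a reflected random walk mixed with returns to a few
    # recurrently attended anchor locations (bases) and rare far relocations.
    # Consecutive centers are kept >= MIN_JUMP apart so every between-
    # fixation jump clearly violates the dispersion cap.
    margin = 4.0 * params.jitter_scale + 1.0
    lo, hi = margin, map_size - margin
    anchors = rng.uniform(lo, hi, (N_ANCHORS, 2))
    centers = np.empty((n_fix, 2))
    pos = anchors[0] + rng.normal(0.0, 2.0, 2)
    lengths = np.maximum(MIN_JUMP, rng.gamma(2.0, params.jump_scale / 2.0, n_fix))
    angles = rng.uniform(0.0, 2.0 * np.pi, n_fix)
    moves_kind = rng.random(n_fix)
    far_targets = rng.uniform(lo, hi, (n_fix, 2))
    anchor_pick = rng.integers(0, N_ANCHORS, n_fix)
    anchor_noise = rng.normal(0.0, 2.0, (n_fix, 2))
    for i in range(n_fix):
        centers[i] = pos
        if moves_kind[i] < params.far_jump_prob:
            target = far_targets[i]
        elif moves_kind[i] < params.far_jump_prob + params.home_prob:
            target = anchors[anchor_pick[i]] + anchor_noise[i]
        else:
            target = pos + lengths[i] * np.array([np.cos(angles[i]), np.sin(angles[i])])
        delta = target - pos
        norm = float(np.hypot(delta[0], delta[1]))
        if norm < MIN_JUMP:
            if norm < 1e-9:
                delta = np.array([np.cos(angles[i]), np.sin(angles[i])])
                norm = 1.0
            target = pos + delta * (MIN_JUMP / norm)
        # reflect back into the playable area
        for d in range(2):
            if target[d] < lo:
                target[d] = min(hi, 2 * lo - target[d])
            elif target[d] > hi:
                target[d] = max(lo, 2 * hi - target[d])
        pos = target

    t_parts: list[np.ndarray] = []
    kind_parts: list[np.ndarray] = []
    x_parts: list[np.ndarray] = []
    y_parts: list[np.ndarray] = []

    # Within-fixation screen moves: endpoints plus Poisson-thinned extras.
    move_t: list[int] = []
    move_xy: list[np.ndarray] = []
    for i in range(n_fix):
        times = [int(start[i]), int(start[i] + dwell[i])]
        n_extra = rng.poisson(dwell[i] / params.move_interval_ts)
        if n_extra:
            times.extend(
                int(v) for v in start[i] + rng.integers(1, dwell[i], n_extra)
            )
        times.sort()
        jit = rng.uniform(-params.jitter_scale, params.jitter_scale, (len(times), 2))
        move_t.extend(times)
        move_xy.append(centers[i] + jit)
        # Transition move shortly after the fixation ends, partway along the
        # jump to the next center: it violates the dispersion cap and closes
        # the PoV near the true dwell end.
        if i + 1 < n_fix and gap[i] >= 6:
            move_t.append(int(start[i] + dwell[i] + 2))
            trans = centers[i] + 0.5 * (centers[i + 1] - centers[i]) + rng.normal(
                0.0, 1.0, 2
            )
            move_xy.append(trans.reshape(1, 2))
    xy = np.clip(np.vstack(move_xy), 0.0, map_size) if move_xy else np.empty((0, 2))
    t_parts.append(np.asarray(move_t, dtype=np.int64))
    kind_parts.append(np.full(len(move_t), "screen_move", dtype=object))
    x_parts.append(xy[:, 0])
    y_parts.append(xy[:, 1])

    # Action bursts inside action-bearing fixations.
    bearing = rng.random(n_fix) < params.pac_action_fraction
    latencies_ms: list[float] = []
    act_t: list[int] = []
    scale_ms = params.first_action_latency_mean_ms / params.latency_shape
    for i in np.flatnonzero(bearing):
        lat_ts = rng.gamma(params.latency_shape, scale_ms) / ms_per_timestamp
        first = int(start[i] + np.clip(lat_ts, 1, max(1, dwell[i] - 2)))
        latencies_ms.append((first - start[i]) * ms_per_timestamp)
        burst = [first]
        n_more = rng.poisson(max(0.0, params.actions_per_pac_mean - 1.0))
        if n_more and first < start[i] + dwell[i]:
            burst.extend(
                int(v)
                for v in rng.integers(first, start[i] + dwell[i], n_more)
            )
        act_t.extend(burst)
    t_parts.append(np.asarray(act_t, dtype=np.int64))
    kind_parts.append(np.full(len(act_t), "command", dtype=object))
    x_parts.append(np.full(len(act_t), np.nan))
    y_parts.append(np.full(len(act_t), np.nan))

    # Poisson background events, uniform in time.
    hot_ids: dict[str, np.ndarray] = {}
    unit_tokens: dict[str, list] = {}
    bg_kinds = {
        "hotkey_select": params.hotkey_select_rate,
        "hotkey_assign": params.hotkey_assign_rate,
        "minimap_right_click": params.minimap_right_click_rate,
        "minimap_attack": params.minimap_attack_rate,
        "worker_train": params.worker_train_rate,
        "unit_train": params.unit_train_rate,
        "complex_unit_train": params.complex_unit_train_rate,
        "complex_ability": params.complex_ability_rate,
    }
    for kind, per_min in bg_kinds.items():
        n = rng.poisson(per_min * minutes)
        t_parts.append(rng.integers(0, max_t, n).astype(np.int64))
        kind_parts.append(np.full(n, kind, dtype=object))
        x_parts.append(np.full(n, np.nan))
        y_parts.append(np.full(n, np.nan))
        if kind in ("hotkey_select", "hotkey_assign"):
            hot_ids[kind] = rng.integers(0, params.n_hotkeys_used, n)
        elif kind == "unit_train":
            unit_tokens[kind] = [
                f"unit_{v:02d}" for v in rng.integers(0, params.unique_unit_pool, n)
            ]
        elif kind == "worker_train":
            unit_tokens[kind] = ["worker"] * n
        elif kind == "complex_unit_train":
            unit_tokens[kind] = [f"complex_{v}" for v in rng.integers(0, 2, n)]

    t_all = np.concatenate(t_parts)
    kind_all = np.concatenate(kind_parts)
    x_all = np.concatenate(x_parts)
    y_all = np.concatenate(y_parts)
    hk_all = np.full(len(t_all), np.nan)
    ut_all = np.full(len(t_all), None, dtype=object)
    offset = 0
    for kinds_arr, t_arr in zip(kind_parts, t_parts):
        n = len(t_arr)
        if n:
            kind = kinds_arr[0]
            if kind in hot_ids:
                hk_all[offset : offset + n] = hot_ids[kind]
            if kind in unit_tokens:
                ut_all[offset : offset + n] = unit_tokens[kind]
        offset += n

    order = np.argsort(t_all, kind="stable")
    events = pd.DataFrame(
        {
            "t": t_all[order],
            "kind": kind_all[order],
            "x": x_all[order],
            "y": y_all[order],
            "hotkey_id": hk_all[order],
            "unit_type": ut_all[order],
        }
    )
    log = ReplayLog(
        player_id=player_id,
        league=league,
        events=events,
        max_timestamp=max_t,
        player_count=2,
    )
    if not return_truth:
        return log
    truth = {
        "n_fixations": n_fix,
        "n_action_fixations": int(bearing.sum()),
        "planted_latencies_ms": latencies_ms,
        "minutes": minutes,
    }
    return log, truth


def iter_cohort(
    spec: CohortSpec,
    params_by_league: Mapping[int, LeagueParams] | None = None,
) -> Iterator[ReplayLog]:
    """Lazily generate a cohort, deterministic under ``spec.seed``.

    In ``null_mode`` each player's generative parameters are drawn from the
    size-weighted mixture over leagues while the league *label* keeps the
    requested sizes, so labels carry no signal about behavior.
    """
    table = params_by_league or DEFAULT_LEAGUE_PARAMS
    leagues = sorted(lg for lg, n in spec.league_sizes.items() if n > 0)
    sizes = np.array([spec.league_sizes[lg] for lg in leagues], dtype=float)
    weights = sizes / sizes.sum()
    for lg in leagues:
        for i in range(spec.league_sizes[lg]):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(lg, i))
            param_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(lg, i, 1))
            )
            if spec.null_mode:
                src = leagues[param_rng.choice(len(leagues), p=weights)]
            else:
                src = lg
            params = draw_player_params(table, src, param_rng, spec)
            yield simulate_player(params, ss, player_id=f"L{lg}_{i:04d}", league=lg)


def simulate_cohort(
    spec: CohortSpec,
    params_by_league: Mapping[int, LeagueParams] | None = None,
) -> list[ReplayLog]:
    """Materialize :func:`iter_cohort` as a list."""
    return list(iter_cohort(spec, params_by_league))


# ---------------------------------------------------------------------------
# Calibration

#: Published pooled (all-league) means and SDs used as calibration anchors.
#: ``total_inputs`` is the published mean number of inputs per game.
DEFAULT_CALIBRATION_TARGETS: dict[str, tuple[float, float]] = {
    "action_latency_ms": (719.94, 217.3),
    "actions_per_pac": (5.27, 1.49),
    "apm": (117.05, 51.95),
    "gap_between_pacs_s": (0.46, 0.2),
    "hotkey_selects_per_min": (22.83, 28.07),
    "hotkey_assigns_per_min": (1.99, 1.19),
    "minimap_attacks_per_min": (0.52, 0.88),
    "minimap_rightclicks_per_min": (2.06, 2.0),
    "workers_per_min": (5.48, 2.76),
    "map_explored_pct": (22.13, 7.43),
    "complex_units_per_min": (0.32, 0.59),
    "complex_abilities_per_min": (0.75, 1.4),
    "total_inputs": (1635.0, float("nan")),
}

#: Direct rate knobs: target variable -> LeagueParams field.
_RATE_KNOBS = {
    "hotkey_selects_per_min": "hotkey_select_rate",
    "hotkey_assigns_per_min": "hotkey_assign_rate",
    "minimap_attacks_per_min": "minimap_attack_rate",
    "minimap_rightclicks_per_min": "minimap_right_click_rate",
    "workers_per_min": "worker_train_rate",
    "complex_units_per_min": "complex_unit_train_rate",
    "complex_abilities_per_min": "complex_ability_rate",
}


class CalibrationError(RuntimeError):
    def __init__(self, residuals: dict[str, float], report: list[dict]):
        worst = max(residuals, key=lambda k: abs(residuals[k]))
        super().__init__(
            f"calibration did not converge; worst residual {worst} = "
            f"{residuals[worst]:+.3f} (relative)"
        )
        self.residuals = residuals
        self.report = report


def _apply_factor(table, update):
    """Multiplicatively update a field in every league's params."""
    field_name, factor = update
    return {
        lg: replace(p, **{field_name: getattr(p, field_name) * factor})
        for lg, p in table.items()
    }


def _measure(table, sizes, seed, feature_cfg):
    spec = CohortSpec(league_sizes=sizes, seed=seed)
    feats = build_feature_table(
        iter_cohort(spec, table), cfg=feature_cfg, diagnostics=True
    )
    measured = feats[
        [c for c in feats.columns if c not in ("player_id", "league")]
    ].mean()
    return measured, feats


def calibrate_params(
    targets: Mapping[str, tuple[float, float] | float] | None = None,
    base: Mapping[int, LeagueParams] | None = None,
    league_sizes: Mapping[int, int] | None = None,
    cohort_scale: float = 0.15,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 0.02,
    damping: float = 0.8,
    feature_cfg: FeatureConfig | None = None,
) -> tuple[dict[int, LeagueParams], list[dict]]:
    """Iterative proportional calibration of the generator to pooled targets.

    Each iteration simulates a scaled-down cohort, extracts features, and
    rescales one mapped parameter per off-target quantity by
    ``(target / measured) ** damping`` uniformly across leagues, preserving
    the league gradients.  Converges when every targeted pooled mean is
    within ``tol`` (relative); raises :class:`CalibrationError` otherwise.
    """
    raw_targets = targets or DEFAULT_CALIBRATION_TARGETS
    tgt = {
        k: (v[0] if isinstance(v, (tuple, list)) else float(v))
        for k, v in raw_targets.items()
    }
    table = dict(base or base_params_table())
    sizes = {
        lg: max(4, int(round(n * cohort_scale)))
        for lg, n in (league_sizes or DEFAULT_COHORT_SIZES).items()
    }
    report: list[dict] = []
    residuals: dict[str, float] = {}
    resid_hist: list[dict[str, float]] = []
    for it in range(max_iter):
        measured, _ = _measure(table, sizes, seed + it, feature_cfg)
        resid_hist.append(
            {k: float(measured[k] / t - 1.0) for k, t in tgt.items() if k in measured}
        )
        # Judge convergence (and steer) on the mean of the last few cohorts:
        # single-cohort means of the rare event rates are noisier than tol.
        window = resid_hist[-3:]
        residuals = {
            k: float(np.mean([w[k] for w in window])) for k in resid_hist[-1]
        }
        max_err = max(abs(r) for r in residuals.values())
        report.append(
            {
                "iteration": it,
                "measured": {k: float(measured[k]) for k in residuals},
                "smoothed_rel_err": dict(residuals),
                "max_rel_err": max_err,
            }
        )
        logger.info("calibration iter %d: max relative error %.4f", it, max_err)
        if max_err <= tol:
            return table, report
        step = damping * max(0.3, 0.9**it)
        for name, res in residuals.items():
            if abs(res) <= tol * 0.5:
                continue
            f = (1.0 / (1.0 + res)) ** step
            if name == "action_latency_ms":
                table = _apply_factor(table, ("first_action_latency_mean_ms", f))
            elif name == "actions_per_pac":
                table = {
                    lg: replace(
                        p,
                        actions_per_pac_mean=1.0 + (p.actions_per_pac_mean - 1.0) * f,
                    )
                    for lg, p in table.items()
                }
            elif name == "apm":
                # faster perception-action cycling raises APM at fixed burst size
                inv = 1.0 / f
                for fld in (
                    "fixation_dwell_mean_ts",
                    "fixation_dwell_sd_ts",
                    "fixation_gap_mean_ts",
                    "move_interval_ts",
                ):
                    table = _apply_factor(table, (fld, inv))
            elif name == "gap_between_pacs_s":
                table = _apply_factor(table, ("fixation_gap_mean_ts", f))
            elif name == "total_inputs":
                table = _apply_factor(table, ("move_interval_ts", 1.0 / f))
            elif name == "map_explored_pct":
                # revisiting anchors concentrates PoV centroids, so the
                # home-return probability moves exploration inversely
                table = {
                    lg: replace(
                        p,
                        home_prob=float(
                            np.clip(p.home_prob / f, 0.0, 0.9 - p.far_jump_prob)
                        ),
                    )
                    for lg, p in table.items()
                }
            elif name in _RATE_KNOBS:
                table = _apply_factor(table, (_RATE_KNOBS[name], f))
            # quantities without a knob (e.g. pacs_per_min) are reported only
    raise CalibrationError(residuals, report)


# ---------------------------------------------------------------------------
# Flat parameter-table serialization (key = "<league>.<parameter>")


def params_table_to_flat(table: Mapping[int, LeagueParams]) -> dict[str, float]:
    flat = {}
    for lg in sorted(table):
        p = table[lg]
        for name in LeagueParams.__dataclass_fields__:
            flat[f"{lg}.{name}"] = getattr(p, name)
    return flat


def params_table_from_flat(flat: Mapping[str, float]) -> dict[int, LeagueParams]:
    by_league: dict[int, dict] = {}
    for key, value in flat.items():
        lg_str, _, name = key.partition(".")
        by_league.setdefault(int(lg_str), {})[name] = value
    table = {}
    for lg, kwargs in by_league.items():
        kwargs["n_hotkeys_used"] = int(kwargs["n_hotkeys_used"])
        kwargs["unique_unit_pool"] = int(kwargs["unique_unit_pool"])
        table[lg] = LeagueParams(**kwargs)
    return table


#: Calibrated default parameter table: one converged run of
#: :func:`calibrate_params` against ``DEFAULT_CALIBRATION_TARGETS`` at 30%
#: cohort scale, frozen as literals so the default cohort is stable.
DEFAULT_LEAGUE_PARAMS: dict[int, LeagueParams] = {
    1: LeagueParams(
        fixation_dwell_mean_ts=373.464,
        fixation_dwell_sd_ts=130.712,
        fixation_gap_mean_ts=53.771,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=178.147,
        first_action_latency_mean_ms=981.109,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=2.26028,
        hotkey_assign_rate=0.921192,
        minimap_right_click_rate=0.952266,
        minimap_attack_rate=0.205406,
        worker_train_rate=3.74732,
        unit_train_rate=1.264,
        complex_unit_train_rate=0.0946317,
        complex_ability_rate=0.219376,
        n_hotkeys_used=2,
        unique_unit_pool=2,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    2: LeagueParams(
        fixation_dwell_mean_ts=332.719,
        fixation_dwell_sd_ts=116.452,
        fixation_gap_mean_ts=47.9045,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=158.711,
        first_action_latency_mean_ms=912.431,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=4.0685,
        hotkey_assign_rate=1.15149,
        minimap_right_click_rate=1.19033,
        minimap_attack_rate=0.267028,
        worker_train_rate=4.197,
        unit_train_rate=1.4536,
        complex_unit_train_rate=0.132484,
        complex_ability_rate=0.307127,
        n_hotkeys_used=3,
        unique_unit_pool=3,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    3: LeagueParams(
        fixation_dwell_mean_ts=296.419,
        fixation_dwell_sd_ts=103.747,
        fixation_gap_mean_ts=42.6781,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=141.395,
        first_action_latency_mean_ms=848.561,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=7.3233,
        hotkey_assign_rate=1.43936,
        minimap_right_click_rate=1.48792,
        minimap_attack_rate=0.347136,
        worker_train_rate=4.70064,
        unit_train_rate=1.67164,
        complex_unit_train_rate=0.185478,
        complex_ability_rate=0.429978,
        n_hotkeys_used=3,
        unique_unit_pool=4,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    4: LeagueParams(
        fixation_dwell_mean_ts=264.079,
        fixation_dwell_sd_ts=92.4276,
        fixation_gap_mean_ts=38.0219,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=125.969,
        first_action_latency_mean_ms=789.162,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=13.1819,
        hotkey_assign_rate=1.7992,
        minimap_right_click_rate=1.8599,
        minimap_attack_rate=0.451277,
        worker_train_rate=5.26472,
        unit_train_rate=1.92239,
        complex_unit_train_rate=0.259669,
        complex_ability_rate=0.601969,
        n_hotkeys_used=4,
        unique_unit_pool=4,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    5: LeagueParams(
        fixation_dwell_mean_ts=235.268,
        fixation_dwell_sd_ts=82.3437,
        fixation_gap_mean_ts=33.8736,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=112.226,
        first_action_latency_mean_ms=733.92,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=23.7275,
        hotkey_assign_rate=2.249,
        minimap_right_click_rate=2.32487,
        minimap_attack_rate=0.586661,
        worker_train_rate=5.89649,
        unit_train_rate=2.21074,
        complex_unit_train_rate=0.363537,
        complex_ability_rate=0.842756,
        n_hotkeys_used=5,
        unique_unit_pool=5,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    6: LeagueParams(
        fixation_dwell_mean_ts=209.6,
        fixation_dwell_sd_ts=73.3599,
        fixation_gap_mean_ts=30.178,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=99.9816,
        first_action_latency_mean_ms=682.546,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=42.7095,
        hotkey_assign_rate=2.81125,
        minimap_right_click_rate=2.90609,
        minimap_attack_rate=0.762659,
        worker_train_rate=6.60407,
        unit_train_rate=2.54236,
        complex_unit_train_rate=0.508952,
        complex_ability_rate=1.17986,
        n_hotkeys_used=6,
        unique_unit_pool=5,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
    7: LeagueParams(
        fixation_dwell_mean_ts=186.732,
        fixation_dwell_sd_ts=65.3562,
        fixation_gap_mean_ts=26.8855,
        jump_scale=18,
        far_jump_prob=0.03,
        home_prob=0.606281,
        jitter_scale=0.8,
        move_interval_ts=89.0735,
        first_action_latency_mean_ms=634.768,
        latency_shape=4,
        actions_per_pac_mean=4.67791,
        pac_action_fraction=0.97,
        hotkey_select_rate=76.877,
        hotkey_assign_rate=3.51407,
        minimap_right_click_rate=3.63261,
        minimap_attack_rate=0.991457,
        worker_train_rate=7.39655,
        unit_train_rate=2.92371,
        complex_unit_train_rate=0.712533,
        complex_ability_rate=1.6518,
        n_hotkeys_used=8,
        unique_unit_pool=6,
        game_minutes_mean=8,
        game_minutes_sd=1.5,
    ),
}
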