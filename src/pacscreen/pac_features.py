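"""Perception-action-cycle identification and per-player feature extraction.

A PAC (Perception-Action-Cycle) is a PoV containing at least one qualifying
action; hotkey selects and screen moves never qualify.  Action latency — the
delay from PoV onset to the first qualifying action — is the telemetry
analogue of laboratory reaction time.

Fifteen per-player variables are computed: four PAC variables (action
latency, actions per PAC, PACs per minute, gap between PACs), hotkey usage
(selects and assigns per minute, unique hotkeys), attentional-control
measures (minimap right-clicks and attacks per minute, fraction of the map
explored), production measures (workers per minute, unique units, complex
units and complex abilities per minute) and overall actions per minute.

Per-minute rates use the game length ``max_timestamp * ms_per_timestamp``.
Players with no PAC get their PAC-derived fields missing-coded (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pov_segmentation import IdtParams, PoV, segment_log
from .telemetry_io import (
    FilterConfig,
    HOTKEY_KINDS,
    NON_QUALIFYING_KINDS,
    ReplayLog,
    TRAIN_KINDS,
    apply_game_filters,
)

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "PAC",
    "identify_pacs",
    "action_latency",
    "compute_player_features",
    "pac_time_coverage",
    "extract_features",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

#: Column order of the per-player feature vector.
FEATURE_NAMES = [
    "action_latency_ms",
    "actions_per_pac",
    "pacs_per_min",
    "gap_between_pacs_s",
    "hotkey_selects_per_min",
    "hotkey_assigns_per_min",
    "unique_hotkeys",
    "minimap_attacks_per_min",
    "minimap_rightclicks_per_min",
    "workers_per_min",
    "map_explored_pct",
    "unique_units",
    "complex_units_per_min",
    "complex_abilities_per_min",
    "apm",
]

#: Feature columns that are undefined for a player without PACs.
PAC_DERIVED = ("action_latency_ms", "actions_per_pac", "gap_between_pacs_s")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the feature definitions.

    ``ms_per_timestamp`` converts game timestamps to wall time; ``map_size``
    and ``grid_cells`` define the square grid used for the map-explored
    percentage (cells visited by at least one PoV centroid); ``apm_exclude``
    lists event kinds left out of the APM count (empty by default — APM
    counts every non-screen-move input, hotkeys included).
    """

    ms_per_timestamp: float = 11.5
    map_size: float = 128.0
    grid_cells: int = 16
    apm_exclude: frozenset = frozenset()

    def __post_init__(self):
        if self.ms_per_timestamp <= 0 or self.map_size <= 0 or self.grid_cells <= 0:
            raise ValueError("feature-config values must be positive")


@dataclass
class PAC:
    """A PoV with at least one qualifying action."""

    pov: PoV
    qualifying_actions: np.ndarray  # indices into the log's event table
    first_action_t: int

    @property
    def n_actions(self) -> int:
        return len(self.qualifying_actions)


def identify_pacs(povs: Sequence[PoV], events: pd.DataFrame) -> list[PAC]:
    """Return, in order, the PoVs that contain one or more qualifying actions."""
    kinds = events["kind"].to_numpy()
    t = events["t"].to_numpy(dtype=np.int64)
    pacs = []
    for pov in povs:
        contained = pov.contained_events
        if len(contained) == 0:
            continue
        qual = contained[~np.isin(kinds[contained], list(NON_QUALIFYING_KINDS))]
        if len(qual) == 0:
            continue
        pacs.append(
            PAC(pov=pov, qualifying_actions=qual, first_action_t=int(t[qual].min()))
        )
    return pacs


def action_latency(pac: PAC, ms_per_timestamp: float = 11.5) -> float:
    """Delay from PoV onset to the first qualifying action, in milliseconds."""
    return (pac.first_action_t - pac.pov.start_t) * ms_per_timestamp


def pac_time_coverage(pacs: Sequence[PAC], max_timestamp: int) -> float:
    """Fraction of game time spent inside PACs."""
    if max_timestamp <= 0:
        raise ValueError("max_timestamp must be positive")
    return float(sum(p.pov.duration for p in pacs)) / float(max_timestamp)


def compute_player_features(
    log: ReplayLog,
    pacs: Sequence[PAC],
    povs: Sequence[PoV],
    cfg: FeatureConfig | None = None,
) -> dict:
    """Compute the 15 per-player variables for one game log."""
    cfg = cfg or FeatureConfig()
    minutes = log.max_timestamp * cfg.ms_per_timestamp / 60000.0
    if minutes <= 0:
        raise ValueError("zero game length")
    ev = log.events
    kinds = ev["kind"].to_numpy()
    counts = pd.Series(kinds).value_counts()

    def rate(kind: str) -> float:
        return float(counts.get(kind, 0)) / minutes

    apm_mask = kinds != "screen_move"
    for kind in cfg.apm_exclude:
        apm_mask &= kinds != kind
    feats = {
        "hotkey_selects_per_min": rate("hotkey_select"),
        "hotkey_assigns_per_min": rate("hotkey_assign"),
        "minimap_attacks_per_min": rate("minimap_attack"),
        "minimap_rightclicks_per_min": rate("minimap_right_click"),
        "workers_per_min": rate("worker_train"),
        "complex_units_per_min": rate("complex_unit_train"),
        "complex_abilities_per_min": rate("complex_ability"),
        "apm": float(apm_mask.sum()) / minutes,
    }

    hot = ev.loc[np.isin(kinds, list(HOTKEY_KINDS)), "hotkey_id"]
    feats["unique_hotkeys"] = float(hot.dropna().nunique())
    trained = ev.loc[np.isin(kinds, list(TRAIN_KINDS)), "unit_type"]
    feats["unique_units"] = float(trained.dropna().nunique())

    # Map exploration: fraction of grid cells visited by >=1 PoV centroid.
    if povs:
        cell = cfg.map_size / cfg.grid_cells
        cxi = np.clip(
            np.floor(np.array([p.cx for p in povs]) / cell), 0, cfg.grid_cells - 1
        )
        cyi = np.clip(
            np.floor(np.array([p.cy for p in povs]) / cell), 0, cfg.grid_cells - 1
        )
        visited = len(set(zip(cxi.astype(int), cyi.astype(int))))
        feats["map_explored_pct"] = 100.0 * visited / (cfg.grid_cells**2)
    else:
        feats["map_explored_pct"] = 0.0

    feats["pacs_per_min"] = len(pacs) / minutes
    if pacs:
        feats["action_latency_ms"] = float(
            np.mean([action_latency(p, cfg.ms_per_timestamp) for p in pacs])
        )
        feats["actions_per_pac"] = float(np.mean([p.n_actions for p in pacs]))
        if len(pacs) >= 2:
            gaps = [
                (pacs[i + 1].pov.start_t - pacs[i].pov.end_t)
                for i in range(len(pacs) - 1)
            ]
            feats["gap_between_pacs_s"] = float(
                np.mean(gaps) * cfg.ms_per_timestamp / 1000.0
            )
        else:
            feats["gap_between_pacs_s"] = np.nan
    else:
        for name in PAC_DERIVED:
            feats[name] = np.nan
    return {name: feats[name] for name in FEATURE_NAMES}


def extract_features(
    log: ReplayLog,
    idt: IdtParams | None = None,
    cfg: FeatureConfig | None = None,
) -> tuple[dict, dict]:
    """Segment one log and compute its feature vector.

    Returns ``(features, diagnostics)`` where diagnostics report the PoV/PAC
    counts, PAC time coverage and total input count for auditing.
    """
    cfg = cfg or FeatureConfig()
    povs = segment_log(log, idt)
    pacs = identify_pacs(povs, log.events)
    feats = compute_player_features(log, pacs, povs, cfg)
    diags = {
        "n_povs": len(povs),
        "n_pacs": len(pacs),
        "pac_time_coverage": pac_time_coverage(pacs, log.max_timestamp),
        "total_inputs": log.n_events,
    }
    return feats, diags


def build_feature_table(
    cohort: Iterable[ReplayLog],
    filter_cfg: FilterConfig | None = None,
    idt: IdtParams | None = None,
    cfg: FeatureConfig | None = None,
    diagnostics: bool = False,
) -> pd.DataFrame:
    """Filter a cohort and build the players-by-variables feature table.

    Columns: ``player_id``, ``league``, the 15 feature names, and (with
    ``diagnostics=True``) ``pac_time_coverage`` and ``total_inputs``.
    """
    filter_cfg = filter_cfg or FilterConfig()
    rows = []
    n_rejected = 0
    seen = set()
    for log in cohort:
        decision = apply_game_filters(log, filter_cfg)
        if not decision.accepted:
            n_rejected += 1
            logger.debug("dropped %s: %s", log.player_id, decision.reasons)
            continue
        if log.player_id in seen:
            raise ValueError(f"duplicated player_id {log.player_id!r}")
        seen.add(log.player_id)
        feats, diags = extract_features(log, idt, cfg)
        row = {"player_id": log.player_id, "league": log.league, **feats}
        if diagnostics:
            row["pac_time_coverage"] = diags["pac_time_coverage"]
            row["total_inputs"] = diags["total_inputs"]
        rows.append(row)
    if not rows:
        raise ValueError("no player passed the game filters")
    table = pd.DataFrame(rows)
    logger.info(
        "feature table: %d players kept, %d rejected, mean PAC coverage %.3f",
        len(table),
        n_rejected,
        table["pac_time_coverage"].mean() if diagnostics else float("nan"),
    )
    return table
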