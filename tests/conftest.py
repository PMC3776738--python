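"""Shared fixtures: hand-built logs small enough to verify by hand."""

from __future__ import annotations

import numpy as np
import pytest

from pacscreen.telemetry_io import GameEvent, ReplayLog


def _ev(t, kind, **kw):
    return GameEvent(t=t, kind=kind, **kw)


@pytest.fixture
def three_event_log() -> ReplayLog:
    """Minimal log with one event of each structural flavor."""
    events = [
        _ev(5, "screen_move", x=10.0, y=20.0),
        _ev(9, "command"),
        _ev(12, "hotkey_select", hotkey_id=3),
    ]
    return ReplayLog.from_events("tiny", 2, events, max_timestamp=30000)


@pytest.fixture
def worked_log() -> ReplayLog:
    """Two-minute game (10000 timestamps at 12 ms each) with three planted
    fixations; every feature value is hand-computable.

    Expected segmentation (dispersion 6, duration 20):
      PoV1 [0, 95)    centroid (11, 11)
      PoV2 [200, 300) centroid (51, 51)
      PoV3 [400, 461) centroid (101, 101)
    PoV1 and PoV2 are PACs (2 qualifying actions each, first-action delay 10
    timestamps = 120 ms); PoV3 contains only a hotkey select.
    """
    moves = [
        # fixation 1: dispersion (2 + 2) = 4
        _ev(0, "screen_move", x=10.0, y=10.0),
        _ev(30, "screen_move", x=10.0, y=12.0),
        _ev(60, "screen_move", x=12.0, y=10.0),
        _ev(90, "screen_move", x=12.0, y=12.0),
        _ev(95, "screen_move", x=30.0, y=30.0),  # violator -> travel
        # fixation 2
        _ev(200, "screen_move", x=50.0, y=50.0),
        _ev(230, "screen_move", x=52.0, y=52.0),
        _ev(260, "screen_move", x=51.0, y=51.0),
        _ev(300, "screen_move", x=70.0, y=70.0),  # violator -> travel
        # fixation 3 (runs to end of stream)
        _ev(400, "screen_move", x=100.0, y=100.0),
        _ev(420, "screen_move", x=100.0, y=102.0),
        _ev(440, "screen_move", x=102.0, y=102.0),
        _ev(460, "screen_move", x=102.0, y=100.0),
    ]
    actions = [
        _ev(5, "hotkey_select", hotkey_id=0),     # in PoV1, not qualifying
        _ev(10, "command"),                        # PoV1 first action
        _ev(50, "command"),                        # PoV1 second action
        _ev(99, "unit_train", unit_type="marine"),     # between PoVs
        _ev(130, "unit_train", unit_type="zealot"),    # between PoVs
        _ev(140, "complex_unit_train", unit_type="colossus"),
        _ev(150, "worker_train", unit_type="worker"),
        _ev(160, "complex_ability"),
        _ev(170, "minimap_right_click"),
        _ev(180, "hotkey_select", hotkey_id=2),
        _ev(190, "command"),                       # between PoVs
        _ev(210, "hotkey_assign", hotkey_id=1),    # PoV2 first action
        _ev(250, "minimap_attack"),                # PoV2 second action
        _ev(350, "worker_train", unit_type="worker"),
        _ev(410, "hotkey_select", hotkey_id=0),    # PoV3: select only, no PAC
    ]
    return ReplayLog.from_events(
        "worked", 4, moves + actions, max_timestamp=10000
    )


#: Hand-computed feature values for ``worked_log`` with ms_per_timestamp=12,
#: map_size=128, grid_cells=16 (game length exactly 2 minutes).
WORKED_EXPECTED = {
    "action_latency_ms": 120.0,          # mean(10, 10) timestamps * 12 ms
    "actions_per_pac": 2.0,
    "pacs_per_min": 1.0,                  # 2 PACs / 2 min
    "gap_between_pacs_s": 1.26,           # (200 - 95) ts * 12 ms
    "hotkey_selects_per_min": 1.5,
    "hotkey_assigns_per_min": 0.5,
    "unique_hotkeys": 3.0,                # ids {0, 1, 2}
    "minimap_attacks_per_min": 0.5,
    "minimap_rightclicks_per_min": 0.5,
    "workers_per_min": 1.0,
    "map_explored_pct": 100.0 * 3 / 256,  # cells (1,1), (6,6), (12,12)
    "unique_units": 4.0,                  # worker, marine, zealot, colossus
    "complex_units_per_min": 0.5,
    "complex_abilities_per_min": 0.5,
    "apm": 7.5,                           # 15 non-screen events / 2 min
}


@pytest.fixture
def rng():
    return np.random.default_rng(20130918)
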