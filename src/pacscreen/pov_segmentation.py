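"""Dispersion-threshold (I-DT) segmentation of screen movements into PoVs.

Players relocate the game view-screen in quick jumps separated by dwells at
one map region, much like saccades between eye fixations.  A Point of View
(PoV) is one such dwell, detected with the classic dispersion-threshold
identification algorithm: a duration-seeded sliding window whose spatial
dispersion, defined as (max x - min x) + (max y - min y), must stay under a
cap.

Defaults follow the telemetry setting: dispersion threshold 6 game
coordinates, duration threshold 20 timestamps (~230 ms at 11.5 ms per
timestamp).

Conventions (the algorithm statement leaves these open):

* a PoV interval is half-open ``[start_t, end_t)`` for event containment;
* ``end_t`` is the timestamp of the screen move that violates the dispersion
  cap (the moment the screen leaves the region); at end of stream it is the
  last member move's timestamp + 1;
* multiple moves sharing a timestamp are processed in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IdtParams",
    "PoV",
    "compute_dispersion",
    "segment_povs",
    "assign_events_to_povs",
    "pov_time_coverage",
    "segment_log",
]


@dataclass(frozen=True)
class IdtParams:
    dispersion_threshold: float = 6.0
    duration_threshold: int = 20

    def __post_init__(self):
        if self.dispersion_threshold <= 0 or self.duration_threshold <= 0:
            raise ValueError("I-DT thresholds must be positive")


@dataclass
class PoV:
    """One fixation-like screen epoch.

    ``member_moves`` indexes the constituent screen moves in the move stream
    that was segmented; ``contained_events`` indexes non-screen events with
    ``start_t <= t < end_t`` once :func:`assign_events_to_povs` has run.
    """

    cx: float
    cy: float
    start_t: int
    end_t: int
    member_moves: np.ndarray
    contained_events: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def duration(self) -> int:
        return self.end_t - self.start_t

    @property
    def n_moves(self) -> int:
        return len(self.member_moves)


def compute_dispersion(points) -> float:
    """Dispersion of a set of screen positions: x-range plus y-range."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.size == 0:
        raise ValueError("dispersion of an empty point set is undefined")
    return float(np.ptp(pts[:, 0]) + np.ptp(pts[:, 1]))


def _coerce_moves(screen_moves) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(screen_moves, pd.DataFrame):
        t = screen_moves["t"].to_numpy(dtype=np.int64)
        x = screen_moves["x"].to_numpy(dtype=float)
        y = screen_moves["y"].to_numpy(dtype=float)
    else:
        arr = np.asarray(screen_moves, dtype=float)
        if arr.size == 0:
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=float),
                np.empty(0, dtype=float),
            )
        t = arr[:, 0].astype(np.int64)
        x = arr[:, 1]
        y = arr[:, 2]
    return t, x, y


def segment_povs(screen_moves, params: IdtParams | None = None) -> list[PoV]:
    """Run sliding-window I-DT over a time-sorted stream of screen moves.

    ``screen_moves`` is an ``(n, 3)`` array-like of ``(t, x, y)`` rows or a
    DataFrame with those columns.  Returns time-ordered, non-overlapping
    PoVs; every screen move belongs to at most one PoV.
    """
    params = params or IdtParams()
    t, x, y = _coerce_moves(screen_moves)
    n = len(t)
    if n and np.any(np.diff(t) < 0):
        raise ValueError("screen moves must be sorted by timestamp")
    disp_thr = params.dispersion_threshold
    dur_thr = params.duration_threshold

    povs: list[PoV] = []
    i = 0
    while i < n:
        # Seed: minimal window starting at i whose time span reaches the
        # duration threshold.
        j = int(np.searchsorted(t, t[i] + dur_thr, side="left"))
        if j >= n:
            break  # remaining moves cannot span the duration threshold
        xw = x[i : j + 1]
        yw = y[i : j + 1]
        if (np.ptp(xw) + np.ptp(yw)) > disp_thr:
            i += 1  # drop the first move and re-seed
            continue
        # Extend until the next move would violate the dispersion cap.
        xmin, xmax = xw.min(), xw.max()
        ymin, ymax = yw.min(), yw.max()
        k = j + 1
        while k < n:
            nxmin, nxmax = min(xmin, x[k]), max(xmax, x[k])
            nymin, nymax = min(ymin, y[k]), max(ymax, y[k])
            if (nxmax - nxmin) + (nymax - nymin) > disp_thr:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            k += 1
        members = np.arange(i, k, dtype=np.int64)
        end_t = int(t[k]) if k < n else int(t[n - 1]) + 1
        povs.append(
            PoV(
                cx=float(x[i:k].mean()),
                cy=float(y[i:k].mean()),
                start_t=int(t[i]),
                end_t=end_t,
                member_moves=members,
            )
        )
        if k >= n:
            break
        i = k  # the violating move starts the next window
    return povs


def assign_events_to_povs(povs: list[PoV], events) -> list[PoV]:
    """Attach non-screen events to the PoV whose ``[start_t, end_t)`` holds them.

    ``events`` is the full event DataFrame (or an array of timestamps with a
    parallel kind column already removed); screen moves are ignored.  Events
    falling between PoVs are attached to none.  Returns the same PoV list,
    populated.
    """
    if isinstance(events, pd.DataFrame):
        mask = (events["kind"] != "screen_move").to_numpy()
        idx = np.flatnonzero(mask).astype(np.int64)
        t_ev = events["t"].to_numpy(dtype=np.int64)[mask]
    else:
        t_ev = np.asarray(events, dtype=np.int64)
        idx = np.arange(len(t_ev), dtype=np.int64)
    for pov in povs:
        pov.contained_events = np.empty(0, dtype=np.int64)
    if not povs or len(t_ev) == 0:
        return povs
    starts = np.array([p.start_t for p in povs], dtype=np.int64)
    ends = np.array([p.end_t for p in povs], dtype=np.int64)
    pos = np.searchsorted(starts, t_ev, side="right") - 1
    ok = (pos >= 0) & (t_ev < ends[np.clip(pos, 0, None)])
    for p_i in np.unique(pos[ok]):
        pov_events = idx[ok & (pos == p_i)]
        povs[int(p_i)].contained_events = pov_events
    return povs


def pov_time_coverage(povs: Sequence[PoV], max_timestamp: int) -> float:
    """Fraction of game time spent inside PoVs."""
    if max_timestamp <= 0:
        raise ValueError("max_timestamp must be positive")
    total = sum(p.duration for p in povs)
    return float(total) / float(max_timestamp)


def povs_to_frame(povs: Sequence[PoV]) -> pd.DataFrame:
    """Tabular PoV export (one row per PoV, CSV-ready)."""
    return pd.DataFrame(
        {
            "pov_index": np.arange(len(povs)),
            "cx": [p.cx for p in povs],
            "cy": [p.cy for p in povs],
            "start_t": [p.start_t for p in povs],
            "end_t": [p.end_t for p in povs],
            "n_moves": [p.n_moves for p in povs],
            "n_events": [len(p.contained_events) for p in povs],
        }
    )


def segment_log(log, params: IdtParams | None = None) -> list[PoV]:
    """Segment a :class:`~pacscreen.telemetry_io.ReplayLog` and assign events."""
    moves = log.events[log.events["kind"] == "screen_move"]
    povs = segment_povs(moves[["t", "x", "y"]], params)
    return assign_events_to_povs(povs, log.events)
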