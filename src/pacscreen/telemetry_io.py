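"""Event-log data model, JSON-lines dialect, and game-level inclusion filters.

The unit of analysis is one player's input stream for one game: every
command, hotkey press, minimap action, unit-production order and movement of
the game view-screen, stamped with an integer game timestamp (11.5 ms per
timestamp under the default conversion).  Logs are serialized as JSON-lines:
a header record with player metadata followed by one record per event.

Only replay-level comparability filters are computed here (game length,
input count, number of human players); survey-derived exclusions are not
recomputable from an event log and are out of scope.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "HOTKEY_KINDS",
    "TRAIN_KINDS",
    "NON_QUALIFYING_KINDS",
    "GameEvent",
    "ReplayLog",
    "FilterConfig",
    "FilterDecision",
    "TelemetryError",
    "ParseError",
    "read_event_log",
    "write_event_log",
    "apply_game_filters",
    "filter_cohort",
    "write_cohort",
    "read_cohort",
]

#: Recognized event kinds.  ``screen_move`` carries map coordinates; the
#: hotkey kinds carry a hotkey id; the train kinds carry a unit-type token.
EVENT_KINDS = (
    "screen_move",
    "command",
    "hotkey_select",
    "hotkey_assign",
    "minimap_right_click",
    "minimap_attack",
    "worker_train",
    "unit_train",
    "complex_unit_train",
    "complex_ability",
    "other_action",
)

HOTKEY_KINDS = frozenset({"hotkey_select", "hotkey_assign"})
TRAIN_KINDS = frozenset({"worker_train", "unit_train", "complex_unit_train"})

#: Kinds that never count as a qualifying action inside a perception-action
#: cycle: screen movements are not actions, and hotkey selects are excluded
#: because they can themselves relocate the view-screen.
NON_QUALIFYING_KINDS = frozenset({"screen_move", "hotkey_select"})

EVENT_COLUMNS = ("t", "kind", "x", "y", "hotkey_id", "unit_type")

LEAGUE_NAMES = {
    1: "Bronze",
    2: "Silver",
    3: "Gold",
    4: "Platinum",
    5: "Diamond",
    6: "Masters",
    7: "Professional",
}


class TelemetryError(ValueError):
    """Invalid event-log content."""


class ParseError(TelemetryError):
    """Malformed record in a serialized event log; names the line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True)
class GameEvent:
    """One timestamped player input.

    Coordinates are game-map coordinates (origin bottom-left, continuous),
    present exactly when ``kind == "screen_move"``; ``hotkey_id`` (0-9) is
    present exactly for hotkey kinds and ``unit_type`` for train kinds.
    """

    t: int
    kind: str
    x: float | None = None
    y: float | None = None
    hotkey_id: int | None = None
    unit_type: str | None = None

    def __post_init__(self):
        if self.t < 0:
            raise TelemetryError(f"negative timestamp {self.t}")
        if self.kind not in EVENT_KINDS:
            raise TelemetryError(f"unknown event kind {self.kind!r}")
        has_xy = self.x is not None and self.y is not None
        if (self.kind == "screen_move") != has_xy:
            raise TelemetryError(
                f"coordinates must be present iff kind is screen_move (kind={self.kind})"
            )
        if (self.kind in HOTKEY_KINDS) != (self.hotkey_id is not None):
            raise TelemetryError(
                f"hotkey_id must be present iff kind is a hotkey kind (kind={self.kind})"
            )
        if self.hotkey_id is not None and not 0 <= self.hotkey_id <= 9:
            raise TelemetryError(f"hotkey_id {self.hotkey_id} outside 0-9")
        if (self.kind in TRAIN_KINDS) != (self.unit_type is not None):
            raise TelemetryError(
                f"unit_type must be present iff kind is a train kind (kind={self.kind})"
            )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": pd.Series(dtype=np.int64),
            "kind": pd.Series(dtype=object),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "hotkey_id": pd.Series(dtype=float),
            "unit_type": pd.Series(dtype=object),
        }
    )


@dataclass
class ReplayLog:
    """One player's event stream for one game, plus metadata.

    ``events`` is a DataFrame with columns ``t, kind, x, y, hotkey_id,
    unit_type`` (NaN/None where a field does not apply), kept sorted by ``t``
    with a stable sort so ties keep input order.
    """

    player_id: str
    league: int
    events: pd.DataFrame
    max_timestamp: int
    player_count: int = 2

    def __post_init__(self):
        if not 1 <= int(self.league) <= 7:
            raise TelemetryError(f"league {self.league} outside 1..7")
        self.league = int(self.league)
        self.max_timestamp = int(self.max_timestamp)
        if self.events is None:
            self.events = _empty_events()
        ev = self.events
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise TelemetryError(f"events missing columns {missing}")
        if len(ev):
            t = ev["t"].to_numpy()
            if np.any(t < 0):
                raise TelemetryError("negative event timestamp")
            if np.any(np.diff(t) < 0):
                self.events = ev.sort_values("t", kind="stable", ignore_index=True)
            elif not ev.index.equals(pd.RangeIndex(len(ev))):
                self.events = ev.reset_index(drop=True)
            if self.max_timestamp < int(self.events["t"].iloc[-1]):
                raise TelemetryError(
                    "max_timestamp smaller than the latest event timestamp"
                )

    @classmethod
    def from_events(
        cls,
        player_id: str,
        league: int,
        events: Iterable[GameEvent],
        max_timestamp: int,
        player_count: int = 2,
    ) -> "ReplayLog":
        rows = list(events)
        if rows:
            df = pd.DataFrame(
                {
                    "t": np.array([e.t for e in rows], dtype=np.int64),
                    "kind": [e.kind for e in rows],
                    "x": [np.nan if e.x is None else float(e.x) for e in rows],
                    "y": [np.nan if e.y is None else float(e.y) for e in rows],
                    "hotkey_id": [
                        np.nan if e.hotkey_id is None else float(e.hotkey_id)
                        for e in rows
                    ],
                    "unit_type": [e.unit_type for e in rows],
                }
            )
        else:
            df = _empty_events()
        return cls(player_id, league, df, max_timestamp, player_count)

    def iter_events(self) -> Iterator[GameEvent]:
        for row in self.events.itertuples(index=False):
            yield GameEvent(
                t=int(row.t),
                kind=row.kind,
                x=None if pd.isna(row.x) else float(row.x),
                y=None if pd.isna(row.y) else float(row.y),
                hotkey_id=None if pd.isna(row.hotkey_id) else int(row.hotkey_id),
                unit_type=None if row.unit_type is None else str(row.unit_type),
            )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def equals(self, other: "ReplayLog") -> bool:
        return (
            self.player_id == other.player_id
            and self.league == other.league
            and self.max_timestamp == other.max_timestamp
            and self.player_count == other.player_count
            and self.events.equals(other.events)
        )


@dataclass(frozen=True)
class FilterConfig:
    """Replay-level inclusion thresholds (inclusive on the accepted side)."""

    min_max_timestamp: int = 25000
    min_total_inputs: int = 100
    required_player_count: int = 2
    ms_per_timestamp: float = 11.5

    def __post_init__(self):
        if (
            self.min_max_timestamp <= 0
            or self.min_total_inputs <= 0
            or self.required_player_count <= 0
            or self.ms_per_timestamp <= 0
        ):
            raise ValueError("all filter thresholds must be positive")


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ValueError("accepted must hold exactly when reasons is empty")


def apply_game_filters(log: ReplayLog, cfg: FilterConfig | None = None) -> FilterDecision:
    """Decide whether one game log enters the analysis.

    A log is accepted iff the game lasted at least ``min_max_timestamp``
    timestamps, contains at least ``min_total_inputs`` events (commands plus
    screen movements), and was declared a game between exactly
    ``required_player_count`` humans.  Every failed criterion is reported.
    """
    cfg = cfg or FilterConfig()
    reasons = []
    if log.max_timestamp < cfg.min_max_timestamp:
        reasons.append("too_short")
    if log.n_events < cfg.min_total_inputs:
        reasons.append("too_few_inputs")
    if log.player_count != cfg.required_player_count:
        reasons.append("wrong_player_count")
    return FilterDecision(accepted=not reasons, reasons=tuple(reasons))


def filter_cohort(
    logs: Iterable[ReplayLog], cfg: FilterConfig | None = None
) -> tuple[list[ReplayLog], list[tuple[str, tuple[str, ...]]]]:
    """Split a cohort into accepted logs (unchanged) and rejection records."""
    cfg = cfg or FilterConfig()
    accepted, rejected = [], []
    for log in logs:
        decision = apply_game_filters(log, cfg)
        if decision.accepted:
            accepted.append(log)
        else:
            rejected.append((log.player_id, decision.reasons))
    return accepted, rejected


# ---------------------------------------------------------------------------
# JSON-lines dialect


def _coerce_stream(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    if isinstance(source, (io.RawIOBase, io.BufferedIOBase)):
        return io.TextIOWrapper(source, encoding="utf-8"), False
    return source, False


def read_event_log(source) -> ReplayLog:
    """Read one event log from a path or text/byte stream.

    The first record is a header with ``player_id, league, max_timestamp,
    player_count``; each following record is one event.  Events are re-sorted
    by timestamp if needed (stable for ties).
    """
    stream, owned = _coerce_stream(source, "r")
    try:
        header = None
        t, kind, xs, ys, hk, ut = [], [], [], [], [], []
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(lineno, f"invalid JSON ({exc.msg})") from exc
            if header is None:
                for key in ("player_id", "league", "max_timestamp", "player_count"):
                    if key not in rec:
                        raise ParseError(lineno, f"header missing key {key!r}")
                if not 1 <= int(rec["league"]) <= 7:
                    raise ParseError(lineno, f"league {rec['league']} outside 1..7")
                header = rec
                continue
            try:
                ev = GameEvent(
                    t=int(rec["t"]),
                    kind=rec["kind"],
                    x=rec.get("x"),
                    y=rec.get("y"),
                    hotkey_id=rec.get("hotkey_id"),
                    unit_type=rec.get("unit_type"),
                )
            except (KeyError, TypeError, TelemetryError) as exc:
                raise ParseError(lineno, f"invalid event record ({exc})") from exc
            t.append(ev.t)
            kind.append(ev.kind)
            xs.append(np.nan if ev.x is None else ev.x)
            ys.append(np.nan if ev.y is None else ev.y)
            hk.append(np.nan if ev.hotkey_id is None else float(ev.hotkey_id))
            ut.append(ev.unit_type)
        if header is None:
            raise ParseError(0, "empty stream: missing header record")
        if t:
            events = pd.DataFrame(
                {
                    "t": np.asarray(t, dtype=np.int64),
                    "kind": kind,
                    "x": xs,
                    "y": ys,
                    "hotkey_id": hk,
                    "unit_type": ut,
                }
            )
        else:
            events = _empty_events()
        return ReplayLog(
            player_id=str(header["player_id"]),
            league=int(header["league"]),
            events=events,
            max_timestamp=int(header["max_timestamp"]),
            player_count=int(header["player_count"]),
        )
    finally:
        if owned:
            stream.close()


def _event_record(row) -> dict:
    rec = {"t": int(row.t), "kind": row.kind}
    if row.kind not in EVENT_KINDS:
        raise TelemetryError(f"unknown event kind {row.kind!r}")
    if row.kind == "screen_move":
        rec["x"] = float(row.x)
        rec["y"] = float(row.y)
    if row.kind in HOTKEY_KINDS:
        rec["hotkey_id"] = int(row.hotkey_id)
    if row.kind in TRAIN_KINDS:
        rec["unit_type"] = str(row.unit_type)
    return rec


def write_event_log(log: ReplayLog, sink) -> None:
    """Write a log in the JSON-lines dialect (deterministic field order).

    All records are serialized before anything is written, so an invalid
    event never leaves a partial file behind.
    """
    header = {
        "player_id": log.player_id,
        "league": log.league,
        "max_timestamp": log.max_timestamp,
        "player_count": log.player_count,
    }
    lines = [json.dumps(header)]
    for row in log.events.itertuples(index=False):
        lines.append(json.dumps(_event_record(row)))
    payload = "\n".join(lines) + "\n"
    stream, owned = _coerce_stream(sink, "w")
    try:
        stream.write(payload)
    finally:
        if owned:
            stream.close()


# ---------------------------------------------------------------------------
# Cohort manifests


def write_cohort(logs: Iterable[ReplayLog], directory) -> Path:
    """Write one ``.events.jsonl`` file per log plus a ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for log in logs:
        fname = f"{log.player_id}.events.jsonl"
        write_event_log(log, directory / fname)
        rows.append({"player_id": log.player_id, "league": log.league, "path": fname})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=["player_id", "league", "path"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_cohort(manifest_path) -> Iterator[ReplayLog]:
    """Lazily yield logs listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    base = manifest_path.parent
    for row in table.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        yield read_event_log(path)
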