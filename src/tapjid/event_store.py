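"""Touch-event and screen-episode storage.

Reads/writes the plain-CSV event dialects, segments touch streams into
screen-on usage sessions, extracts inter-touch-interval (ITI) sequences,
and applies the cohort and per-test time-window filters.

Conventions
-----------
* timestamps are integer epoch milliseconds (UTC);
* duplicate (participant, timestamp) touches are collapsed to one event —
  zero intervals are undefined on a log scale;
* a touch exactly at an episode boundary belongs to the episode (closed
  interval on both ends);
* intervals never span sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

__all__ = [
    "EventFormatError",
    "EVENT_COLUMNS",
    "EPISODE_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "MS_PER_DAY",
    "Session",
    "SessionSet",
    "ITISequence",
    "load_events",
    "write_events",
    "load_episodes",
    "load_participants",
    "normalize_episodes",
    "segment_sessions",
    "extract_itis",
    "filter_cohort",
    "window_around_test",
]

MS_PER_DAY = 86_400_000

EVENT_COLUMNS = ["participant_id", "timestamp_ms", "app_id"]
EPISODE_COLUMNS = ["participant_id", "on_ms", "off_ms"]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "age_years",
    "gender",
    "thumb_pref",
    "dual_thumb_pref",
    "years_smartphone",
    "screen_size_inch",
]


class EventFormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass
class Session:
    """Touches of one participant inside one screen-on episode."""

    participant_id: str
    timestamps: np.ndarray  # int64 ms, strictly increasing
    app_ids: np.ndarray  # object, aligned to timestamps
    on_ms: int
    off_ms: int

    @property
    def n_touches(self) -> int:
        return int(self.timestamps.size)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.app_ids = np.asarray(self.app_ids, dtype=object)
        if self.timestamps.size != self.app_ids.size:
            raise ValueError("timestamps and app_ids must be aligned")
        if self.timestamps.size and (
            self.timestamps.min() < self.on_ms or self.timestamps.max() > self.off_ms
        ):
            raise ValueError("touches must fall within the episode bounds")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("session timestamps must be strictly increasing")


@dataclass
class SessionSet:
    """Result of session segmentation plus a drop audit."""

    sessions: list[Session]
    n_dropped: int
    dropped_per_participant: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    def for_participant(self, participant_id: str) -> list[Session]:
        return [s for s in self.sessions if s.participant_id == participant_id]


@dataclass
class ITISequence:
    """Per-session ordered inter-touch intervals with bounding app labels.

    ``lead_apps[i]`` is the app of the touch opening interval ``i`` and
    ``trail_apps[i]`` the app of the touch closing it; for consecutive
    intervals ``trail_apps[i] == lead_apps[i + 1]``.
    """

    participant_id: str
    intervals_ms: np.ndarray  # float, all > 0
    lead_apps: np.ndarray
    trail_apps: np.ndarray

    def __len__(self) -> int:
        return int(self.intervals_ms.size)


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EventFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def load_events(path) -> pd.DataFrame:
    """Read an events CSV (``participant_id,timestamp_ms,app_id``).

    Returns a DataFrame sorted by (participant_id, timestamp_ms) with
    duplicate timestamps per participant collapsed.  Malformed rows are
    dropped; their 1-based file line numbers and reasons are recorded in
    ``df.attrs['malformed_rows']`` and counted in ``df.attrs['n_malformed']``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, EVENT_COLUMNS, str(path))
    ts = pd.to_numeric(raw["timestamp_ms"], errors="coerce")
    bad = ts.isna() | (ts < 0)
    malformed = [
        (int(i) + 2, f"non-numeric or negative timestamp: {raw['timestamp_ms'].iloc[i]!r}")
        for i in np.flatnonzero(bad.to_numpy())
    ]
    df = pd.DataFrame(
        {
            "participant_id": raw.loc[~bad, "participant_id"].astype(str),
            "timestamp_ms": ts[~bad].astype(np.int64),
            "app_id": raw.loc[~bad, "app_id"].astype(str),
        }
    )
    df = (
        df.sort_values(["participant_id", "timestamp_ms"], kind="mergesort")
        .drop_duplicates(["participant_id", "timestamp_ms"], keep="first")
        .reset_index(drop=True)
    )
    df.attrs["malformed_rows"] = malformed
    df.attrs["n_malformed"] = len(malformed)
    return df


def write_events(events: pd.DataFrame, path) -> None:
    """Write an events table back to CSV (round-trip identity with load)."""
    events.to_csv(path, index=False, columns=EVENT_COLUMNS)


def load_episodes(path) -> pd.DataFrame:
    """Read a screen-episode CSV (``participant_id,on_ms,off_ms``)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, EPISODE_COLUMNS, str(path))
    on = pd.to_numeric(raw["on_ms"], errors="coerce")
    off = pd.to_numeric(raw["off_ms"], errors="coerce")
    bad = on.isna() | off.isna() | (off <= on)
    malformed = [
        (int(i) + 2, "invalid episode bounds (need numeric off_ms > on_ms)")
        for i in np.flatnonzero(bad.to_numpy())
    ]
    df = pd.DataFrame(
        {
            "participant_id": raw.loc[~bad, "participant_id"].astype(str),
            "on_ms": on[~bad].astype(np.int64),
            "off_ms": off[~bad].astype(np.int64),
        }
    ).reset_index(drop=True)
    df.attrs["malformed_rows"] = malformed
    df.attrs["n_malformed"] = len(malformed)
    return df


def load_participants(path) -> pd.DataFrame:
    """Read the participant-metadata CSV; last four columns are nullable."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, PARTICIPANT_COLUMNS, str(path))
    for col in PARTICIPANT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def normalize_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (or boundary-sharing) episodes per participant.

    Closed-interval semantics: episodes with ``off_ms == next on_ms`` share
    the boundary touch and are merged.  Emits a warning when any merge
    happens.
    """
    merged_rows = []
    n_merged = 0
    for pid, grp in episodes.groupby("participant_id", sort=True):
        grp = grp.sort_values("on_ms")
        cur_on = cur_off = None
        for on, off in zip(grp["on_ms"], grp["off_ms"]):
            if cur_on is None:
                cur_on, cur_off = on, off
            elif on <= cur_off:
                cur_off = max(cur_off, off)
                n_merged += 1
            else:
                merged_rows.append((pid, cur_on, cur_off))
                cur_on, cur_off = on, off
        if cur_on is not None:
            merged_rows.append((pid, cur_on, cur_off))
    if n_merged:
        warnings.warn(
            f"merged {n_merged} overlapping screen episode(s)", stacklevel=2
        )
    return pd.DataFrame(merged_rows, columns=EPISODE_COLUMNS)


def segment_sessions(events: pd.DataFrame, episodes: pd.DataFrame) -> SessionSet:
    """Assign touches to screen-on episodes, one Session per non-empty episode.

    Touches outside every episode are dropped and counted in the returned
    :class:`SessionSet`.  Overlapping episodes are merged first.
    """
    episodes = normalize_episodes(episodes)
    sessions: list[Session] = []
    n_dropped = 0
    dropped_per_participant: dict[str, int] = {}
    ep_by_pid = {pid: grp for pid, grp in episodes.groupby("participant_id")}
    for pid, grp in events.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp_ms").drop_duplicates("timestamp_ms")
        ts = grp["timestamp_ms"].to_numpy(dtype=np.int64)
        apps = grp["app_id"].to_numpy(dtype=object)
        used = np.zeros(ts.size, dtype=bool)
        eps = ep_by_pid.get(pid)
        if eps is not None:
            for on, off in zip(eps["on_ms"], eps["off_ms"]):
                lo = np.searchsorted(ts, on, side="left")
                hi = np.searchsorted(ts, off, side="right")
                if hi > lo:
                    used[lo:hi] = True
                    sessions.append(
                        Session(pid, ts[lo:hi], apps[lo:hi], int(on), int(off))
                    )
        n_out = int((~used).sum())
        if n_out:
            dropped_per_participant[pid] = n_out
            n_dropped += n_out
    return SessionSet(sessions, n_dropped, dropped_per_participant)


def extract_itis(session: Session) -> ITISequence:
    """Turn a session's n touches into its n−1 inter-touch intervals.

    A single-touch session yields an empty sequence (not an error).
    """
    if session.n_touches == 0:
        raise ValueError("session must contain at least one touch")
    intervals = np.diff(session.timestamps).astype(float)
    return ITISequence(
        participant_id=session.participant_id,
        intervals_ms=intervals,
        lead_apps=session.app_ids[:-1],
        trail_apps=session.app_ids[1:],
    )


def filter_cohort(
    events: pd.DataFrame,
    min_days: float = 7.0,
    min_interactions: int = 100,
) -> tuple[list[str], pd.DataFrame]:
    """Retain participants with ≥ ``min_days`` recording span and
    ≥ ``min_interactions`` touches.

    Recording span is last − first event timestamp.  Returns the retained
    participant ids and a per-participant audit table.
    """
    grp = events.groupby("participant_id")["timestamp_ms"]
    span_days = (grp.max() - grp.min()) / MS_PER_DAY
    n_touches = grp.size()
    audit = pd.DataFrame(
        {
            "participant_id": span_days.index,
            "span_days": span_days.to_numpy(),
            "n_touches": n_touches.to_numpy(),
        }
    )
    audit["retained"] = (audit["span_days"] >= min_days) & (
        audit["n_touches"] >= min_interactions
    )
    kept = audit.loc[audit["retained"], "participant_id"].tolist()
    return kept, audit.reset_index(drop=True)


def _day_start_ms(d: date) -> int:
    return int(
        datetime(d.year, d.month, d.day, tzinfo=timezone.utc).timestamp() * 1000
    )


def window_around_test(
    events: pd.DataFrame,
    test_day,
    window_days: int = 10,
) -> pd.DataFrame:
    """Keep events within ± ``window_days`` days of the test day (inclusive).

    ``test_day`` may be a :class:`datetime.date` / ISO date string (whole
    calendar days, UTC, are then included) or an integer epoch-ms instant
    (a symmetric ±window in ms is used).  An empty result means the
    participant is excluded from that test's regression; callers check
    ``len(result) == 0``.
    """
    if isinstance(test_day, str):
        test_day = date.fromisoformat(test_day)
    if isinstance(test_day, datetime):
        test_day = test_day.date()
    if isinstance(test_day, date):
        lo = _day_start_ms(test_day - timedelta(days=window_days))
        hi = _day_start_ms(test_day + timedelta(days=window_days + 1)) - 1
    else:
        t = int(test_day)
        lo = t - window_days * MS_PER_DAY
        hi = t + window_days * MS_PER_DAY
    mask = (events["timestamp_ms"] >= lo) & (events["timestamp_ms"] <= hi)
    return events.loc[mask].reset_index(drop=True)
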