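"""Extraction of hold/flight-time features from raw keyboard event logs.

The raw input is a stream of time-stamped press/release events per typing
session. Presses are paired with releases of the same key, hold time (HT)
is release minus press within a keystroke, flight time (FT) is the next
press minus the current release. Implausible values (HT > 700 ms,
FT > 3000 ms) are excluded, sessions with 40 or fewer presses are dropped,
and the retained per-keystroke values are aggregated per participant.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Exclusion threshold for hold times, milliseconds (values strictly above
#: are dropped).
DEFAULT_HT_MAX_MS = 700.0
#: Exclusion threshold for flight times, milliseconds.
DEFAULT_FT_MAX_MS = 3000.0
#: Sessions are retained when n_presses >= this bound (i.e. "more than 40").
DEFAULT_MIN_PRESSES = 41

PRESS = "press"
RELEASE = "release"

_ACTION_ALIASES = {
    "press": PRESS,
    "down": PRESS,
    "release": RELEASE,
    "up": RELEASE,
}


@dataclass(frozen=True)
class RawKeyEvent:
    """One time-stamped keyboard event.

    Parameters
    ----------
    timestamp : float
        Milliseconds since an arbitrary per-session epoch.
    action : str
        Either ``"press"`` or ``"release"``.
    key_id : str
        Opaque anonymized key token.
    session_id, participant_id : str
        Opaque grouping tokens.
    """

    timestamp: float
    action: str
    key_id: str
    session_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp) or self.timestamp < 0:
            raise ValueError(f"timestamp must be finite and non-negative, got {self.timestamp}")
        if self.action not in (PRESS, RELEASE):
            raise ValueError(f"action must be 'press' or 'release', got {self.action!r}")


@dataclass(frozen=True)
class Keystroke:
    """A matched press/release pair for one key."""

    press_time: float
    release_time: float
    key_id: str

    def __post_init__(self) -> None:
        if self.release_time < self.press_time:
            raise ValueError("release_time must be >= press_time")

    @property
    def hold_time(self) -> float:
        return self.release_time - self.press_time


@dataclass
class PairingReport:
    """Accounting of the press/release matching for one event stream."""

    n_press_events: int = 0
    n_release_events: int = 0
    n_pairs: int = 0
    n_orphan_presses: int = 0
    n_orphan_releases: int = 0


@dataclass
class TypingSession:
    """One typing episode: ordered keystrokes plus raw-event counts."""

    session_id: str
    participant_id: str
    keystrokes: list[Keystroke]
    n_presses: int
    pairing: PairingReport | None = None

    def __post_init__(self) -> None:
        times = [k.press_time for k in self.keystrokes]
        if times != sorted(times):
            raise ValueError("keystrokes must be sorted by press_time")


@dataclass
class FeatureSet:
    """Per-keystroke HT/FT value lists with exclusion accounting."""

    hold_times: list[float] = field(default_factory=list)
    flight_times: list[float] = field(default_factory=list)
    n_excluded_ht: int = 0
    n_excluded_ft: int = 0


@dataclass
class ParticipantFeatures:
    """Participant-level aggregate of filtered keystroke features."""

    participant_id: str
    mean_ht: float
    mean_ft: float
    n_sessions_total: int
    n_sessions_retained: int
    n_keystrokes: int
    n_excluded_ht: int = 0
    n_excluded_ft: int = 0
    has_data: bool = True


@dataclass
class ParseReport:
    n_sessions: int = 0
    n_events: int = 0
    n_malformed_records: int = 0
    n_unsorted_sessions: int = 0


def pair_events(events: Sequence[RawKeyEvent]) -> tuple[list[Keystroke], PairingReport]:
    """Match each press to the earliest subsequent release of the same key.

    Events must be sorted by timestamp. Unmatched presses and releases are
    dropped and counted in the returned :class:`PairingReport`. Output is
    sorted by press time; rollover (overlapping keystrokes) is preserved.
    """
    report = PairingReport()
    pending: dict[str, deque[RawKeyEvent]] = defaultdict(deque)
    strokes: list[Keystroke] = []
    for ev in events:
        if ev.action == PRESS:
            report.n_press_events += 1
            pending[ev.key_id].append(ev)
        else:
            report.n_release_events += 1
            queue = pending[ev.key_id]
            if queue:
                press = queue.popleft()
                strokes.append(Keystroke(press.timestamp, ev.timestamp, ev.key_id))
            else:
                report.n_orphan_releases += 1
    report.n_orphan_presses = sum(len(q) for q in pending.values())
    report.n_pairs = len(strokes)
    strokes.sort(key=lambda k: k.press_time)
    return strokes, report


def compute_hold_times(session: TypingSession) -> list[float]:
    """HT per keystroke: release minus press, order preserved."""
    return [k.release_time - k.press_time for k in session.keystrokes]


def compute_flight_times(session: TypingSession) -> list[float]:
    """FT between consecutive keystrokes: next press minus current release.

    Computed only within the session; negative values (rollover) retained.
    """
    ks = session.keystrokes
    return [ks[j + 1].press_time - ks[j].release_time for j in range(len(ks) - 1)]


def extract_features(session: TypingSession) -> FeatureSet:
    """Unfiltered HT/FT lists for one session."""
    return FeatureSet(
        hold_times=compute_hold_times(session),
        flight_times=compute_flight_times(session),
    )


def apply_preprocessing_filters(
    features: FeatureSet,
    ht_max_ms: float = DEFAULT_HT_MAX_MS,
    ft_max_ms: float = DEFAULT_FT_MAX_MS,
    ft_min_ms: float | None = None,
) -> FeatureSet:
    """Drop implausible keystroke timings.

    HT values strictly greater than ``ht_max_ms`` and FT values strictly
    greater than ``ft_max_ms`` are excluded; boundary values are retained.
    ``ft_min_ms`` optionally drops flight times below a lower bound
    (default: none, rollover values kept).
    """
    ht_kept = [v for v in features.hold_times if v <= ht_max_ms]
    ft_kept = [v for v in features.flight_times if v <= ft_max_ms]
    if ft_min_ms is not None:
        ft_kept = [v for v in ft_kept if v >= ft_min_ms]
    return FeatureSet(
        hold_times=ht_kept,
        flight_times=ft_kept,
        n_excluded_ht=features.n_excluded_ht + len(features.hold_times) - len(ht_kept),
        n_excluded_ft=features.n_excluded_ft + len(features.flight_times) - len(ft_kept),
    )


def filter_sessions(
    sessions: Sequence[TypingSession],
    min_presses: int = DEFAULT_MIN_PRESSES,
) -> tuple[list[TypingSession], float]:
    """Retain sessions with at least ``min_presses`` press events.

    Returns the retained sessions and the retention fraction (nan for an
    empty input).
    """
    retained = [s for s in sessions if s.n_presses >= min_presses]
    fraction = len(retained) / len(sessions) if sessions else float("nan")
    return retained, fraction


def aggregate_participant(
    participant_id: str,
    sessions: Sequence[TypingSession],
    *,
    mode: str = "pooled",
    ht_max_ms: float = DEFAULT_HT_MAX_MS,
    ft_max_ms: float = DEFAULT_FT_MAX_MS,
    ft_min_ms: float | None = None,
    min_presses: int = DEFAULT_MIN_PRESSES,
) -> ParticipantFeatures:
    """Aggregate one participant's sessions into mean HT/FT.

    ``mode="pooled"`` (default) averages all retained keystroke values
    pooled across sessions, weighting sessions by keystroke count;
    ``mode="session_mean"`` averages per-session means instead. A
    participant with no retained data is flagged (``has_data=False``) with
    NaN means so downstream analysis can exclude them.
    """
    if mode not in ("pooled", "session_mean"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    retained, _ = filter_sessions(sessions, min_presses=min_presses)
    pooled_ht: list[float] = []
    pooled_ft: list[float] = []
    session_ht_means: list[float] = []
    session_ft_means: list[float] = []
    n_excl_ht = n_excl_ft = n_keystrokes = 0
    for sess in retained:
        fs = apply_preprocessing_filters(
            extract_features(sess), ht_max_ms=ht_max_ms, ft_max_ms=ft_max_ms, ft_min_ms=ft_min_ms
        )
        n_excl_ht += fs.n_excluded_ht
        n_excl_ft += fs.n_excluded_ft
        n_keystrokes += len(fs.hold_times)
        pooled_ht.extend(fs.hold_times)
        pooled_ft.extend(fs.flight_times)
        if fs.hold_times:
            session_ht_means.append(sum(fs.hold_times) / len(fs.hold_times))
        if fs.flight_times:
            session_ft_means.append(sum(fs.flight_times) / len(fs.flight_times))

    if mode == "pooled":
        ht_src, ft_src = pooled_ht, pooled_ft
    else:
        ht_src, ft_src = session_ht_means, session_ft_means
    has_data = bool(pooled_ht)
    if not has_data:
        logger.info("participant %s has no retained keystrokes; flagged for exclusion", participant_id)
    mean_ht = sum(ht_src) / len(ht_src) if ht_src else float("nan")
    mean_ft = sum(ft_src) / len(ft_src) if ft_src else float("nan")
    return ParticipantFeatures(
        participant_id=participant_id,
        mean_ht=mean_ht,
        mean_ft=mean_ft,
        n_sessions_total=len(sessions),
        n_sessions_retained=len(retained),
        n_keystrokes=n_keystrokes,
        n_excluded_ht=n_excl_ht,
        n_excluded_ft=n_excl_ft,
        has_data=has_data,
    )


def _session_from_record(obj: dict, report: ParseReport) -> TypingSession | None:
    """Build one TypingSession from a raw session object, or None if malformed."""
    try:
        participant_id = str(obj["participant_id"])
        session_id = str(obj["session_id"])
        raw_events = obj["events"]
        if not isinstance(raw_events, list):
            raise TypeError("events must be a list")
    except (KeyError, TypeError) as exc:
        report.n_malformed_records += 1
        logger.warning("rejecting malformed session record: %s", exc)
        return None

    events: list[RawKeyEvent] = []
    for rec in raw_events:
        try:
            action = _ACTION_ALIASES[rec["action"]]
            events.append(
                RawKeyEvent(
                    timestamp=float(rec["t"]),
                    action=action,
                    key_id=str(rec["key"]),
                    session_id=session_id,
                    participant_id=participant_id,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            report.n_malformed_records += 1
            logger.warning("rejecting malformed event record in session %s: %s", session_id, exc)
    report.n_events += len(events)

    timestamps = [e.timestamp for e in events]
    if timestamps != sorted(timestamps):
        report.n_unsorted_sessions += 1
        logger.warning("non-monotone timestamps in session %s; sorting", session_id)
    events.sort(key=lambda e: (e.timestamp, 0 if e.action == PRESS else 1))
    strokes, pairing = pair_events(events)
    return TypingSession(
        session_id=session_id,
        participant_id=participant_id,
        keystrokes=strokes,
        n_presses=pairing.n_press_events,
        pairing=pairing,
    )


def parse_event_log(path: str | Path) -> tuple[list[TypingSession], ParseReport]:
    """Read an event-log file into typing sessions.

    The file is either a JSON array of session objects
    ``{participant_id, session_id, events: [{t, action: down|up, key}]}``
    or a newline-delimited variant (one session object per line).
    Malformed records are rejected, counted in the report and logged;
    a missing file is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event log not found: {path}")
    text = path.read_text()
    report = ParseReport()
    if not text.strip():
        return [], report

    try:
        payload = json.loads(text)
        records = payload if isinstance(payload, list) else [payload]
    except json.JSONDecodeError:
        records = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                report.n_malformed_records += 1
                logger.warning("rejecting unparsable line in %s", path)

    sessions: list[TypingSession] = []
    for obj in records:
        if not isinstance(obj, dict):
            report.n_malformed_records += 1
            continue
        sess = _session_from_record(obj, report)
        if sess is not None:
            sessions.append(sess)
    # stable grouping by participant, preserving first-seen order
    order: dict[str, int] = {}
    for s in sessions:
        order.setdefault(s.participant_id, len(order))
    sessions.sort(key=lambda s: order[s.participant_id])
    report.n_sessions = len(sessions)
    return sessions, report


def sessions_by_participant(
    sessions: Iterable[TypingSession],
) -> dict[str, list[TypingSession]]:
    grouped: dict[str, list[TypingSession]] = defaultdict(list)
    for s in sessions:
        grouped[s.participant_id].append(s)
    return dict(grouped)


def extract_participant_features(
    sessions: Sequence[TypingSession],
    *,
    mode: str = "pooled",
    ht_max_ms: float = DEFAULT_HT_MAX_MS,
    ft_max_ms: float = DEFAULT_FT_MAX_MS,
    ft_min_ms: float | None = None,
    min_presses: int = DEFAULT_MIN_PRESSES,
) -> list[ParticipantFeatures]:
    """Run the full per-participant aggregation over a parsed event log."""
    grouped = sessions_by_participant(sessions)
    return [
        aggregate_participant(
            pid,
            sess,
            mode=mode,
            ht_max_ms=ht_max_ms,
            ft_max_ms=ft_max_ms,
            ft_min_ms=ft_min_ms,
            min_presses=min_presses,
        )
        for pid, sess in grouped.items()
    ]


FEATURE_CSV_COLUMNS = [
    "participant_id",
    "mean_ht_ms",
    "mean_ft_ms",
    "n_sessions_total",
    "n_sessions_retained",
    "n_keystrokes",
    "n_excluded_ht",
    "n_excluded_ft",
]


def features_to_rows(features: Sequence[ParticipantFeatures]) -> list[dict]:
    """Feature rows in the output-CSV schema (flagged participants included)."""
    return [
        {
            "participant_id": f.participant_id,
            "mean_ht_ms": f.mean_ht,
            "mean_ft_ms": f.mean_ft,
            "n_sessions_total": f.n_sessions_total,
            "n_sessions_retained": f.n_sessions_retained,
            "n_keystrokes": f.n_keystrokes,
            "n_excluded_ht": f.n_excluded_ht,
            "n_excluded_ft": f.n_excluded_ft,
        }
        for f in features
    ]
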