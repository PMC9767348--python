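"""Coded behavioral event streams and their combined-signal state sequences.

A mother--infant free-play session is coded on three sensory channels
(auditory, visual, tactile) as intervals ``[onset, offset)`` in seconds.
At any instant the maternal signal configuration is one of eight
presence/absence combinations, encoded as a 3-bit mask::

    bit 0 = auditory, bit 1 = visual, bit 2 = tactile, 0 = no signal

The state sequence of a session is the run-length-deduplicated series of
bitmask states obtained by exact change-point construction from the
interval endpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "CHANNEL_BITS",
    "N_STATES",
    "SignalEvent",
    "SessionRecord",
    "StateSequence",
    "ShortSessionWarning",
    "EventLogError",
    "read_event_log",
    "merge_intervals",
    "build_state_sequence",
    "transition_count",
    "write_state_sequences",
    "state_sequence_summary",
]

#: Channel labels in bit order.
CHANNELS = ("auditory", "visual", "tactile")
CHANNEL_BITS = {name: 1 << i for i, name in enumerate(CHANNELS)}
#: Size of the combined-signal state space (2**3 presence/absence combinations).
N_STATES = 2 ** len(CHANNELS)

#: Sessions shorter than this (seconds) are flagged, mirroring the common
#: exclusion of free-play recordings under 7 minutes.
MIN_SESSION_DURATION_S = 420.0


class EventLogError(ValueError):
    """Malformed behavioral annotation input."""


class ShortSessionWarning(UserWarning):
    """Session duration below the configured minimum."""


@dataclass(frozen=True)
class SignalEvent:
    """One coded interval on a single sensory channel.

    Times are seconds from session start; intervals are half-open
    ``[onset, offset)`` and must have strictly positive duration.
    """

    channel: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_BITS:
            raise EventLogError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if not (self.onset >= 0):
            raise EventLogError(f"onset must be >= 0, got {self.onset}")
        if not (self.offset > self.onset):
            raise EventLogError(
                f"offset must exceed onset, got [{self.onset}, {self.offset})"
            )

    @property
    def bit(self) -> int:
        return CHANNEL_BITS[self.channel]


@dataclass
class SessionRecord:
    """One coded interaction session: events plus total duration.

    ``events`` are validated, clipped to ``[0, duration]`` and merged per
    channel on construction, so same-channel intervals never overlap.
    """

    session_id: str
    duration: float
    events: list[SignalEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise EventLogError(
                f"session {self.session_id!r}: duration must be > 0, "
                f"got {self.duration}"
            )
        self.events = self._normalize(self.events)
        if self.duration < MIN_SESSION_DURATION_S:
            self.metadata.setdefault("flags", []).append("short_session")
            warnings.warn(
                f"session {self.session_id!r} lasts {self.duration:.1f} s "
                f"(< {MIN_SESSION_DURATION_S:.0f} s minimum)",
                ShortSessionWarning,
                stacklevel=3,
            )

    def _normalize(self, events: list[SignalEvent]) -> list[SignalEvent]:
        clipped: list[SignalEvent] = []
        for ev in events:
            if ev.onset >= self.duration:
                warnings.warn(
                    f"session {self.session_id!r}: dropping {ev.channel} event "
                    f"starting at {ev.onset} s, past duration {self.duration} s",
                    UserWarning,
                    stacklevel=4,
                )
                continue
            if ev.offset > self.duration:
                warnings.warn(
                    f"session {self.session_id!r}: clipping {ev.channel} event "
                    f"[{ev.onset}, {ev.offset}) to duration {self.duration} s",
                    UserWarning,
                    stacklevel=4,
                )
                ev = SignalEvent(ev.channel, ev.onset, self.duration)
            clipped.append(ev)
        merged: list[SignalEvent] = []
        for channel in CHANNELS:
            ivals = [(e.onset, e.offset) for e in clipped if e.channel == channel]
            for onset, offset in merge_intervals(ivals):
                merged.append(SignalEvent(channel, onset, offset))
        merged.sort(key=lambda e: (e.onset, e.offset, e.channel))
        return merged


@dataclass(frozen=True)
class StateSequence:
    """Run-length-deduplicated combined-signal states of one session."""

    session_id: str
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        for s in self.states:
            if not (0 <= s < N_STATES):
                raise ValueError(f"state {s} outside 0..{N_STATES - 1}")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("consecutive states must be distinct")

    @property
    def n_transitions(self) -> int:
        return len(self.states) - 1

    def __len__(self) -> int:
        return len(self.states)


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union overlapping or touching half-open intervals.

    Idempotent and independent of input order; ``[0, 5)`` and ``[3, 8)``
    merge to ``[0, 8)``, and abutting ``[0, 3)``/``[3, 5)`` merge too
    (the channel is simply *on* throughout).
    """
    if not intervals:
        return []
    out: list[tuple[float, float]] = []
    for onset, offset in sorted(intervals):
        if out and onset <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], offset))
        else:
            out.append((onset, offset))
    return out


_REQUIRED_COLUMNS = ("session_id", "channel", "onset_s", "offset_s")


def read_event_log(
    path,
    dialect: str = ",",
    durations: dict[str, float] | None = None,
) -> list[SessionRecord]:
    """Read a delimited behavioral annotation log into SessionRecords.

    The file must carry a header ``session_id,channel,onset_s,offset_s``
    with an optional ``duration_s`` column; channel labels are lowercase
    ``auditory`` / ``visual`` / ``tactile``.  ``durations`` may supply
    per-session durations when the column is absent; otherwise the
    largest offset of the session is used (with a warning).

    Parameters
    ----------
    path : str or path-like
        Delimited UTF-8 text file.
    dialect : str
        Field delimiter (default comma).
    durations : dict, optional
        Sidecar mapping session_id -> duration in seconds.

    Returns
    -------
    list of SessionRecord, one per distinct session_id, in order of first
    appearance.
    """
    df = pd.read_csv(path, sep=dialect, dtype={"session_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"{path}: missing required column(s) {missing}")
    sessions: list[SessionRecord] = []
    for sid, grp in df.groupby("session_id", sort=False):
        events = []
        for row in grp.itertuples():
            # itertuples Index is the original 0-based row; +2 = file line with header
            line = row.Index + 2
            channel = str(row.channel).strip()
            if channel not in CHANNEL_BITS:
                raise EventLogError(
                    f"{path} line {line}: unknown channel {channel!r} "
                    f"(expected one of {CHANNELS})"
                )
            onset, offset = float(row.onset_s), float(row.offset_s)
            if not np.isfinite(onset) or not np.isfinite(offset) or offset <= onset:
                raise EventLogError(
                    f"{path} line {line}: invalid interval [{onset}, {offset})"
                )
            events.append(SignalEvent(channel, onset, offset))
        if "duration_s" in grp.columns and grp["duration_s"].notna().any():
            duration = float(grp["duration_s"].dropna().iloc[0])
        elif durations is not None and sid in durations:
            duration = float(durations[sid])
        elif events:
            duration = max(e.offset for e in events)
            warnings.warn(
                f"session {sid!r}: no duration given; using last offset "
                f"{duration:.3f} s",
                UserWarning,
                stacklevel=2,
            )
        else:
            raise EventLogError(f"session {sid!r}: no duration and no events")
        sessions.append(SessionRecord(str(sid), duration, events))
    return sessions


def _masks_at(session: SessionRecord, times: np.ndarray) -> np.ndarray:
    """Channel bitmask at each query time (vectorized over sorted events)."""
    masks = np.zeros(len(times), dtype=np.int64)
    for channel, bit in CHANNEL_BITS.items():
        ivals = [(e.onset, e.offset) for e in session.events if e.channel == channel]
        if not ivals:
            continue
        onsets = np.array([iv[0] for iv in ivals])
        offsets = np.array([iv[1] for iv in ivals])
        idx = np.searchsorted(onsets, times, side="right") - 1
        on = (idx >= 0) & (times < offsets[np.clip(idx, 0, None)])
        masks[on] |= bit
    return masks


def build_state_sequence(
    session: SessionRecord, bin_width: float | None = None
) -> StateSequence:
    """Derive the combined-signal state sequence of a session.

    By default an exact change-point construction is used: all onsets and
    offsets are pooled and sorted; on each half-open segment between
    consecutive change points the channel bitmask is constant and is
    evaluated exactly.  Consecutive equal states are then collapsed, so the
    result records only *changes* of the signal combination.  The initial
    state is the configuration at t = 0 (state 0 when no event covers the
    session start).  A session with no events yields the single state
    ``[0]``.

    ``bin_width`` (seconds) switches to a fixed-grid sampling of the
    bitmask at ``0, w, 2w, ...`` — a sensitivity mode emulating a coarser
    moment-by-moment coding clock; brief configurations shorter than one
    bin may then be missed.
    """
    if bin_width is not None:
        if not bin_width > 0:
            raise ValueError("bin_width must be > 0")
        cuts = np.arange(0.0, session.duration, bin_width)
    else:
        times = {0.0}
        for ev in session.events:
            times.add(ev.onset)
            times.add(ev.offset)
        cuts = np.array(sorted(t for t in times if 0.0 <= t < session.duration))
    masks = _masks_at(session, cuts)
    keep = np.ones(len(masks), dtype=bool)
    keep[1:] = masks[1:] != masks[:-1]
    return StateSequence(session.session_id, tuple(int(m) for m in masks[keep]))


def transition_count(seq: StateSequence) -> int:
    """Number of state changes in the sequence (``len(states) - 1``)."""
    return seq.n_transitions


def state_sequence_summary(seq: StateSequence) -> dict:
    """JSON-ready summary: transition count and state dwell fractions.

    Dwell fractions here are occupancy shares of sequence *steps* (the
    sequence abstracts away physical dwell times).
    """
    states = np.asarray(seq.states)
    counts = np.bincount(states, minlength=N_STATES)
    return {
        "session_id": seq.session_id,
        "n_transitions": seq.n_transitions,
        "n_states_visited": int((counts > 0).sum()),
        "dwell_fractions": (counts / len(states)).round(6).tolist(),
    }


def write_state_sequences(sequences: list[StateSequence], csv_path, json_path=None) -> None:
    """Export sequences as ``session_id,step,state`` plus a JSON summary."""
    rows = [
        {"session_id": s.session_id, "step": i, "state": st}
        for s in sequences
        for i, st in enumerate(s.states)
    ]
    pd.DataFrame(rows, columns=["session_id", "step", "state"]).to_csv(
        csv_path, index=False
    )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([state_sequence_summary(s) for s in sequences], fh, indent=2)
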