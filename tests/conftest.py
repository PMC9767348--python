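"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from entrate.events import CHANNELS, SessionRecord, SignalEvent


def rasterized_states(session: SessionRecord, tick_s: float = 0.001) -> list[int]:
    """Brute-force oracle: sample the channel bitmask on a fine fixed grid.

    Ticks at 0, tick_s, 2*tick_s, ... < duration; at each tick the mask is
    the OR over events covering it; the tick series is then run-length
    deduplicated.  Event endpoints must lie on the grid for the result to
    be exact.
    """
    n_ticks = int(round(session.duration / tick_s))
    ticks = np.arange(n_ticks) / (1.0 / tick_s)
    masks = np.zeros(n_ticks, dtype=int)
    for ev in session.events:
        covered = (ticks >= ev.onset) & (ticks < ev.offset)
        masks[covered] |= ev.bit
    out = [int(masks[0])]
    for m in masks[1:]:
        if m != out[-1]:
            out.append(int(m))
    return out


def random_session(rng: np.random.Generator, max_ms: int = 20_000) -> SessionRecord:
    """Random coded session with integer-millisecond endpoints."""
    duration_ms = int(rng.integers(1_000, max_ms))
    n_events = int(rng.integers(0, 12))
    events = []
    for _ in range(n_events):
        onset_ms = int(rng.integers(0, duration_ms - 1))
        offset_ms = int(rng.integers(onset_ms + 1, duration_ms + 1))
        channel = CHANNELS[rng.integers(len(CHANNELS))]
        events.append(SignalEvent(channel, onset_ms / 1000.0, offset_ms / 1000.0))
    return SessionRecord(f"rand-{rng.integers(1 << 30)}", duration_ms / 1000.0, events)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def three_event_session() -> SessionRecord:
    """Overlapping auditory/tactile/visual events walking through 6 states."""
    return SessionRecord(
        "toy-3ev",
        30.0,
        [
            SignalEvent("auditory", 0.0, 5.0),
            SignalEvent("tactile", 2.0, 7.0),
            SignalEvent("visual", 4.0, 6.0),
        ],
    )


@pytest.fixture(autouse=True)
def _quiet_short_session_warnings():
    """Short toy sessions are expected throughout; silence the flag noise."""
    import warnings

    from entrate.events import ShortSessionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortSessionWarning)
        yield
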