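"""Stance-phase extraction from raw force traces.

A stance phase is a maximal run of samples whose force exceeds a 30 N
contact threshold.  Interior runs of at most three consecutive samples that
are missing (device fault) or at/below threshold do not terminate the
event; longer interruptions do.  Events shorter than 300 ms or longer than
3500 ms are discarded as non-stride activity.  An event can neither start
nor end on a bridged gap: its boundaries are always genuinely loaded
samples.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .data import RawRecording, StanceEvent

#: contact threshold (newtons); loading means force strictly above this
DEFAULT_THRESHOLD_N = 30.0
#: max interior run of missing/sub-threshold samples bridged into an event
DEFAULT_GAP_SAMPLES = 3
#: duration bounds for a plausible stance (milliseconds, inclusive)
DEFAULT_MIN_MS = 300.0
DEFAULT_MAX_MS = 3500.0


def detect_stance_events(
    rec: RawRecording,
    *,
    threshold_n: float = DEFAULT_THRESHOLD_N,
    gap_samples: int = DEFAULT_GAP_SAMPLES,
    min_ms: float = DEFAULT_MIN_MS,
    max_ms: float = DEFAULT_MAX_MS,
) -> List[StanceEvent]:
    """Extract stance events from a recording.

    Returns time-ordered, non-overlapping :class:`StanceEvent` objects.
    Bridged interior samples keep their recorded values; missing samples
    inside a bridged gap are linearly interpolated from their neighbours so
    the sample grid stays uniform.  An empty list is a valid result.
    """
    f = rec.forces
    n = f.size
    if n == 0:
        return []
    above = np.zeros(n, dtype=bool)
    finite = np.isfinite(f)
    above[finite] = f[finite] > threshold_n

    # maximal runs of above-threshold samples
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1

    # merge runs separated by <= gap_samples interior samples
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] - 1 <= gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: List[StanceEvent] = []
    for s, e in merged:
        dur_ms = (e - s + 1) * 1000.0 / rec.sample_rate_hz
        if dur_ms < min_ms or dur_ms > max_ms:
            continue
        seg = f[s : e + 1].copy()
        missing = ~np.isfinite(seg)
        if missing.any():
            # interior only: boundaries are above threshold, hence present
            idx = np.arange(seg.size)
            seg[missing] = np.interp(idx[missing], idx[~missing], seg[~missing])
        events.append(
            StanceEvent(
                source=rec,
                start_index=rec.start_index + int(s),
                end_index=rec.start_index + int(e),
                samples=seg,
            )
        )
    return events
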