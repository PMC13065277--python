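"""Floor transfers and floor-transfer offsets (FTOs) in a triad.

A *floor transfer* is the moment the active-speaker role passes from one
interlocutor to a different one.  Its signed offset is the time between
the outgoing speaker's offset and the incoming speaker's onset: positive
offsets are gaps (silence between turns), negative offsets are overlaps
(the incomer starts before the floor holder finishes and keeps talking).
Same-speaker resumptions and failed interjections — an incomer who stops
before the floor holder does, e.g. a backchannel — are not transfers and
produce no event.

When two candidates could take the floor after a gap, the earlier
starter wins; ties are broken by the longer next segment, then by
lexicographic speaker id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vad import UtteranceSet


@dataclass
class TurnEvent:
    kind: str  # "gap" | "overlap"
    from_speaker: str
    to_speaker: str
    offset_s: float  # gap >= 0, overlap < 0
    at_time_s: float  # end of the outgoing speaker's segment

    def __post_init__(self):
        if self.kind not in ("gap", "overlap"):
            raise ValueError(f"unknown turn-event kind {self.kind!r}")
        if self.from_speaker == self.to_speaker:
            raise ValueError("a floor transfer joins two distinct speakers")
        if self.kind == "gap" and self.offset_s < 0:
            raise ValueError("gap events need offset >= 0")
        if self.kind == "overlap" and self.offset_s >= 0:
            raise ValueError("overlap events need offset < 0")


@dataclass
class TurnSummary:
    median_gap_s: float
    median_overlap_s: float  # negative by convention
    gap_rate_per_min: float
    overlap_rate_per_min: float
    n_transfers: int
    ftos: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "median_gap_s": self.median_gap_s,
            "median_overlap_s": self.median_overlap_s,
            "gap_rate_per_min": self.gap_rate_per_min,
            "overlap_rate_per_min": self.overlap_rate_per_min,
            "n_transfers": self.n_transfers,
        }


def _segment_records(utterances: dict) -> list:
    segs = []
    for speaker, uset in utterances.items():
        iv = uset.intervals if isinstance(uset, UtteranceSet) else np.asarray(
            uset, dtype=float).reshape(-1, 2)
        for s, e in iv:
            segs.append((float(s), float(e), str(speaker)))
    return segs


def _pick(cands: list) -> tuple:
    """Earliest start; ties: longer segment, then lexicographic speaker."""
    return min(cands, key=lambda seg: (seg[0], -(seg[1] - seg[0]), seg[2]))


def find_floor_transfers(utterances: dict) -> list:
    """Extract the chronological list of floor transfers.

    Parameters
    ----------
    utterances : dict
        speaker id -> :class:`UtteranceSet` (or (n, 2) interval array);
        each speaker's segments must be disjoint.

    The scan follows the floor holder: when the holder's segment ends at
    ``t_e``, another speaker already talking past ``t_e`` captures the
    floor (overlap, offset = their start - t_e < 0); otherwise the first
    segment starting at or after ``t_e`` takes it (gap, offset >= 0),
    unless it belongs to the holder (resumption, no event).
    """
    segs = _segment_records(utterances)
    if not segs:
        return []
    segs.sort(key=lambda seg: (seg[0], seg[2]))

    first = _pick(segs)
    floor, cur_end = first[2], first[1]
    events: list[TurnEvent] = []

    while True:
        t_e = cur_end
        over = [s for s in segs if s[2] != floor and s[0] < t_e and s[1] > t_e]
        if over:
            b = _pick(over)
            events.append(TurnEvent("overlap", floor, b[2], b[0] - t_e, t_e))
            floor, cur_end = b[2], b[1]
            continue
        upcoming = [s for s in segs if s[0] >= t_e]
        if not upcoming:
            break
        b = _pick(upcoming)
        if b[2] != floor:
            events.append(TurnEvent("gap", floor, b[2], b[0] - t_e, t_e))
        floor, cur_end = b[2], b[1]
    return events


def fto_summary(events: list, duration_s: float | None = None) -> TurnSummary:
    """Median gap/overlap durations and per-minute rates.

    ``duration_s`` is the conversation duration used for the rates; when
    omitted, rates are NaN.  Medians of an empty event class are NaN.
    """
    gaps = np.array([e.offset_s for e in events if e.kind == "gap"])
    overlaps = np.array([e.offset_s for e in events if e.kind == "overlap"])
    minutes = duration_s / 60.0 if duration_s else np.nan
    return TurnSummary(
        median_gap_s=float(np.median(gaps)) if len(gaps) else float("nan"),
        median_overlap_s=float(np.median(overlaps)) if len(overlaps) else float("nan"),
        gap_rate_per_min=len(gaps) / minutes if minutes and np.isfinite(minutes)
        else float("nan"),
        overlap_rate_per_min=len(overlaps) / minutes if minutes and
        np.isfinite(minutes) else float("nan"),
        n_transfers=len(events),
        ftos=np.array([e.offset_s for e in events]),
    )


def fto_histogram(offsets, bin_width: float = 0.25):
    """Histogram of FTOs in fixed-width bins aligned on the zero boundary.

    Returns ``(bin_edges, counts, kde)`` where bins are half-open
    ``[left, left + bin_width)``, counts sum to the number of events, and
    ``kde`` is a Gaussian kernel density estimate (None when fewer than
    two distinct offsets are available).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if hasattr(offsets, "__iter__") and len(offsets) and isinstance(
            offsets[0], TurnEvent):
        offsets = [e.offset_s for e in offsets]
    offsets = np.asarray(offsets, dtype=float)
    if not len(offsets):
        return np.array([0.0, bin_width]), np.zeros(1, dtype=int), None
    idx = np.floor(offsets / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = (np.arange(lo, hi + 2)) * bin_width
    kde = None
    if len(offsets) >= 2 and np.ptp(offsets) > 0:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(offsets)
    return edges, counts, kde
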