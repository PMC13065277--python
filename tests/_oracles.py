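"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's optimised code paths: the
merge/discard oracle works by exhaustive pairwise interval scanning to
convergence, and the floor-transfer oracle is a literal transcription of
the transfer definitions with full rescans at every step.
"""

import numpy as np


def oracle_merge_segments(mask, times, dt, merge_pause, min_duration):
    """Sections from a boolean mask, merged pairwise to convergence,
    then filtered by duration."""
    secs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = times[i]
        if not m and start is not None:
            secs.append([start, times[i]])
            start = None
    if start is not None:
        secs.append([start, times[-1] + dt])
    changed = True
    while changed:
        changed = False
        for i in range(len(secs)):
            for j in range(len(secs)):
                if i == j:
                    continue
                a, b = secs[i], secs[j]
                gap = max(b[0] - a[1], a[0] - b[1])
                if gap < merge_pause:
                    secs[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del secs[j]
                    changed = True
                    break
            if changed:
                break
    return sorted([s for s in secs if s[1] - s[0] >= min_duration])


def oracle_floor_transfers(utterances):
    """Floor transfers from first principles: follow the floor holder and
    rescan all segments at every segment end."""
    segs = [(float(s), float(e), spk)
            for spk, u in utterances.items() for s, e in u.intervals]
    if not segs:
        return []

    def rank(seg):
        return (seg[0], -(seg[1] - seg[0]), seg[2])

    events = []
    current = min(segs, key=rank)
    while True:
        t_e = current[1]
        holder = current[2]
        extending = [s for s in segs if s[2] != holder and s[1] > t_e]
        if not extending:
            break
        running = [s for s in extending if s[0] < t_e]
        if running:
            nxt = min(running, key=rank)
            events.append(("overlap", holder, nxt[2], nxt[0] - t_e, t_e))
            current = nxt
            continue
        own_next = [s for s in segs if s[2] == holder and s[0] >= t_e]
        nxt = min(extending, key=rank)
        if own_next and rank(min(own_next, key=rank)) < rank(nxt):
            current = min(own_next, key=rank)
            continue
        events.append(("gap", holder, nxt[2], nxt[0] - t_e, t_e))
        current = nxt
    return events


def random_activity_mask(rng, n):
    """Blocky random activity mask with realistic run lengths."""
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        run = int(rng.integers(1, 80))
        if rng.random() < 0.5:
            mask[i:i + run] = True
        i += run
    return mask


def random_triadic_schedule(rng, max_segments=40):
    """Random 3-speaker utterance schedules with per-speaker disjointness."""
    from triadtalk.vad import UtteranceSet

    utts = {}
    total = 0
    for spk in ("A", "B", "C"):
        n = int(rng.integers(0, 14))
        n = min(n, max_segments - total)
        total += n
        t = float(rng.uniform(0, 3))
        iv = []
        for _ in range(n):
            d = float(rng.uniform(0.2, 3.0))
            iv.append([t, t + d])
            t += d + float(rng.uniform(0.05, 3.0))
        utts[spk] = UtteranceSet(spk, np.array(iv).reshape(-1, 2))
    return utts
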