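"""Naive token-by-token risk-plot simulator used as an independent oracle.

Deliberately simple-minded: stairs are found by linear scan, tokens move one
at a time, and window bookkeeping is recomputed from scratch.  Kept free of
any code from riskplot.core so that agreement between the two is evidence,
not tautology.
"""

from __future__ import annotations


def naive_assign(rri, edges, oor_policy):
    k = len(edges) - 1
    if rri < edges[0]:
        return 0 if oor_policy == "clamp" else -1
    if rri > edges[-1]:
        return k - 1 if oor_policy == "clamp" else -1
    if rri == edges[-1]:
        return k - 1
    for j in range(k):
        if edges[j] <= rri < edges[j + 1]:
            return j
    raise AssertionError("unreachable")


def naive_trace(intervals, mask, edges, drain_rate, capacity, window_beats,
                oor_policy="clamp"):
    """Simulate the plot beat by beat; returns per-beat rows and window dicts.

    Each row: (stair, occupancy tuple, valley, projected, dropped, any_stuck)
    with stair == -2 for flagged beats and -1 for dropped ones.  Window dicts
    carry projection counts, stuck-beat counts and terminal totals.
    """
    K = len(edges) - 1
    occ = [0] * K
    stuck = [False] * K
    valley = projected = dropped = 0
    rows = []
    windows = []
    win_counts = [0] * K
    win_stuck = 0
    win_start = 0

    def reset(end, partial):
        nonlocal occ, stuck, valley, projected, dropped, win_counts, win_stuck, win_start
        windows.append({
            "start_beat": win_start, "n_beats": end - win_start,
            "projection_counts": tuple(win_counts), "stuck_beats": win_stuck,
            "projected": projected, "valley": valley, "dropped": dropped,
            "terminal_occupancy": tuple(occ), "partial": partial,
        })
        occ = [0] * K
        stuck = [False] * K
        valley = projected = dropped = 0
        win_counts = [0] * K
        win_stuck = 0
        win_start = end

    for i, rri in enumerate(intervals):
        if mask[i]:
            stair = -2
        else:
            stair = naive_assign(float(rri), edges, oor_policy)
            projected += 1
            if stair == -1:
                dropped += 1
            else:
                occ[stair] += 1
                if occ[stair] >= capacity:
                    stuck[stair] = True
                win_counts[stair] += 1
            for k in range(K):
                if stuck[k]:
                    continue
                for _ in range(drain_rate):   # one token at a time
                    if occ[k] > 0:
                        occ[k] -= 1
                        valley += 1
        any_now = any(stuck)
        if any_now:
            win_stuck += 1
        rows.append((stair, tuple(occ), valley, projected, dropped, any_now))
        if (i + 1 - win_start) == window_beats:
            reset(i + 1, False)
    if win_start < len(intervals):
        reset(len(intervals), True)
    return rows, windows
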