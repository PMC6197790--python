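"""The risk-plot (RP) state machine.

Each RR interval is one indivisible token, thrown ("projected") onto the
stair whose bin contains it.  After every projection, a spring under each
stair drains up to ``drain_rate`` tokens from that stair into the valley of
life — unless the stair is *stuck*: once a stair's occupancy reaches
``capacity``, its spring fails and the stair drains nothing.  Because a
stuck stair cannot fall below capacity within a window, stuckness is
absorbing until the periodic window reset (every ``window_beats`` beats),
which restores a time-resolved signal.

Healthy, dispersed RR streams spread tokens over many stairs and the springs
keep every stair clear; a collapsing-variability stream concentrates tokens
on one or two stairs, which is what the downstream risk index measures.

Conservation invariant maintained by every operation::

    projected == sum(occupancy) + valley + dropped
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import RRISeries

__all__ = [
    "RiskPlotConfig",
    "RiskPlotState",
    "WindowSummary",
    "RiskPlotTrace",
    "assign_stair",
    "project_beat",
    "drain_step",
    "run_risk_plot",
    "occupancy_histogram",
    "DROPPED",
]

#: sentinel returned by :func:`assign_stair` when the drop policy discards a beat
DROPPED = -1


def default_stair_edges() -> np.ndarray:
    """24 stairs of 50 ms spanning 0.275–1.475 s.

    The grid is centred so that 0.8 s — the canonical resting RR interval —
    falls at a bin centre rather than on an edge; a narrow near-death RR
    distribution then lands on one stair instead of splitting across two,
    which keeps the concentration signal sharp.
    """
    return np.round(np.arange(0.275, 1.475 + 1e-9, 0.05), 3)


@dataclass
class RiskPlotConfig:
    """Stair geometry and spring dynamics.

    stair_edges : increasing bin boundaries (s); K = len(edges) - 1 stairs.
    drain_rate : tokens each non-stuck stair drains per beat step (d >= 0).
    capacity : occupancy at which a spring fails (stuck), C > d.
    window_beats : beats per analysis window; state resets at each boundary.
    oor_policy : 'clamp' sends out-of-range intervals to the edge stair,
        'drop' discards them (counted, for conservation).
    """

    stair_edges: np.ndarray = field(default_factory=default_stair_edges)
    drain_rate: int = 1
    capacity: int = 8
    window_beats: int = 300
    oor_policy: str = "clamp"

    def __post_init__(self) -> None:
        self.stair_edges = np.asarray(self.stair_edges, dtype=float)
        if self.stair_edges.size < 3 or np.any(np.diff(self.stair_edges) <= 0):
            raise ValueError("stair_edges must be strictly increasing with >= 2 stairs")
        if self.drain_rate < 0:
            raise ValueError("drain_rate must be >= 0")
        if self.capacity < 1 or self.capacity <= self.drain_rate:
            raise ValueError("capacity must satisfy C >= 1 and C > drain_rate")
        if self.window_beats < 1:
            raise ValueError("window_beats must be >= 1")
        if self.oor_policy not in ("clamp", "drop"):
            raise ValueError(f"oor_policy must be 'clamp' or 'drop', got {self.oor_policy!r}")

    @property
    def n_stairs(self) -> int:
        return int(self.stair_edges.size - 1)


@dataclass
class RiskPlotState:
    """Instantaneous RP configuration (token counts and spring status)."""

    occupancy: list[int]
    stuck: list[bool]
    valley: int = 0
    projected: int = 0
    dropped: int = 0

    @classmethod
    def empty(cls, n_stairs: int) -> "RiskPlotState":
        return cls(occupancy=[0] * n_stairs, stuck=[False] * n_stairs)

    def copy(self) -> "RiskPlotState":
        return RiskPlotState(occupancy=list(self.occupancy), stuck=list(self.stuck),
                             valley=self.valley, projected=self.projected,
                             dropped=self.dropped)

    def conserved(self) -> bool:
        return self.projected == sum(self.occupancy) + self.valley + self.dropped


@dataclass
class WindowSummary:
    """Per-window aggregate recorded at each reset (or at end of series)."""

    window_id: int
    start_beat: int            # index of first interval in the window
    n_beats: int               # intervals covered (flagged ones included)
    projection_counts: np.ndarray  # beats landing on each stair (K-vector)
    stuck_beats: int           # beats during which >= 1 stair was stuck
    projected: int
    valley: int
    dropped: int
    terminal_state: RiskPlotState
    partial: bool = False      # True when the series ended mid-window


@dataclass
class RiskPlotTrace:
    """Per-beat evolution of the RP plus window summaries.

    Per-beat arrays cover every interval of the input series in order;
    flagged beats carry stair index -2 and leave the state unchanged.
    """

    config: RiskPlotConfig
    stair_of_beat: np.ndarray        # stair index, DROPPED (-1), or -2 flagged
    occupancy_by_beat: np.ndarray    # (n_beats, K) post-drain occupancy
    valley_by_beat: np.ndarray
    projected_by_beat: np.ndarray
    dropped_by_beat: np.ndarray
    any_stuck_by_beat: np.ndarray    # bool, post-drain
    windows: list[WindowSummary]

    @property
    def n_beats(self) -> int:
        return int(self.stair_of_beat.size)

    def complete_windows(self) -> list[WindowSummary]:
        return [w for w in self.windows if not w.partial]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def assign_stair(rri: float, config: RiskPlotConfig) -> int:
    """Bin an interval: half-open stairs, the last stair closed on the right.

    Out-of-range intervals follow ``oor_policy``: clamp to the nearest edge
    stair, or return :data:`DROPPED`.
    """
    if rri <= 0:
        raise ValueError(f"RR interval must be > 0, got {rri}")
    edges = config.stair_edges
    k = config.n_stairs
    if rri < edges[0]:
        return 0 if config.oor_policy == "clamp" else DROPPED
    if rri > edges[-1]:
        return k - 1 if config.oor_policy == "clamp" else DROPPED
    if rri == edges[-1]:  # right edge of the last stair is closed
        return k - 1
    return bisect_right(edges, rri) - 1


def project_beat(state: RiskPlotState, rri: float, config: RiskPlotConfig) -> RiskPlotState:
    """Throw one token: increment its stair (or the drop counter)."""
    new = state.copy()
    stair = assign_stair(rri, config)
    new.projected += 1
    if stair == DROPPED:
        new.dropped += 1
    else:
        new.occupancy[stair] += 1
        new.stuck[stair] = new.occupancy[stair] >= config.capacity
    return new


def drain_step(state: RiskPlotState, config: RiskPlotConfig) -> RiskPlotState:
    """Springs fire once: every non-stuck stair drains up to d tokens."""
    new = state.copy()
    d = config.drain_rate
    for k in range(len(new.occupancy)):
        if new.stuck[k]:
            continue
        moved = min(d, new.occupancy[k])
        new.occupancy[k] -= moved
        new.valley += moved
        new.stuck[k] = new.occupancy[k] >= config.capacity
    return new


def occupancy_histogram(state: RiskPlotState) -> np.ndarray:
    """Current token count on each stair (K-vector)."""
    return np.asarray(state.occupancy, dtype=np.int64)


# ---------------------------------------------------------------------------
# streaming driver
# ---------------------------------------------------------------------------

def run_risk_plot(series: RRISeries, mask: Optional[Sequence[bool]] = None,
                  config: RiskPlotConfig | None = None) -> RiskPlotTrace:
    """Drive the RP over a whole interval series.

    Each unflagged beat is projected and then one drain step fires; flagged
    beats (``mask[i]`` truthy) are skipped entirely but still advance the
    window clock.  Every ``window_beats`` beats the pre-reset state is
    recorded as that window's terminal state and the plot empties.  A
    trailing partial window is summarised with ``partial=True``.
    """
    config = config or RiskPlotConfig()
    n = len(series)
    if n == 0:
        raise ValueError("interval series is empty")
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != n:
            raise ValueError("mask length must match number of intervals")

    K = config.n_stairs
    W = config.window_beats
    d = config.drain_rate
    C = config.capacity

    # mutable engine state kept as plain lists for speed
    occ = [0] * K
    stuck = [False] * K
    valley = projected = dropped = 0

    stair_of_beat = np.empty(n, dtype=np.int64)
    occupancy_by_beat = np.empty((n, K), dtype=np.int64)
    valley_by_beat = np.empty(n, dtype=np.int64)
    projected_by_beat = np.empty(n, dtype=np.int64)
    dropped_by_beat = np.empty(n, dtype=np.int64)
    any_stuck_by_beat = np.empty(n, dtype=bool)

    windows: list[WindowSummary] = []
    win_counts = [0] * K
    win_stuck_beats = 0
    win_start = 0

    def close_window(end_beat: int, partial: bool) -> None:
        nonlocal win_counts, win_stuck_beats, win_start, occ, stuck
        nonlocal valley, projected, dropped
        terminal = RiskPlotState(occupancy=list(occ), stuck=list(stuck),
                                 valley=valley, projected=projected, dropped=dropped)
        windows.append(WindowSummary(
            window_id=len(windows), start_beat=win_start,
            n_beats=end_beat - win_start,
            projection_counts=np.asarray(win_counts, dtype=np.int64),
            stuck_beats=win_stuck_beats, projected=projected, valley=valley,
            dropped=dropped, terminal_state=terminal, partial=partial))
        occ = [0] * K
        stuck = [False] * K
        valley = projected = dropped = 0
        win_counts = [0] * K
        win_stuck_beats = 0
        win_start = end_beat

    for i in range(n):
        if mask[i]:
            stair_of_beat[i] = -2
        else:
            rri = float(series.intervals[i])
            stair = assign_stair(rri, config)
            stair_of_beat[i] = stair
            projected += 1
            if stair == DROPPED:
                dropped += 1
            else:
                occ[stair] += 1
                if occ[stair] >= C:
                    stuck[stair] = True
                win_counts[stair] += 1
            # drain step: every non-stuck stair fires once
            if d > 0:
                for k in range(K):
                    if stuck[k] or occ[k] == 0:
                        continue
                    moved = d if occ[k] >= d else occ[k]
                    occ[k] -= moved
                    valley += moved
                    if occ[k] >= C:  # cannot happen with d>0, kept for clarity
                        stuck[k] = True

        any_now = any(stuck)
        if any_now:
            win_stuck_beats += 1
        occupancy_by_beat[i, :] = occ
        valley_by_beat[i] = valley
        projected_by_beat[i] = projected
        dropped_by_beat[i] = dropped
        any_stuck_by_beat[i] = any_now

        if (i + 1 - win_start) == W:
            close_window(i + 1, partial=False)

    if win_start < n:
        close_window(n, partial=True)

    return RiskPlotTrace(config=config, stair_of_beat=stair_of_beat,
                         occupancy_by_beat=occupancy_by_beat,
                         valley_by_beat=valley_by_beat,
                         projected_by_beat=projected_by_beat,
                         dropped_by_beat=dropped_by_beat,
                         any_stuck_by_beat=any_stuck_by_beat,
                         windows=windows)
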