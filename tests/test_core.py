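"""Risk-plot token dynamics: binning, projection, drainage, windows.

The hand-worked expectations in TestRunRiskPlot were derived by simulating
the beat/drain cycle on paper before the engine was written.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reference import naive_trace
from riskplot import (RiskPlotConfig, RiskPlotState, RRISeries, assign_stair,
                      drain_step, occupancy_histogram, project_beat,
                      run_risk_plot)
from riskplot.core import DROPPED

DECIMETER_EDGES = np.round(np.arange(0.3, 1.5 + 1e-9, 0.1), 3)  # 12 stairs


def cfg(**kw):
    kw.setdefault("stair_edges", DECIMETER_EDGES)
    return RiskPlotConfig(**kw)


class TestAssignStair:
    def test_interior_bin(self):
        assert assign_stair(0.80, cfg()) == 5

    def test_right_edge_closed(self):
        assert assign_stair(1.50, cfg()) == 11

    def test_out_of_range_policies(self):
        assert assign_stair(2.0, cfg(oor_policy="clamp")) == 11
        assert assign_stair(2.0, cfg(oor_policy="drop")) == DROPPED
        assert assign_stair(0.1, cfg(oor_policy="clamp")) == 0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            assign_stair(0.0, cfg())

    def test_left_edges_belong_to_their_bin(self):
        for k, edge in enumerate(DECIMETER_EDGES[:-1]):
            assert assign_stair(float(edge), cfg()) == k


class TestProjectAndDrain:
    def test_projection_increments_one_stair(self):
        state = RiskPlotState.empty(12)
        new = project_beat(state, 0.85, cfg())
        assert new.occupancy[5] == 1 and new.valley == 0 and new.projected == 1
        assert state.occupancy[5] == 0  # input untouched

    def test_reaching_capacity_sets_stuck(self):
        c = cfg(capacity=8)
        state = RiskPlotState.empty(12)
        state.occupancy[5] = 7
        state.projected = 7
        new = project_beat(state, 0.85, c)
        assert new.occupancy[5] == 8 and new.stuck[5]

    def test_drop_preserves_conservation(self):
        state = RiskPlotState.empty(12)
        new = project_beat(state, 2.5, cfg(oor_policy="drop"))
        assert new.projected == 1 and new.dropped == 1
        assert sum(new.occupancy) == 0 and new.conserved()

    def test_drain_moves_min_of_rate_and_occupancy(self):
        c = cfg(drain_rate=2, capacity=8)
        state = RiskPlotState.empty(12)
        state.occupancy[0] = 3
        state.projected = 3
        new = drain_step(state, c)
        assert new.occupancy[0] == 1 and new.valley == 2

    def test_stuck_stair_drains_nothing(self):
        c = cfg(drain_rate=2, capacity=8)
        state = RiskPlotState.empty(12)
        state.occupancy[0] = 9
        state.stuck[0] = True
        state.projected = 9
        new = drain_step(state, c)
        assert new.occupancy[0] == 9 and new.valley == 0

    def test_drain_clears_small_occupancies(self):
        c = cfg(drain_rate=2, capacity=8)
        state = RiskPlotState.empty(12)
        state.occupancy[0] = state.occupancy[1] = 1
        state.projected = 2
        new = drain_step(state, c)
        assert sum(new.occupancy) == 0 and new.valley == 2

    def test_histogram_is_occupancy(self):
        state = RiskPlotState.empty(12)
        assert occupancy_histogram(state).sum() == 0
        new = project_beat(state, 0.85, cfg(drain_rate=0))
        hist = occupancy_histogram(new)
        assert hist[5] == 1 and hist.sum() == 1


class TestRunRiskPlot:
    def test_drain_keeps_pace_with_identical_rris(self):
        """3 identical beats, d=1: each token drains immediately."""
        series = RRISeries(intervals=np.array([0.85, 0.85, 0.85]))
        trace = run_risk_plot(series, None, cfg(drain_rate=1, capacity=10,
                                                window_beats=100))
        last = trace.windows[-1]
        assert sum(last.terminal_state.occupancy) == 0
        assert last.valley == 3 and last.projected == 3

    def test_no_drain_sticks_at_capacity(self):
        """100 identical beats, d=0, C=8: stair sticks at beat 8, holds all."""
        series = RRISeries(intervals=np.full(100, 0.85))
        trace = run_risk_plot(series, None, cfg(drain_rate=0, capacity=8,
                                                window_beats=100))
        target = assign_stair(0.85, cfg())
        assert not trace.any_stuck_by_beat[6]          # beat 7: occupancy 7
        assert trace.any_stuck_by_beat[7]              # beat 8: occupancy 8
        assert all(trace.any_stuck_by_beat[7:])
        last = trace.windows[-1]
        assert last.terminal_state.occupancy[target] == 100
        assert last.valley == 0 and last.stuck_beats == 93

    def test_conservation_over_random_stream(self):
        rng = np.random.default_rng(11)
        series = RRISeries(intervals=rng.uniform(0.25, 2.0, size=5000))
        trace = run_risk_plot(series, None, cfg(drain_rate=1, capacity=8,
                                                window_beats=300, oor_policy="drop"))
        total = trace.occupancy_by_beat.sum(axis=1)
        np.testing.assert_array_equal(
            trace.projected_by_beat, total + trace.valley_by_beat + trace.dropped_by_beat)

    def test_window_boundaries_and_partial_tail(self):
        series = RRISeries(intervals=np.full(750, 0.8))
        trace = run_risk_plot(series, None, cfg(window_beats=300))
        assert [w.partial for w in trace.windows] == [False, False, True]
        assert [w.n_beats for w in trace.windows] == [300, 300, 150]
        assert [w.start_beat for w in trace.windows] == [0, 300, 600]

    def test_flagged_beats_skipped_but_advance_clock(self):
        series = RRISeries(intervals=np.full(10, 0.8))
        mask = np.zeros(10, dtype=bool)
        mask[3:6] = True
        trace = run_risk_plot(series, mask, cfg(window_beats=10))
        w = trace.windows[0]
        assert w.projected == 7 and w.n_beats == 10
        assert np.all(trace.stair_of_beat[3:6] == -2)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            RRISeries(intervals=np.array([]))

    def test_mask_length_mismatch_rejected(self):
        series = RRISeries(intervals=np.full(10, 0.8))
        with pytest.raises(ValueError):
            run_risk_plot(series, np.zeros(5, dtype=bool), cfg())


class TestProperties:
    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 400))
        series = RRISeries(intervals=rng.uniform(0.1, 2.5, size=n))
        mask = rng.random(n) < 0.05
        c = cfg(drain_rate=int(rng.integers(0, 3)),
                capacity=int(rng.integers(3, 10)),
                window_beats=int(rng.integers(10, 200)),
                oor_policy=str(rng.choice(["clamp", "drop"])))
        trace = run_risk_plot(series, mask, c)
        assert np.all(trace.occupancy_by_beat >= 0)
        total = trace.occupancy_by_beat.sum(axis=1)
        np.testing.assert_array_equal(
            trace.projected_by_beat,
            total + trace.valley_by_beat + trace.dropped_by_beat)
        # valley never decreases within a window
        for w in trace.windows:
            seg = trace.valley_by_beat[w.start_beat:w.start_beat + w.n_beats]
            assert np.all(np.diff(seg) >= 0)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_higher_drain_rate_never_increases_occupancy(self, seed):
        rng = np.random.default_rng(seed)
        series = RRISeries(intervals=rng.uniform(0.25, 1.6, size=300))
        totals = []
        for d in (0, 1, 2):
            trace = run_risk_plot(series, None, cfg(drain_rate=d, capacity=6,
                                                    window_beats=100))
            totals.append([sum(w.terminal_state.occupancy) for w in trace.windows])
        for lo, hi in zip(totals[1:], totals[:-1]):
            assert all(a <= b for a, b in zip(lo, hi))

    def test_constant_stream_returns_to_zero_with_positive_drain(self):
        """With d >= 1 the hit stair empties after every beat (closed form)."""
        series = RRISeries(intervals=np.full(200, 0.85))
        trace = run_risk_plot(series, None, cfg(drain_rate=1, capacity=8,
                                                window_beats=1000))
        assert np.all(trace.occupancy_by_beat.sum(axis=1) == 0)
        assert not trace.any_stuck_by_beat.any()


class TestOracleEquivalence:
    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_engine_matches_naive_simulator(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        series = RRISeries(intervals=rng.uniform(0.1, 2.5, size=n))
        mask = rng.random(n) < 0.05
        d = int(rng.integers(0, 4))
        c = cfg(drain_rate=d, capacity=int(rng.integers(d + 1, d + 9)),
                window_beats=int(rng.integers(10, 300)),
                oor_policy=str(rng.choice(["clamp", "drop"])))
        trace = run_risk_plot(series, mask, c)
        rows, windows = naive_trace(series.intervals, mask, list(c.stair_edges),
                                    c.drain_rate, c.capacity, c.window_beats,
                                    c.oor_policy)
        for i, (stair, occ, valley, projected, dropped, any_stuck) in enumerate(rows):
            assert trace.stair_of_beat[i] == stair
            assert tuple(trace.occupancy_by_beat[i]) == occ
            assert trace.valley_by_beat[i] == valley
            assert trace.projected_by_beat[i] == projected
            assert trace.dropped_by_beat[i] == dropped
            assert bool(trace.any_stuck_by_beat[i]) == any_stuck
        assert len(trace.windows) == len(windows)
        for w, ref in zip(trace.windows, windows):
            assert tuple(w.projection_counts) == ref["projection_counts"]
            assert w.stuck_beats == ref["stuck_beats"]
            assert (w.projected, w.valley, w.dropped) == (
                ref["projected"], ref["valley"], ref["dropped"])
            assert tuple(w.terminal_state.occupancy) == ref["terminal_occupancy"]
            assert w.partial == ref["partial"]
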