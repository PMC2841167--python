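"""Event-parser unit and property tests, including an independent
brute-force oracle implementing the documented per-sample rules with
plain Python loops."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculomap.events import (
    Event,
    EventSequence,
    GazeRecording,
    ParserSpec,
    compute_kinematics,
    merge_saccades,
    parse_events,
)

from conftest import make_recording


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_parse(rec: GazeRecording, spec: ParserSpec) -> list:
    """Per-sample classifier + run-length segmentation, loop by loop."""
    n = rec.n_samples
    h = 1.0 / rec.rate
    ppd = rec.px_per_deg
    miss = [math.isnan(p) for p in rec.pupil]

    def defined(i):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        return not any(miss[j] for j in range(lo, hi + 1))

    vel = [float("nan")] * n
    for i in range(n):
        if not defined(i):
            continue
        a, b = (i - 1, i + 1) if 0 < i < n - 1 else ((i, i + 1) if i == 0 else (i - 1, i))
        span = (b - a) * h
        vel[i] = math.hypot(rec.x[b] - rec.x[a], rec.y[b] - rec.y[a]) / ppd / span
    acc = [float("nan")] * n
    for i in range(n):
        a, b = (i - 1, i + 1) if 0 < i < n - 1 else ((i, i + 1) if i == 0 else (i - 1, i))
        if math.isnan(vel[a]) or math.isnan(vel[b]):
            continue
        acc[i] = (vel[b] - vel[a]) / ((b - a) * h)

    sacc = [
        (not math.isnan(vel[i]) and vel[i] > spec.v_thresh)
        or (not math.isnan(acc[i]) and acc[i] > spec.a_thresh)
        for i in range(n)
    ]
    for i in range(n):
        if math.isnan(vel[i]):
            sacc[i] = False

    # blinks: missing runs >= blink_min_missing, extended through
    # contiguous saccade-flagged or missing samples
    blink = [False] * n
    i = 0
    while i < n:
        if miss[i]:
            j = i
            while j < n and miss[j]:
                j += 1
            if j - i >= spec.blink_min_missing:
                lo = i
                while lo > 0 and (sacc[lo - 1] or miss[lo - 1]):
                    lo -= 1
                hi = j
                while hi < n and (sacc[hi] or miss[hi]):
                    hi += 1
                for k in range(lo, hi):
                    blink[k] = True
            i = j
        else:
            i += 1
    sacc = [s and not b for s, b in zip(sacc, blink)]

    # merge temporally+spatially contiguous saccade runs, to fixpoint
    def runs(flags):
        out, i = [], 0
        while i < n:
            if flags[i]:
                j = i
                while j < n and flags[j]:
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    changed = True
    while changed:
        changed = False
        rs = runs(sacc)
        for (s0, e0), (s1, e1) in zip(rs, rs[1:]):
            gap_ms = (s1 - e0) * (1000.0 / rec.rate)
            if gap_ms >= spec.merge_gap:
                continue
            if any(blink[k] for k in range(e0, s1)):
                continue
            d = math.hypot(rec.x[s1] - rec.x[e0 - 1], rec.y[s1] - rec.y[e0 - 1]) / ppd
            if d < spec.merge_dist:
                for k in range(e0, s1):
                    sacc[k] = True
                changed = True
                break

    labels = ["blink" if blink[i] else "saccade" if sacc[i] else "fixation" for i in range(n)]
    events, start = [], 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            events.append((labels[start], start, i))
            start = i
    return events


def random_recording(rng, n):
    """A jumpy random walk with occasional pupil dropouts."""
    x = np.cumsum(rng.normal(0, 0.3, n))
    y = np.cumsum(rng.normal(0, 0.3, n))
    # inject a few fast ramps so both event kinds occur
    for _ in range(rng.integers(1, 4)):
        s = rng.integers(0, max(1, n - 30))
        x[s:] += rng.uniform(30, 120)
    pupil = np.full(n, 800.0)
    for _ in range(rng.integers(0, 3)):
        s = rng.integers(0, max(1, n - 10))
        pupil[s:s + rng.integers(1, 8)] = np.nan
    return make_recording(x + 150, y + 150, pupil)


# ---------------------------------------------------------------------------
# kinematics


class TestKinematics:
    def test_stationary_gaze_has_zero_kinematics(self, stationary_recording):
        vel, acc = compute_kinematics(stationary_recording)
        assert np.allclose(vel, 0) and np.allclose(acc, 0)

    def test_constant_speed_ramp_velocity(self):
        # 25 px per 1 ms sample at 25 px/deg -> 1000 deg/s
        x = np.arange(100) * 25.0
        rec = make_recording(x, np.zeros(100))
        vel, _ = compute_kinematics(rec)
        assert np.allclose(vel[1:-1], 1000.0)

    def test_slow_drift_stays_below_threshold(self):
        x = np.arange(100) * 0.01
        rec = make_recording(x, np.zeros(100))
        vel, _ = compute_kinematics(rec)
        assert np.allclose(vel[1:-1], 0.4)
        assert (vel[1:-1] < 30.0).all()

    def test_too_short_recording_rejected(self):
        rec = make_recording([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="too short"):
            compute_kinematics(rec)

    def test_non_uniform_sampling_rejected(self):
        rec = make_recording(np.zeros(10), np.zeros(10))
        rec.t = rec.t.copy()
        rec.t[5] += 0.4
        with pytest.raises(ValueError, match="non-uniform"):
            compute_kinematics(rec)

    def test_kinematics_missing_near_pupil_loss(self):
        pupil = np.full(50, 800.0)
        pupil[20:25] = np.nan
        rec = make_recording(np.zeros(50), np.zeros(50), pupil)
        vel, acc = compute_kinematics(rec)
        assert np.isnan(vel[19:26]).all()
        assert not np.isnan(vel[:18]).any()


# ---------------------------------------------------------------------------
# parsing


def two_epoch_recording(gap=30, jump=75.0):
    """Two stationary epochs joined by a fast ramp."""
    a = np.full(200, 100.0)
    ramp = np.linspace(100.0, 100.0 + jump, gap)
    b = np.full(200, 100.0 + jump)
    x = np.concatenate([a, ramp, b])
    return make_recording(x, np.full(len(x), 150.0))


class TestParseEvents:
    def test_stationary_trace_single_fixation(self, stationary_recording):
        seq = parse_events(stationary_recording)
        assert [e.kind for e in seq] == ["fixation"]
        assert seq.events[0].duration == pytest.approx(500.0)

    def test_two_epochs_one_saccade(self):
        seq = parse_events(two_epoch_recording())
        assert len(seq.fixations) == 2
        assert len(seq.saccades) == 1
        f1, f2 = seq.fixations
        assert f1.x == pytest.approx(100.0, abs=0.5)
        assert f2.x == pytest.approx(175.0, abs=0.5)

    def test_five_missing_samples_one_blink(self):
        pupil = np.full(400, 800.0)
        pupil[100:105] = np.nan
        seq = parse_events(make_recording(np.full(400, 50.0), np.full(400, 50.0), pupil))
        assert len(seq.blinks) == 1

    def test_short_dropout_is_not_a_blink(self):
        pupil = np.full(400, 800.0)
        pupil[100:102] = np.nan  # below the 3-sample minimum
        seq = parse_events(make_recording(np.full(400, 50.0), np.full(400, 50.0), pupil))
        assert len(seq.blinks) == 0

    def test_all_missing_pupil_single_blink(self):
        rec = make_recording(np.zeros(100), np.zeros(100), np.full(100, np.nan))
        seq = parse_events(rec)
        assert [e.kind for e in seq] == ["blink"]
        assert seq.events[0].duration == pytest.approx(100.0)

    def test_partition_property(self, rng):
        for k in range(10):
            rec = random_recording(rng, int(rng.integers(50, 800)))
            seq = parse_events(rec)
            assert sum(e.duration for e in seq) == pytest.approx(rec.span_ms)
            for prev, nxt in zip(seq.events, seq.events[1:]):
                assert nxt.onset == pytest.approx(prev.offset)

    def test_matches_bruteforce_oracle_exactly(self, rng):
        spec = ParserSpec()
        for k in range(40):
            rec = random_recording(rng, int(rng.integers(20, 1000)))
            got = [(e.kind, e.onset, e.offset) for e in parse_events(rec, spec)]
            dt = rec.dt_ms
            want = [(kind, s * dt, e * dt) for kind, s, e in oracle_parse(rec, spec)]
            assert got == pytest.approx(want)


# ---------------------------------------------------------------------------
# saccade merging


def seq_of(events):
    return EventSequence(list(events), "t", 25.0, 1000.0)


def sac(on, off, x0, y0, x1, y1):
    return Event("saccade", on, off, x_start=x0, y_start=y0, x_end=x1, y_end=y1)


def fix(on, off, x, y):
    return Event("fixation", on, off, x=x, y=y)


class TestMergeSaccades:
    def test_close_pair_merges(self):
        # 15 ms apart, 0.2 deg (= 5 px) apart: both conditions hold
        s = seq_of([sac(0, 10, 0, 0, 50, 0), fix(10, 25, 52, 0), sac(25, 35, 55, 0, 100, 0)])
        merged = merge_saccades(s)
        assert [e.kind for e in merged] == ["saccade"]
        assert merged.events[0].onset == 0 and merged.events[0].offset == 35

    def test_temporal_condition_fails(self):
        s = seq_of([sac(0, 10, 0, 0, 50, 0), fix(10, 35, 52, 0), sac(35, 45, 55, 0, 100, 0)])
        assert len(merge_saccades(s).saccades) == 2

    def test_spatial_condition_fails(self):
        # 15 ms apart but 2 deg apart
        s = seq_of([sac(0, 10, 0, 0, 50, 0), fix(10, 25, 75, 0), sac(25, 35, 100, 0, 150, 0)])
        assert len(merge_saccades(s).saccades) == 2

    def test_chain_merges_to_single_saccade(self):
        s = seq_of([
            sac(0, 10, 0, 0, 50, 0), fix(10, 24, 51, 0),
            sac(24, 34, 52, 0, 90, 0), fix(34, 48, 91, 0),
            sac(48, 58, 92, 0, 130, 0),
        ])
        merged = merge_saccades(s)
        assert [e.kind for e in merged] == ["saccade"]
        assert merged.events[0].x_end == 130

    def test_idempotent_without_mergeable_pairs(self):
        s = seq_of([sac(0, 10, 0, 0, 50, 0), fix(10, 100, 75, 0), sac(100, 110, 100, 0, 150, 0)])
        once = merge_saccades(s)
        twice = merge_saccades(once)
        assert [(e.kind, e.onset, e.offset) for e in once] == [
            (e.kind, e.onset, e.offset) for e in twice
        ]


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10**6))
def test_parser_oracle_equivalence_property(seed):
    """Exact agreement with the loop-based oracle on random short traces."""
    rng = np.random.default_rng(seed)
    rec = random_recording(rng, int(rng.integers(20, 400)))
    spec = ParserSpec()
    got = [(e.kind, e.onset, e.offset) for e in parse_events(rec, spec)]
    dt = rec.dt_ms
    want = [(kind, s * dt, e * dt) for kind, s, e in oracle_parse(rec, spec)]
    assert got == pytest.approx(want)
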