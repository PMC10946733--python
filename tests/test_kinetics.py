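"""Touch-kinetics unit tests: block averaging, centre-of-pressure recovery,
onset detection and the trial-rejection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchersp.config import G_STANDARD
from touchersp.kinetics import (
    KineticsError,
    KineticsTrace,
    block_average,
    compute_kinetics,
    detect_movement_onset,
    qc_and_summarise,
    zscore_exclude,
    TouchTrial,
)


def sensor_frame(fx, fy, fz, mx, my, fs=20.0):
    n = len(fx)
    return pd.DataFrame(
        {
            "t_ms": np.arange(n) * 1000.0 / fs,
            "Fx_N": fx,
            "Fy_N": fy,
            "Fz_N": fz,
            "Mx_Nm": mx,
            "My_Nm": my,
            "Mz_Nm": np.zeros(n),
        }
    )


class TestBlockAverage:
    def test_constant_preserved(self):
        out = block_average(np.full(1000, 2.0), 1000.0, 20.0)
        assert out.shape == (20,)
        assert np.allclose(out, 2.0)

    def test_first_block_mean(self):
        x = np.arange(1.0, 1001.0)
        out = block_average(x, 1000.0, 20.0)
        assert out[0] == pytest.approx(25.5)  # mean of 1..50

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(750)
        out = block_average(x, 150.0, 30.0)  # blocks of 5
        oracle = np.array([sum(x[5 * i : 5 * i + 5]) / 5.0 for i in range(150)])
        assert np.max(np.abs(out - oracle)) < 1e-12

    def test_truncates_partial_block(self):
        out = block_average(np.ones(57), 10.0, 2.0)  # blocks of 5 -> 11 full
        assert out.shape == (11,)

    def test_rate_above_fs_rejected(self):
        with pytest.raises(KineticsError):
            block_average(np.ones(10), 10.0, 20.0)


class TestComputeKinetics:
    def test_friction_345_triangle(self):
        df = sensor_frame([0.3], [0.4], [-1.0], [0.0], [0.0])
        tr = compute_kinetics(df, 20.0, plate_thickness_mm=0.0)
        assert tr.friction_n[0] == pytest.approx(0.5)

    def test_cop_static_equilibrium(self):
        # Fz=-2 N, My=0.1 N*m, Mx=0.06 N*m -> x=50 mm, y=-30 mm (h=0)
        df = sensor_frame([0.0], [0.0], [-2.0], [0.06], [0.1])
        tr = compute_kinetics(df, 20.0, plate_thickness_mm=0.0)
        assert tr.x_mm[0] == pytest.approx(50.0)
        assert tr.y_mm[0] == pytest.approx(-30.0)
        assert tr.load_g[0] == pytest.approx(2.0 / G_STANDARD * 1000.0)

    def test_plate_thickness_roundtrip(self):
        # build moments from a known contact point with h=3mm, recover it
        x, y, h = 0.02, -0.01, 0.003
        fx, fy, fz = 0.3, -0.2, -1.5
        my = -x * fz - fx * h
        mx = y * fz + fy * h
        df = sensor_frame([fx], [fy], [fz], [mx], [my])
        tr = compute_kinetics(df, 20.0, plate_thickness_mm=3.0)
        assert tr.x_mm[0] == pytest.approx(20.0, abs=1e-9)
        assert tr.y_mm[0] == pytest.approx(-10.0, abs=1e-9)

    def test_speed_from_positions(self):
        # (0,0) mm then (3,4) mm across one 50-ms step -> 100 mm/s
        fz = [-1.0, -1.0]
        mx = [0.0, 0.004 * -1.0]  # y = Mx/Fz
        my = [0.0, -0.003 * -1.0]  # x = -My/Fz
        df = sensor_frame([0.0, 0.0], [0.0, 0.0], fz, mx, my)
        tr = compute_kinetics(df, 20.0, plate_thickness_mm=0.0)
        assert tr.speed_mm_s[0] == 0.0
        assert tr.speed_mm_s[1] == pytest.approx(100.0)

    def test_low_load_marks_position_undefined(self):
        df = sensor_frame([0.0, 0.0], [0.0, 0.0], [-1.0, -0.01], [0.0, 0.0], [0.0, 0.0])
        tr = compute_kinetics(df, 20.0)
        assert np.isfinite(tr.x_mm[0])
        assert np.isnan(tr.x_mm[1]) and np.isnan(tr.speed_mm_s[1])

    @given(theta=st.floats(0.0, 2 * np.pi))
    @settings(deadline=None, max_examples=25)
    def test_friction_rotation_invariant(self, theta):
        """Friction depends only on the tangential magnitude."""
        fx, fy = 0.3, 0.4
        rx = fx * np.cos(theta) - fy * np.sin(theta)
        ry = fx * np.sin(theta) + fy * np.cos(theta)
        df = sensor_frame([rx], [ry], [-1.0], [0.0], [0.0])
        tr = compute_kinetics(df, 20.0)
        assert tr.friction_n[0] == pytest.approx(0.5, rel=1e-12)


def trace_from_positions(x_mm, y_mm, fs=20.0, t0_ms=-200.0):
    n = len(x_mm)
    t = t0_ms + np.arange(n) * 1000.0 / fs
    return KineticsTrace(
        t_ms=t,
        x_mm=np.asarray(x_mm, float),
        y_mm=np.asarray(y_mm, float),
        friction_n=np.zeros(n),
        load_g=np.full(n, 100.0),
        speed_mm_s=np.concatenate([[0.0], np.abs(np.diff(x_mm)) * fs]),
        fs=fs,
    )


class TestOnsetDetection:
    def test_flat_trace_undefined(self):
        tr = trace_from_positions(np.zeros(85), np.zeros(85))
        assert detect_movement_onset(tr, 0.0) is None

    def test_bump_matches_enumeration_oracle(self):
        """Detected onset equals the brute-force first half-height velocity
        peak on a synthesised velocity bump."""
        fs = 20.0
        t = -200.0 + np.arange(85) * 1000.0 / fs
        v = 150.0 * np.exp(-0.5 * ((t - 200.0) / 120.0) ** 2)  # mm/s bump at 200 ms
        x = np.concatenate([[0.0], np.cumsum(v[:-1]) / fs])  # forward-difference inverse
        tr = trace_from_positions(x, np.zeros_like(x))
        got = detect_movement_onset(tr, 0.0)
        # oracle: enumerate forward-difference velocity samples, find first
        # local max with height >= max/2
        vf = np.diff(x) * fs
        tv = t[:-1]
        half = vf.max() / 2.0
        expect = None
        for i in range(1, len(vf) - 1):
            if vf[i] >= half and vf[i] >= vf[i - 1] and vf[i] >= vf[i + 1]:
                expect = tv[i]
                break
        assert got == pytest.approx(expect)

    def test_earliest_candidate_wins(self):
        """A negative-going y extremum at 150 ms beats a positive x peak at
        300 ms."""
        fs = 20.0
        n = 85
        t = -200.0 + np.arange(n) * 1000.0 / fs
        vx = 100.0 * np.exp(-0.5 * ((t - 300.0) / 80.0) ** 2)
        vy = -100.0 * np.exp(-0.5 * ((t - 150.0) / 80.0) ** 2)
        x = np.concatenate([[0.0], np.cumsum(vx[:-1]) / fs])
        y = np.concatenate([[0.0], np.cumsum(vy[:-1]) / fs])
        tr = trace_from_positions(x, np.zeros_like(x))
        tr.y_mm = y
        got = detect_movement_onset(tr, 0.0)
        assert 100.0 <= got <= 200.0

    def test_scalar_speed_mode(self):
        fs = 20.0
        t = -200.0 + np.arange(85) * 1000.0 / fs
        v = 150.0 * np.exp(-0.5 * ((t - 250.0) / 100.0) ** 2)
        x = np.concatenate([[0.0], np.cumsum(v[:-1]) / fs])
        tr = trace_from_positions(x, np.zeros_like(x))
        got = detect_movement_onset(tr, 0.0, use_scalar_speed=True)
        assert got == pytest.approx(250.0, abs=60.0)


def qc_trial(onset_ms, fs=20.0, still_baseline=True):
    """Kinetics trace spanning -5000..4000 ms whose forward-difference
    velocity has its first (half-height) peak exactly at ``onset_ms``."""
    t = np.arange(-5000.0, 4000.0, 1000.0 / fs)
    tv = t[:-1]  # forward-difference stamps
    v = np.where(tv >= onset_ms, 120.0 * np.exp(-(tv - onset_ms) / 1500.0), 0.0)
    if not still_baseline:
        v = v + np.where((tv >= -3000) & (tv <= -1000), 50.0, 0.0)
    x = np.concatenate([[0.0], np.cumsum(v) / fs])
    moving = t >= onset_ms
    tr = KineticsTrace(
        t_ms=t,
        x_mm=x,
        y_mm=np.zeros_like(x),
        friction_n=np.where(moving, 0.5, 0.0),
        load_g=np.full_like(x, 100.0),
        speed_mm_s=np.concatenate([[0.0], np.abs(np.diff(x)) * fs]),
        fs=fs,
    )
    ev = pd.Series(
        {"trial": 0, "cue_time_ms": 0.0, "texture": "hessian", "condition": "sensory"}
    )
    return tr, ev


class TestQc:
    def test_late_onset_strict_boundary(self):
        # detected onset 450 ms (> 400, rejected); 400 ms exactly (kept,
        # "exceeded" is strict); 250 ms (kept)
        late = qc_and_summarise([qc_trial(450.0)])[0]
        assert late.onset_ms == pytest.approx(450.0)
        assert "late_onset" in late.qc_flags
        at_bound = qc_and_summarise([qc_trial(400.0)])[0]
        assert at_bound.onset_ms == pytest.approx(400.0)
        assert at_bound.accepted
        ok = qc_and_summarise([qc_trial(250.0)])[0]
        assert ok.accepted
        assert ok.median_speed is not None

    def test_missing_trigger_flagged(self):
        tr, ev = qc_trial(250.0)
        ev["cue_time_ms"] = np.nan
        out = qc_and_summarise([(tr, ev)])
        assert out[0].qc_flags == {"no_trigger"}

    def test_baseline_movement_flagged(self):
        out = qc_and_summarise([qc_trial(250.0, still_baseline=False)])
        assert "baseline_movement" in out[0].qc_flags

    def test_medians_match_sort_oracle(self):
        tr, ev = qc_trial(250.0)
        out = qc_and_summarise([(tr, ev)])[0]
        rel = tr.t_ms
        win = (rel >= out.onset_ms) & (rel <= 4000.0)

        def sort_median(v):
            s = sorted(v)
            m = len(s)
            return s[m // 2] if m % 2 else 0.5 * (s[m // 2 - 1] + s[m // 2])

        assert out.median_friction == pytest.approx(sort_median(tr.friction_n[win]))
        assert out.median_load == pytest.approx(sort_median(tr.load_g[win]))
        assert out.median_speed == pytest.approx(sort_median(tr.speed_mm_s[win]))

    def test_empty_list_rejected(self):
        with pytest.raises(KineticsError):
            qc_and_summarise([])


def make_touch(vals, subject="s1", block=1, texture="hessian"):
    out = []
    for i, v in enumerate(vals):
        tt = TouchTrial(i, texture, "sensory", subject=subject, block=block)
        tt.onset_ms = 200.0
        tt.median_speed = v
        tt.median_friction = 0.5
        tt.median_load = 100.0
        out.append(tt)
    return out


class TestZscoreExclude:
    def test_single_outlier_among_ten(self):
        # 9 identical + 1 distinct: |z| = (n-1)/sqrt(n) = 2.846 > 2
        trials = make_touch([1.0] * 9 + [5.0])
        vals = np.array([1.0] * 9 + [5.0])
        z_max = abs(vals[-1] - vals.mean()) / vals.std(ddof=1)
        assert z_max == pytest.approx(9 / np.sqrt(10), rel=1e-12)
        zscore_exclude(trials)
        assert "zscore_outlier" in trials[-1].qc_flags
        assert all(t.accepted for t in trials[:-1])

    def test_zero_sd_group_untouched(self):
        trials = make_touch([2.0] * 8)
        zscore_exclude(trials)
        assert all(t.accepted for t in trials)

    def test_exactly_two_sd_kept(self):
        # z-scores [-0.5 x4, 0, 2]: sum 0, sum of squares = n-1 = 5, so the
        # last value sits at exactly |z| = 2 -> kept (strict "exceeded")
        vals = [-0.5, -0.5, -0.5, -0.5, 0.0, 2.0]
        x = np.array(vals)
        z = (x - x.mean()) / x.std(ddof=1)
        assert abs(z[-1]) == 2.0
        trials = make_touch(vals)
        zscore_exclude(trials)
        assert all(t.accepted for t in trials)

    def test_small_groups_skipped(self):
        trials = make_touch([1.0])
        zscore_exclude(trials)
        assert trials[0].accepted
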