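"""Pairing criteria, deltaF, brace height, attenuation slope, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picpipe.metrics import (
    MUPair,
    attenuation_slope,
    brace_height,
    delta_f,
    delta_f_per_test_unit,
    evaluate_pair,
    pair_units,
    thresholds,
)
from picpipe.smoothing import AscendingSegment, GRID_DT, SmoothedRate
from picpipe.torque import FilteredTorque


def curve(t0, t1, fn, unit_id="u"):
    """SmoothedRate from an analytic rate function on [t0, t1]."""
    n = int(round((t1 - t0) / GRID_DT)) + 1
    t = t0 + GRID_DT * np.arange(n)
    r = np.asarray([fn(x) for x in t], float)
    i = int(np.argmax(r))
    return SmoothedRate(
        grid_time=t, rate=r, t_rec=t0, t_derec=t1,
        t_peak=float(t[i]), peak_rate=float(r[i]), unit_id=unit_id,
    )


def tent(t0, t1, lo, hi):
    """Symmetric rise-and-fall rate profile."""
    mid = (t0 + t1) / 2

    def fn(t):
        frac = (t - t0) / (mid - t0) if t <= mid else (t1 - t) / (t1 - mid)
        return lo + (hi - lo) * frac

    return fn


class TestPairingCriteria:
    def _pair(self, *, ctrl=(1.0, 18.0), test=(3.0, 16.0), hi=14.0):
        control = curve(*ctrl, tent(*ctrl, 8.0, hi), "c")
        testu = curve(*test, tent(*test, 8.0, 12.0), "t")
        return evaluate_pair(control, testu)

    def test_all_criteria_pass(self):
        p = self._pair()
        assert p.valid
        assert p.failed_criteria() == []

    def test_low_correlation_rejected(self):
        """A control whose rate is anti-correlated with the test fails (i)."""
        control = curve(1.0, 18.0, lambda t: 20.0 - 0.5 * t, "c")
        testu = curve(3.0, 16.0, tent(3.0, 16.0, 8.0, 12.0), "t")
        p = evaluate_pair(control, testu)
        assert p.r_rate < 0.7
        assert not p.valid
        assert "r_rate" in p.failed_criteria()

    def test_short_recruitment_gap_rejected(self):
        p = self._pair(test=(1.8, 16.0))
        assert p.recruit_gap == pytest.approx(0.8)
        assert not p.valid
        assert p.failed_criteria() == ["recruit_gap"]

    def test_low_control_modulation_rejected(self):
        """Control barely modulating after test recruitment fails (iii)."""
        control = curve(1.0, 18.0, tent(1.0, 18.0, 8.0, 8.4), "c")
        testu = curve(3.0, 16.0, tent(3.0, 16.0, 8.0, 12.0), "t")
        p = evaluate_pair(control, testu)
        assert p.control_mod < 0.5
        assert not p.valid
        assert "control_mod" in p.failed_criteria()

    def test_derecruitment_order_rejected(self):
        p = self._pair(test=(3.0, 18.5))
        assert not p.derec_order_ok
        assert not p.valid
        assert "derec_order" in p.failed_criteria()

    def test_control_must_recruit_first(self):
        assert self._pair(ctrl=(5.0, 18.0), test=(3.0, 16.0)) is None

    def test_pair_units_returns_only_valid(self):
        units = [
            curve(1.0, 18.0, tent(1.0, 18.0, 8.0, 14.0), "a"),
            curve(3.0, 16.0, tent(3.0, 16.0, 8.0, 12.0), "b"),
            curve(3.5, 15.0, tent(3.5, 15.0, 8.0, 11.0), "c"),
        ]
        valid, rejections = pair_units(units)
        assert all(p.valid for p in valid)
        got = {(p.control_id, p.test_id) for p in valid}
        # a->b and a->c have gaps > 1 s; b->c has a 0.5 s gap
        assert ("a", "b") in got and ("a", "c") in got
        assert ("b", "c") not in got
        assert rejections["recruit_gap"] >= 1


class TestDeltaF:
    def _valid_pair(self):
        return MUPair("c", "t", r_rate=0.95, recruit_gap=2.0,
                      control_mod=3.0, derec_order_ok=True)

    def test_direct_definition(self):
        """Control at 10 pps when the test recruits and 7.5 pps when it
        derecruits: deltaF = 2.5 pps."""
        control = curve(
            0.0, 20.0,
            lambda t: 10.0 - 2.5 * (min(t, 16.0) - 4.0) / 12.0 if t > 4 else 10.0,
            "c",
        )
        testu = curve(4.0, 16.0, tent(4.0, 16.0, 8.0, 12.0), "t")
        assert control.at(4.0) == pytest.approx(10.0)
        assert control.at(16.0) == pytest.approx(7.5)
        df = delta_f(self._valid_pair(), control, testu)
        assert df == pytest.approx(2.5)

    def test_equal_landmark_rates_give_zero(self):
        control = curve(0.0, 20.0, tent(0.0, 20.0, 8.0, 14.0), "c")
        testu = curve(4.0, 16.0, tent(4.0, 16.0, 8.0, 12.0), "t")
        # symmetric tent: rate at 4 s equals rate at 16 s
        assert delta_f(self._valid_pair(), control, testu) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_pair_rejected(self):
        bad = MUPair("c", "t", r_rate=0.5, recruit_gap=2.0,
                     control_mod=3.0, derec_order_ok=True)
        control = curve(0.0, 20.0, tent(0.0, 20.0, 8.0, 14.0), "c")
        testu = curve(4.0, 16.0, tent(4.0, 16.0, 8.0, 12.0), "t")
        with pytest.raises(ValueError):
            delta_f(bad, control, testu)

    @pytest.mark.parametrize(
        "values,expected",
        [([2.0, 3.0], 2.5), ([4.2], 4.2), ([1.0, 2.0, 6.0], 3.0)],
        ids=["two-controls", "single-control", "no-outlier-trimming"],
    )
    def test_per_test_unit_mean(self, values, expected):
        assert delta_f_per_test_unit(values) == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 10), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_per_test_unit_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert delta_f_per_test_unit(shuffled) == pytest.approx(
            delta_f_per_test_unit(values)
        )


def segment(x, y):
    """AscendingSegment from unit-square samples (scaled to arbitrary axes)."""
    return AscendingSegment(time=np.asarray(x, float),
                            rate=np.asarray(y, float), unit_id="u")


class TestBraceHeight:
    def test_chord_scores_zero(self):
        x = np.linspace(0, 1, 200)
        geo = brace_height(segment(x, 5 + 10 * x))
        assert geo.brace_height == pytest.approx(0.0, abs=1e-9)

    def test_vertex_curve_scores_100(self):
        """A curve that jumps to the plateau instantly passes through the
        right-angle vertex (0, 1): brace height 100 % rTri."""
        x = np.linspace(0, 1, 201)
        y = np.ones_like(x)
        y[0] = 0.0
        geo = brace_height(segment(x, y))
        assert geo.brace_height == pytest.approx(100.0, abs=0.6)

    def test_sqrt_curve_analytic_value(self):
        """y = sqrt(x) on the unit square: max of (sqrt(x) - x) is 1/4 at
        x = 1/4, i.e. 25.0 % rTri; verified against dense brute force."""
        x = np.linspace(0, 1, 2001)
        geo = brace_height(segment(x, np.sqrt(x)))
        assert geo.brace_height == pytest.approx(25.0, abs=0.05)
        assert geo.insertion_time == pytest.approx(0.25, abs=0.01)
        # independent dense-grid brute force of the orthogonal distance
        xs = np.linspace(0, 1, 400001)
        brute = np.max((np.sqrt(xs) - xs) / np.sqrt(2)) * np.sqrt(2) * 100
        assert geo.brace_height == pytest.approx(brute, abs=0.05)

    def test_concave_below_chord_is_negative(self):
        x = np.linspace(0, 1, 500)
        geo = brace_height(segment(x, x**2))
        assert geo.brace_height < 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a_t=st.floats(0.1, 50), b_t=st.floats(-100, 100),
        a_r=st.floats(0.1, 50), b_r=st.floats(-100, 100),
    )
    def test_affine_axis_rescaling_invariance(self, a_t, b_t, a_r, b_r):
        """Brace height is unchanged under separate affine rescalings of
        the time and rate axes."""
        x = np.linspace(0, 6, 300)
        y = 8 + 6 * np.sqrt(x / 6)
        ref = brace_height(segment(x, y)).brace_height
        scaled = brace_height(segment(a_t * x + b_t, a_r * y + b_r)).brace_height
        assert scaled == pytest.approx(ref, abs=1e-8)

    def test_monotone_saturating_in_range(self):
        for k in (0.5, 1, 2, 5, 10):
            x = np.linspace(0, 1, 400)
            y = (1 - np.exp(-k * x)) / (1 - np.exp(-k))
            bh = brace_height(segment(x, y)).brace_height
            assert 0.0 <= bh <= 100.0

    def test_degenerate_flat_curve_rejected(self):
        with pytest.raises(ValueError):
            brace_height(segment(np.linspace(0, 1, 100), np.full(100, 5.0)))


class TestAttenuationSlope:
    def _torque(self, fn, fs=100.0, t_end=20.0):
        t = np.arange(0, t_end, 1 / fs)
        return FilteredTorque(time=t, torque_pct=np.asarray([fn(x) for x in t]), fs=fs)

    def test_linear_rate_vs_linear_torque(self):
        """Rate 12 -> 16 pps while torque 10 -> 18 %MVT: slope 0.5."""
        seg = segment(np.linspace(2, 6, 401), np.linspace(12, 16, 401))
        tq = self._torque(lambda t: 2 * t + 6)  # 10% at t=2, 18% at t=6
        slope = attenuation_slope(seg, insertion_time=2.0, torque=tq)
        assert slope == pytest.approx(0.5, rel=1e-6)

    def test_flat_rate_zero_slope(self):
        seg = segment(np.linspace(2, 6, 401), np.full(401, 14.0))
        tq = self._torque(lambda t: 2 * t)
        assert attenuation_slope(seg, 2.0, tq) == pytest.approx(0.0, abs=1e-9)

    def test_saturated_unit_flatter_than_linear(self, noiseless_pool_config):
        """A PIC-saturated unit's rate flattens against torque compared to
        a purely linear unit (oracle: generating rate functions)."""
        from dataclasses import replace
        from picpipe.datamodel import Condition, Phase
        from picpipe.simulate import simulate_trial
        from picpipe.smoothing import smooth_unit, ascending_phase
        from picpipe.torque import filter_torque
        from picpipe.metrics import unit_geometry

        rng = np.random.default_rng(21)
        # near-flat linear gain + strong early-saturating acceleration:
        # the rate barely rises past the insertion while torque keeps rising
        sat = replace(noiseless_pool_config, gain=0.05, pic_amplitude=4.0,
                      pic_saturation=1.5, units_per_trial=4)
        trial, trains, _ = simulate_trial(sat, "P1", Condition.CONTROL,
                                          Phase.BEFORE, rng)
        tq = filter_torque(trial)
        slopes_sat = [unit_geometry(smooth_unit(tr), tq).attenuation_slope
                      for tr in trains]

        rng = np.random.default_rng(21)
        lin = replace(noiseless_pool_config, units_per_trial=4)
        trial, trains, _ = simulate_trial(lin, "P1", Condition.CONTROL,
                                          Phase.BEFORE, rng)
        tq = filter_torque(trial)
        slopes_lin = [unit_geometry(smooth_unit(tr), tq).attenuation_slope
                      for tr in trains]
        assert np.mean(slopes_sat) < np.mean(slopes_lin)

    def test_too_few_samples_rejected(self):
        seg = segment(np.linspace(2, 6, 401), np.linspace(12, 16, 401))
        tq = self._torque(lambda t: 2 * t)
        with pytest.raises(ValueError):
            attenuation_slope(seg, insertion_time=5.99, torque=tq)


class TestThresholds:
    def test_torque_read_at_landmarks(self):
        """Recruitment at the moment torque hits 2 N*m of a 10 N*m peak
        reads 20% of peak."""
        tq = FilteredTorque(
            time=np.arange(0, 20, 0.01),
            torque_pct=np.asarray([2.0 * t for t in np.arange(0, 20, 0.01)]),
            fs=100.0,
        )
        sr = curve(10.0, 15.0, tent(10.0, 15.0, 8.0, 12.0))
        rec, derec, peak = thresholds(sr, tq)
        assert rec == pytest.approx(20.0)
        assert derec == pytest.approx(30.0)
        assert peak == pytest.approx(12.0)

    def test_recruited_at_onset_reads_zero(self):
        tq = FilteredTorque(
            time=np.arange(0, 20, 0.01),
            torque_pct=2.0 * np.arange(0, 20, 0.01),
            fs=100.0,
        )
        sr = curve(0.0, 10.0, tent(0.0, 10.0, 8.0, 12.0))
        rec, _, _ = thresholds(sr, tq)
        assert rec == pytest.approx(0.0, abs=1e-9)

    def test_simulator_threshold_recovery(self, noiseless_trial):
        """Noiseless simulated units: recovered recruitment threshold
        within 0.5% of the generator's drive threshold."""
        from picpipe.smoothing import smooth_unit
        from picpipe.torque import filter_torque

        trial, trains, truth = noiseless_trial
        tq = filter_torque(trial)
        by_id = {u.unit_id: u for u in truth.units}
        for tr in trains:
            rec, _, _ = thresholds(smooth_unit(tr), tq)
            assert rec == pytest.approx(by_id[tr.unit_id].theta, abs=0.5)

    def test_landmark_outside_torque_fatal(self):
        tq = FilteredTorque(time=np.arange(0, 5, 0.01),
                            torque_pct=np.zeros(500), fs=100.0)
        sr = curve(2.0, 8.0, tent(2.0, 8.0, 8.0, 12.0))
        with pytest.raises(ValueError):
            thresholds(sr, tq)
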